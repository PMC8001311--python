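"""Chromatogram peak-area quantification and the cDNA/gDNA confirmation rule.

A Sanger trace is modelled as four non-negative intensity series (one per
nucleotide channel) on a common scan axis, plus a base-call track giving
the scan center of each called base.  The editing efficiency at an assayed
position is the edited-channel peak area divided by the summed edited and
unedited peak areas, in percent; areas are trapezoidal integrals of a
channel over the base's scan window (midpoints to the neighbouring calls).

A site is a *dual peak* when the second-largest channel area in its window
reaches a configurable fraction of the largest (default 10%, a
conventional chromatogram heterozygosity cutoff).  An editing site is
*confirmed* when at least one cDNA sample shows a dual peak with nonzero
edited signal while the matched gDNA trace shows a clean single peak — a
gDNA dual peak instead indicates genomic heterozygosity or a SNP and
vetoes the site.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import NoSignalError

__all__ = [
    "BaseCall",
    "ChromatogramTrace",
    "ValidationResult",
    "peak_area",
    "editing_efficiency",
    "dual_peak",
    "confirm_site",
    "write_trace",
    "read_trace",
]

CHANNELS = ("A", "C", "G", "T")


class BaseCall(NamedTuple):
    base_index: int
    scan_center: float
    called_base: str


@dataclass
class ChromatogramTrace:
    """Four-channel intensity series with base calls for one amplicon."""

    intensities: Mapping[str, np.ndarray]  # channel -> series over scans
    basecalls: Sequence[BaseCall]
    source: str = "cDNA"  # "cDNA" | "gDNA"
    site_index: int | None = None

    def __post_init__(self):
        lengths = {len(np.asarray(v)) for v in self.intensities.values()}
        if len(lengths) != 1:
            raise ValueError("channel series have unequal lengths")
        self.intensities = {
            ch: np.asarray(self.intensities[ch], dtype=float) for ch in CHANNELS
        }
        for ch, series in self.intensities.items():
            if (series < 0).any():
                raise ValueError(f"negative intensity in channel {ch}")
        centers = [bc.scan_center for bc in self.basecalls]
        if any(b <= a for a, b in zip(centers, centers[1:])):
            raise ValueError("base-call scan centers must be strictly increasing")

    @property
    def n_scans(self) -> int:
        return len(next(iter(self.intensities.values())))

    def scans(self) -> np.ndarray:
        return np.arange(self.n_scans, dtype=float)

    def called_sequence(self) -> str:
        return "".join(bc.called_base for bc in self.basecalls)


def _call_window(trace: ChromatogramTrace, base_index: int) -> tuple[float, float]:
    """Scan window of a base: midpoints to neighbouring calls, clipped to the trace."""
    calls = trace.basecalls
    idx = {bc.base_index: i for i, bc in enumerate(calls)}
    if base_index not in idx:
        raise IndexError(f"base index {base_index} not in base-call track")
    i = idx[base_index]
    center = calls[i].scan_center
    lo = 0.0 if i == 0 else (calls[i - 1].scan_center + center) / 2.0
    hi = (
        float(trace.n_scans - 1)
        if i == len(calls) - 1
        else (center + calls[i + 1].scan_center) / 2.0
    )
    return max(lo, 0.0), min(hi, float(trace.n_scans - 1))


def peak_area(trace: ChromatogramTrace, base_index: int, channel: str) -> float:
    """Trapezoidal integral of one channel over the base's scan window.

    Windows truncated by the trace edge integrate the clipped portion only.
    """
    if channel not in CHANNELS:
        raise ValueError(f"channel must be one of {CHANNELS}, got {channel!r}")
    lo, hi = _call_window(trace, base_index)
    x = trace.scans()
    y = trace.intensities[channel]
    mask = (x >= lo) & (x <= hi)
    if mask.sum() < 2:
        return 0.0
    return float(np.trapezoid(y[mask], x[mask]))


def editing_efficiency(
    trace: ChromatogramTrace,
    base_index: int,
    edited_base: str,
    unedited_base: str,
) -> float:
    """Percent editing: 100 × edited area / (edited + unedited area).

    Only the two relevant channels enter the ratio; the other channels'
    signal (neighbouring peaks, baseline) is ignored.
    """
    if edited_base == unedited_base:
        raise ValueError("edited and unedited base must differ")
    edited = peak_area(trace, base_index, edited_base)
    unedited = peak_area(trace, base_index, unedited_base)
    if edited == 0.0 and unedited == 0.0:
        raise NoSignalError(
            f"no signal in channels {edited_base}/{unedited_base} at base {base_index}"
        )
    return 100.0 * edited / (edited + unedited)


def dual_peak(
    trace: ChromatogramTrace, base_index: int, secondary_min_frac: float = 0.10
) -> bool:
    """True when a secondary channel area reaches the threshold fraction
    of the primary channel area at the assayed base (≥, boundary counts)."""
    if not 0.0 < secondary_min_frac < 1.0:
        raise ValueError("secondary_min_frac must be in (0, 1)")
    areas = sorted(
        (peak_area(trace, base_index, ch) for ch in CHANNELS), reverse=True
    )
    if areas[0] <= 0.0:
        return False
    return areas[1] >= secondary_min_frac * areas[0]


@dataclass
class ValidationResult:
    """Outcome of the cDNA-vs-gDNA confirmation at one candidate site."""

    gene_id: str
    position: int
    feature: str
    efficiency_pct: dict[str, float]  # per sample, 0 when unedited
    confirmed: bool
    flag: str | None = None  # "heterozygous-or-SNP" when gDNA is dual


def confirm_site(
    cdna_traces: Mapping[str, ChromatogramTrace],
    gdna_trace: ChromatogramTrace,
    base_index: int,
    edited_base: str,
    unedited_base: str,
    secondary_min_frac: float = 0.10,
    gene_id: str = "NA",
    position: int = 0,
    feature: str = "NA",
) -> ValidationResult:
    """Apply the dual-peak confirmation rule across per-sample cDNA traces.

    Confirmed iff ≥1 cDNA sample shows a dual peak with nonzero edited
    signal AND the gDNA trace is single-peak.  A gDNA dual peak flags the
    site as genomic heterozygosity/SNP and rejects it regardless of cDNA.
    """
    gdna_dual = dual_peak(gdna_trace, base_index, secondary_min_frac)
    efficiency: dict[str, float] = {}
    any_edited = False
    for sample, trace in cdna_traces.items():
        if dual_peak(trace, base_index, secondary_min_frac):
            eff = editing_efficiency(trace, base_index, edited_base, unedited_base)
        else:
            eff = 0.0
        efficiency[sample] = eff
        if eff > 0.0:
            any_edited = True
    return ValidationResult(
        gene_id=gene_id,
        position=position,
        feature=feature,
        efficiency_pct=efficiency,
        confirmed=any_edited and not gdna_dual,
        flag="heterozygous-or-SNP" if gdna_dual else None,
    )


# ---------------------------------------------------------------------------
# columnar trace interchange (TSV)


def write_trace(trace: ChromatogramTrace, trace_path, calls_path) -> None:
    """Write the scan matrix and the base-call track as two TSV files."""
    scan_df = pd.DataFrame({"scan": np.arange(trace.n_scans, dtype=int)})
    for ch in CHANNELS:
        scan_df[ch] = trace.intensities[ch]
    scan_df.to_csv(trace_path, sep="\t", index=False, float_format="%.6g")
    calls_df = pd.DataFrame(trace.basecalls, columns=BaseCall._fields)
    calls_df.to_csv(calls_path, sep="\t", index=False)


def read_trace(
    trace_path, calls_path, source: str = "cDNA", site_index: int | None = None
) -> ChromatogramTrace:
    scan_df = pd.read_csv(trace_path, sep="\t")
    calls_df = pd.read_csv(calls_path, sep="\t")
    return ChromatogramTrace(
        intensities={ch: scan_df[ch].to_numpy(dtype=float) for ch in CHANNELS},
        basecalls=[
            BaseCall(int(r.base_index), float(r.scan_center), str(r.called_base))
            for r in calls_df.itertuples(index=False)
        ],
        source=source,
        site_index=site_index,
    )
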