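"""RNA–DNA difference calling from read pileups.

The stage chain implemented here: place clean reads on the reference by
minimum-mismatch ungapped search (at most 2 mismatches, unique best hit),
tally per-site base counts, emit conversion events where an alternative
base has enough read support, classify each event into one of the 12
transcript-strand conversion types, and remove events explained by known
genomic variants or by apparent homozygous polymorphisms (alternative
allele carried by ~100% of reads in every covered sample).

Conversion types are expressed on the transcript strand in the RNA
alphabet: a genomic T→C difference inside a plus-strand gene is a U-to-C
conversion; the same difference inside a minus-strand gene is A-to-G.
Coordinates are 1-based inclusive throughout.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidConfigError
from .read_qc import Read

__all__ = [
    "ConversionType",
    "classify_conversion",
    "genomic_pair",
    "Alignment",
    "place_reads",
    "build_pileup",
    "ConversionEvent",
    "EditingCandidate",
    "call_conversions",
    "filter_candidates",
    "spectrum_summary",
    "read_pileup_table",
    "write_pileup_table",
    "write_event_table",
]

BASES = "ACGT"
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


class ConversionType(enum.Enum):
    """The 12 ordered substitution classes over the RNA alphabet."""

    G_TO_A = "G-to-A"
    C_TO_U = "C-to-U"
    U_TO_C = "U-to-C"
    U_TO_A = "U-to-A"
    A_TO_G = "A-to-G"
    C_TO_A = "C-to-A"
    A_TO_U = "A-to-U"
    G_TO_U = "G-to-U"
    C_TO_G = "C-to-G"
    A_TO_C = "A-to-C"
    G_TO_C = "G-to-C"
    U_TO_G = "U-to-G"

    def __str__(self) -> str:
        return self.value

    @property
    def rna_ref(self) -> str:
        return self.value[0]

    @property
    def rna_alt(self) -> str:
        return self.value[-1]

    @classmethod
    def parse(cls, label: str) -> "ConversionType":
        """Parse a label; DNA spellings such as "A-to-T" are accepted."""
        norm = label.strip()
        parts = norm.split("-")
        if len(parts) == 3 and parts[1].lower() == "to":
            a = parts[0].upper().replace("T", "U")
            b = parts[2].upper().replace("T", "U")
            norm = f"{a}-to-{b}"
        for member in cls:
            if member.value == norm:
                return member
        raise ValueError(f"unknown conversion type: {label!r}")


def _complement(base: str) -> str:
    try:
        return _COMPLEMENT[base]
    except KeyError:
        raise ValueError(f"not a DNA base: {base!r}") from None


def classify_conversion(ref_base: str, alt_base: str, strand: str) -> ConversionType:
    """Map a genomic (ref, alt) substitution to its transcript-strand type.

    On "+" the DNA bases are transliterated T→U directly; on "−" both bases
    are complemented first (the transcript reads the other strand), then
    transliterated.
    """
    ref_base, alt_base = ref_base.upper(), alt_base.upper()
    if ref_base not in BASES or alt_base not in BASES:
        raise ValueError(f"bases must be A/C/G/T, got ({ref_base!r}, {alt_base!r})")
    if ref_base == alt_base:
        raise ValueError(f"ref and alt are both {ref_base!r}")
    if strand not in "+-":
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    if strand == "-":
        ref_base, alt_base = _complement(ref_base), _complement(alt_base)
    return ConversionType.parse(f"{ref_base}-to-{alt_base}")


def genomic_pair(conversion: ConversionType, strand: str) -> tuple[str, str]:
    """Inverse of :func:`classify_conversion`: genomic (ref, alt) DNA bases."""
    if strand not in "+-":
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    ref = conversion.rna_ref.replace("U", "T")
    alt = conversion.rna_alt.replace("U", "T")
    if strand == "-":
        ref, alt = _complement(ref), _complement(alt)
    return ref, alt


# ---------------------------------------------------------------------------
# read placement


@dataclass(frozen=True)
class Alignment:
    """An ungapped read placement (1-based start) with its mismatch count."""

    read_id: str
    contig: str
    start: int
    sequence: str
    mismatches: int

    @property
    def end(self) -> int:
        return self.start + len(self.sequence) - 1


class _ContigIndex:
    """Exact k-mer index over one contig for seed-and-verify placement.

    Splitting a read into ``max_mismatches + 1`` chunks guarantees (by
    pigeonhole) that every placement within the mismatch bound has at
    least one chunk matching exactly, so the candidate set is complete.
    """

    def __init__(self, name: str, sequence: str):
        self.name = name
        self.seq = sequence.upper()
        self.arr = np.frombuffer(self.seq.encode(), dtype=np.uint8)
        self._kmer_index: dict[int, dict[str, list[int]]] = {}

    def kmer_positions(self, k: int) -> dict[str, list[int]]:
        idx = self._kmer_index.get(k)
        if idx is None:
            idx = {}
            for i in range(len(self.seq) - k + 1):
                idx.setdefault(self.seq[i : i + k], []).append(i)
            self._kmer_index[k] = idx
        return idx

    def mismatches_at(self, read_arr: np.ndarray, start0: int) -> int:
        window = self.arr[start0 : start0 + len(read_arr)]
        return int((window != read_arr).sum())


def place_reads(
    reads: Iterable[Read],
    reference: Mapping[str, str],
    max_mismatches: int = 2,
) -> list[Alignment]:
    """Assign each read its unique minimum-mismatch ungapped placement.

    A read is left unplaced (omitted from the result) when no position has
    ≤ ``max_mismatches`` mismatches or when two positions tie for the
    minimum — ambiguous placements would corrupt the pileup.
    """
    if not reference or all(len(s) == 0 for s in reference.values()):
        raise ValueError("reference is empty")
    indexes = [_ContigIndex(name, seq) for name, seq in reference.items() if seq]

    n_chunks = max_mismatches + 1
    placements: list[Alignment] = []
    for read in reads:
        rl = len(read)
        if rl == 0:
            continue
        seq = read.sequence.upper()
        read_arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        chunk = rl // n_chunks
        best: tuple[int, str, int] | None = None  # (mismatches, contig, start0)
        tied = False
        if chunk == 0:
            continue
        for ci in indexes:
            if rl > len(ci.seq):
                continue
            kmers = ci.kmer_positions(chunk)
            candidates: set[int] = set()
            for j in range(n_chunks):
                off = j * chunk
                for pos in kmers.get(seq[off : off + chunk], ()):
                    start0 = pos - off
                    if 0 <= start0 <= len(ci.seq) - rl:
                        candidates.add(start0)
            for start0 in candidates:
                mm = ci.mismatches_at(read_arr, start0)
                if mm > max_mismatches:
                    continue
                key = (mm, ci.name, start0)
                if best is None or mm < best[0]:
                    best, tied = key, False
                elif mm == best[0]:
                    tied = True
        if best is not None and not tied:
            placements.append(
                Alignment(read.id, best[1], best[2] + 1, seq, best[0])
            )
    return placements


# ---------------------------------------------------------------------------
# pileup


def build_pileup(
    alignments: Mapping[str, Sequence[Alignment]],
    reference: Mapping[str, str],
) -> pd.DataFrame:
    """Tally per-position base counts for each sample.

    Returns a frame with columns ``contig, pos, ref`` plus one count
    column ``"<sample>:<base>"`` per sample and base (A/C/G/T/N), covering
    every position overlapped by at least one read in any sample.
    """
    samples = list(alignments)
    counts: dict[str, dict[str, np.ndarray]] = {}
    base_index = {b: i for i, b in enumerate("ACGTN")}
    for contig, seq in reference.items():
        counts[contig] = {
            s: np.zeros((len(seq), 5), dtype=np.int64) for s in samples
        }
    for sample, alns in alignments.items():
        for aln in alns:
            mat = counts[aln.contig][sample]
            start0 = aln.start - 1
            for offset, base in enumerate(aln.sequence):
                mat[start0 + offset, base_index.get(base, 4)] += 1
    rows = []
    for contig, seq in reference.items():
        per_sample = counts[contig]
        total = sum(per_sample[s] for s in samples)
        covered = np.nonzero(total.sum(axis=1) > 0)[0]
        for p0 in covered:
            row: dict = {"contig": contig, "pos": int(p0) + 1, "ref": seq[p0]}
            for s in samples:
                for b, bi in base_index.items():
                    row[f"{s}:{b}"] = int(per_sample[s][p0, bi])
            rows.append(row)
    columns = ["contig", "pos", "ref"] + [
        f"{s}:{b}" for s in samples for b in "ACGTN"
    ]
    return pd.DataFrame(rows, columns=columns)


def pileup_samples(pileup: pd.DataFrame) -> list[str]:
    """Sample names present in a pileup frame, in column order."""
    seen: list[str] = []
    for col in pileup.columns:
        if ":" in col:
            s = col.split(":")[0]
            if s not in seen:
                seen.append(s)
    return seen


# ---------------------------------------------------------------------------
# conversion events and candidates


@dataclass(frozen=True)
class ConversionEvent:
    """A called RNA–DNA difference at one site, with per-sample support."""

    contig: str
    position: int  # 1-based
    ref: str
    alt: str
    conversion: ConversionType
    strand: str
    gene_id: str
    support: Mapping[str, int]  # alt-carrying reads per sample
    depth: Mapping[str, int]  # A+C+G+T reads per sample
    frequency: Mapping[str, float]  # support/depth; NaN at depth 0

    @property
    def samples(self) -> list[str]:
        return list(self.support)


@dataclass(frozen=True)
class EditingCandidate(ConversionEvent):
    """A ConversionEvent that survived the SNP/polymorphism filters."""

    feature: str = "NA"
    description: str = ""


def _gene_lookup(gene_models: pd.DataFrame):
    """Per-contig gene spans, ordered by (start, gene_id) for overlap ties."""
    spans: dict[str, list[tuple[int, int, str, str]]] = {}
    if gene_models is None or len(gene_models) == 0:
        return spans
    grouped = gene_models.groupby(["contig", "gene_id"], sort=False)
    for (contig, gene_id), grp in grouped:
        strand = grp["strand"].iloc[0]
        spans.setdefault(contig, []).append(
            (int(grp["start"].min()), int(grp["end"].max()), strand, gene_id)
        )
    for contig in spans:
        spans[contig].sort(key=lambda t: (t[0], t[3]))
    return spans


def gene_at(spans, contig: str, position: int) -> tuple[str, str]:
    """(gene_id, strand) containing a position, or ("NA", "+") if intergenic."""
    for start, end, strand, gene_id in spans.get(contig, ()):
        if start <= position <= end:
            return gene_id, strand
    return "NA", "+"


def call_conversions(
    pileup: pd.DataFrame,
    gene_models: pd.DataFrame | None,
    min_alt_reads: int = 2,
    min_alt_frac: float = 0.05,
) -> list[ConversionEvent]:
    """Emit one event per (site, alt base) with enough support.

    A site/alt pair qualifies when, in at least one sample, the alt base is
    carried by ≥ ``min_alt_reads`` reads making up ≥ ``min_alt_frac`` of
    the A+C+G+T depth.  The support floor keeps single stray reads —
    overwhelmingly sequencing artifacts — out of the candidate list.
    """
    if min_alt_reads < 0 or min_alt_frac < 0:
        raise InvalidConfigError("thresholds must be non-negative")
    samples = pileup_samples(pileup)
    spans = _gene_lookup(gene_models)
    events: list[ConversionEvent] = []
    for row in pileup.to_dict("records"):
        ref = str(row["ref"]).upper()
        if ref not in BASES:
            continue
        cnt = {s: {b: int(row[f"{s}:{b}"]) for b in "ACGT"} for s in samples}
        depth = {s: sum(cnt[s].values()) for s in samples}
        for alt in BASES:
            if alt == ref:
                continue
            support = {s: int(cnt[s][alt]) for s in samples}
            freq = {
                s: (support[s] / depth[s]) if depth[s] > 0 else float("nan")
                for s in samples
            }
            passing = any(
                depth[s] > 0
                and support[s] >= min_alt_reads
                and freq[s] >= min_alt_frac
                for s in samples
            )
            if not passing:
                continue
            gene_id, strand = gene_at(spans, str(row["contig"]), int(row["pos"]))
            events.append(
                ConversionEvent(
                    contig=str(row["contig"]),
                    position=int(row["pos"]),
                    ref=ref,
                    alt=alt,
                    conversion=classify_conversion(ref, alt, strand),
                    strand=strand,
                    gene_id=gene_id,
                    support=support,
                    depth=depth,
                    frequency=freq,
                )
            )
    return events


def filter_candidates(
    events: Iterable[ConversionEvent],
    known_snps: Iterable[tuple[str, int]] | pd.DataFrame | None,
    mode: str = "both",
    polymorphism_min_frac: float = 0.999,
) -> list[EditingCandidate]:
    """Remove events explained by DNA rather than editing.

    Two rules, selectable via ``mode`` ("snp_list", "frequency", "both"):
    the blacklist rule drops events at known genomic-variant positions;
    the polymorphism rule drops events whose alt frequency is ~100%
    (≥ ``polymorphism_min_frac``, tolerating one error read at high depth)
    in **every** sample with nonzero depth.  Samples with zero depth carry
    no information and are ignored by the frequency rule.
    """
    if mode not in ("both", "snp_list", "frequency"):
        raise ValueError(f"unknown filter mode: {mode!r}")
    blacklist: set[tuple[str, int]] = set()
    if known_snps is not None and mode in ("both", "snp_list"):
        if isinstance(known_snps, pd.DataFrame):
            blacklist = {
                (str(c), int(p))
                for c, p in zip(known_snps["contig"], known_snps["position"])
            }
        else:
            blacklist = {(str(c), int(p)) for c, p in known_snps}
    out: list[EditingCandidate] = []
    for ev in events:
        if (ev.contig, ev.position) in blacklist:
            continue
        if mode in ("both", "frequency"):
            covered = [s for s in ev.samples if ev.depth[s] > 0]
            if covered and all(
                ev.frequency[s] >= polymorphism_min_frac for s in covered
            ):
                continue
        out.append(
            EditingCandidate(
                contig=ev.contig,
                position=ev.position,
                ref=ev.ref,
                alt=ev.alt,
                conversion=ev.conversion,
                strand=ev.strand,
                gene_id=ev.gene_id,
                support=ev.support,
                depth=ev.depth,
                frequency=ev.frequency,
            )
        )
    return out


def spectrum_summary(candidates: Sequence[ConversionEvent]) -> pd.DataFrame:
    """Per-conversion-type site and gene counts plus integer percentages.

    Percentages are ``round(100 * sites_of_type / total_sites)``, the
    precision at which such spectra are conventionally reported; they sum
    to 100 up to rounding.
    """
    index = [ct.value for ct in ConversionType]
    sites = {label: 0 for label in index}
    genes: dict[str, set[str]] = {label: set() for label in index}
    for cand in candidates:
        label = cand.conversion.value
        sites[label] += 1
        if cand.gene_id != "NA":
            genes[label].add(cand.gene_id)
    total = sum(sites.values())
    return pd.DataFrame(
        {
            "conversion": index,
            "n_sites": [sites[l] for l in index],
            "n_genes": [len(genes[l]) for l in index],
            "pct_sites": [
                round(100 * sites[l] / total) if total else 0 for l in index
            ],
        }
    )


# ---------------------------------------------------------------------------
# TSV interchange


def write_pileup_table(pileup: pd.DataFrame, path) -> None:
    pileup.to_csv(path, sep="\t", index=False)


def read_pileup_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def events_from_table(table: pd.DataFrame) -> list[EditingCandidate]:
    """Rebuild events/candidates from the VCF-like TSV written by
    :func:`write_event_table`."""
    samples = []
    for col in table.columns:
        if col.endswith(":support"):
            samples.append(col[: -len(":support")])
    out = []
    for row in table.to_dict("records"):
        support = {s: int(row[f"{s}:support"]) for s in samples}
        depth = {s: int(row[f"{s}:depth"]) for s in samples}
        freq = {}
        for s in samples:
            raw = row[f"{s}:frequency"]
            freq[s] = float("nan") if raw in ("NA", None) else float(raw)
        out.append(
            EditingCandidate(
                contig=str(row["contig"]),
                position=int(row["position"]),
                ref=str(row["ref"]),
                alt=str(row["alt"]),
                conversion=ConversionType.parse(str(row["conversion"])),
                strand=str(row["strand"]),
                gene_id=str(row["gene_id"]),
                support=support,
                depth=depth,
                frequency=freq,
                feature=str(row.get("feature", "NA")),
            )
        )
    return out


def write_event_table(events: Sequence[ConversionEvent], path) -> None:
    """Serialize events/candidates to a VCF-like TSV."""
    rows = []
    for ev in events:
        row = {
            "contig": ev.contig,
            "position": ev.position,
            "ref": ev.ref,
            "alt": ev.alt,
            "conversion": ev.conversion.value,
            "strand": ev.strand,
            "gene_id": ev.gene_id,
            "feature": getattr(ev, "feature", "NA"),
        }
        for s in ev.samples:
            row[f"{s}:support"] = ev.support[s]
            row[f"{s}:depth"] = ev.depth[s]
            f = ev.frequency[s]
            row[f"{s}:frequency"] = "NA" if f != f else f"{f:.6g}"
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
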