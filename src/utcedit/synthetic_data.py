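"""Seeded generators for reference, reads, pileups, and chromatogram traces.

The simulated study mirrors a two-timepoint seedling RNA-seq comparison:
two samples (default "d12" and "d20"), a compact genome of single-exon
genes with contiguous 5′UTR/CDS/3′UTR blocks on either strand, planted
U-to-C (or any other) editing sites whose alternative-base read support is
a per-site binomial draw at the planted efficiency, genomic SNPs carried
by 100% of reads in both samples, an i.i.d. per-base substitution error
channel, and cDNA/gDNA Sanger trace pairs where only the cDNA shows a dual
peak.  Every planted feature is recorded in a truth table so each pipeline
stage can be scored exactly.

Planted efficiencies default to the 20–80% range seen for validated sites;
coverage per site is Poisson in the direct pileup generator and emerges
from uniform read starts in the read generator.  All outputs are a pure
function of the configuration (including its seed).

Coordinates are 1-based inclusive in all tables and file formats.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import InvalidConfigError
from .pileup_variants import BASES, ConversionType, genomic_pair
from .read_qc import Read
from .sanger import CHANNELS, BaseCall, ChromatogramTrace

__all__ = [
    "EditSpec",
    "SynthConfig",
    "simulate_reference",
    "simulate_reads",
    "simulate_pileup",
    "simulate_trace_pair",
    "plan_random_edits",
    "simulate_validation_traces",
    "write_reference_fasta",
    "read_reference_fasta",
    "write_gene_models",
    "read_gene_models",
    "write_truth_table",
    "read_truth_table",
]

FEATURES = ("5'UTR", "CDS", "3'UTR")
_BASE_INDEX = {b: i for i, b in enumerate("ACGTN")}


@dataclass(frozen=True)
class EditSpec:
    """One planted editing site.

    ``offset`` is the 0-based genomic offset from the left end of the named
    feature interval; ``efficiency`` holds one value per configured sample.
    """

    gene_index: int
    feature: str
    offset: int
    conversion: ConversionType = ConversionType.U_TO_C
    efficiency: tuple[float, ...] = (0.5, 0.5)


@dataclass(frozen=True)
class SynthConfig:
    """Configuration fully determining every synthetic output."""

    seed: int = 0
    samples: tuple[str, ...] = ("d12", "d20")
    n_genes: int = 12
    gene_length: int = 600
    utr5_len: int = 100
    utr3_len: int = 150
    intergenic_len: int = 200
    coverage: float = 50.0
    error_rate: float = 0.001
    n_snp_sites: int = 8
    editing_plan: tuple[EditSpec, ...] = ()
    read_length: int = 100
    adapter_fraction: float = 0.0
    n_fraction_high: float = 0.0
    adapter_sequence: str = "AGATCGGAAGAGC"
    contig: str = "chrS"

    def __post_init__(self):
        for name in ("error_rate", "adapter_fraction", "n_fraction_high"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidConfigError(f"{name} must be in [0, 1], got {v}")
        if self.gene_length < self.utr5_len + self.utr3_len + 3:
            raise InvalidConfigError(
                "gene_length must leave at least one codon of CDS: "
                f"{self.gene_length} < {self.utr5_len} + {self.utr3_len} + 3"
            )
        if self.n_genes < 0 or self.n_snp_sites < 0:
            raise InvalidConfigError("counts must be non-negative")
        lengths = {
            "5'UTR": self.utr5_len,
            "CDS": self.gene_length - self.utr5_len - self.utr3_len,
            "3'UTR": self.utr3_len,
        }
        for spec in self.editing_plan:
            if spec.feature not in FEATURES:
                raise InvalidConfigError(f"unknown feature {spec.feature!r}")
            if not 0 <= spec.gene_index < self.n_genes:
                raise InvalidConfigError(
                    f"gene index {spec.gene_index} outside 0..{self.n_genes - 1}"
                )
            if not 0 <= spec.offset < lengths[spec.feature]:
                raise InvalidConfigError(
                    f"offset {spec.offset} outside feature {spec.feature} "
                    f"(length {lengths[spec.feature]})"
                )
            if len(spec.efficiency) != len(self.samples):
                raise InvalidConfigError(
                    "efficiency tuple length must match sample count"
                )
            if any(not 0.0 <= f <= 1.0 for f in spec.efficiency):
                raise InvalidConfigError("efficiencies must be in [0, 1]")

    @property
    def cds_len(self) -> int:
        return self.gene_length - self.utr5_len - self.utr3_len


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, 4, n, dtype=np.int8)


def _decode(idx: np.ndarray) -> str:
    return "".join("ACGTN"[i] for i in idx)


def simulate_reference(
    config: SynthConfig,
) -> tuple[dict[str, str], pd.DataFrame, pd.DataFrame]:
    """Generate the reference contig, gene models, and the truth table.

    Genes are laid out left to right with intergenic spacers; each gene is
    a contiguous 5′UTR/CDS/3′UTR block whose genomic order follows its
    (seeded random) strand.  Planted edits overwrite the reference base so
    that the site's genomic (ref, alt) realises the requested
    transcript-strand conversion; SNP positions are drawn from the
    remaining sites.  ``n_genes == 0`` yields an intergenic-only contig.
    """
    rng = np.random.default_rng(config.seed)
    L = (
        config.intergenic_len * (config.n_genes + 1)
        + config.gene_length * config.n_genes
    )
    ref_idx = _random_seq(rng, L)
    strands = ["+" if rng.random() < 0.5 else "-" for _ in range(config.n_genes)]

    gene_rows = []
    feature_start: dict[tuple[int, str], int] = {}  # (gene, feature) -> pos0
    for gi in range(config.n_genes):
        g_start0 = config.intergenic_len + gi * (
            config.gene_length + config.intergenic_len
        )
        gene_id = f"SYNG{gi + 1:04d}"
        strand = strands[gi]
        order = (
            ("5'UTR", config.utr5_len),
            ("CDS", config.cds_len),
            ("3'UTR", config.utr3_len),
        )
        if strand == "-":  # transcript runs right-to-left
            order = order[::-1]
        cursor = g_start0
        for feature, flen in order:
            feature_start[(gi, feature)] = cursor
            gene_rows.append(
                {
                    "contig": config.contig,
                    "start": cursor + 1,
                    "end": cursor + flen,
                    "strand": strand,
                    "feature": feature,
                    "gene_id": gene_id,
                }
            )
            cursor += flen
    genes = pd.DataFrame(
        gene_rows, columns=["contig", "start", "end", "strand", "feature", "gene_id"]
    )

    truth_rows = []
    edited_pos0: set[int] = set()
    for spec in config.editing_plan:
        strand = strands[spec.gene_index]
        pos0 = feature_start[(spec.gene_index, spec.feature)] + spec.offset
        if pos0 in edited_pos0:
            raise InvalidConfigError(f"duplicate planted position {pos0 + 1}")
        edited_pos0.add(pos0)
        g_ref, g_alt = genomic_pair(spec.conversion, strand)
        ref_idx[pos0] = _BASE_INDEX[g_ref]
        row = {
            "contig": config.contig,
            "position": pos0 + 1,
            "ref": g_ref,
            "alt": g_alt,
            "conversion": spec.conversion.value,
            "strand": strand,
            "is_snp": False,
        }
        for s, f in zip(config.samples, spec.efficiency):
            row[f"eff_{s}"] = f
        truth_rows.append(row)

    if config.n_snp_sites > 0:
        free = np.setdiff1d(np.arange(L), np.fromiter(edited_pos0, dtype=int))
        snp_pos0 = rng.choice(free, size=config.n_snp_sites, replace=False)
        snp_pos0.sort()
        for pos0 in snp_pos0:
            ref_b = "ACGT"[ref_idx[pos0]]
            alt_b = rng.choice([b for b in BASES if b != ref_b])
            row = {
                "contig": config.contig,
                "position": int(pos0) + 1,
                "ref": ref_b,
                "alt": str(alt_b),
                "conversion": "NA",
                "strand": "+",
                "is_snp": True,
            }
            for s in config.samples:
                row[f"eff_{s}"] = 0.0
            truth_rows.append(row)

    truth = pd.DataFrame(
        truth_rows,
        columns=["contig", "position", "ref", "alt", "conversion", "strand", "is_snp"]
        + [f"eff_{s}" for s in config.samples],
    )
    if len(truth):
        truth = truth.sort_values("position", kind="stable").reset_index(drop=True)
    reference = {config.contig: _decode(ref_idx)}
    return reference, genes, truth


def simulate_reads(
    reference: Mapping[str, str],
    truth: pd.DataFrame,
    config: SynthConfig,
) -> dict[str, list[Read]]:
    """Simulate per-sample FASTQ-ready reads from the reference and truth.

    Read starts are uniform; at a planted site with efficiency *f* each
    covering read independently carries the alternative base with
    probability *f* (so alt support is Binomial(coverage, f)); SNP sites
    put the alternative on every read in every sample.  The error channel
    substitutes each base i.i.d.; configured fractions of reads are then
    poly-N contaminated or adapter-tagged to exercise QC.  Read ids encode
    the sample, serial number, and true 1-based start.
    """
    if config.coverage <= 0:
        raise InvalidConfigError("coverage must be positive")
    seq = reference[config.contig]
    L = len(seq)
    rl = config.read_length
    if L < rl:
        raise InvalidConfigError(f"contig ({L} bp) shorter than read length {rl}")
    for p in truth["position"]:
        if not 1 <= int(p) <= L:
            raise InvalidConfigError(f"truth position {p} outside reference")
    ref_arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    lut = np.zeros(256, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        lut[ord(b)] = i
    ref_idx = lut[ref_arr]

    truth_sites = [
        (
            int(r["position"]) - 1,
            _BASE_INDEX[str(r["alt"])],
            bool(r["is_snp"]),
            {s: float(r[f"eff_{s}"]) for s in config.samples},
        )
        for r in truth.to_dict("records")
    ]

    out: dict[str, list[Read]] = {}
    qualities = tuple([40] * rl)
    for si, sample in enumerate(config.samples):
        rng = np.random.default_rng([config.seed, 100 + si])
        n_reads = int(round(config.coverage * L / rl))
        starts = rng.integers(0, L - rl + 1, n_reads)
        reads_idx = ref_idx[starts[:, None] + np.arange(rl)]

        for pos0, alt_i, is_snp, eff in truth_sites:
            covering = np.nonzero((starts <= pos0) & (pos0 < starts + rl))[0]
            if covering.size == 0:
                continue
            if is_snp:
                chosen = covering
            else:
                f = eff[sample]
                chosen = covering[rng.random(covering.size) < f] if f > 0 else covering[:0]
            reads_idx[chosen, pos0 - starts[chosen]] = alt_i

        if config.error_rate > 0:
            err = rng.random(reads_idx.shape) < config.error_rate
            shifts = rng.integers(1, 4, int(err.sum()), dtype=np.int8)
            reads_idx[err] = (reads_idx[err] + shifts) % 4

        if config.n_fraction_high > 0:
            contaminated = np.nonzero(rng.random(n_reads) < config.n_fraction_high)[0]
            k = max(int(math.ceil(0.2 * rl)), int(rl * 0.1) + 1)
            for ri in contaminated:
                cols = rng.choice(rl, size=k, replace=False)
                reads_idx[ri, cols] = 4

        if config.adapter_fraction > 0:
            tagged = np.nonzero(rng.random(n_reads) < config.adapter_fraction)[0]
            ad = np.array(
                [_BASE_INDEX[b] for b in config.adapter_sequence[:rl]], dtype=np.int8
            )
            reads_idx[np.ix_(tagged, np.arange(rl - len(ad), rl))] = ad

        reads = [
            Read(
                f"{sample}:r{i:06d}:{int(starts[i]) + 1}",
                _decode(reads_idx[i]),
                qualities,
            )
            for i in range(n_reads)
        ]
        out[sample] = reads
    return out


def simulate_pileup(
    reference: Mapping[str, str],
    truth: pd.DataFrame,
    config: SynthConfig,
    positions: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Directly simulate per-site base counts without reads.

    Per site and sample, depth is Poisson(coverage); at a planted editing
    site the alternative count is Binomial(depth, f) (all of depth at a
    SNP) and the error channel then relocates a Binomial(count,
    error_rate) portion of each allele's reads uniformly onto the other
    three bases.  ``positions`` (1-based) restricts the output; default is
    every reference position.
    """
    if config.coverage <= 0:
        raise InvalidConfigError("coverage must be positive")
    seq = reference[config.contig]
    if positions is None:
        positions = range(1, len(seq) + 1)
    truth_at = {
        int(r["position"]): r for r in truth.to_dict("records")
    }
    rng = np.random.default_rng([config.seed, 555])
    rows = []
    for pos in positions:
        ref_b = seq[pos - 1]
        row: dict = {"contig": config.contig, "pos": int(pos), "ref": ref_b}
        planted = truth_at.get(int(pos))
        for sample in config.samples:
            counts = {b: 0 for b in "ACGTN"}
            depth = int(rng.poisson(config.coverage))
            alt_b, alt_n = None, 0
            if planted is not None and depth > 0:
                alt_b = str(planted["alt"])
                if bool(planted["is_snp"]):
                    alt_n = depth
                else:
                    alt_n = int(rng.binomial(depth, float(planted[f"eff_{sample}"])))
            pools = [(ref_b, depth - alt_n)]
            if alt_b is not None:
                pools.append((alt_b, alt_n))
            for base, n in pools:
                if n <= 0:
                    continue
                n_err = (
                    int(rng.binomial(n, config.error_rate))
                    if config.error_rate > 0
                    else 0
                )
                counts[base] += n - n_err
                if n_err:
                    others = [b for b in BASES if b != base]
                    for b, k in zip(others, rng.multinomial(n_err, [1 / 3] * 3)):
                        counts[b] += int(k)
            for b in "ACGTN":
                row[f"{sample}:{b}"] = counts[b]
        rows.append(row)
    columns = ["contig", "pos", "ref"] + [
        f"{s}:{b}" for s in config.samples for b in "ACGTN"
    ]
    return pd.DataFrame(rows, columns=columns)


# ---------------------------------------------------------------------------
# chromatogram synthesis


def simulate_trace_pair(
    context: str,
    site_index: int,
    edited_base: str,
    efficiency: float,
    noise: float = 0.0,
    seed: int = 0,
    scans_per_base: int = 10,
    sigma: float = 1.8,
    amplitude: float = 1000.0,
) -> tuple[ChromatogramTrace, ChromatogramTrace]:
    """Synthesize a (cDNA, gDNA) trace pair for one assayed position.

    Each called base contributes a Gaussian peak (σ in scan units) on its
    channel, confined to the base's own scan window so neighbouring peaks
    never bleed into an adjacent call's area.  In the cDNA trace the
    assayed base splits its amplitude between the unedited channel
    (1 − efficiency) and the edited channel (efficiency); the gDNA trace is
    single-peak everywhere.  ``noise`` is the standard deviation of
    additive Gaussian intensity noise as a fraction of the full peak
    amplitude (intensities are clipped at zero).
    """
    if not 0.0 <= efficiency <= 1.0:
        raise ValueError(f"efficiency must be in [0, 1], got {efficiency}")
    if not 0 <= site_index < len(context):
        raise IndexError(f"site_index {site_index} outside context")
    edited_base = edited_base.upper()
    unedited_base = context[site_index].upper()
    if edited_base == unedited_base:
        raise ValueError("edited base equals the unedited (reference) base")

    n_scans = len(context) * scans_per_base
    x = np.arange(n_scans, dtype=float)

    def build(site_mix: dict[str, float], source: str, rng_key: int):
        channels = {ch: np.zeros(n_scans) for ch in CHANNELS}
        calls = []
        for i, base in enumerate(context.upper()):
            center = i * scans_per_base + scans_per_base / 2.0
            lo, hi = i * scans_per_base, (i + 1) * scans_per_base
            window = (x > lo) & (x < hi)  # strict: boundary scans stay zero
            shape = np.exp(-0.5 * ((x[window] - center) / sigma) ** 2)
            if i == site_index:
                mix = site_mix
            else:
                mix = {base: 1.0}
            for ch, weight in mix.items():
                if weight > 0:
                    channels[ch][window] += amplitude * weight * shape
            called = max(mix, key=mix.get)
            calls.append(BaseCall(i, center, called))
        if noise > 0:
            rng = np.random.default_rng([seed, rng_key])
            for ch in CHANNELS:
                channels[ch] = np.clip(
                    channels[ch] + rng.normal(0.0, noise * amplitude, n_scans),
                    0.0,
                    None,
                )
        return ChromatogramTrace(
            intensities=channels,
            basecalls=calls,
            source=source,
            site_index=site_index,
        )

    cdna = build(
        {unedited_base: 1.0 - efficiency, edited_base: efficiency}, "cDNA", 0
    )
    gdna = build({unedited_base: 1.0}, "gDNA", 1)
    return cdna, gdna


def _random_context(rng: np.random.Generator, unedited_base: str, flank: int = 5) -> str:
    left = _decode(rng.integers(0, 4, flank, dtype=np.int8))
    right = _decode(rng.integers(0, 4, flank, dtype=np.int8))
    return left + unedited_base + right


def simulate_validation_traces(
    validated_sites: pd.DataFrame,
    samples: tuple[str, ...] = ("d12", "d20"),
    noise: float = 0.0,
    seed: int = 0,
    n_decoys: int = 10,
    n_het_decoys: int = 2,
) -> list[dict]:
    """Build a Sanger assay set from a validated-sites ledger plus decoys.

    ``validated_sites`` uses the validation-table layout (columns
    ``gene_id, position, edited_site, eff_<sample>`` with efficiencies in
    percent).  For every row a per-sample cDNA trace is synthesized at the
    recorded efficiency alongside a clean gDNA trace.  Decoys are unedited
    sites (single-peak everywhere); heterozygous decoys show a 50% dual
    peak in gDNA *and* cDNA, which the confirmation rule must reject.
    """
    rng = np.random.default_rng([seed, 77])
    records: list[dict] = []
    for k, row in enumerate(validated_sites.to_dict("records")):
        context = _random_context(rng, "T")
        site_index = 5
        cdna = {}
        for si, sample in enumerate(samples):
            eff = float(row[f"eff_{sample}"]) / 100.0
            cd, gd = simulate_trace_pair(
                context, site_index, "C", eff, noise=noise, seed=seed * 1000 + k * 10 + si
            )
            cdna[sample] = cd
        records.append(
            {
                "gene_id": str(row["gene_id"]),
                "position": int(row["position"]),
                "feature": str(row.get("edited_site", "NA")),
                "context": context,
                "base_index": site_index,
                "edited_base": "C",
                "unedited_base": "T",
                "cdna": cdna,
                "gdna": gd,
                "true_eff": {s: float(row[f"eff_{s}"]) for s in samples},
                "kind": "edited",
            }
        )
    for d in range(n_decoys):
        context = _random_context(rng, "T")
        cdna = {}
        for si, sample in enumerate(samples):
            cd, gd = simulate_trace_pair(
                context, 5, "C", 0.0, noise=noise, seed=seed * 1000 + 900 + d * 10 + si
            )
            cdna[sample] = cd
        records.append(
            {
                "gene_id": f"DECOY{d + 1:03d}",
                "position": 1_000_000 + d,
                "feature": "NA",
                "context": context,
                "base_index": 5,
                "edited_base": "C",
                "unedited_base": "T",
                "cdna": cdna,
                "gdna": gd,
                "true_eff": {s: 0.0 for s in samples},
                "kind": "decoy",
            }
        )
    for h in range(n_het_decoys):
        context = _random_context(rng, "T")
        cdna = {}
        for si, sample in enumerate(samples):
            cd, _ = simulate_trace_pair(
                context, 5, "C", 0.5, noise=noise, seed=seed * 1000 + 990 + h * 10 + si
            )
            cdna[sample] = cd
        het_gdna, _ = simulate_trace_pair(
            context, 5, "C", 0.5, noise=noise, seed=seed * 1000 + 995 + h
        )
        het_gdna.source = "gDNA"
        records.append(
            {
                "gene_id": f"HETSNP{h + 1:03d}",
                "position": 2_000_000 + h,
                "feature": "NA",
                "context": context,
                "base_index": 5,
                "edited_base": "C",
                "unedited_base": "T",
                "cdna": cdna,
                "gdna": het_gdna,
                "true_eff": {s: 0.0 for s in samples},
                "kind": "het-decoy",
            }
        )
    return records


def plan_random_edits(
    config: SynthConfig,
    n_sites: int,
    efficiency_range: tuple[float, float] = (0.2, 0.8),
    conversion: ConversionType = ConversionType.U_TO_C,
    seed: int | None = None,
) -> tuple[EditSpec, ...]:
    """Draw ``n_sites`` distinct planted edits across the configured genes.

    Efficiencies are uniform per sample in ``efficiency_range`` (default
    the 20–80% band of validated sites).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    lengths = {"5'UTR": config.utr5_len, "CDS": config.cds_len, "3'UTR": config.utr3_len}
    capacity = config.n_genes * sum(lengths.values())
    if n_sites > capacity:
        raise InvalidConfigError(f"cannot place {n_sites} sites in {capacity} bases")
    chosen: set[tuple[int, str, int]] = set()
    specs: list[EditSpec] = []
    while len(specs) < n_sites:
        gi = int(rng.integers(0, config.n_genes))
        feature = FEATURES[int(rng.integers(0, 3))]
        offset = int(rng.integers(0, lengths[feature]))
        key = (gi, feature, offset)
        if key in chosen:
            continue
        chosen.add(key)
        eff = tuple(
            float(rng.uniform(*efficiency_range)) for _ in config.samples
        )
        specs.append(EditSpec(gi, feature, offset, conversion, eff))
    return tuple(specs)


# ---------------------------------------------------------------------------
# file interchange


def write_fastq_dict(reads: Mapping[str, Sequence[Read]], outdir) -> None:
    """Write one ``reads_<sample>.fastq`` per sample into a directory."""
    from pathlib import Path

    from .read_qc import write_fastq

    for sample, rr in reads.items():
        write_fastq(rr, Path(outdir) / f"reads_{sample}.fastq")


def write_reference_fasta(reference: Mapping[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in reference.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_reference_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_gene_models(genes: pd.DataFrame, path) -> None:
    genes.to_csv(path, sep="\t", index=False)


def read_gene_models(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_truth_table(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
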