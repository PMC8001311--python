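"""End-to-end orchestration: simulate → QC → place/pileup → call → filter
→ annotate → validate → report.

Every stage is a pure function of its inputs and the configuration, so two
runs with the same config produce byte-identical output files; the run
manifest records the seed, package version, parameters, and per-stage
counts.  The Sanger stage stands in for the wet-lab assay: for each
surviving candidate it synthesizes the cDNA/gDNA trace pair from the
planted truth (efficiency 0 for false positives) and applies the
dual-peak confirmation rule.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .annotate import annotate_candidates, utr_fraction, write_candidate_table
from .errors import InvalidConfigError, PipelineError
from .pileup_variants import (
    build_pileup,
    call_conversions,
    filter_candidates,
    place_reads,
    spectrum_summary,
    write_event_table,
    write_pileup_table,
)
from .read_qc import QcParams, filter_read, write_fastq
from .sanger import confirm_site
from .synthetic_data import (
    EditSpec,
    SynthConfig,
    plan_random_edits,
    read_gene_models,
    read_reference_fasta,
    simulate_reads,
    simulate_reference,
    simulate_trace_pair,
    write_gene_models,
    write_reference_fasta,
    write_truth_table,
)

log = logging.getLogger("utcedit")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """All knobs for one reproducible pipeline run."""

    outdir: str = "utcedit_run"
    seed: int = 0
    synth: SynthConfig = field(default_factory=SynthConfig)
    n_random_edits: int = 0  # extra sites drawn on top of synth.editing_plan
    qc: QcParams = field(default_factory=QcParams)
    max_mismatches: int = 2
    min_alt_reads: int = 2
    min_alt_frac: float = 0.05
    polymorphism_min_frac: float = 0.999
    filter_mode: str = "both"
    secondary_min_frac: float = 0.10
    trace_noise: float = 0.0
    reference_fasta: str | None = None  # optional pre-existing inputs
    gene_models: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        synth_raw = raw.pop("synth", {})
        plan = tuple(
            EditSpec(
                gene_index=int(e["gene_index"]),
                feature=str(e["feature"]),
                offset=int(e["offset"]),
                efficiency=tuple(float(x) for x in e.get("efficiency", (0.5, 0.5))),
            )
            for e in synth_raw.pop("editing_plan", [])
        )
        seed = int(raw.get("seed", 0))
        synth = SynthConfig(
            seed=int(synth_raw.pop("seed", seed)),
            editing_plan=plan,
            **{
                k: tuple(v) if k == "samples" else v
                for k, v in synth_raw.items()
            },
        )
        qc = QcParams(**raw.pop("qc", {}))
        cfg = cls(synth=synth, qc=qc, **raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for name in ("reference_fasta", "gene_models"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise InvalidConfigError(f"{name} path does not exist: {p}")
        if (self.reference_fasta is None) != (self.gene_models is None):
            raise InvalidConfigError(
                "reference_fasta and gene_models must be provided together"
            )
        if not 0.0 < self.secondary_min_frac < 1.0:
            raise InvalidConfigError("secondary_min_frac must be in (0, 1)")


def _manifest_params(config: PipelineConfig) -> dict:
    params = asdict(config)
    # locations are not parameters: identical runs into different
    # directories must produce identical manifests
    for key in ("outdir", "reference_fasta", "gene_models"):
        params.pop(key, None)
    params["synth"]["editing_plan"] = [
        {**asdict(e), "conversion": e.conversion.value}
        for e in config.synth.editing_plan
    ]
    return params


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages into ``config.outdir``; returns the manifest dict.

    Outputs: reference/annotation/truth, raw and clean FASTQ per sample,
    QC report, pileup, events, candidate table (ledger layout), conversion
    spectrum, validation table, and ``manifest.json``.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, object] = {}

    synth = config.synth
    if config.n_random_edits > 0:
        extra = plan_random_edits(synth, config.n_random_edits)
        synth = replace(synth, editing_plan=synth.editing_plan + extra)

    # -- simulate ----------------------------------------------------------
    stage = "simulate"
    try:
        if config.reference_fasta is not None:
            reference = read_reference_fasta(config.reference_fasta)
            genes = read_gene_models(config.gene_models)
            truth = pd.DataFrame(
                columns=["contig", "position", "ref", "alt", "conversion",
                         "strand", "is_snp"]
                + [f"eff_{s}" for s in synth.samples]
            )
        else:
            reference, genes, truth = simulate_reference(synth)
        write_reference_fasta(reference, outdir / "reference.fasta")
        write_gene_models(genes, outdir / "gene_models.tsv")
        write_truth_table(truth, outdir / "truth.tsv")
        snps = truth[truth["is_snp"]][["contig", "position", "ref", "alt"]]
        snps.to_csv(outdir / "known_snps.tsv", sep="\t", index=False)
        reads = simulate_reads(reference, truth, synth)
        for sample, rr in reads.items():
            write_fastq(rr, outdir / f"reads_{sample}.fastq")
        counts["planted_edits"] = int((~truth["is_snp"]).sum())
        counts["planted_snps"] = int(truth["is_snp"].sum())
        counts["raw_reads"] = {s: len(r) for s, r in reads.items()}
        log.info("simulate: %s", counts["raw_reads"])
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise PipelineError(stage, str(exc)) from exc

    # -- qc ----------------------------------------------------------------
    stage = "qc"
    try:
        clean: dict[str, list] = {}
        qc_rows = []
        for sample, rr in reads.items():
            kept = []
            reasons: dict[str, int] = {}
            for read in rr:
                decision = filter_read(read, config.qc)
                if decision.keep:
                    kept.append(read)
                else:
                    reasons[decision.reason] = reasons.get(decision.reason, 0) + 1
            clean[sample] = kept
            write_fastq(kept, outdir / f"clean_{sample}.fastq")
            qc_rows.append(
                {
                    "sample": sample,
                    "total": len(rr),
                    "kept": len(kept),
                    "discarded_adapter": reasons.get("adapter", 0),
                    "discarded_n_fraction": reasons.get("n-fraction", 0),
                    "discarded_low_quality": reasons.get("low-quality", 0),
                    "discarded_empty": reasons.get("empty", 0),
                }
            )
        pd.DataFrame(qc_rows).to_csv(outdir / "qc_report.tsv", sep="\t", index=False)
        counts["clean_reads"] = {s: len(r) for s, r in clean.items()}
        log.info("qc: kept %s", counts["clean_reads"])
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    # -- place + pileup ----------------------------------------------------
    stage = "pileup"
    try:
        alignments = {
            s: place_reads(rr, reference, config.max_mismatches)
            for s, rr in clean.items()
        }
        counts["placed_reads"] = {s: len(a) for s, a in alignments.items()}
        pileup = build_pileup(alignments, reference)
        write_pileup_table(pileup, outdir / "pileup.tsv")
        counts["pileup_sites"] = int(len(pileup))
        log.info("pileup: %d covered sites", len(pileup))
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    # -- call + filter -----------------------------------------------------
    stage = "call"
    try:
        events = call_conversions(
            pileup, genes, config.min_alt_reads, config.min_alt_frac
        )
        write_event_table(events, outdir / "events.tsv")
        known = {(r["contig"], int(r["position"])) for r in snps.to_dict("records")}
        candidates = filter_candidates(
            events, known, config.filter_mode, config.polymorphism_min_frac
        )
        candidates = annotate_candidates(candidates, genes)
        write_event_table(candidates, outdir / "candidates.tsv")
        samples = list(synth.samples)
        ledger = pd.DataFrame(
            {
                "s_no": range(1, len(candidates) + 1),
                "position": [c.position for c in candidates],
                **{
                    f"reads_{s}": [c.support[s] for c in candidates]
                    for s in samples
                },
                "gene_id": [c.gene_id for c in candidates],
                "description": [c.description or "-" for c in candidates],
            }
        )
        write_candidate_table(ledger, outdir / "candidate_ledger.tsv")
        spectrum = spectrum_summary(candidates)
        spectrum.to_csv(outdir / "spectrum.tsv", sep="\t", index=False)
        frac = utr_fraction(candidates)
        counts["events"] = len(events)
        counts["candidates"] = len(candidates)
        counts["utr_fraction"] = None if frac is None else round(frac, 4)
        log.info(
            "call: %d events, %d candidates after SNP/polymorphism filters",
            len(events), len(candidates),
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    # -- validate ----------------------------------------------------------
    stage = "validate"
    try:
        truth_at = {
            int(r["position"]): r for r in truth.to_dict("records")
        }
        val_rows = []
        confirmed = 0
        for i, cand in enumerate(candidates, start=1):
            planted = truth_at.get(cand.position)
            context_start = max(0, cand.position - 1 - 5)
            context = reference[cand.contig][context_start : context_start + 11]
            site_index = cand.position - 1 - context_start
            cdna = {}
            for si, sample in enumerate(samples):
                eff = (
                    float(planted[f"eff_{sample}"])
                    if planted is not None and not bool(planted["is_snp"])
                    else 0.0
                )
                cd, gd = simulate_trace_pair(
                    context,
                    site_index,
                    cand.alt,
                    eff,
                    noise=config.trace_noise,
                    seed=config.seed * 10000 + i * 10 + si,
                )
                cdna[sample] = cd
            result = confirm_site(
                cdna,
                gd,
                site_index,
                edited_base=cand.alt,
                unedited_base=cand.ref,
                secondary_min_frac=config.secondary_min_frac,
                gene_id=cand.gene_id,
                position=cand.position,
                feature=cand.feature,
            )
            confirmed += result.confirmed
            row = {
                "s_no": i,
                "position": cand.position,
                "edited_site": cand.feature,
                "gene_id": cand.gene_id,
            }
            for sample in samples:
                row[f"eff_{sample}"] = f"{result.efficiency_pct[sample]:.2f}"
            row["confirmed"] = str(result.confirmed).lower()
            row["flag"] = result.flag or "-"
            val_rows.append(row)
        pd.DataFrame(val_rows).to_csv(
            outdir / "validation.tsv", sep="\t", index=False
        )
        counts["confirmed_sites"] = confirmed
        log.info("validate: %d of %d candidates confirmed", confirmed, len(candidates))
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    manifest = {
        "package": "utcedit",
        "version": __version__,
        "seed": config.seed,
        "parameters": _manifest_params(config),
        "counts": counts,
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest
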