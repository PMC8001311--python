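"""Feature annotation of candidate sites and ledger (candidate table) I/O.

Every genomic position receives exactly one label: the containing 5′UTR,
CDS, or 3′UTR interval of a gene model; "intron" when inside a gene span
but no feature interval; "intergenic" otherwise.  Overlapping genes are
resolved by taking the first gene by start coordinate (ties broken by
gene id) — gene models are expected to be non-overlapping per strand.

The package ships two transcribed ledgers under ``utcedit/data``: the
56-row candidate table (per-sample read support at each called site) and
the 7-row validated-sites table (per-sample peak-area editing efficiency
in percent).  They are kept verbatim, including internal inconsistencies,
which are catalogued in the accompanying ``errata.md``; code never
silently corrects the fixtures.
"""

from __future__ import annotations

from importlib import resources
from typing import Iterable, Sequence

import pandas as pd

from .errors import TableFormatError
from .pileup_variants import EditingCandidate

__all__ = [
    "annotate_feature",
    "annotate_candidates",
    "utr_fraction",
    "intersect_gene_list",
    "read_candidate_table",
    "write_candidate_table",
    "read_validation_table",
    "write_validation_table",
    "load_candidate_ledger",
    "load_validated_ledger",
    "load_ppr_genes",
    "normalize_feature",
]

UTR_FEATURES = ("5'UTR", "3'UTR")

_FEATURE_ALIASES = {
    "5' UTR": "5'UTR",
    "5'UTR": "5'UTR",
    "5UTR": "5'UTR",
    "3' UTR": "3'UTR",
    "3'UTR": "3'UTR",
    "3UTR": "3'UTR",
    "CDS": "CDS",
    "INTRON": "intron",
    "INTERGENIC": "intergenic",
}


def normalize_feature(label: str) -> str:
    key = label.strip().replace("′", "'").upper().replace("INTRON", "INTRON")
    return _FEATURE_ALIASES.get(key, _FEATURE_ALIASES.get(label.strip(), label.strip()))


def _interval_rows(gene_models: pd.DataFrame):
    rows = gene_models.sort_values(
        ["contig", "start", "gene_id"], kind="stable"
    ).to_dict("records")
    by_gene: dict[tuple[str, str], list[dict]] = {}
    for r in rows:
        by_gene.setdefault((r["contig"], r["gene_id"]), []).append(r)
    spans = []
    for (contig, gene_id), feats in by_gene.items():
        spans.append(
            {
                "contig": contig,
                "gene_id": gene_id,
                "start": min(int(f["start"]) for f in feats),
                "end": max(int(f["end"]) for f in feats),
                "features": feats,
            }
        )
    spans.sort(key=lambda s: (s["contig"], s["start"], s["gene_id"]))
    return spans


def annotate_feature(
    contig: str, position: int, gene_models: pd.DataFrame
) -> tuple[str, str]:
    """Label one position: (feature, gene_id); intergenic → ("intergenic", "NA")."""
    for span in _interval_rows(gene_models):
        if span["contig"] != contig:
            continue
        if span["start"] <= position <= span["end"]:
            for feat in span["features"]:
                if int(feat["start"]) <= position <= int(feat["end"]):
                    return normalize_feature(str(feat["feature"])), span["gene_id"]
            return "intron", span["gene_id"]
    return "intergenic", "NA"


def annotate_candidates(
    candidates: Sequence[EditingCandidate], gene_models: pd.DataFrame
) -> list[EditingCandidate]:
    """Fill the ``feature`` field of each candidate from the gene models."""
    spans = _interval_rows(gene_models)
    out = []
    for cand in candidates:
        feature, gene_id = "intergenic", "NA"
        for span in spans:
            if span["contig"] != cand.contig:
                continue
            if span["start"] <= cand.position <= span["end"]:
                gene_id = span["gene_id"]
                feature = "intron"
                for feat in span["features"]:
                    if int(feat["start"]) <= cand.position <= int(feat["end"]):
                        feature = normalize_feature(str(feat["feature"]))
                        break
                break
        out.append(
            EditingCandidate(
                contig=cand.contig,
                position=cand.position,
                ref=cand.ref,
                alt=cand.alt,
                conversion=cand.conversion,
                strand=cand.strand,
                gene_id=cand.gene_id if cand.gene_id != "NA" else gene_id,
                support=cand.support,
                depth=cand.depth,
                frequency=cand.frequency,
                feature=feature,
                description=cand.description,
            )
        )
    return out


def utr_fraction(
    candidates: Iterable, exclude_intergenic: bool = False
) -> float | None:
    """Fraction of candidates annotated to a UTR (5′ or 3′).

    Accepts candidates (with a ``feature`` attribute) or plain feature
    labels.  Returns None when the denominator is empty.
    """
    labels = [
        normalize_feature(getattr(c, "feature", c) if not isinstance(c, str) else c)
        for c in candidates
    ]
    if exclude_intergenic:
        labels = [l for l in labels if l != "intergenic"]
    if not labels:
        return None
    return sum(1 for l in labels if l in UTR_FEATURES) / len(labels)


def intersect_gene_list(
    candidate_gene_ids: Iterable[str], gene_list: Iterable[str]
) -> list[str]:
    """Case-normalized, sorted intersection of candidate genes with a list."""
    cands = {str(g).strip().upper() for g in candidate_gene_ids}
    listed = {str(g).strip().upper() for g in gene_list}
    return sorted(cands & listed)


# ---------------------------------------------------------------------------
# ledger I/O — candidate table (read-support) and validation table (efficiency)

CANDIDATE_COLUMNS = ("s_no", "position", "reads_d12", "reads_d20", "gene_id", "description")
VALIDATION_COLUMNS = (
    "s_no",
    "position",
    "edited_site",
    "gene_id",
    "eff_d12",
    "eff_d20",
    "encoded_protein",
)


def _parse_table(path, columns, int_cols, float_cols) -> pd.DataFrame:
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise TableFormatError("empty table", 1)
    header = lines[0].split("\t")
    if tuple(header) != tuple(columns):
        raise TableFormatError(
            f"expected columns {list(columns)}, found {header}", 1
        )
    rows = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != len(columns):
            raise TableFormatError(
                f"expected {len(columns)} fields, found {len(fields)}", lineno
            )
        row = dict(zip(columns, fields))
        for col in int_cols:
            try:
                row[col] = int(row[col])
            except ValueError:
                raise TableFormatError(
                    f"column {col!r}: not an integer: {row[col]!r}", lineno
                ) from None
        for col in float_cols:
            # validated for parseability but kept verbatim so the ledger
            # round-trips byte-for-byte ("77.30" must not become "77.3")
            try:
                float(row[col])
            except ValueError:
                raise TableFormatError(
                    f"column {col!r}: not a number: {row[col]!r}", lineno
                ) from None
        rows.append(row)
    return pd.DataFrame(rows, columns=list(columns))


def read_candidate_table(path) -> pd.DataFrame:
    """Parse a candidate ledger (read-support layout); strict, with line numbers."""
    return _parse_table(
        path, CANDIDATE_COLUMNS, ("s_no", "position", "reads_d12", "reads_d20"), ()
    )


def write_candidate_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_validation_table(path) -> pd.DataFrame:
    """Parse a validated-sites ledger (per-sample efficiency in percent)."""
    return _parse_table(
        path, VALIDATION_COLUMNS, ("s_no", "position"), ("eff_d12", "eff_d20")
    )


def write_validation_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, lineterminator="\n")


def _data_path(name: str):
    return resources.files("utcedit") / "data" / name


def load_candidate_ledger() -> pd.DataFrame:
    """The packaged 56-row candidate table (per-sample read support)."""
    return read_candidate_table(_data_path("candidate_sites.tsv"))


def load_validated_ledger() -> pd.DataFrame:
    """The packaged 7-row validated-sites table (efficiency in percent)."""
    return read_validation_table(_data_path("validated_sites.tsv"))


def load_ppr_genes() -> list[str]:
    """The packaged list of expressed PPR genes showing nucleotide conversion."""
    text = _data_path("ppr_genes.txt").read_text()
    return [l.strip() for l in text.splitlines() if l.strip() and not l.startswith("#")]
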