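"""Generator correctness: determinism, planted-feature placement, and the
binomial read-support model."""

import numpy as np
import pandas as pd
import pytest

from utcedit.errors import InvalidConfigError
from utcedit.pileup_variants import ConversionType
from utcedit.synthetic_data import (
    EditSpec,
    SynthConfig,
    plan_random_edits,
    simulate_pileup,
    simulate_reads,
    simulate_reference,
    simulate_trace_pair,
    write_gene_models,
    write_reference_fasta,
)
from utcedit.sanger import dual_peak, peak_area


def _pileup_from_read_ids(reads, contig_len):
    """Independent pileup: read ids carry the true 1-based start position."""
    counts = {b: np.zeros(contig_len, dtype=int) for b in "ACGTN"}
    for read in reads:
        start = int(read.id.rsplit(":", 1)[1]) - 1
        for off, base in enumerate(read.sequence):
            counts[base][start + off] += 1
    return counts


def test_reference_is_deterministic(small_config, tmp_path):
    ref1, genes1, truth1 = simulate_reference(small_config)
    ref2, genes2, truth2 = simulate_reference(small_config)
    for tag, (r, g, t) in {"a": (ref1, genes1, truth1), "b": (ref2, genes2, truth2)}.items():
        write_reference_fasta(r, tmp_path / f"{tag}.fasta")
        write_gene_models(g, tmp_path / f"{tag}.tsv")
    assert (tmp_path / "a.fasta").read_bytes() == (tmp_path / "b.fasta").read_bytes()
    assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()
    pd.testing.assert_frame_equal(truth1, truth2)


def test_reads_are_deterministic(small_config, small_genome):
    reference, _, truth = small_genome
    r1 = simulate_reads(reference, truth, small_config)
    r2 = simulate_reads(reference, truth, small_config)
    assert r1 == r2


def test_no_genes_yields_intergenic_contig():
    config = SynthConfig(n_genes=0, n_snp_sites=0, intergenic_len=300, read_length=50)
    reference, genes, truth = simulate_reference(config)
    assert len(genes) == 0
    assert len(truth) == 0
    assert len(reference[config.contig]) == 300


def test_planted_site_lands_inside_named_feature(small_config, small_genome):
    """Interval containment: each truth position is inside the feature its
    plan entry named, for the right gene."""
    _, genes, truth = small_genome
    edits = truth[~truth["is_snp"]].reset_index(drop=True)
    assert len(edits) == len(small_config.editing_plan)
    by_pos = {}
    for spec in small_config.editing_plan:
        gene_id = f"SYNG{spec.gene_index + 1:04d}"
        feat = genes[(genes["gene_id"] == gene_id) & (genes["feature"] == spec.feature)]
        assert len(feat) == 1
        by_pos[(gene_id, spec.feature)] = (int(feat["start"].iloc[0]), int(feat["end"].iloc[0]))
        pos = int(feat["start"].iloc[0]) + spec.offset
        row = truth[truth["position"] == pos]
        assert len(row) == 1, "planted position resolves inside the named feature"
        assert int(feat["start"].iloc[0]) <= pos <= int(feat["end"].iloc[0])


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(gene_length=100, utr5_len=60, utr3_len=40),  # no room for CDS
        dict(error_rate=1.5),
        dict(editing_plan=(EditSpec(0, "3'UTR", 10, efficiency=(1.2, 0.5)),)),
        dict(editing_plan=(EditSpec(0, "3'UTR", 500, efficiency=(0.5, 0.5)),)),
        dict(editing_plan=(EditSpec(99, "CDS", 0, efficiency=(0.5, 0.5)),)),
    ],
)
def test_invalid_configs_rejected(kwargs):
    with pytest.raises(InvalidConfigError):
        SynthConfig(**kwargs)


def test_zero_coverage_rejected(small_config, small_genome):
    reference, _, truth = small_genome
    from dataclasses import replace

    with pytest.raises(InvalidConfigError):
        simulate_reads(reference, truth, replace(small_config, coverage=0.0))


def test_no_alt_reads_without_editing_or_errors(small_genome, small_config):
    """With all efficiencies 0 and error rate 0, reads match the reference
    everywhere except SNP sites."""
    from dataclasses import replace

    config = replace(
        small_config,
        editing_plan=tuple(
            EditSpec(e.gene_index, e.feature, e.offset, e.conversion, (0.0, 0.0))
            for e in small_config.editing_plan
        ),
    )
    reference, _, truth = simulate_reference(config)
    reads = simulate_reads(reference, truth, config)
    seq = reference[config.contig]
    snp_pos0 = {int(p) - 1 for p in truth[truth["is_snp"]]["position"]}
    for sample_reads in reads.values():
        counts = _pileup_from_read_ids(sample_reads, len(seq))
        for p0, ref_base in enumerate(seq):
            depth = sum(int(counts[b][p0]) for b in "ACGT")
            if p0 in snp_pos0:
                continue
            assert counts[ref_base][p0] == depth


def test_snp_sites_have_full_alt_support(small_genome, small_config):
    reference, _, truth = small_genome
    reads = simulate_reads(reference, truth, small_config)
    for sample_reads in reads.values():
        counts = _pileup_from_read_ids(sample_reads, len(reference[small_config.contig]))
        for row in truth[truth["is_snp"]].to_dict("records"):
            p0 = int(row["position"]) - 1
            depth = sum(int(counts[b][p0]) for b in "ACGT")
            assert depth > 0
            assert counts[row["alt"]][p0] == depth, "SNP alt fraction must be 1.0"


def test_alt_support_is_binomial_at_planted_efficiency():
    """A site at 29% efficiency and ~2231-fold coverage supports the
    alternative base with ~647 reads (within 3 binomial sigma)."""
    config = SynthConfig(
        seed=11,
        n_genes=1,
        gene_length=300,
        utr5_len=60,
        utr3_len=80,
        intergenic_len=100,
        coverage=2231.0,
        error_rate=0.0,
        n_snp_sites=0,
        editing_plan=(EditSpec(0, "CDS", 80, ConversionType.U_TO_C, (0.29, 0.19)),),
        read_length=80,
    )
    reference, _, truth = simulate_reference(config)
    reads = simulate_reads(reference, truth, config)
    p0 = int(truth["position"].iloc[0]) - 1
    alt = truth["alt"].iloc[0]
    counts = _pileup_from_read_ids(reads["d12"], len(reference[config.contig]))
    n = sum(int(counts[b][p0]) for b in "ACGT")
    observed = int(counts[alt][p0])
    expected = 0.29 * n
    sigma = np.sqrt(n * 0.29 * 0.71)
    assert abs(observed - expected) < 3 * sigma
    # and against the printed-scale anchor (total scaled to 2231 -> 647)
    assert abs(observed / n - 647 / 2231) < 3 * sigma / n


def test_per_site_conservation(small_genome, small_config):
    """alt + ref reads = realized coverage at every planted site (no errors)."""
    reference, _, truth = small_genome
    reads = simulate_reads(reference, truth, small_config)
    for sample_reads in reads.values():
        counts = _pileup_from_read_ids(sample_reads, len(reference[small_config.contig]))
        for row in truth.to_dict("records"):
            p0 = int(row["position"]) - 1
            depth = sum(int(counts[b][p0]) for b in "ACGTN")
            assert counts[row["ref"]][p0] + counts[row["alt"]][p0] == depth


def test_pileup_generator_recovers_frequency():
    """Direct pileup simulation: estimated alt fraction tracks the planted
    efficiency to binomial accuracy (smoke-scale; the full-depth sweep runs
    in the acceptance suite)."""
    config = SynthConfig(seed=3, n_genes=4, coverage=500.0, error_rate=0.0, n_snp_sites=0)
    plan = plan_random_edits(config, 20, seed=5)
    from dataclasses import replace

    config = replace(config, editing_plan=plan)
    reference, _, truth = simulate_reference(config)
    pileup = simulate_pileup(reference, truth, config, positions=list(truth["position"]))
    for prow, trow in zip(pileup.to_dict("records"), truth.to_dict("records")):
        for sample in config.samples:
            depth = sum(prow[f"{sample}:{b}"] for b in "ACGT")
            est = prow[f"{sample}:{trow['alt']}"] / depth
            f = float(trow[f"eff_{sample}"])
            assert abs(est - f) < 3 * np.sqrt(max(f * (1 - f), 0.01) / depth) + 1e-9


# ---------------------------------------------------------------------------
# chromatogram synthesis


def test_unedited_trace_pair_is_single_peak():
    cdna, gdna = simulate_trace_pair("GATCGTTGCCA", 5, "C", 0.0)
    assert not dual_peak(cdna, 5)
    assert not dual_peak(gdna, 5)


def test_half_edited_site_has_equal_peak_areas():
    cdna, _ = simulate_trace_pair("GATCGTTGCCA", 5, "C", 0.5)
    a_c = peak_area(cdna, 5, "C")
    a_t = peak_area(cdna, 5, "T")
    assert a_c > 0
    assert a_c == pytest.approx(a_t, rel=1e-12)


def test_trace_noise_is_seeded():
    a1, _ = simulate_trace_pair("GATCGTTGCCA", 5, "C", 0.3, noise=0.02, seed=9)
    a2, _ = simulate_trace_pair("GATCGTTGCCA", 5, "C", 0.3, noise=0.02, seed=9)
    b, _ = simulate_trace_pair("GATCGTTGCCA", 5, "C", 0.3, noise=0.02, seed=10)
    for ch in "ACGT":
        np.testing.assert_array_equal(a1.intensities[ch], a2.intensities[ch])
    assert any(
        not np.array_equal(a1.intensities[ch], b.intensities[ch]) for ch in "ACGT"
    )


@pytest.mark.parametrize("eff", [-0.1, 1.1])
def test_trace_efficiency_domain(eff):
    with pytest.raises(ValueError):
        simulate_trace_pair("GATCGTTGCCA", 5, "C", eff)
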