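"""Conversion-type algebra, read placement, pileup counting, event calling,
and the SNP/polymorphism filters."""

import itertools

import numpy as np
import pandas as pd
import pytest

from utcedit.pileup_variants import (
    Alignment,
    ConversionType,
    build_pileup,
    call_conversions,
    classify_conversion,
    events_from_table,
    filter_candidates,
    genomic_pair,
    place_reads,
    spectrum_summary,
    write_event_table,
)
from utcedit.read_qc import Read

COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
BASES = "ACGT"


def _read(seq, rid="r"):
    return Read(rid, seq, tuple([40] * len(seq)))


def _pileup_row(ref, d12, d20, contig="chrS", pos=100):
    row = {"contig": contig, "pos": pos, "ref": ref}
    for sample, counts in (("d12", d12), ("d20", d20)):
        for b in "ACGTN":
            row[f"{sample}:{b}"] = counts.get(b, 0)
    return row


# ---------------------------------------------------------------------------
# conversion algebra


def test_examples_from_transcript_strand_logic():
    assert classify_conversion("T", "C", "+") is ConversionType.U_TO_C
    assert classify_conversion("A", "G", "-") is ConversionType.U_TO_C
    assert classify_conversion("C", "T", "+") is ConversionType.C_TO_U


def test_classification_is_a_strand_aware_bijection():
    """Exhaustive 24-case oracle: plus-strand classification transliterates
    T to U; minus-strand equals plus-strand on complemented bases; at fixed
    strand the 12 DNA pairs map one-to-one onto the 12 types."""
    pairs = [(r, a) for r, a in itertools.product(BASES, BASES) if r != a]
    assert len(pairs) == 12
    for strand in "+-":
        images = [classify_conversion(r, a, strand) for r, a in pairs]
        assert len(set(images)) == 12
        assert set(images) == set(ConversionType)
    for r, a in pairs:
        # independent oracle for the minus strand
        expected = f"{COMP[r]}-to-{COMP[a]}".replace("T", "U").replace("Uo", "to")
        assert classify_conversion(r, a, "-").value == expected
        # round trip through the genomic projection
        for strand in "+-":
            conv = classify_conversion(r, a, strand)
            assert genomic_pair(conv, strand) == (r, a)


def test_parser_accepts_dna_spellings():
    assert ConversionType.parse("A-to-T") is ConversionType.A_TO_U
    assert ConversionType.parse("G-to-T") is ConversionType.G_TO_U
    assert ConversionType.parse("U-to-C") is ConversionType.U_TO_C


@pytest.mark.parametrize(
    "args", [("A", "A", "+"), ("A", "N", "+"), ("X", "C", "+"), ("A", "C", "*")]
)
def test_classify_rejects_bad_input(args):
    with pytest.raises(ValueError):
        classify_conversion(*args)


# ---------------------------------------------------------------------------
# placement


@pytest.fixture(scope="module")
def tiny_reference():
    rng = np.random.default_rng(42)
    seq = "".join(rng.choice(list(BASES), size=400))
    # append an exact repeat of one segment so ambiguity is guaranteed
    return {"c1": seq + seq[100:140] + seq[-60:]}


def test_exact_read_places_uniquely(tiny_reference):
    seq = tiny_reference["c1"]
    read = _read(seq[200:260])
    [aln] = place_reads([read], tiny_reference)
    assert (aln.start, aln.mismatches) == (201, 0)


def test_three_mismatches_unplaced(tiny_reference):
    seq = tiny_reference["c1"]
    window = list(seq[200:260])
    for i in (5, 25, 45):
        window[i] = COMP[window[i]]  # guaranteed substitutions
    assert place_reads([_read("".join(window))], tiny_reference) == []


def test_two_mismatches_placed(tiny_reference):
    seq = tiny_reference["c1"]
    window = list(seq[200:260])
    for i in (5, 45):
        window[i] = COMP[window[i]]
    [aln] = place_reads([_read("".join(window))], tiny_reference)
    assert (aln.start, aln.mismatches) == (201, 2)


def test_ambiguous_read_unplaced(tiny_reference):
    seq = tiny_reference["c1"]
    read = _read(seq[100:140])  # the repeated segment
    assert place_reads([read], tiny_reference) == []


def test_empty_reference_rejected():
    with pytest.raises(ValueError):
        place_reads([_read("ACGT" * 10)], {})


def test_placement_matches_bruteforce_oracle():
    """Randomized cross-check against an exhaustive mismatch scan."""
    rng = np.random.default_rng(7)
    ref = "".join(rng.choice(list(BASES), size=300))
    reads = []
    for i in range(40):
        start = int(rng.integers(0, 300 - 50))
        window = list(ref[start : start + 50])
        for j in rng.choice(50, size=int(rng.integers(0, 4)), replace=False):
            window[j] = BASES[(BASES.index(window[j]) + 1 + int(rng.integers(3))) % 4]
        reads.append(_read("".join(window), rid=f"r{i}"))

    def brute(seq):
        hits = []
        for s in range(len(ref) - len(seq) + 1):
            mm = sum(a != b for a, b in zip(ref[s : s + len(seq)], seq))
            if mm <= 2:
                hits.append((mm, s))
        if not hits:
            return None
        best = min(h[0] for h in hits)
        winners = [h for h in hits if h[0] == best]
        return winners[0] if len(winners) == 1 else None

    placed = {a.read_id: (a.mismatches, a.start - 1) for a in place_reads(reads, {"c": ref})}
    for read in reads:
        assert placed.get(read.id) == brute(read.sequence)


# ---------------------------------------------------------------------------
# pileup


def test_single_read_depth_one():
    ref = {"c": "ACGT" * 30}
    aln = Alignment("r1", "c", 1, ref["c"][:100], 0)
    pileup = build_pileup({"d12": [aln]}, ref)
    assert len(pileup) == 100
    depth = pileup[[f"d12:{b}" for b in "ACGT"]].sum(axis=1)
    assert (depth == 1).all()


def test_zero_reads_empty_stream():
    pileup = build_pileup({"d12": []}, {"c": "ACGT" * 10})
    assert len(pileup) == 0


def test_pileup_counts_sum_to_overlapping_reads():
    ref = {"c": "A" * 50}
    alns = [Alignment(f"r{i}", "c", s, "A" * 20, 0) for i, s in enumerate((1, 11, 11))]
    pileup = build_pileup({"d12": alns}, ref)
    at15 = pileup[pileup["pos"] == 15].iloc[0]
    assert at15["d12:A"] == 3
    at5 = pileup[pileup["pos"] == 5].iloc[0]
    assert at5["d12:A"] == 1


# ---------------------------------------------------------------------------
# calling and filtering


def test_called_event_support_and_frequency():
    """A T site with 647 C reads out of 2231 is a U-to-C event at 29%."""
    genes = pd.DataFrame(
        [{"contig": "chrS", "start": 50, "end": 150, "strand": "+",
          "feature": "3'UTR", "gene_id": "G1"}]
    )
    pileup = pd.DataFrame(
        [_pileup_row("T", {"T": 1584, "C": 647}, {"T": 1021, "C": 240})]
    )
    [event] = call_conversions(pileup, genes)
    assert event.conversion is ConversionType.U_TO_C
    assert event.support == {"d12": 647, "d20": 240}
    assert event.frequency["d12"] == pytest.approx(0.29, abs=0.001)
    assert event.gene_id == "G1"


def test_support_threshold_suppresses_single_reads():
    pileup = pd.DataFrame([_pileup_row("T", {"T": 99, "C": 1}, {"T": 100})])
    assert call_conversions(pileup, None, min_alt_reads=2) == []
    events = call_conversions(pileup, None, min_alt_reads=1, min_alt_frac=0.0)
    assert len(events) == 1


def test_all_reference_pileup_yields_nothing():
    pileup = pd.DataFrame([_pileup_row("A", {"A": 500}, {"A": 300})])
    assert call_conversions(pileup, None) == []


def test_intergenic_site_reported_on_plus_strand():
    pileup = pd.DataFrame([_pileup_row("T", {"T": 50, "C": 50}, {"T": 50, "C": 50})])
    [event] = call_conversions(pileup, None)
    assert (event.gene_id, event.strand) == ("NA", "+")
    assert event.conversion is ConversionType.U_TO_C


def _event(pos, f12, f20, d12=100, d20=100):
    pileup = pd.DataFrame(
        [
            _pileup_row(
                "T",
                {"T": round(d12 * (1 - f12)), "C": round(d12 * f12)},
                {"T": round(d20 * (1 - f20)), "C": round(d20 * f20)},
                pos=pos,
            )
        ]
    )
    events = call_conversions(pileup, None, min_alt_reads=1, min_alt_frac=0.0)
    [ev] = [e for e in events if e.alt == "C"]
    return ev


def test_filter_removes_blacklisted_and_fixed_variants():
    events = [
        _event(10, 0.29, 0.19),      # genuine candidate
        _event(20, 1.0, 1.0),        # homozygous polymorphism
        _event(30, 0.5, 0.5),        # on the SNP blacklist
        _event(40, 1.0, 0.0, d20=0),  # 100% in the only covered sample
    ]
    kept = filter_candidates(events, [("chrS", 30)])
    assert [c.position for c in kept] == [10]
    # the 29%/19% event survives untouched
    assert kept[0].frequency["d12"] == pytest.approx(0.29)
    assert len(kept) <= len(events)


def test_filter_modes():
    events = [_event(20, 1.0, 1.0), _event(30, 0.5, 0.5)]
    assert [c.position for c in filter_candidates(events, [("chrS", 30)], "snp_list")] == [20]
    assert [c.position for c in filter_candidates(events, [("chrS", 30)], "frequency")] == [30]
    with pytest.raises(ValueError):
        filter_candidates(events, None, "bogus")


def test_polymorphism_rule_tolerates_one_error_read():
    # 999/1000 alt in both samples is still "100%" at the default tolerance
    ev = _event(50, 0.999, 0.999, d12=1000, d20=1000)
    assert filter_candidates([ev], None) == []


# ---------------------------------------------------------------------------
# spectrum


def test_spectrum_reports_thirteen_percent_u_to_c():
    """79 U-to-C sites among 590 total is a 13% share."""
    candidates = [_event(1000 + i, 0.3, 0.3) for i in range(79)]
    pileup_rows = []
    for i in range(590 - 79):
        pileup_rows.append(_pileup_row("C", {"C": 70, "T": 30}, {"C": 100}, pos=i + 1))
    others = call_conversions(pd.DataFrame(pileup_rows), None)
    spectrum = spectrum_summary(candidates + others)
    assert spectrum["n_sites"].sum() == 590
    row = spectrum[spectrum["conversion"] == "U-to-C"].iloc[0]
    assert row["n_sites"] == 79
    assert row["pct_sites"] == 13
    assert abs(spectrum["pct_sites"].sum() - 100) <= 2  # integer rounding


def test_spectrum_empty_and_single_type():
    empty = spectrum_summary([])
    assert (empty["n_sites"] == 0).all() and (empty["pct_sites"] == 0).all()
    only = spectrum_summary([_event(5, 0.4, 0.4)])
    assert only[only["conversion"] == "U-to-C"]["pct_sites"].iloc[0] == 100


def test_event_table_round_trip(tmp_path):
    events = [_event(10, 0.29, 0.19), _event(40, 1.0, 0.0, d20=0)]
    path = tmp_path / "events.tsv"
    write_event_table(events, path)
    back = events_from_table(pd.read_csv(path, sep="\t"))
    assert [(e.position, e.support, e.depth) for e in back] == [
        (e.position, dict(e.support), dict(e.depth)) for e in events
    ]
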