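"""Barcode/allele co-occurrence counting and mutation-ratio arithmetic."""

import pytest
from Bio.Seq import reverse_complement

from blockamp import ReadSimConfig, simulate_reads
from blockamp.nanopore_count import (
    AlleleSignature,
    BarcodeTally,
    call_from_ratio,
    classify_read,
    mutation_ratio_percent,
    tally,
)


def make_read(template, barcode, allele="wt"):
    body = template.wt_seq if allele == "wt" else template.mu_seq
    return barcode.pad_seq + barcode.barcode_seq + body


def test_forward_mutant_read(panel, signature, nanopore_template):
    read = make_read(nanopore_template, panel[0], "mu")
    cls = classify_read(read, panel, signature)
    assert (cls.barcode_id, cls.allele, cls.orientation) == ("BC1", "mu", "forward")


def test_reverse_strand_read(panel, signature, nanopore_template):
    read = reverse_complement(make_read(nanopore_template, panel[0], "mu"))
    cls = classify_read(read, panel, signature)
    assert (cls.barcode_id, cls.allele, cls.orientation) == ("BC1", "mu", "reverse")
    # without both-strand search the read is invisible
    cls1 = classify_read(read, panel, signature, both_strands=False)
    assert cls1.barcode_id is None


def test_error_in_signature_leaves_read_unassigned(panel, signature, nanopore_template):
    read = make_read(nanopore_template, panel[1], "wt")
    pos = read.index(signature.wt_signature) + 3
    base = read[pos]
    corrupted = read[:pos] + ("G" if base != "G" else "C") + read[pos + 1:]
    cls = classify_read(corrupted, panel, signature)
    assert (cls.barcode_id, cls.allele) == ("BC2", "unassigned")


def test_two_barcodes_is_chimeric_ambiguous(panel, signature, nanopore_template):
    read = make_read(nanopore_template, panel[0]) + panel[1].barcode_seq
    cls = classify_read(read, panel, signature)
    assert cls.barcode_id is None
    assert cls.allele == "ambiguous"


def test_both_signatures_is_ambiguous(panel, signature, nanopore_template):
    read = make_read(nanopore_template, panel[2], "wt") + signature.mu_signature
    cls = classify_read(read, panel, signature)
    assert (cls.barcode_id, cls.allele) == ("BC3", "ambiguous")


def test_no_barcode_is_unassigned(panel, signature, nanopore_template):
    cls = classify_read(nanopore_template.wt_seq, panel, signature)
    assert (cls.barcode_id, cls.allele) == (None, "unassigned")


def test_mismatch_tolerant_mode_recovers_noisy_barcode(panel, signature,
                                                       nanopore_template):
    read = make_read(nanopore_template, panel[0], "mu")
    pos = read.index(panel[0].barcode_seq) + 5
    noisy = read[:pos] + ("A" if read[pos] != "A" else "T") + read[pos + 1:]
    assert classify_read(noisy, panel, signature).barcode_id is None
    cls = classify_read(noisy, panel, signature, max_mismatch=1)
    assert (cls.barcode_id, cls.allele) == ("BC1", "mu")


@pytest.mark.parametrize(
    "n_wt,n_mu,expected",
    [
        (986, 14, 1.4),
        (2000, 0, 0.0),
        (1999, 1, 0.1),   # 0.05 % rounds half-up
        (1, 1, 50.0),
        (0, 5, 100.0),
        (0, 0, None),
    ],
)
def test_mutation_ratio_rounding(n_wt, n_mu, expected):
    assert mutation_ratio_percent(n_wt, n_mu) == expected


def test_tally_counts_and_depth(panel, signature, nanopore_template):
    reads = (
        [make_read(nanopore_template, panel[0], "wt")] * 986
        + [make_read(nanopore_template, panel[0], "mu")] * 14
        + [make_read(nanopore_template, panel[1], "wt")] * 400
        + ["ACGT" * 50] * 5
    )
    result = tally(reads, panel, signature, min_reads=1000)
    bc1, bc2 = result["BC1"], result["BC2"]
    assert (bc1.n_wt, bc1.n_mu, bc1.ratio_percent) == (986, 14, 1.4)
    assert bc1.sufficient_depth
    assert (bc2.n_wt, bc2.ratio_percent, bc2.sufficient_depth) == (400, 0.0, False)
    assert result.n_unassigned == 5
    assert result.n_total == 1405


def test_tally_conservation_with_errors(panel, signature, nanopore_template):
    """Every read lands in exactly one bucket even at high error rates."""
    cfg = ReadSimConfig(n_reads=500, true_mu_fraction=0.3, sub_rate=0.05,
                        ins_rate=0.03, del_rate=0.03, seed=11)
    reads = [s for _, s, _ in simulate_reads(nanopore_template, panel[3], cfg)]
    result = tally(reads, panel, signature)
    bucketed = sum(
        t.n_wt + t.n_mu + t.n_ambiguous + t.n_barcode_only
        for t in result.barcodes
    )
    assert bucketed + result.n_unassigned + result.n_multi_barcode == 500


def test_tally_strand_invariance(panel, signature, nanopore_template):
    cfg = ReadSimConfig(n_reads=300, true_mu_fraction=0.2, seed=5)
    reads = [s for _, s, _ in simulate_reads(nanopore_template, panel[4], cfg)]
    flipped = [reverse_complement(s) for s in reads]
    a = tally(reads, panel, signature)
    b = tally(flipped, panel, signature)
    for ta, tb in zip(a.barcodes, b.barcodes):
        assert (ta.n_wt, ta.n_mu, ta.n_ambiguous, ta.n_barcode_only) == (
            tb.n_wt, tb.n_mu, tb.n_ambiguous, tb.n_barcode_only)


def _tally_of(ratio, depth_ok, n_wt=1000, n_mu=0):
    return BarcodeTally("BC1", n_wt, n_mu, 0, 0, ratio, depth_ok)


@pytest.mark.parametrize(
    "tally_obj,expected",
    [
        (_tally_of(1.4, True, 986, 14), "positive"),
        (_tally_of(0.0, True), "negative"),
        (_tally_of(25.0, False, 300, 100), "insufficient"),
        (_tally_of(None, False, 0, 0), "insufficient"),
    ],
)
def test_call_from_ratio(tally_obj, expected):
    assert call_from_ratio(tally_obj) == expected


def test_signature_validation():
    with pytest.raises(ValueError, match="exactly one"):
        AlleleSignature("ACGTA", "TGGTA")
    with pytest.raises(ValueError, match="equal length"):
        AlleleSignature("ACGTA", "ACGT")
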