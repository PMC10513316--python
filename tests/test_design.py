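"""Primer/blocker geometry around the SNV: regeneration of the published
panel, product-size enumeration, and the Tm-balance scoring heuristic."""

import random

import pytest
from Bio.Seq import reverse_complement

from blockamp.design import (
    SnvLocus,
    enumerate_candidates,
    make_allele_primer,
    make_blocker,
    rank_candidates,
    score_candidate,
)
from blockamp.thermo import Oligo


ALLELE_PRIMERS = [
    ("F4", 18, "downstream"),
    ("F5", 19, "downstream"),
    ("F6", 20, "downstream"),
    ("R1", 17, "upstream"),
    ("R2", 18, "upstream"),
    ("R3", 19, "upstream"),
]

BLOCKERS = [
    ("BF1", 21, "downstream"),
    ("BF2", 23, "downstream"),
    ("BF3", 25, "downstream"),
    ("BR1", 21, "upstream"),
    ("BR2", 23, "upstream"),
    ("BR3", 24, "upstream"),  # even length: SNV one base 5' of center
]


@pytest.mark.parametrize("name,length,orientation", ALLELE_PRIMERS)
def test_published_allele_primers_regenerate(table1, locus, name, length, orientation):
    primer = make_allele_primer(locus, length, orientation)
    assert primer.bases == table1[name].bases
    assert primer.role == "allele_primer"


@pytest.mark.parametrize("name,length,orientation", BLOCKERS)
def test_published_blockers_regenerate(table1, locus, name, length, orientation):
    blocker = make_blocker(locus, length, orientation)
    assert blocker.bases == table1[name].bases
    assert blocker.three_prime_phosphate


@pytest.mark.parametrize("orientation", ["upstream", "downstream"])
@pytest.mark.parametrize("length", [1, 2, 10, 18, 25])
def test_allele_primer_ends_on_mutant_base(locus, length, orientation):
    primer = make_allele_primer(locus, length, orientation)
    assert len(primer) == length
    three_prime = primer.bases[-1]
    expected = locus.mut_base if orientation == "downstream" else \
        reverse_complement(locus.mut_base)
    assert three_prime == expected
    assert three_prime != (locus.wt_base if orientation == "downstream"
                           else reverse_complement(locus.wt_base))


@pytest.mark.parametrize("orientation", ["upstream", "downstream"])
@pytest.mark.parametrize("length", [3, 5, 21, 24, 25])
def test_blocker_matches_wt_and_mismatches_mut_once(locus, length, orientation):
    blocker = make_blocker(locus, length, orientation)
    assert len(blocker) == length
    forward = (blocker.bases if orientation == "downstream"
               else reverse_complement(blocker.bases))
    assert forward in locus.wt_context
    # exactly one mismatch against the mutant sequence at the same position
    start = locus.wt_context.index(forward)
    mut_window = locus.mut_context[start:start + length]
    diffs = [i for i, (a, b) in enumerate(zip(forward, mut_window)) if a != b]
    assert len(diffs) == 1
    assert start + diffs[0] == len(locus.left_flank)


def test_minimal_centered_blocker(locus):
    b = make_blocker(locus, 3, "downstream")
    assert b.bases == locus.left_flank[-1] + locus.wt_base + locus.right_flank[0]


def test_length_one_allele_primer_is_the_mutant_base(locus):
    assert make_allele_primer(locus, 1, "downstream").bases == locus.mut_base


def test_flank_exhaustion_rejected():
    tiny = SnvLocus("ACGT", "T", "A", "GGCC")
    with pytest.raises(ValueError, match="flank"):
        make_allele_primer(tiny, 10, "downstream")
    with pytest.raises(ValueError, match="flank"):
        make_blocker(tiny, 15, "upstream")


def test_identical_alleles_rejected():
    with pytest.raises(ValueError, match="differ"):
        SnvLocus("ACGT", "T", "T", "GGCC")


def _opposites(table1, names):
    return [table1[n] for n in names]


def test_upstream_panel_has_27_combinations(table1, locus):
    cands = enumerate_candidates(
        locus, [17, 18, 19], [21, 23, 24],
        _opposites(table1, ["F1", "F2", "F3"]), orientation="upstream",
    )
    assert len(cands) == 27


def test_downstream_panel_has_45_combinations(table1, locus):
    cands = enumerate_candidates(
        locus, [18, 19, 20], [21, 23, 25],
        _opposites(table1, ["R4", "R5", "R6", "R7", "R8"]),
        orientation="downstream",
    )
    assert len(cands) == 45
    # every candidate regenerates published oligo sequences
    allele_seqs = {c.allele_primer.bases for c in cands}
    assert allele_seqs == {table1[n].bases for n in ("F4", "F5", "F6")}
    blocker_seqs = {c.blocker.bases for c in cands}
    assert blocker_seqs == {table1[n].bases for n in ("BF1", "BF2", "BF3")}


def test_candidate_count_is_product_of_sizes(table1, locus):
    rng = random.Random(0)
    for _ in range(20):
        na, nb, no = rng.randint(0, 3), rng.randint(0, 3), rng.randint(0, 3)
        cands = enumerate_candidates(
            locus,
            rng.sample(range(15, 22), na),
            rng.sample(range(19, 26), nb),
            _opposites(table1, rng.sample(["R4", "R5", "R6", "R7", "R8"], no)),
        )
        assert len(cands) == na * nb * no


def test_score_prefers_moderate_blocker_tm_gap(table1, locus):
    cands = enumerate_candidates(
        locus, [18], [21], _opposites(table1, ["R8"]))
    base = cands[0]
    near = base.__class__(**{**base.__dict__, "tm_blocker": base.tm_allele + 4})
    far = base.__class__(**{**base.__dict__, "tm_blocker": base.tm_allele + 15})
    assert score_candidate(near) > score_candidate(far)
    assert score_candidate(near) == score_candidate(near)  # deterministic


def test_hottest_blocker_is_penalized(table1, locus):
    """With the allele primer fixed, the coolest blocker of the family
    outranks the hottest -- matching the empirically selected set."""
    cands = enumerate_candidates(
        locus, [18], [21, 23, 25], _opposites(table1, ["R8"]))
    ranked = rank_candidates(cands)
    by_blocker = {c.blocker.bases: c for c in cands}
    bf1 = by_blocker[table1["BF1"].bases]
    bf3 = by_blocker[table1["BF3"].bases]
    assert bf1.score > bf3.score
    assert ranked[0].blocker.bases == table1["BF1"].bases


def test_empty_inputs_give_empty_output(locus):
    assert enumerate_candidates(locus, [], [21], []) == []
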