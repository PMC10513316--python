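"""Design and rank allele-primer / blocker combinations around the SNV.

Builds the built-in T>A locus, enumerates the downstream candidate panel
(three nested allele primers x three blockers x five opposite primers),
and prints the top combinations.  The score favours a blocker melting
about 5 degrees C above the allele primer and penalises the hottest
member of each family; every top-ranked combination pairs the coolest
blocker (BF1) with one of the two cooler allele primers (F4/F5) and
avoids the hottest primer F6 -- the same region of the design space the
bench screen converged on (F4 + BF1).
"""

from blockamp import enumerate_candidates, fixture_locus, load_table1, rank_candidates

table1 = load_table1()
locus = fixture_locus()

candidates = enumerate_candidates(
    locus,
    allele_lengths=[18, 19, 20],      # regenerate F4, F5, F6
    blocker_lengths=[21, 23, 25],     # regenerate BF1, BF2, BF3
    opposite_primers=[table1[n] for n in ("R4", "R5", "R6", "R7", "R8")],
    orientation="downstream",
)
print(f"{len(candidates)} candidate combinations\n")
print("rank  allele              blocker                    opposite  "
      "Tm(a)  Tm(b)  score")
for rank, c in enumerate(rank_candidates(candidates)[:8], start=1):
    print(f"{rank:>4}  {c.allele_primer.bases:<18}  {c.blocker.bases:<25}  "
          f"{c.opposite_primer.name:<8}  {c.tm_allele:5.1f}  {c.tm_blocker:5.1f}  "
          f"{c.score:6.2f}")
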