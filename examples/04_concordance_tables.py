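"""Summarise the two shipped verification tables against Sanger calls.

Loads the built-in call tables (38 urine-sediment samples), cross-
tabulates the Sanger call against the blocker-PCR call, and prints the
marginals.  All four discordant samples are Sanger-negative /
blocker-PCR-positive with sequencing ratios of 0.1-1.4% -- mutant
fractions below the ~15% detection floor of Sanger chromatograms, i.e.
the discordances are extra sensitivity, not false positives.
"""

from blockamp import discordance_pattern, load_table2, load_table3, summarize

records = load_table2() + load_table3()
s = summarize(records)

print(f"samples: {s.n_total}   concordant: {s.n_match}   "
      f"discordant: {s.n_discordant}")
print(f"Sanger positives: {s.n_sanger_pos}   new-method positives: {s.n_new_pos}")
print(f"discordant samples: {', '.join(s.discordant_ids)}")
lo, hi = s.ratio_range_discordant
print(f"discordant sequencing ratios: {lo}% - {hi}%")
print(f"lowest ratio among Sanger positives: {s.ratio_min_sanger_pos}%")

print("\n2x2 contingency (sanger, new method):")
for (sanger, new), n in discordance_pattern(records).items():
    print(f"  {sanger:>8} / {new:<8}  {n:>2}")
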