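"""Simulate the serial-dilution sensitivity experiment and fit it.

Mixes the mutant and wild-type standards to 9000 mutant copies/uL,
dilutes three-fold five times (9000 ... 37 copies), simulates triplicate
qPCR wells on the log-linear Ct response, and fits Ct against
log10(copies) over the specific wells.  A slope near -3.32 cycles/log10
means near-100% amplification efficiency; |r| close to 1 confirms the
quantitative range of the assay.
"""

from blockamp import (
    QpcrSimConfig,
    build_dilution_series,
    fit_ct_vs_logcopies,
    mix_standards,
    simulate_dilution_run,
)
from blockamp.synthetic_data import standard_mu, standard_wt

top = mix_standards(standard_mu(), standard_wt(), 0.5)
print(f"equal Mu/WT mix: {top.mutant_copies_per_uL:.0f} mutant copies/uL")

series = build_dilution_series(int(top.mutant_copies_per_uL), fold=3, steps=6)
print("dilution series:", series)

points = simulate_dilution_run(series, QpcrSimConfig(seed=42), replicates=3)
for copies in series:
    cts = [f"{p.ct:.1f}" for p in points if p.copies == copies and p.ct]
    print(f"  {copies:>5} copies -> Ct {', '.join(cts)}")

slope, intercept, r = fit_ct_vs_logcopies(points)
print(f"\nfit: Ct = {slope:.2f} * log10(copies) + {intercept:.2f}   (r = {r:.4f})")
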