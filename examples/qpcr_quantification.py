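"""Estimate amplification efficiency, Cq, relative template, and the LOD.

Simulates amplification curves for two starting-template amounts 100x apart,
fits each by the window-of-linearity method, and shows that the recovered
relative N0 ratio matches the spiked ratio. Then computes the theoretical
limit of detection at Cq = 40 from replicate dilution standards.
"""

import math

from gutreads.qpcr import fit_amplification, lod_at_cq40
from gutreads.synthetic import qpcr_fluorescence

for n0 in (1e-5, 1e-7):
    cycles, fluor = qpcr_fluorescence(n0=n0, efficiency=1.95, plateau=2.0)
    fit = fit_amplification(cycles, fluor, threshold=0.05)
    print(f"spiked N0 {n0:.0e}: E = {fit.efficiency:.4f}, "
          f"Cq = {fit.cq:.2f}, recovered N0 = {fit.n0:.3e}")
print(f"expected Cq shift for a 100x dilution: "
      f"{math.log(100) / math.log(1.95):.2f} cycles\n")

# dilution standards: Cq = 10 - 3.4 * log10(mass in pg), three replicates
standards = [[(lm, 10 - 3.4 * lm + dev) for lm in (2.0, 1.0, 0.0, -1.0)]
             for dev in (-0.15, 0.0, 0.15)]
lod = lod_at_cq40(standards)
print(f"LOD at Cq=40: geometric mean {lod.geometric_mean:.2e} pg, "
      f"upper 95% CI {lod.upper_ci95:.2e} pg (n={lod.n})")
# The efficiency near 2 means even sub-picogram template crosses threshold
# within 40 cycles; the upper CI quantifies between-replicate uncertainty.
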