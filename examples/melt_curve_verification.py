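"""Verify amplicon identity from qPCR melt curves.

Simulates three technical replicates of a product melting at 76.5 degC plus
a wrong-product control melting at 79.2 degC, computes -dF/dT, and applies
the replicate-consensus call against the expected Tm: positive iff >=2
replicates show a peak more than 0.1 above background (or one replicate
more than 0.2) within +-0.5 degC of the control Tm.
"""

from gutreads.mca import call_melt_table
from gutreads.synthetic import MeltTransition, simulate_melt

assays = {}
for rep in ("r1", "r2", "r3"):
    # true product: sharp transition at the control Tm
    assays[("sample_A", "prey_assay", rep)] = [MeltTransition(76.5, 2.0, 0.5)]
    # false detection: clean product, but melting 2.7 degC too high
    assays[("sample_B", "prey_assay", rep)] = [MeltTransition(79.2, 2.0, 0.5)]
    # no amplification at all
    assays[("sample_C", "prey_assay", rep)] = []

melt = simulate_melt(assays, seed=3, noise_sd=0.005)
calls = call_melt_table(melt, expected_tms={"prey_assay": 76.5})
print(calls.to_string(index=False))
# sample_A is positive (peak at the control Tm in all replicates);
# sample_B is negative despite its sharp peak -- wrong melting temperature
# means a different amplicon; sample_C is negative (no peak above background).
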