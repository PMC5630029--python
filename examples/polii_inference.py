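"""Infer RNAPII flux parameters and attribute explained variance.

Simulates a gene cluster in which only promoter flux (p1) changes after
activation, infers the four parameters from the density time courses, and
shows that a model where only p1 varies explains essentially all of the
response — the signature of regulation at the level of polymerase loading.
"""

import numpy as np

from mycflux.polii import (ClusterProfile, PolymeraseRates, infer_rates,
                           simulate_compartments, single_parameter_variance)

knots = np.array([0.0, 1 / 6, 0.5, 1.0, 2.0, 4.0])
truth = PolymeraseRates(knots, p1=np.array([60, 80, 100, 90, 80, 80.0]),
                        p2=2.0, p3=3.0, p4=6.0)
init = (30.0, 20.0, 10.0)  # steady state: Pr=p1/p2, Gb=p1/p3, Te=p1/p4
Pr, Gb, Te, k1 = simulate_compartments(truth, init, knots)
profile = ClusterProfile(1, knots, Pr, Gb, Te, k1)

full = infer_rates(profile, mode="linear")
print("inferred p1 at knots:", np.round(full.p1, 1), "(truth:", truth.p1, ")")

print("\nexplained variance of single-parameter models:")
for which in ("p1", "p2", "p3", "p4"):
    ev, _ = single_parameter_variance(profile, which, rates_full=full)
    print(f"  only {which} varying: {ev:6.3f}")
# The p1-only model reaches ~1.0 while the others go negative: the cluster's
# entire response is attributable to changed polymerase loading.
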