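"""Evaluate the thermodynamic model for one parameter set.

Builds a parameterisation inside the sampling ranges, computes the 48
statistical weights, the partition function, the state probabilities and
the RNAp-binding probability, and demonstrates the closed-form decoupling
limit: with the Fer1-RNAp cooperativity switched off (wCR = 1), the
polymerase occupies the TATA box independently of the cluster, so
P_binding collapses to qR/(1+qR).
"""

from orthermo import (
    BindingAffinities,
    ChromatinState,
    EpigeneticFactors,
    InteractionFactors,
    evaluate,
)

affinities = BindingAffinities(qR=0.028, qA1=2000.0, qA2=0.5, qB1=2.0, qB2=1200.0, qC=500.0)
interactions = InteractionFactors(wA1A2=60.0, wB1B2=80.0, wA1B2=0.0005, wB1A2=0.0005, wCR=85.0)
epigenetics = EpigeneticFactors.nominal(ChromatinState.C)

result = evaluate(affinities, interactions, epigenetics)
print(f"partition function Z_tot = {result.Ztot:.4g}")
print(f"P_binding (RNAp on the TATA box) = {result.pBinding:.4f}")
top = result.probabilities.argsort()[::-1][:5]
print("five most probable configurations (canonical index, probability):")
for k in top:
    print(f"  sigma_{k + 1}: {result.probabilities[k]:.4f}")

no_coop = evaluate(affinities, interactions.replace(wCR=1.0), epigenetics)
print(
    f"\nwith wCR = 1: P_binding = {no_coop.pBinding:.6f} "
    f"(closed form qR/(1+qR) = {affinities.qR / (1 + affinities.qR):.6f})"
)
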