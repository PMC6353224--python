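"""List the 48 molecular configurations of the enhancer cluster.

Each configuration is one joint occupancy of the five DNA sites (two
Homeobox sites, the shared Pou site, the Ebox and the TATA box).  The
printed factor columns show which affinity (q), interaction (w) and
epigenetic (h) factors multiply into each state's statistical weight.
"""

from orthermo import enumerate_states, state_table_frame

states = enumerate_states()
rnap_bound = [c for c in states if c.rnap_bound]
print(f"{len(states)} configurations, {len(rnap_bound)} with RNA polymerase bound\n")

table = state_table_frame()
print(table.to_string(index=False))

print(
    "\nStates 25-48 mirror states 1-24 with RNAp added; the RNAp-binding\n"
    "probability of the model is the summed probability of that second half."
)
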