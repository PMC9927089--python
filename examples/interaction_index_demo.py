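"""Zinc-arginine interaction index from treatment-group Young's moduli.

Uses the reported group-mean moduli (kPa) of DZA-, arginine-, and
zinc-treated saliva-plaque biofilms.
"""

from biofilmmech import ModulusTable, interaction_index
from biofilmmech.interaction import replicate_interaction_summary

res = interaction_index(e_dza=9.29, e_arg=15.38, e_zn=11.14)
print(f"IAI_Arg = E_DZA/E_Arg = {res.iai_arg:.4f}")
print(f"IAI_Zn  = E_DZA/E_Zn  = {res.iai_zn:.4f}")
print(f"IAI     = {res.iai:.4f}  ->  {res.classification}")

# Per-replicate version: pair the i-th replicate of each group.
table = ModulusTable()
for i, (d, a, z) in enumerate([(9.0, 16.1, 10.2), (12.1, 14.8, 11.9),
                               (7.5, 15.2, 10.8), (8.6, 15.4, 11.6)]):
    table.add("dza", f"r{i}", d)
    table.add("arginine", f"r{i}", a)
    table.add("zinc", f"r{i}", z)
mean, sd, _ = replicate_interaction_summary(table, pairing="matched")
print(f"replicate-level IAI = {mean:.2f} +/- {sd:.2f} (mean +/- SD)")

# An IAI in (0.5, 4) means the two actives weaken the biofilm additively:
# the combined effect is about the sum of the single-agent effects.
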