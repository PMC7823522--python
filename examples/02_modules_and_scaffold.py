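"""Parse a domain arrangement into modules, classify them, and assemble the
predicted scaffold molecule.

Run:  python examples/02_modules_and_scaffold.py
"""

from scaffoldmine.modules import classify_all, segment_into_modules
from scaffoldmine.scaffold import assemble, blocks_from_modules

# A three-module NRPS: glycine loading, N-methylated alanine extension,
# epimerized valine extension released by a thioesterase.
arrangement = ["A", "PCP", "C", "A", "nMT", "PCP", "C", "A", "PCP", "E", "TE"]
modules = classify_all(segment_into_modules(arrangement))
for m, substrate in zip(modules, ["G", "A", "V"]):
    m.substrate = substrate
    print(
        f"{m.arrangement:12s} {m.functional_class:7s} {m.type:4s} "
        f"loading={m.loading} N-methyl={m.methylation == 'N_methyl'} "
        f"epimerized={m.epimerized} terminal={m.terminal}"
    )

scaffold = assemble([blocks_from_modules(modules)])
print("\npredicted scaffold:", scaffold.smiles)
# The SMILES is the linear Gly -> N-Me-Ala -> D-Val tripeptide acid: each
# module contributes one residue, the nMT methylates the second peptide
# nitrogen, the E domain flips the valine alpha-carbon to the D form, and
# the TE caps the chain with a free carboxyl.
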