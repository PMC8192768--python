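"""Structure-contact features: monomeric (MAP) and dimeric (DAP) token pairs.

Builds a toy homodimer whose contacts are known by construction, derives
the Cbeta contact map (strict < 7.5 Angstrom), and assembles pair features.
"""

import tempfile
from pathlib import Path

import lctox as lx

positions = list(range(45, 65))
pdb_text, mapping = lx.generate_toy_structure(
    positions, interface_positions=[49, 52], monomer_pairs=[(56, 59)])
pdb_path = Path(tempfile.mkdtemp()) / "toy_dimer.pdb"
pdb_path.write_text(pdb_text)

cmap = lx.contact_map_from_pdb(pdb_path, mapping, threshold=7.5)
print(f"monomeric contact pairs: {sorted(cmap.monomeric_pairs)}")
print(f"dimeric (interface) pairs: {sorted(cmap.dimeric_pairs)}")
# The designated pairs - and only those - fall under the 7.5 A Cbeta cutoff.

enc = lx.SMutEncoding("lc1", {p: ("A" if p == 49 else "X") for p in positions}, "g")
matrix = lx.assemble_matrix([enc], ("MAP", "DAP"), contact_map=cmap,
                            position_universe=positions)
print(matrix.data.T.rename(columns={"lc1": "token pair"}))
# 49-A at the interface shows up as the dimeric pair value 'A-X': a mutated
# residue facing an unmutated partner across the dimer interface.
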