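"""Structure clean-up: crystallization-agent detection and MSE repair.

Builds a small structure containing a poly-glycine chain, a glycerol
(GOL, blacklisted), a large ligand (kept by the >20-heavy-atom rule)
and a selenomethionine residue, then shows the ligand verdicts and the
MSE -> MET replacement.
"""

import numpy as np

from solvaxs import Structure, AtomRecord
from solvaxs.prep import (
    apply_ligand_policy,
    classify_hetero_molecules,
    replace_selenomethionine,
)


def atom(serial, name, res, resid, element, xyz, hetero=False):
    return AtomRecord(serial=serial, name=name, residue_name=res, residue_id=resid,
                      chain="A", element=element, coords=np.array(xyz, float),
                      hetero=hetero)


atoms = [atom(i + 1, "CA", "GLY", i + 1, "C", [1.5 * i, 0, 0]) for i in range(10)]
atoms += [atom(20 + k, f"C{k}", "GOL", 50, "C", [1.5 * k, 30, 0], hetero=True)
          for k in range(6)]
atoms += [atom(40 + k, f"C{k}", "LIG", 60, "C", [1.5 * k, 60, 0], hetero=True)
          for k in range(22)]
atoms += [
    atom(80, "N", "MSE", 70, "N", [0, 90, 0], hetero=True),
    atom(81, "CA", "MSE", 70, "C", [1.5, 90, 0], hetero=True),
    atom(82, "SE", "MSE", 70, "Se", [3.0, 91, 0], hetero=True),
]
mols = [list(range(10)), list(range(10, 16)), list(range(16, 38)), [38, 39, 40]]
structure = Structure(atoms=atoms, molecules=mols)

for v in classify_hetero_molecules(structure):
    names = "/".join(v.residue_names)
    print(f"molecule {v.molecule_index} ({names}): {v.decision} [{v.matched_rule}]")

cleaned, _ = apply_ligand_policy(structure, "default")
print(f"\ndefault policy: {len(structure)} -> {len(cleaned)} atoms")

repaired = replace_selenomethionine(cleaned)
se = [a for a in repaired.atoms if a.serial == 82]
print(f"MSE selenium now: name={se[0].name}, element={se[0].element}, "
      f"residue={se[0].residue_name}")
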