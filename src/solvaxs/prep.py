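"""Structure clean-up: crystallization-agent detection, selenomethionine
replacement and form-factor element assignment.

Crystallographic structures routinely contain molecules from the
crystallization buffer (glycerol, PEGs, detergents) that are absent from
the scattering sample, and selenomethionine substituted for methionine
to aid phasing.  Both are reverted before computing a solution curve.

A hetero molecule is kept as biologically relevant iff one of:
(i) it is covalently bonded to the biomolecule; (ii) it forms more than
2.5 contacts per heavy atom with the biomolecule (heavy-atom cutoff
3.5 Å); (iii) it has more than 20 heavy atoms; (iv) its residue name is
HEM.  Residue names on the crystallization-agent blacklist (GOL, BNG,
BOG, PG, PE, PGE) are removed unconditionally, before any keep rule —
this must override the size rule for long PEG chains.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial import cKDTree

from .formfactors import FormFactorTable, load_default_table
from .io_formats import AtomRecord, Structure, WATER_RESIDUES, POLYMER_RESIDUES

__all__ = [
    "LigandVerdict",
    "classify_hetero_molecules",
    "apply_ligand_policy",
    "replace_selenomethionine",
    "assign_form_factor_elements",
    "BLACKLIST_RESIDUES",
]

#: Residue names that always denote crystallization agents.
BLACKLIST_RESIDUES = frozenset({"GOL", "BNG", "BOG", "PG", "PE", "PGE"})

CONTACT_CUTOFF = 3.5  # Å, heavy-atom contact distance
CONTACTS_PER_HEAVY = 2.5  # keep threshold
SIZE_THRESHOLD = 20  # heavy atoms
COVALENT_CUTOFF = 1.9  # Å heavy–heavy
COVALENT_CUTOFF_SOFT = 2.4  # Å when one partner is S/Se/metal

_SOFT_ELEMENTS = frozenset({"S", "Se", "Fe", "Zn", "Cu", "Mn", "Mg", "Ca", "Na", "K", "Ni", "Co"})


@dataclass(frozen=True)
class LigandVerdict:
    molecule_index: int
    decision: str  # "keep" | "remove"
    matched_rule: str  # covalent | contacts | size | heme-name | blacklist-name | default-remove
    residue_names: tuple[str, ...] = ()


def _heavy(structure: Structure, indices) -> list[int]:
    return [i for i in indices if structure.atoms[i].element.capitalize() != "H"]


def _biomolecule_atoms(structure: Structure) -> list[int]:
    """Heavy atoms of polymer (non-hetero, non-water) molecules."""
    out = []
    for mol in structure.molecules:
        names = {structure.atoms[i].residue_name.upper() for i in mol}
        if names & WATER_RESIDUES:
            continue
        if any(not structure.atoms[i].hetero for i in mol) or names & POLYMER_RESIDUES:
            out.extend(_heavy(structure, mol))
    return out


def classify_hetero_molecules(structure: Structure) -> list[LigandVerdict]:
    """Classify every non-water hetero molecule as keep or remove.

    Order-independent: each molecule is judged on its own against the
    biomolecule.  Raises if the structure has no polymer chain, since
    the contact and covalency rules are undefined then.
    """
    bio = _biomolecule_atoms(structure)
    hetero_mols = [
        (im, mol)
        for im, mol in enumerate(structure.molecules)
        if all(structure.atoms[i].hetero for i in mol) and not structure.is_water(mol)
    ]
    if not hetero_mols:
        return []
    if not bio:
        raise ValueError(
            "structure has no polymer chain: contact/covalency rules are undefined"
        )
    bio_coords = np.array([structure.atoms[i].coords for i in bio])
    bio_elements = [structure.atoms[i].element.capitalize() for i in bio]
    tree = cKDTree(bio_coords)

    verdicts = []
    for im, mol in hetero_mols:
        res_names = tuple(dict.fromkeys(structure.atoms[i].residue_name.upper() for i in mol))
        heavy = _heavy(structure, mol)
        # blacklist first: always crystallization agents, overriding the
        # size rule (long PEG chains exceed 20 heavy atoms)
        if any(rn in BLACKLIST_RESIDUES for rn in res_names):
            verdicts.append(LigandVerdict(im, "remove", "blacklist-name", res_names))
            continue
        if not heavy:
            verdicts.append(LigandVerdict(im, "remove", "default-remove", res_names))
            continue
        coords = np.array([structure.atoms[i].coords for i in heavy])
        elements = [structure.atoms[i].element.capitalize() for i in heavy]
        if _covalent_to(coords, elements, tree, bio_elements):
            verdicts.append(LigandVerdict(im, "keep", "covalent", res_names))
            continue
        n_contacts = sum(len(nb) for nb in tree.query_ball_point(coords, CONTACT_CUTOFF))
        if n_contacts / len(heavy) > CONTACTS_PER_HEAVY:
            verdicts.append(LigandVerdict(im, "keep", "contacts", res_names))
            continue
        if len(heavy) > SIZE_THRESHOLD:
            verdicts.append(LigandVerdict(im, "keep", "size", res_names))
            continue
        if "HEM" in res_names:
            verdicts.append(LigandVerdict(im, "keep", "heme-name", res_names))
            continue
        verdicts.append(LigandVerdict(im, "remove", "default-remove", res_names))
    return verdicts


def _covalent_to(coords, elements, bio_tree: cKDTree, bio_elements) -> bool:
    pairs = bio_tree.query_ball_point(coords, COVALENT_CUTOFF_SOFT)
    for i, partners in enumerate(pairs):
        for j in partners:
            d = np.linalg.norm(coords[i] - bio_tree.data[j])
            soft = elements[i] in _SOFT_ELEMENTS or bio_elements[j] in _SOFT_ELEMENTS
            if d < (COVALENT_CUTOFF_SOFT if soft else COVALENT_CUTOFF):
                return True
    return False


def apply_ligand_policy(structure: Structure, policy: str = "default") -> tuple[Structure, list[LigandVerdict]]:
    """Retain atoms according to a ligand-handling policy.

    default   — keep ligands, remove detected crystallization agents;
    keep-all  — keep every hetero molecule;
    remove-all — drop every non-water hetero molecule.
    The three modes nest: keep-all ⊇ default ⊇ remove-all.
    """
    if policy not in ("default", "keep-all", "remove-all"):
        raise ValueError(f"unknown ligand policy {policy!r}")
    verdicts = classify_hetero_molecules(structure) if policy != "keep-all" else []
    drop: set[int] = set()
    if policy == "default":
        for vd in verdicts:
            if vd.decision == "remove":
                drop.update(structure.molecules[vd.molecule_index])
    elif policy == "remove-all":
        for vd in verdicts:
            drop.update(structure.molecules[vd.molecule_index])
    keep = [i for i in range(len(structure)) if i not in drop]
    return _subset(structure, keep), verdicts


def _subset(structure: Structure, keep: list[int]) -> Structure:
    remap = {old: new for new, old in enumerate(keep)}
    atoms = [structure.atoms[i] for i in keep]
    mols = []
    for mol in structure.molecules:
        m = [remap[i] for i in mol if i in remap]
        if m:
            mols.append(m)
    return Structure(atoms=atoms, molecules=mols, box=structure.box)


# ---------------------------------------------------------------------------
# selenomethionine

def replace_selenomethionine(structure: Structure, enabled: bool = True) -> Structure:
    """Rename MSE residues to MET, Se → SD sulfur; coordinates untouched."""
    if not enabled:
        return structure
    atoms = []
    for a in structure.atoms:
        if a.residue_name.upper() == "MSE":
            name = a.name
            element = a.element
            if a.element.capitalize() == "Se" or a.name.strip().upper() in ("SE", "SED"):
                name = "SD"
                element = "S"
            atoms.append(replace(a, residue_name="MET", name=name, element=element, hetero=False))
        else:
            atoms.append(a)
    return Structure(atoms=atoms, molecules=[list(m) for m in structure.molecules],
                     box=structure.box)


# ---------------------------------------------------------------------------
# form-factor assignment

def assign_form_factor_elements(
    structure: Structure, table: FormFactorTable | None = None
) -> tuple[dict[int, str], str]:
    """Map every atom to a form-factor table key and emit a report.

    Ions keep their own element — an exotic ion that an MD engine would
    substitute still scatters with its original form factor.  Water
    atoms map to the OW/HW species.  Raises if any atom's element has no
    table entry, naming the offenders.
    """
    from .scattering import _species_keys

    if table is None:
        table = load_default_table()
    keys = _species_keys(structure)
    missing = [
        (a.serial, a.residue_name, a.element)
        for a, k in zip(structure.atoms, keys)
        if k not in table
    ]
    if missing:
        listing = ", ".join(f"serial {s} ({r}/{e})" for s, r, e in missing[:10])
        raise ValueError(f"no form-factor entry for {len(missing)} atom(s): {listing}")
    mapping = {i: k for i, k in enumerate(keys)}
    lines = ["# atom -> form factor assignment", "# serial name residue element key f(0)"]
    for a, k in zip(structure.atoms, keys):
        lines.append(
            f"{a.serial:>6d} {a.name:<4s} {a.residue_name:<4s} "
            f"{a.element:<2s} {k:<2s} {table[k].f0:8.4f}"
        )
    return mapping, "\n".join(lines) + "\n"
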