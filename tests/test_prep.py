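import numpy as np
import pytest

from solvaxs.io_formats import AtomRecord, Structure
from solvaxs.prep import (
    apply_ligand_policy,
    assign_form_factor_elements,
    classify_hetero_molecules,
    replace_selenomethionine,
)


def _atom(serial, name, res, resid, element, xyz, hetero=False, chain="A"):
    return AtomRecord(serial=serial, name=name, residue_name=res, residue_id=resid,
                      chain=chain, element=element, coords=np.array(xyz, float),
                      hetero=hetero)


def _protein_atoms(n=12, start_serial=1):
    """A short poly-GLY 'biomolecule' along x, one heavy atom per Å."""
    atoms = []
    for i in range(n):
        atoms.append(_atom(start_serial + i, "CA", "GLY", i + 1, "C",
                           [float(i) * 1.5, 0.0, 0.0]))
    return atoms


def _build(protein_atoms, hetero_groups):
    atoms = list(protein_atoms)
    mols = [list(range(len(protein_atoms)))]
    for grp in hetero_groups:
        idx0 = len(atoms)
        atoms.extend(grp)
        mols.append(list(range(idx0, idx0 + len(grp))))
    return Structure(atoms=atoms, molecules=mols, box=None)


def _cluster(res, n_heavy, origin, start_serial, element="C", spacing=1.5):
    """n_heavy heavy atoms packed on a line starting at origin."""
    return [
        _atom(start_serial + k, f"C{k+1}", res, 90, element,
              [origin[0] + spacing * k, origin[1], origin[2]], hetero=True)
        for k in range(n_heavy)
    ]


class TestClassification:
    def test_blacklist_always_removed(self):
        gol = _cluster("GOL", 6, (0.0, 3.0, 0.0), 100)
        s = _build(_protein_atoms(), [gol])
        (v,) = classify_hetero_molecules(s)
        assert v.decision == "remove" and v.matched_rule == "blacklist-name"

    def test_blacklist_overrides_size_rule(self):
        """A long PEG exceeds 20 heavy atoms but is still removed."""
        peg = _cluster("PGE", 25, (0.0, 30.0, 0.0), 100)
        s = _build(_protein_atoms(), [peg])
        (v,) = classify_hetero_molecules(s)
        assert v.decision == "remove" and v.matched_rule == "blacklist-name"

    def test_size_rule_keeps_21_heavy_atoms(self):
        big = _cluster("LIG", 21, (0.0, 40.0, 0.0), 100)
        s = _build(_protein_atoms(), [big])
        (v,) = classify_hetero_molecules(s)
        assert v.decision == "keep" and v.matched_rule == "size"

    def test_twenty_heavy_atoms_not_kept_by_size(self):
        """The size rule is strictly >20 heavy atoms."""
        mid = _cluster("LIG", 20, (0.0, 40.0, 0.0), 100)
        s = _build(_protein_atoms(), [mid])
        (v,) = classify_hetero_molecules(s)
        assert v.decision == "remove" and v.matched_rule == "default-remove"

    def test_heme_kept_by_name(self):
        hem = _cluster("HEM", 4, (0.0, 40.0, 0.0), 100, element="N")
        s = _build(_protein_atoms(), [hem])
        (v,) = classify_hetero_molecules(s)
        assert v.decision == "keep" and v.matched_rule == "heme-name"

    def test_contact_rule(self):
        """4 heavy atoms with 12 contacts within 3.5 Å -> 3.0 per heavy atom."""
        lig = [
            _atom(100 + k, f"C{k+1}", "LIG", 90, "C", [1.5 * (2 * k), 2.5, 0.0],
                  hetero=True)
            for k in range(4)
        ]  # each ligand atom sits 2.5 Å above the CA line: 3 CAs within 3.5 Å
        s = _build(_protein_atoms(), [lig])
        (v,) = classify_hetero_molecules(s)
        assert v.decision == "keep" and v.matched_rule == "contacts"

    def test_covalent_rule(self):
        lig = _cluster("LIG", 2, (0.0, 1.7, 0.0), 100)  # 1.7 Å from CA 1
        s = _build(_protein_atoms(), [lig])
        (v,) = classify_hetero_molecules(s)
        assert v.decision == "keep" and v.matched_rule == "covalent"

    def test_order_independence(self):
        groups = [
            _cluster("GOL", 6, (0.0, 30.0, 0.0), 100),
            _cluster("LIG", 21, (0.0, 60.0, 0.0), 200),
            _cluster("HEM", 4, (0.0, 90.0, 0.0), 300, element="N"),
        ]
        s_fwd = _build(_protein_atoms(), groups)
        s_rev = _build(_protein_atoms(), groups[::-1])
        by_res_fwd = {v.residue_names[0]: (v.decision, v.matched_rule)
                      for v in classify_hetero_molecules(s_fwd)}
        by_res_rev = {v.residue_names[0]: (v.decision, v.matched_rule)
                      for v in classify_hetero_molecules(s_rev)}
        assert by_res_fwd == by_res_rev

    def test_no_polymer_chain_is_config_error(self):
        lig = _cluster("LIG", 3, (0.0, 0.0, 0.0), 1)
        s = Structure(atoms=lig, molecules=[[0, 1, 2]])
        with pytest.raises(ValueError, match="polymer"):
            classify_hetero_molecules(s)

    def test_policy_lattice(self):
        groups = [
            _cluster("GOL", 6, (0.0, 30.0, 0.0), 100),
            _cluster("LIG", 21, (0.0, 60.0, 0.0), 200),
            _cluster("XYZ", 3, (0.0, 90.0, 0.0), 300),
        ]
        s = _build(_protein_atoms(), groups)
        keep_all, _ = apply_ligand_policy(s, "keep-all")
        default, _ = apply_ligand_policy(s, "default")
        remove_all, _ = apply_ligand_policy(s, "remove-all")
        assert len(keep_all) >= len(default) >= len(remove_all)
        serial = lambda st: {a.serial for a in st.atoms}
        assert serial(remove_all) <= serial(default) <= serial(keep_all)


class TestSelenomethionine:
    def _mse_structure(self):
        atoms = [
            _atom(1, "N", "MSE", 1, "N", [0, 0, 0], hetero=True),
            _atom(2, "CA", "MSE", 1, "C", [1.5, 0, 0], hetero=True),
            _atom(3, "SE", "MSE", 1, "Se", [3.0, 1.0, 0], hetero=True),
            _atom(4, "N", "MSE", 2, "N", [4.5, 0, 0], hetero=True),
            _atom(5, "SE", "MSE", 2, "Se", [6.0, 1.0, 0], hetero=True),
            _atom(6, "CA", "GLY", 3, "C", [7.5, 0, 0]),
        ]
        return Structure(atoms=atoms, molecules=[list(range(6))])

    def test_replacement(self):
        s = self._mse_structure()
        out = replace_selenomethionine(s, enabled=True)
        assert len(out) == len(s)
        assert all(a.residue_name != "MSE" for a in out.atoms)
        assert sum(a.residue_name == "MET" for a in out.atoms) == 5
        ses = [a for a in out.atoms if a.serial in (3, 5)]
        assert all(a.element == "S" and a.name == "SD" for a in ses)
        # coordinates untouched
        assert np.allclose(out.coords, s.coords)

    def test_no_mse_is_identity(self):
        s = Structure(atoms=_protein_atoms(4), molecules=[[0, 1, 2, 3]])
        out = replace_selenomethionine(s, enabled=True)
        assert [a.residue_name for a in out.atoms] == ["GLY"] * 4

    def test_disabled_is_identity(self):
        s = self._mse_structure()
        out = replace_selenomethionine(s, enabled=False)
        assert out is s


class TestAssignment:
    def test_standard_protein_elements(self, table):
        s = Structure(atoms=_protein_atoms(3), molecules=[[0, 1, 2]])
        mapping, report = assign_form_factor_elements(s, table)
        assert set(mapping.values()) == {"C"}
        assert "form factor" in report or "assignment" in report

    def test_zinc_keeps_its_own_form_factor(self, table):
        atoms = _protein_atoms(3) + [
            _atom(50, "ZN", "ZN", 99, "Zn", [0, 5, 0], hetero=True)
        ]
        s = Structure(atoms=atoms, molecules=[[0, 1, 2], [3]])
        mapping, _ = assign_form_factor_elements(s, table)
        assert mapping[3] == "Zn"

    def test_water_maps_to_water_species(self, table):
        atoms = [
            _atom(1, "O", "HOH", 1, "O", [0, 0, 0], hetero=True),
            _atom(2, "H1", "HOH", 1, "H", [1, 0, 0], hetero=True),
            _atom(3, "H2", "HOH", 1, "H", [0, 1, 0], hetero=True),
        ]
        s = Structure(atoms=atoms, molecules=[[0, 1, 2]])
        mapping, _ = assign_form_factor_elements(s, table)
        assert [mapping[i] for i in range(3)] == ["OW", "HW", "HW"]

    def test_unknown_element_names_the_atom(self, table):
        atoms = _protein_atoms(2) + [
            _atom(99, "UNK", "XXX", 5, "Xq", [9, 9, 9], hetero=True)
        ]
        s = Structure(atoms=atoms, molecules=[[0, 1], [2]])
        with pytest.raises(ValueError, match="serial 99"):
            assign_form_factor_elements(s, table)
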