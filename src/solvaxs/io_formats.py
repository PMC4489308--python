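"""Structures, trajectories and scattering curves: the I/O layer.

All downstream modules consume only the types defined here.  Coordinates
are carried internally in Å and scattering vectors in Å⁻¹; unit
conversions happen only at the I/O boundary.  The native trajectory
dialect is the multi-model PDB file (parsed with gemmi); other formats
enter through a thin MDAnalysis adapter so the core never sees format
detail.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

__all__ = [
    "AtomRecord",
    "Structure",
    "Trajectory",
    "ExperimentalCurve",
    "ScatteringCurve",
    "read_structure",
    "read_trajectory",
    "read_curve",
    "write_curve",
    "write_structure",
    "write_trajectory",
]

#: Default frame spacing (ps) assigned when a trajectory carries no times.
DEFAULT_FRAME_SPACING_PS = 0.5

#: Residue names recognised as water models.
WATER_RESIDUES = frozenset({"HOH", "WAT", "SOL", "TIP3", "TIP", "SPC", "H2O"})

#: Standard polymer residues (amino acids + nucleotides) used for the
#: residue-level molecule fallback when no CONECT records are present.
_AMINO = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "MSE", "PHE", "PRO", "SER", "THR", "TRP", "TYR",
    "VAL",
}
_NUCLEIC = {"A", "C", "G", "U", "T", "DA", "DC", "DG", "DT", "DU"}
POLYMER_RESIDUES = frozenset(_AMINO | _NUCLEIC)

# Two-letter element disambiguation for atom names without an element
# column.  PDB v3 right-justifies element symbols in columns 77-78; when
# absent, names starting with these pairs denote two-letter elements
# provided the residue is a hetero compound or the name fills column 13.
_TWO_LETTER = {
    "NA", "MG", "CL", "CA", "MN", "FE", "CU", "ZN", "SE", "BR", "CD", "NI",
    "CO", "HG", "PT", "AU", "AG", "SR", "BA", "RB", "CS", "LI", "AL", "SI",
}


@dataclass(frozen=True)
class AtomRecord:
    """One atom: identity, residue membership and coordinates (Å)."""

    serial: int
    name: str
    residue_name: str
    residue_id: int
    chain: str
    element: str
    coords: np.ndarray
    hetero: bool = False

    def __post_init__(self):
        c = np.asarray(self.coords, dtype=float)
        if c.shape != (3,) or not np.all(np.isfinite(c)):
            raise ValueError(f"atom {self.serial}: coords must be a finite 3-vector")
        object.__setattr__(self, "coords", c)


@dataclass
class Structure:
    """An ordered atom list plus a partition into molecules.

    ``molecules`` lists atom-index groups (connected components); every
    atom belongs to exactly one molecule.  ``box`` holds orthorhombic box
    lengths in Å when known.
    """

    atoms: list[AtomRecord]
    molecules: list[list[int]] = field(default_factory=list)
    box: np.ndarray | None = None

    def __post_init__(self):
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
        if not self.molecules:
            self.molecules = [[i] for i in range(len(self.atoms))]
        covered = sorted(i for mol in self.molecules for i in mol)
        if covered != list(range(len(self.atoms))):
            raise ValueError("molecule partition must cover every atom exactly once")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(N, 3) coordinate array in atom order."""
        return np.array([a.coords for a in self.atoms], dtype=float)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    def is_water(self, molecule: list[int]) -> bool:
        return all(self.atoms[i].residue_name.upper() in WATER_RESIDUES for i in molecule)


@dataclass
class Trajectory:
    """Ordered coordinate frames sharing the Structure's atom order.

    coords: (n_frames, n_atoms, 3) in Å; boxes: (n_frames, 3) in Å;
    times: (n_frames,) in ps, strictly increasing.
    """

    coords: np.ndarray
    boxes: np.ndarray
    times: np.ndarray

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.boxes = np.asarray(self.boxes, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        n = self.coords.shape[0]
        if self.boxes.shape != (n, 3) or self.times.shape != (n,):
            raise ValueError("boxes/times do not match the frame count")
        if n > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def total_time(self) -> float:
        """Time span covered by the frames, in ps."""
        if self.n_frames < 2:
            return 0.0
        return float(self.times[-1] - self.times[0])

    def drop_before(self, t: float) -> "Trajectory":
        """Return the trajectory restricted to frames with time ≥ t."""
        keep = self.times >= t
        if not np.any(keep):
            raise ValueError("no frames remain after the equilibration discard")
        return Trajectory(self.coords[keep], self.boxes[keep], self.times[keep])


@dataclass
class ExperimentalCurve:
    """An experimental scattering curve as uploaded: no unit conversion yet."""

    q: np.ndarray
    I: np.ndarray
    sigma: np.ndarray | None = None
    q_units: str = "A^-1"  # "A^-1" or "nm^-1"
    convention: str = "q"  # "q" (4π sinθ/λ) or "s" (2 sinθ/λ)

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        if self.q.shape != self.I.shape:
            raise ValueError("q and I must have equal length")
        if len(self.q) > 1 and not np.all(np.diff(self.q) > 0):
            raise ValueError("q values must be strictly increasing")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.I.shape:
                raise ValueError("sigma must match I in length")
            if np.any(self.sigma <= 0):
                raise ValueError("sigma values must be strictly positive")
        if self.q_units not in ("A^-1", "nm^-1"):
            raise ValueError(f"unknown q units {self.q_units!r}")
        if self.convention not in ("q", "s"):
            raise ValueError(f"unknown scattering convention {self.convention!r}")


@dataclass
class ScatteringCurve:
    """A computed curve: q (Å⁻¹), intensity (e², arbitrary overall scale),
    statistical error estimate and provenance metadata."""

    q: np.ndarray
    I: np.ndarray
    sigma_stat: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        if self.q.shape != self.I.shape:
            raise ValueError("q and I must have equal length")
        if self.sigma_stat is not None:
            self.sigma_stat = np.asarray(self.sigma_stat, dtype=float)
            if self.sigma_stat.shape != self.I.shape:
                raise ValueError("sigma_stat must match I in length")
            if np.any(self.sigma_stat < 0):
                raise ValueError("sigma_stat must be non-negative")


# ---------------------------------------------------------------------------
# element inference

def infer_element(atom_name: str, residue_name: str, hetero: bool) -> str:
    """Infer an element symbol from a PDB atom name.

    Follows PDB v3 conventions: a leading digit is stripped (e.g. 1HG1),
    and two-letter symbols are recognised from a fixed disambiguation
    table, preferring them for hetero/ion records (NA in HOH is sodium
    only when the residue says so; the N of an ATOM record never is).
    """
    name = atom_name.strip().upper()
    name = name.lstrip("0123456789")
    if not name:
        raise ValueError(f"cannot infer element from atom name {atom_name!r}")
    two = name[:2]
    # Two-letter elements (ions, Se, metals) are effectively always hetero
    # records or share the residue name (CA in residue CA is calcium; the
    # CA of an ATOM amino-acid record is an alpha carbon).
    if two in _TWO_LETTER and (hetero or residue_name.strip().upper() == two):
        return two.capitalize()
    return name[0]


def _element_from_gemmi(atom: gemmi.Atom, residue: gemmi.Residue, hetero: bool) -> str:
    el = atom.element
    if el is not None and el.name and el.name != "X":
        return el.name
    return infer_element(atom.name, residue.name, hetero)


# ---------------------------------------------------------------------------
# molecule partition

def _molecules_from_connectivity(
    atoms: list[AtomRecord], conect: dict[int, list[int]]
) -> list[list[int]]:
    """Partition atoms into molecules.

    Residue-level fallback: consecutive polymer residues in the same
    chain form one molecule (a chain); every other residue is its own
    molecule.  CONECT records then merge components (a disulfide or a
    covalent ligand link joins molecules).
    """
    import scipy.sparse as sp
    from scipy.sparse.csgraph import connected_components

    n = len(atoms)
    serial_to_index = {a.serial: i for i, a in enumerate(atoms)}
    rows, cols = [], []

    # residue template fallback: link atoms within a residue, and link
    # consecutive polymer residues of the same chain
    prev_key = None
    prev_first = None
    prev_polymer = False
    first_of_res = None
    for i, a in enumerate(atoms):
        key = (a.chain, a.residue_id, a.residue_name)
        if key != prev_key:
            first_of_res = i
            # name-based: MSE and friends are HETATM records yet belong
            # to the polymer chain
            is_polymer = a.residue_name.upper() in POLYMER_RESIDUES
            if (
                prev_key is not None
                and is_polymer
                and prev_polymer
                and a.chain == prev_key[0]
            ):
                rows.append(prev_first)
                cols.append(i)
            prev_key, prev_first, prev_polymer = key, i, is_polymer
        if i != first_of_res:
            rows.append(first_of_res)
            cols.append(i)

    for serial, partners in conect.items():
        if serial not in serial_to_index:
            continue
        i = serial_to_index[serial]
        for p in partners:
            j = serial_to_index.get(p)
            if j is not None:
                rows.append(i)
                cols.append(j)

    graph = sp.coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    n_comp, labels = connected_components(graph, directed=False)
    mols: list[list[int]] = [[] for _ in range(n_comp)]
    for i, lab in enumerate(labels):
        mols[lab].append(i)
    mols.sort(key=lambda m: m[0])
    return mols


# ---------------------------------------------------------------------------
# PDB reading

def _gemmi_read(path: str | os.PathLike) -> gemmi.Structure:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise ValueError(f"{path}: no models found")
    return st


def _model_atoms(model: gemmi.Model) -> list[tuple[gemmi.Chain, gemmi.Residue, gemmi.Atom]]:
    out = []
    for chain in model:
        for res in chain:
            for atom in res:
                out.append((chain, res, atom))
    return out


def read_structure(path: str | os.PathLike) -> Structure:
    """Read a PDB file into a :class:`Structure` (first model only).

    Elements come from the element column when present, otherwise from
    the atom name.  Molecules are derived from CONECT records plus a
    residue-level fallback (polymer chains coalesce, each hetero residue
    stands alone).
    """
    st = _gemmi_read(path)
    model = st[0]
    atoms: list[AtomRecord] = []
    for chain, res, atom in _model_atoms(model):
        hetero = res.het_flag == "H"
        atoms.append(
            AtomRecord(
                serial=atom.serial,
                name=atom.name,
                residue_name=res.name,
                residue_id=res.seqid.num,
                chain=chain.name,
                element=_element_from_gemmi(atom, res, hetero),
                coords=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                hetero=hetero,
            )
        )
    if not atoms:
        raise ValueError(f"{path}: structure contains zero atoms")
    conect = {k: list(v) for k, v in st.conect_map.items()}
    box = None
    cell = st.cell
    if cell is not None and cell.a > 1.0 and cell.volume > 1.0:
        box = np.array([cell.a, cell.b, cell.c])
    return Structure(atoms=atoms, molecules=_molecules_from_connectivity(atoms, conect), box=box)


def read_trajectory(
    path: str | os.PathLike,
    structure: Structure,
    frame_spacing: float = DEFAULT_FRAME_SPACING_PS,
) -> Trajectory:
    """Read coordinate frames matching ``structure``.

    Multi-model PDB is the native dialect (one frame per MODEL).  Other
    formats are delegated to the MDAnalysis adapter when that package is
    installed.  PDB carries no time stamps, so frames are assigned a
    uniform spacing (0.5 ps by default, the interval at which frames are
    customarily written so solvent configurations stay uncorrelated).
    """
    suffix = os.path.splitext(str(path))[1].lower()
    if suffix not in (".pdb", ".ent", ""):
        return _read_trajectory_mda(path, structure, frame_spacing)
    st = _gemmi_read(path)
    n_atoms = len(structure)
    frames = []
    boxes = []
    default_box = structure.box if structure.box is not None else np.zeros(3)
    for imodel, model in enumerate(st):
        triples = _model_atoms(model)
        if len(triples) != n_atoms:
            raise ValueError(
                f"{path}: model {imodel + 1} has {len(triples)} atoms, "
                f"expected {n_atoms}"
            )
        frames.append([[t[2].pos.x, t[2].pos.y, t[2].pos.z] for t in triples])
        cell = st.cell
        if cell is not None and cell.a > 1.0:
            boxes.append([cell.a, cell.b, cell.c])
        else:
            boxes.append(default_box)
    coords = np.asarray(frames, dtype=float)
    times = np.arange(len(frames)) * frame_spacing
    return Trajectory(coords=coords, boxes=np.asarray(boxes, dtype=float), times=times)


def _read_trajectory_mda(path, structure: Structure, frame_spacing: float) -> Trajectory:
    try:
        import MDAnalysis as mda
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "reading non-PDB trajectories requires MDAnalysis"
        ) from exc
    u = mda.Universe.empty(len(structure), trajectory=True)
    u.load_new(str(path))
    frames, boxes, times = [], [], []
    for ts in u.trajectory:
        if ts.n_atoms != len(structure):
            raise ValueError(
                f"{path}: frame {ts.frame} has {ts.n_atoms} atoms, expected {len(structure)}"
            )
        frames.append(ts.positions.copy())
        boxes.append(ts.dimensions[:3] if ts.dimensions is not None else np.zeros(3))
        times.append(ts.time)
    times = np.asarray(times, dtype=float)
    if len(times) > 1 and not np.all(np.diff(times) > 0):
        times = np.arange(len(frames)) * frame_spacing
    return Trajectory(np.asarray(frames), np.asarray(boxes), times)


# ---------------------------------------------------------------------------
# PDB writing

def _to_gemmi(structure: Structure, trajectory: Trajectory | None = None) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = "solvaxs"
    if structure.box is not None:
        b = structure.box
        st.cell = gemmi.UnitCell(b[0], b[1], b[2], 90, 90, 90)
        st.spacegroup_hm = "P 1"
    n_models = trajectory.n_frames if trajectory is not None else 1
    for imodel in range(n_models):
        model = gemmi.Model(imodel + 1)
        coords = trajectory.coords[imodel] if trajectory is not None else structure.coords
        chain = None
        res = None
        prev = (None, None, None)
        for i, a in enumerate(structure.atoms):
            if chain is None or a.chain != prev[0]:
                chain = gemmi.Chain(a.chain or "A")
                model.add_chain(chain)
                chain = model[-1]
                prev = (a.chain, None, None)
            if (a.residue_id, a.residue_name) != (prev[1], prev[2]):
                res = gemmi.Residue()
                res.name = a.residue_name
                res.seqid = gemmi.SeqId(a.residue_id, " ")
                res.het_flag = "H" if a.hetero else "A"
                chain.add_residue(res)
                res = chain[-1]
                prev = (a.chain, a.residue_id, a.residue_name)
            atom = gemmi.Atom()
            atom.name = a.name
            atom.serial = a.serial
            atom.element = gemmi.Element(a.element)
            atom.pos = gemmi.Position(*coords[i])
            res.add_atom(atom)
        st.add_model(model)
    return st


def write_structure(structure: Structure, path: str | os.PathLike) -> None:
    """Write a Structure as a single-model PDB file."""
    _to_gemmi(structure).write_pdb(str(path))


def write_trajectory(
    structure: Structure, trajectory: Trajectory, path: str | os.PathLike
) -> None:
    """Write a Trajectory as a multi-model PDB file."""
    _to_gemmi(structure, trajectory).write_pdb(str(path))


# ---------------------------------------------------------------------------
# curve files

def read_curve(
    path: str | os.PathLike, q_units: str = "A^-1", convention: str = "q"
) -> ExperimentalCurve:
    """Read a 2- or 3-column text curve (q, I[, σ]); '#' comments allowed.

    The declared units/convention are recorded but not applied: curves
    are converted once, later, by :func:`solvaxs.curves.convert_curve`.
    """
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            parts = s.replace(",", " ").split()
            try:
                vals = [float(p) for p in parts]
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: non-numeric row {s!r}") from exc
            if len(vals) < 2:
                raise ValueError(f"{path}:{ln}: need at least 2 columns")
            rows.append(vals[:3])
    if not rows:
        raise ValueError(f"{path}: no data rows")
    ncol = min(len(r) for r in rows)
    arr = np.array([r[:ncol] for r in rows], dtype=float)
    sigma = arr[:, 2] if ncol >= 3 else None
    return ExperimentalCurve(
        q=arr[:, 0], I=arr[:, 1], sigma=sigma, q_units=q_units, convention=convention
    )


def write_curve(
    curve: ScatteringCurve, path: str | os.PathLike, out_units: str = "A^-1"
) -> None:
    """Write a computed curve as 3 text columns with a provenance header.

    Internally q is in Å⁻¹; requesting nm⁻¹ multiplies the q column by 10.
    """
    if len(curve.q) == 0:
        raise ValueError("refusing to write an empty curve")
    if out_units not in ("A^-1", "nm^-1"):
        raise ValueError(f"unknown output units {out_units!r}")
    scale = 10.0 if out_units == "nm^-1" else 1.0
    sigma = curve.sigma_stat if curve.sigma_stat is not None else np.zeros_like(curve.I)
    with open(path, "w") as fh:
        fh.write("# solvaxs scattering curve\n")
        fh.write(f"# q units: {out_units}\n")
        for key in ("envelope_distance", "n_frames_solute", "n_frames_water",
                    "subtraction_scheme", "seed"):
            if key in curve.meta:
                fh.write(f"# {key}: {curve.meta[key]}\n")
        fh.write("# columns: q I sigma_stat\n")
        for qv, iv, sv in zip(curve.q * scale, curve.I, sigma):
            fh.write(f"{qv:.8e} {iv:.8e} {sv:.8e}\n")
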