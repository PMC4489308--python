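"""Synthetic solute/water systems for end-to-end testing without MD.

The generator stands in for the MD engine: it produces a solute
trajectory (a rigid toy solute with optional per-frame Gaussian jitter,
solvated by random rigid waters) and a matched pure-water companion box
at the same density.  Frames are independent draws — the scattering
machinery needs configurational statistics, not physical dynamics — and
everything is bit-reproducible from (spec, seed).

Also houses the run-length configuration rules: the frame-count formula
N_fr = 2·10⁵ / N_A^0.77 with quick/normal/thorough multipliers, and the
5%-of-total-time (≥ 3 ps) equilibration discard.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .formfactors import DEFAULT_BUFFER_DENSITY, ELECTRONS_PER_WATER
from .io_formats import AtomRecord, Structure, Trajectory, DEFAULT_FRAME_SPACING_PS

__all__ = [
    "SyntheticSystemSpec",
    "generate_water_box",
    "generate_system_pair",
    "recommended_frames",
    "equilibration_split",
]

# Rigid water geometry (experimental gas-phase values, also used by the
# common 3-site models): O–H bond and H–O–H angle.
OH_BOND = 0.9572  # Å
HOH_ANGLE = math.radians(104.52)

#: Excluded-volume radius around each solute atom when solvating.
SOLUTE_EXCLUSION = 2.8  # Å

DEFAULT_MIN_OO = 2.4  # Å, minimum O–O distance in dart-throwing


@dataclass
class SyntheticSystemSpec:
    """Study conditions for one synthetic solute/water pair."""

    solute_model: str = "sphere-cluster"  # single-atom | sphere-cluster | helix
    n_solute: int = 20
    solute_radius: float = 5.0  # Å (sphere-cluster) or helix radius
    helix_rise: float = 1.5  # Å per atom (helix model)
    solute_element: str = "C"
    jitter_sigma: float = 0.1  # Å per-frame Gaussian positional noise
    box: tuple[float, float, float] = (40.0, 40.0, 40.0)  # Å
    water_density: float = DEFAULT_BUFFER_DENSITY  # e nm⁻³
    water_min_dist: float = DEFAULT_MIN_OO  # Å
    n_frames: int = 5
    seed: int = 0


def _water_sites(o_pos: np.ndarray, rot: Rotation) -> np.ndarray:
    """O, H1, H2 coordinates of one rigid water at o_pos with orientation rot."""
    h1 = np.array([OH_BOND, 0.0, 0.0])
    h2 = np.array([OH_BOND * math.cos(HOH_ANGLE), OH_BOND * math.sin(HOH_ANGLE), 0.0])
    local = np.stack([np.zeros(3), h1, h2])
    return o_pos + rot.apply(local)


def _place_oxygens(
    box: np.ndarray,
    n: int,
    min_dist: float,
    rng: np.random.Generator,
    exclude_centers: np.ndarray | None = None,
    exclude_radius: float = 0.0,
    max_batches: int = 4000,
) -> np.ndarray:
    """Dart-throwing with a minimum O–O distance and optional exclusion zone."""
    placed = np.empty((0, 3))
    batch = max(64, n // 4)
    excl_tree = cKDTree(exclude_centers) if exclude_centers is not None and len(exclude_centers) else None
    for _ in range(max_batches):
        if len(placed) >= n:
            break
        cand = rng.random((batch, 3)) * box
        if excl_tree is not None:
            d, _ = excl_tree.query(cand, k=1)
            cand = cand[d >= exclude_radius]
        if len(placed):
            tree = cKDTree(placed)
            d, _ = tree.query(cand, k=1)
            cand = cand[d >= min_dist]
        # enforce the minimum distance within the batch itself
        for c in cand:
            if len(placed) >= n:
                break
            if len(placed) and np.min(np.linalg.norm(placed - c, axis=1)) < min_dist:
                continue
            placed = np.vstack([placed, c])
    if len(placed) < n:
        raise RuntimeError(
            f"water packing failed: placed {len(placed)}/{n} molecules "
            f"(density too high for min_dist={min_dist} Å?)"
        )
    return placed[:n]


def _water_structure(n_water: int, box: np.ndarray, first_serial: int = 1,
                     first_resid: int = 1, chain: str = "W") -> list[AtomRecord]:
    atoms = []
    serial = first_serial
    for i in range(n_water):
        for name, el in (("O", "O"), ("H1", "H"), ("H2", "H")):
            atoms.append(
                AtomRecord(
                    serial=serial, name=name, residue_name="HOH",
                    residue_id=first_resid + i, chain=chain, element=el,
                    coords=np.zeros(3), hetero=True,
                )
            )
            serial += 1
    return atoms


def _water_frame(oxygens: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    # uniform random orientations from normalized 4-normal quaternions
    quats = rng.normal(size=(len(oxygens), 4))
    quats /= np.linalg.norm(quats, axis=1, keepdims=True)
    rots = Rotation.from_quat(quats)
    coords = np.empty((len(oxygens) * 3, 3))
    for i, (o, r) in enumerate(zip(oxygens, rots)):
        coords[3 * i : 3 * i + 3] = _water_sites(o, r)
    return coords


def n_waters_for_density(box: np.ndarray, density: float) -> int:
    """Molecule count giving the requested electron density (10 e per water)."""
    v_nm3 = float(np.prod(box)) / 1000.0
    return int(round(density * v_nm3 / ELECTRONS_PER_WATER))


def generate_water_box(
    box, density: float = DEFAULT_BUFFER_DENSITY,
    min_dist: float = DEFAULT_MIN_OO, seed: int = 0, n_frames: int = 1,
) -> tuple[Structure, Trajectory]:
    """A pure-water box: rigid 3-site waters, random positions/orientations.

    Electron count / volume matches the requested density to within one
    molecule; deterministic given the seed; frames are independent draws.
    """
    box = np.asarray(box, dtype=float)
    if density <= 0 or density > 800.0:
        raise ValueError("density must be in (0, 800] e nm^-3 (packing ceiling)")
    rng = np.random.default_rng(seed)
    n = n_waters_for_density(box, density)
    frames = []
    for _ in range(n_frames):
        oxy = _place_oxygens(box, n, min_dist, rng)
        frames.append(_water_frame(oxy, rng))
    atoms = _water_structure(n, box)
    molecules = [[3 * i, 3 * i + 1, 3 * i + 2] for i in range(n)]
    structure = Structure(atoms=atoms, molecules=molecules, box=box)
    traj = Trajectory(
        coords=np.asarray(frames),
        boxes=np.tile(box, (n_frames, 1)),
        times=np.arange(n_frames) * DEFAULT_FRAME_SPACING_PS,
    )
    # fix the placed coordinates of frame 0 into the structure records
    structure = Structure(
        atoms=[
            AtomRecord(a.serial, a.name, a.residue_name, a.residue_id, a.chain,
                       a.element, frames[0][i], a.hetero)
            for i, a in enumerate(atoms)
        ],
        molecules=molecules, box=box,
    )
    return structure, traj


def _solute_coords(spec: SyntheticSystemSpec, rng: np.random.Generator) -> np.ndarray:
    center = np.asarray(spec.box) / 2.0
    if spec.solute_model == "single-atom":
        return center[None, :]
    if spec.solute_model == "sphere-cluster":
        pts = []
        while len(pts) < spec.n_solute:
            p = rng.uniform(-1, 1, 3)
            if p @ p <= 1.0:
                pts.append(p)
        return center + spec.solute_radius * np.asarray(pts)
    if spec.solute_model == "helix":
        k = np.arange(spec.n_solute)
        theta = k * math.radians(100.0)
        z = (k - spec.n_solute / 2.0) * spec.helix_rise
        return center + np.column_stack(
            [spec.solute_radius * np.cos(theta), spec.solute_radius * np.sin(theta), z]
        )
    raise ValueError(f"unknown solute model {spec.solute_model!r}")


def generate_system_pair(
    spec: SyntheticSystemSpec,
) -> tuple[tuple[Structure, Trajectory], tuple[Structure, Trajectory]]:
    """Matched (solute system, pure-water system) pair.

    Solute system: solute atoms first, then waters filling the box
    outside the union of solute-atom exclusion spheres; per-frame solute
    jitter and independent water resampling.  Pure-water system: same
    box and density, water only.
    """
    box = np.asarray(spec.box, dtype=float)
    rng = np.random.default_rng(spec.seed)
    base = _solute_coords(spec, rng)
    n_solute = len(base)
    n_water_bulk = n_waters_for_density(box, spec.water_density)
    # solute system: reduce the water count by the excluded volume so the
    # far-field density still matches the bulk density
    v_excl = n_solute * (4.0 / 3.0) * math.pi * SOLUTE_EXCLUSION ** 3
    v_box = float(np.prod(box))
    n_water_sol = int(round(n_water_bulk * max(0.0, 1.0 - v_excl / v_box)))

    solute_atoms = [
        AtomRecord(serial=i + 1, name=f"{spec.solute_element}{i + 1}"[:4],
                   residue_name="LIG", residue_id=1, chain="A",
                   element=spec.solute_element, coords=base[i], hetero=False)
        for i in range(n_solute)
    ]
    water_atoms = _water_structure(
        n_water_sol, box, first_serial=n_solute + 1, first_resid=2, chain="W"
    )
    atoms_a = solute_atoms + water_atoms
    mols_a = [list(range(n_solute))] + [
        [n_solute + 3 * i + j for j in range(3)] for i in range(n_water_sol)
    ]

    frames_a = []
    for _ in range(spec.n_frames):
        solute = base + (rng.normal(0.0, spec.jitter_sigma, base.shape)
                         if spec.jitter_sigma > 0 else 0.0)
        oxy = _place_oxygens(
            box, n_water_sol, spec.water_min_dist, rng,
            exclude_centers=solute, exclude_radius=SOLUTE_EXCLUSION,
        )
        frames_a.append(np.vstack([solute, _water_frame(oxy, rng)]))
    frames_a = np.asarray(frames_a)
    struct_a = Structure(
        atoms=[
            AtomRecord(a.serial, a.name, a.residue_name, a.residue_id, a.chain,
                       a.element, frames_a[0][i], a.hetero)
            for i, a in enumerate(atoms_a)
        ],
        molecules=mols_a, box=box,
    )
    traj_a = Trajectory(
        coords=frames_a, boxes=np.tile(box, (spec.n_frames, 1)),
        times=np.arange(spec.n_frames) * DEFAULT_FRAME_SPACING_PS,
    )

    struct_b, traj_b = generate_water_box(
        box, spec.water_density, spec.water_min_dist,
        seed=spec.seed + 1, n_frames=spec.n_frames,
    )
    return (struct_a, traj_a), (struct_b, traj_b)


# ---------------------------------------------------------------------------
# run-length configuration rules

def recommended_frames(n_solute_atoms: int, convergence: str = "normal") -> int:
    """Frame count N_fr = 2·10⁵ / N_A^0.77, with convergence multipliers.

    quick = normal/4, thorough = 5 × normal; floor of 2 frames.  N_A is
    the solute atom count.
    """
    if n_solute_atoms < 1:
        raise ValueError("atom count must be at least 1")
    normal = 2.0e5 / float(n_solute_atoms) ** 0.77
    factor = {"quick": 0.25, "normal": 1.0, "thorough": 5.0}.get(convergence)
    if factor is None:
        raise ValueError(f"unknown convergence level {convergence!r}")
    return max(2, int(round(normal * factor)))


def equilibration_split(total_time: float) -> float:
    """Equilibration discard: max(5% of total, 3 ps), capped at the total."""
    if total_time <= 0:
        raise ValueError("total time must be positive")
    return min(total_time, max(0.05 * total_time, 3.0))
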