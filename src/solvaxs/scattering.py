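"""Scattering amplitudes, orientational averaging and the net intensity.

The net buffer-subtracted intensity is assembled from envelope-restricted
amplitudes of the solute system (A) and a matched pure-water system (B):

    I(q) = ⟨ D(q) ⟩_Ω
    D(q) = ⟨|Ã|²⟩ − ⟨|B̃|²⟩ + 2 Re[ −⟨B̃⟩* ⟨Ã − B̃⟩ ]

where ⟨·⟩ is the average over simulation frames at fixed solute
orientation and ⟨·⟩_Ω the orientational average, evaluated numerically
over q-vectors distributed on each |q|-sphere by a deterministic
golden-angle spiral.  The first term is the scattering of solute plus
hydration layer, the second the excluded solvent, the third the
correlation between bulk water and the density contrast inside the
envelope.

The brute-force Debye sum — exact for the orientational average of a
rigid point-atom configuration — is provided as an independent oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .envelope import Envelope
from .formfactors import FormFactorTable, WATER_HYDROGEN, WATER_OXYGEN
from .io_formats import ScatteringCurve, Structure, Trajectory, WATER_RESIDUES

__all__ = [
    "QGrid",
    "jq_count",
    "spiral_directions",
    "amplitude",
    "intensity",
    "vacuum_intensity",
    "debye_intensity",
    "IntensityOptions",
]

_GOLDEN_ANGLE = math.pi * (3.0 - math.sqrt(5.0))


@dataclass(frozen=True)
class QGrid:
    """Strictly increasing q magnitudes (Å⁻¹), 0 … q_max."""

    q: np.ndarray

    def __post_init__(self):
        q = np.asarray(self.q, dtype=float)
        if q.ndim != 1 or len(q) < 2:
            raise ValueError("q grid needs at least 2 points")
        if q[0] < 0 or not np.all(np.diff(q) > 0):
            raise ValueError("q grid must be non-negative and strictly increasing")
        object.__setattr__(self, "q", q)

    @classmethod
    def uniform(cls, q_max: float = 1.0, n_q: int = 101) -> "QGrid":
        return cls(np.linspace(0.0, q_max, n_q))


def jq_count(q: float, D: float) -> int:
    """Number of q-vectors per |q|-shell: J_q = max{100, 0.2 (qD)²}.

    D is the maximum diameter of the scattering volume; the quadratic
    growth keeps the spherical-quadrature error roughly q-independent.
    """
    if q < 0:
        raise ValueError("q must be non-negative")
    if D <= 0:
        raise ValueError("diameter D must be positive")
    return max(100, math.ceil(0.2 * (q * D) ** 2))


def spiral_directions(J: int) -> np.ndarray:
    """J unit vectors spread near-uniformly by the golden-angle spiral.

    Deterministic: z descends uniformly through (−1, 1) at half-step
    offsets while the azimuth advances by the golden angle.
    """
    if J < 1:
        raise ValueError("J must be at least 1")
    k = np.arange(J)
    z = 1.0 - (2.0 * k + 1.0) / J
    r = np.sqrt(np.maximum(1.0 - z * z, 0.0))
    phi = k * _GOLDEN_ANGLE
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _species_keys(structure: Structure) -> list[str]:
    """Form-factor key per atom; water atoms map to the OW/HW species."""
    keys = [a.element for a in structure.atoms]
    for mol in structure.molecules:
        if structure.is_water(mol):
            for i in mol:
                el = structure.atoms[i].element.capitalize()
                keys[i] = WATER_OXYGEN if el == "O" else WATER_HYDROGEN
    return keys


def _group_by_species(keys: list[str]) -> dict[str, np.ndarray]:
    groups: dict[str, list[int]] = {}
    for i, k in enumerate(keys):
        groups.setdefault(k, []).append(i)
    return {k: np.asarray(v, dtype=int) for k, v in groups.items()}


def amplitude(
    coords: np.ndarray,
    elements: list[str] | np.ndarray,
    table: FormFactorTable,
    qvecs: np.ndarray,
) -> np.ndarray:
    """Scattering amplitude Ã(q) = Σ_j f_j(q) exp(−i q·r_j).

    ``qvecs`` may be a single 3-vector or an (J, 3) array; form factors
    are evaluated at |q| per vector.  Returns complex electrons.
    """
    qv = np.atleast_2d(np.asarray(qvecs, dtype=float))
    coords = np.asarray(coords, dtype=float)
    qmag = np.linalg.norm(qv, axis=1)
    out = np.zeros(len(qv), dtype=complex)
    groups = _group_by_species(list(elements))
    phases = np.exp(-1j * (coords @ qv.T))  # (N, J)
    for key, idx in groups.items():
        f = table[key](qmag)  # (J,)
        out += f * phases[idx].sum(axis=0)
    if np.asarray(qvecs).ndim == 1:
        return out[0]
    return out


def _frame_amplitudes(
    frames: np.ndarray,
    keys: list[str],
    table: FormFactorTable,
    qvecs: np.ndarray,
    envelope: Envelope | None,
) -> np.ndarray:
    """(n_frames, J) complex amplitudes, envelope-selected per frame."""
    out = np.empty((len(frames), len(qvecs)), dtype=complex)
    keys_arr = np.asarray(keys)
    for i, frame in enumerate(frames):
        if envelope is not None:
            sel = envelope.select_inside(frame)
            out[i] = amplitude(frame[sel], keys_arr[sel], table, qvecs)
        else:
            out[i] = amplitude(frame, keys_arr, table, qvecs)
    return out


@dataclass
class IntensityOptions:
    """Knobs of the intensity calculation.

    n_blocks controls the jackknife error estimate: frames are split
    into up to 10 contiguous blocks and I(q) is recomputed per
    leave-one-block-out replicate.
    """

    n_blocks: int = 10
    jq_override: int | None = None  #: fixed J per shell (testing/convergence)
    diameter: float | None = None  #: override D in the J_q rule
    seed: int | None = None


def _block_edges(n: int, n_blocks: int) -> list[np.ndarray]:
    """Split frame indices 0..n-1 into contiguous blocks."""
    n_blocks = max(1, min(n_blocks, n))
    return list(np.array_split(np.arange(n), n_blocks))


def _d_from_blocks(sa2, sa, sb2, sb, na, nb):
    """Assemble D(q) per q-vector from summed amplitude statistics."""
    ma2, ma = sa2 / na, sa / na
    mb2, mb = sb2 / nb, sb / nb
    return ma2 - mb2 + 2.0 * np.real(-np.conj(mb) * (ma - mb))


def intensity(
    solute_structure: Structure,
    solute_traj: Trajectory,
    water_structure: Structure | None,
    water_traj: Trajectory | None,
    envelope: Envelope,
    qgrid: QGrid,
    table: FormFactorTable,
    options: IntensityOptions | None = None,
) -> ScatteringCurve:
    """Buffer-subtracted intensity I(q) with jackknife error estimate.

    With no water system ("vacuum mode") the curve reduces to the
    orientational average of ⟨|Ã|²⟩ alone.  The per-q mean excluded-
    solvent term ⟨|B̃|²⟩ (orientation-averaged) is stored in
    ``meta["buffer_intensity"]`` for use by the subtraction schemes.
    """
    opts = options or IntensityOptions()
    if solute_traj.n_frames < 1:
        raise ValueError("solute trajectory has no frames")
    vacuum = water_traj is None
    if not vacuum:
        if water_structure is None:
            raise ValueError("water trajectory given without its structure")
        if water_traj.n_frames < 2 or solute_traj.n_frames < 2:
            raise ValueError("need at least 2 frames per system for the frame averages")
        _check_envelope_fits(envelope, water_traj)

    D = opts.diameter if opts.diameter is not None else envelope.diameter()
    keys_a = _species_keys(solute_structure)
    keys_b = _species_keys(water_structure) if not vacuum else None

    na, nb = solute_traj.n_frames, (water_traj.n_frames if not vacuum else 0)
    blocks_a = _block_edges(na, opts.n_blocks)
    blocks_b = _block_edges(nb, opts.n_blocks) if not vacuum else []
    n_blocks = min(len(blocks_a), len(blocks_b)) if not vacuum else len(blocks_a)

    I = np.empty(len(qgrid.q))
    sigma = np.zeros(len(qgrid.q))
    buffer_I = np.zeros(len(qgrid.q))
    for iq, q in enumerate(qgrid.q):
        J = opts.jq_override or jq_count(q, D)
        qvecs = q * spiral_directions(J)
        amps_a = _frame_amplitudes(solute_traj.coords, keys_a, table, qvecs, envelope)
        if vacuum:
            per_block_a2 = np.stack([(np.abs(amps_a[b]) ** 2).sum(axis=0) for b in blocks_a])
            tot_a2 = per_block_a2.sum(axis=0)
            I[iq] = float((tot_a2 / na).mean())
            if n_blocks > 1:
                reps = [
                    float(((tot_a2 - per_block_a2[k]) / (na - len(blocks_a[k]))).mean())
                    for k in range(n_blocks)
                ]
                sigma[iq] = _jackknife_se(np.asarray(reps))
            continue
        amps_b = _frame_amplitudes(water_traj.coords, keys_b, table, qvecs, envelope)
        pb_a2 = np.stack([(np.abs(amps_a[b]) ** 2).sum(axis=0) for b in blocks_a[:n_blocks]])
        pb_a = np.stack([amps_a[b].sum(axis=0) for b in blocks_a[:n_blocks]])
        pb_b2 = np.stack([(np.abs(amps_b[b]) ** 2).sum(axis=0) for b in blocks_b[:n_blocks]])
        pb_b = np.stack([amps_b[b].sum(axis=0) for b in blocks_b[:n_blocks]])
        ca = np.array([len(b) for b in blocks_a[:n_blocks]])
        cb = np.array([len(b) for b in blocks_b[:n_blocks]])
        d_full = _d_from_blocks(
            pb_a2.sum(0), pb_a.sum(0), pb_b2.sum(0), pb_b.sum(0), ca.sum(), cb.sum()
        )
        I[iq] = float(d_full.mean())
        buffer_I[iq] = float((pb_b2.sum(0) / cb.sum()).mean())
        if n_blocks > 1:
            reps = []
            for k in range(n_blocks):
                d_k = _d_from_blocks(
                    pb_a2.sum(0) - pb_a2[k], pb_a.sum(0) - pb_a[k],
                    pb_b2.sum(0) - pb_b2[k], pb_b.sum(0) - pb_b[k],
                    ca.sum() - ca[k], cb.sum() - cb[k],
                )
                reps.append(float(d_k.mean()))
            sigma[iq] = _jackknife_se(np.asarray(reps))

    meta = {
        "envelope_distance": envelope.build_distance,
        "envelope_volume": envelope.volume(),
        "envelope_diameter": D,
        "n_frames_solute": na,
        "n_frames_water": nb,
        "subtraction_scheme": "vacuum" if vacuum else "total",
        "buffer_intensity": buffer_I,
    }
    if opts.seed is not None:
        meta["seed"] = opts.seed
    return ScatteringCurve(q=qgrid.q.copy(), I=I, sigma_stat=sigma, meta=meta)


def vacuum_intensity(
    coords: np.ndarray,
    elements,
    table: FormFactorTable,
    qgrid: QGrid,
    D: float | None = None,
    jq_override: int | None = None,
) -> ScatteringCurve:
    """Spiral-averaged |Ã|² of a rigid configuration (no solvent).

    D defaults to the point cloud's maximum extent (needed by the J_q
    rule); the result is directly comparable to :func:`debye_intensity`.
    """
    coords = np.asarray(coords, dtype=float)
    if D is None:
        spread = coords.max(axis=0) - coords.min(axis=0)
        D = max(float(np.linalg.norm(spread)), 1.0)
    I = np.empty(len(qgrid.q))
    for iq, q in enumerate(qgrid.q):
        J = jq_override or jq_count(q, D)
        qvecs = q * spiral_directions(J)
        amp = amplitude(coords, elements, table, qvecs)
        I[iq] = float(np.mean(np.abs(amp) ** 2))
    return ScatteringCurve(q=qgrid.q.copy(), I=I, meta={"mode": "vacuum", "diameter": D})


def _jackknife_se(replicates: np.ndarray) -> float:
    n = len(replicates)
    return float(np.sqrt((n - 1) / n * np.sum((replicates - replicates.mean()) ** 2)))


def _check_envelope_fits(envelope: Envelope, water_traj: Trajectory) -> None:
    """The envelope must fit inside the water box in every frame, else
    the excluded-solvent region cannot be filled."""
    extent = envelope.surface_vertices
    span = extent.max(axis=0) - extent.min(axis=0)
    boxes = water_traj.boxes
    if np.any(boxes <= 0):
        raise ValueError("water system has no defined box")
    if np.any(span[None, :] > boxes + 1e-6):
        raise ValueError(
            f"envelope extent {span} exceeds the water box {boxes.min(axis=0)}; "
            "use a larger water system"
        )


def debye_intensity(
    coords: np.ndarray,
    elements,
    table: FormFactorTable,
    q,
) -> np.ndarray:
    """Exact orientationally averaged intensity of rigid point atoms.

    I(q) = Σ_j Σ_k f_j f_k sinc(q r_jk); the j=k and q→0 limits are 1.
    O(N²) — intended as a validation oracle for ≲ 10³ atoms.
    """
    from scipy.spatial.distance import pdist, squareform

    coords = np.asarray(coords, dtype=float)
    scalar_q = np.ndim(q) == 0
    q = np.atleast_1d(np.asarray(q, dtype=float))
    n = len(coords)
    if n > 2000:
        raise ValueError("Debye oracle is O(N²); use < 2000 atoms")
    rjk = squareform(pdist(coords)) if n > 1 else np.zeros((1, 1))
    out = np.empty(len(q))
    for iq, qi in enumerate(q):
        f = np.array([float(table[el](qi)) for el in elements])
        x = qi * rjk
        with np.errstate(invalid="ignore", divide="ignore"):
            sinc = np.where(x > 1e-12, np.sin(x) / np.where(x > 1e-12, x, 1.0), 1.0)
        out[iq] = float(f @ sinc @ f)
    return out[0] if scalar_q else out
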