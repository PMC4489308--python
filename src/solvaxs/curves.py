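"""Buffer-subtraction schemes, experimental-curve fitting and Guinier
analysis.

Two subtraction conventions are supported:

    total:    I(q) = I_sam(q) − I_buf(q)
    reduced:  I(q) = I_sam(q) − (1 − v) I_buf(q)

where v is the solute volume fraction.  The computed three-term net
intensity already realises the total scheme; the reduced scheme adds
back v·I_buf with a per-particle buffer term estimated from the
excluded-solvent intensity scaled by V_solute/V_envelope — an explicit
approximation, flagged in the output metadata.

Experimental curves are fitted **to** the prediction (never the other
way around), since the prediction carries no free parameters: only a
scale f and a constant offset c are adjusted, by either an
error-weighted χ² or a log-space χ² that weights small and wide angles
more evenly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .io_formats import ExperimentalCurve, ScatteringCurve

__all__ = [
    "SubtractionOptions",
    "FitResult",
    "GuinierResult",
    "apply_subtraction",
    "fit_chi2",
    "fit_chi2log",
    "guinier_fit",
    "convert_q",
    "convert_curve",
]


# ---------------------------------------------------------------------------
# units

def convert_q(values, from_units: str = "A^-1", from_convention: str = "q") -> np.ndarray:
    """Convert scattering vectors to internal Å⁻¹, q-convention.

    q = 4π sinθ/λ and s = 2 sinθ/λ, hence q = 2π s; nm⁻¹ → Å⁻¹ divides
    by 10.
    """
    v = np.asarray(values, dtype=float)
    if np.any(v < 0):
        raise ValueError("scattering vectors must be non-negative")
    if from_units == "nm^-1":
        v = v / 10.0
    elif from_units != "A^-1":
        raise ValueError(f"unknown units {from_units!r}")
    if from_convention == "s":
        v = 2.0 * np.pi * v
    elif from_convention != "q":
        raise ValueError(f"unknown convention {from_convention!r}")
    return v


def convert_curve(curve: ExperimentalCurve) -> ExperimentalCurve:
    """Return the curve on the internal Å⁻¹ / q-convention axis."""
    return ExperimentalCurve(
        q=convert_q(curve.q, curve.q_units, curve.convention),
        I=curve.I.copy(),
        sigma=None if curve.sigma is None else curve.sigma.copy(),
        q_units="A^-1",
        convention="q",
    )


# ---------------------------------------------------------------------------
# buffer subtraction

@dataclass
class SubtractionOptions:
    """scheme: 'total' or 'reduced'; v the solute volume fraction, or
    V_solute (Å³) from which v is estimated as V_solute / V_envelope."""

    scheme: str = "reduced"
    v: float | None = None
    V_solute: float | None = None

    def resolve_v(self, V_envelope: float | None) -> float:
        if self.v is not None:
            if not 0.0 <= self.v < 1.0:
                raise ValueError("volume fraction v must be in [0, 1)")
            return self.v
        if self.V_solute is not None:
            if V_envelope is None or V_envelope <= 0:
                raise ValueError("V_envelope required to resolve v from V_solute")
            return float(self.V_solute) / float(V_envelope)
        raise ValueError("reduced scheme requires v or V_solute")


def apply_subtraction(
    raw: ScatteringCurve, opts: SubtractionOptions
) -> ScatteringCurve:
    """Apply the requested buffer-subtraction scheme to a computed curve.

    ``raw`` must come from :func:`solvaxs.scattering.intensity`, which
    realises the total scheme and stores the orientation-averaged
    excluded-solvent term in ``meta["buffer_intensity"]``.  The reduced
    scheme adds v·I_buf with I_buf ≈ (V_solute/V_envelope)·⟨|B̃|²⟩.
    """
    if opts.scheme == "total":
        out = ScatteringCurve(
            raw.q.copy(), raw.I.copy(),
            None if raw.sigma_stat is None else raw.sigma_stat.copy(),
            dict(raw.meta),
        )
        out.meta["subtraction_scheme"] = "total"
        return out
    if opts.scheme != "reduced":
        raise ValueError(f"unknown subtraction scheme {opts.scheme!r}")
    V_env = raw.meta.get("envelope_volume")
    v = opts.resolve_v(V_env)
    if raw.meta.get("buffer_intensity") is None:
        raise ValueError("raw curve carries no buffer intensity; recompute with a water system")
    buf = np.asarray(raw.meta["buffer_intensity"])
    if buf.shape != raw.I.shape:
        raise ValueError("buffer intensity does not match the curve grid")
    # Per-particle buffer term: the excluded-solvent intensity scaled to
    # the solute's own volume when that volume is known.
    frac = (opts.V_solute / V_env) if (opts.V_solute is not None and V_env) else 1.0
    i_buf = frac * buf
    out = ScatteringCurve(
        raw.q.copy(), raw.I + v * i_buf,
        None if raw.sigma_stat is None else raw.sigma_stat.copy(),
        dict(raw.meta),
    )
    out.meta["subtraction_scheme"] = "reduced"
    out.meta["volume_fraction"] = v
    out.meta["buffer_term_approximation"] = "v * (V_solute/V_envelope) * <|B|^2>"
    return out


# ---------------------------------------------------------------------------
# fitting

@dataclass
class FitResult:
    f: float
    c: float
    chi2: float | None
    chi2log: float | None
    fitted_curve: ExperimentalCurve
    meta: dict = field(default_factory=dict)

    @property
    def chi(self) -> float | None:
        return None if self.chi2 is None else float(np.sqrt(self.chi2))

    @property
    def chilog(self) -> float | None:
        return None if self.chi2log is None else float(np.sqrt(self.chi2log))


def _overlap(calc: ScatteringCurve, exp: ExperimentalCurve):
    """Interpolate the calculated curve onto the experimental grid.

    The experimental curve is first converted to Å⁻¹/q-convention; points
    outside the computed q-range are dropped, never extrapolated.
    """
    e = convert_curve(exp)
    mask = (e.q >= calc.q[0] - 1e-12) & (e.q <= calc.q[-1] + 1e-12)
    if mask.sum() < 3:
        raise ValueError("fewer than 3 experimental points overlap the computed q-range")
    qe = e.q[mask]
    Ie = e.I[mask]
    se = e.sigma[mask] if e.sigma is not None else None
    Ic = np.interp(qe, calc.q, calc.I)
    return qe, Ic, Ie, se


def _metrics(Ic, Ie, se, f, c):
    resid = Ic - (f * Ie + c)
    chi2 = float(np.mean((resid / se) ** 2)) if se is not None else None
    chi2log = None
    fit = f * Ie + c
    if np.all(fit > 0) and np.all(Ic > 0):
        chi2log = float(np.mean((np.log(Ic) - np.log(fit)) ** 2))
    return chi2, chi2log


def fit_chi2(calc: ScatteringCurve, exp: ExperimentalCurve) -> FitResult:
    """Error-weighted fit of the experimental curve to the prediction.

    Minimises N⁻¹ Σ [(I_calc − (f I_exp + c))/σ_exp]² over (f, c) by the
    closed-form weighted normal equations.  Falls back to the log-space
    metric when σ is absent.
    """
    if exp.sigma is None:
        import warnings

        warnings.warn(
            "experimental curve has no errors; falling back to the log-space fit",
            stacklevel=2,
        )
        return fit_chi2log(exp=exp, calc=calc)
    qe, Ic, Ie, se = _overlap(calc, exp)
    w = 1.0 / se ** 2
    # normal equations for Ic ≈ f*Ie + c under weights w
    S = np.sum(w)
    Sx = np.sum(w * Ie)
    Sy = np.sum(w * Ic)
    Sxx = np.sum(w * Ie * Ie)
    Sxy = np.sum(w * Ie * Ic)
    det = S * Sxx - Sx * Sx
    if abs(det) < 1e-300:
        raise ValueError("degenerate fit: experimental intensities are constant")
    f = (S * Sxy - Sx * Sy) / det
    c = (Sxx * Sy - Sx * Sxy) / det
    chi2, chi2log = _metrics(Ic, Ie, se, f, c)
    fitted = ExperimentalCurve(q=qe, I=f * Ie + c, sigma=f * se)
    return FitResult(f=f, c=c, chi2=chi2, chi2log=chi2log, fitted_curve=fitted,
                     meta={"metric": "chi2", "n_points": len(qe)})


def fit_chi2log(calc: ScatteringCurve, exp: ExperimentalCurve) -> FitResult:
    """Log-space fit: minimises N⁻¹ Σ [log I_calc − log(f I_exp + c)]².

    Deterministic two-stage search: a coarse logarithmic grid over f with
    the optimal c from a bounded one-dimensional search, then a
    derivative-free polish.  Requires I_calc > 0 on the overlap and
    enforces f·I_exp + c > 0.
    """
    qe, Ic, Ie, se = _overlap(calc, exp)
    if np.any(Ic <= 0):
        raise ValueError("log-space fit requires positive calculated intensities")
    logIc = np.log(Ic)

    def cost(f, c):
        fit = f * Ie + c
        if np.any(fit <= 0):
            return np.inf
        return float(np.mean((logIc - np.log(fit)) ** 2))

    def best_c(f):
        scale = np.max(np.abs(Ic)) + np.max(np.abs(f * Ie))
        lo = -float(np.min(f * Ie)) + 1e-12 * scale
        res = optimize.minimize_scalar(
            lambda c: cost(f, c), bounds=(lo, scale), method="bounded",
            options={"xatol": 1e-12 * scale},
        )
        return float(res.x), float(res.fun)

    f0 = np.median(Ic / np.where(np.abs(Ie) > 1e-300, Ie, 1e-300))
    f0 = abs(f0) if f0 != 0 else 1.0
    fs = f0 * np.logspace(-2, 2, 41)
    coarse = [(cost_f, f, c) for f, (c, cost_f) in ((f, best_c(f)) for f in fs)]
    _, f_best, c_best = min(coarse)
    res = optimize.minimize(
        lambda p: cost(p[0], p[1]), x0=[f_best, c_best], method="Nelder-Mead",
        options={"xatol": 1e-14, "fatol": 1e-16, "maxiter": 4000},
    )
    f, c = float(res.x[0]), float(res.x[1])
    chi2, chi2log = _metrics(Ic, Ie, se, f, c)
    fitted = ExperimentalCurve(q=qe, I=f * Ie + c, sigma=None if se is None else f * se)
    return FitResult(f=f, c=c, chi2=chi2, chi2log=chi2log, fitted_curve=fitted,
                     meta={"metric": "chi2log", "n_points": len(qe)})


# ---------------------------------------------------------------------------
# Guinier analysis

@dataclass
class GuinierResult:
    I0: float
    Rg: float
    q_range_used: tuple[float, float]
    n_points: int

    def __post_init__(self):
        if self.Rg <= 0:
            raise ValueError("Rg must be positive")


#: Upper bound on q·Rg for points admitted to the Guinier window.
GUINIER_QRG_MAX = 1.3


def guinier_fit(curve: ScatteringCurve, qrg_max: float = GUINIER_QRG_MAX) -> GuinierResult:
    """Guinier analysis: ln I ≈ ln I0 − q²Rg²/3 at low q.

    Starts from the lowest 20% of points and iterates the q·Rg < qrg_max
    window to self-consistency.  I0 = exp(intercept), Rg = √(−3·slope).
    """
    q = np.asarray(curve.q, dtype=float)
    I = np.asarray(curve.I, dtype=float)
    pos = I > 0
    q, I = q[pos], I[pos]
    if len(q) < 5:
        raise ValueError("need at least 5 positive-intensity points for a Guinier fit")
    n0 = max(5, int(0.2 * len(q)))
    sel = np.zeros(len(q), dtype=bool)
    sel[:n0] = True
    for _ in range(50):
        if sel.sum() < 5:
            raise ValueError("Guinier window shrank below 5 points")
        slope, intercept = np.polyfit(q[sel] ** 2, np.log(I[sel]), 1)
        if slope >= 0:
            raise ValueError("non-physical Guinier fit: intensity does not decay at low q")
        rg = float(np.sqrt(-3.0 * slope))
        new_sel = q * rg <= qrg_max
        if new_sel.sum() < 5:
            new_sel = np.zeros(len(q), dtype=bool)
            new_sel[:5] = True
        if np.array_equal(new_sel, sel):
            break
        sel = new_sel
    return GuinierResult(
        I0=float(np.exp(intercept)),
        Rg=rg,
        q_range_used=(float(q[sel].min()), float(q[sel].max())),
        n_points=int(sel.sum()),
    )
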