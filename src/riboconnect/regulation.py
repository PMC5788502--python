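"""Quantitative ligand → translation model.

A device's effect on its target is factored into four saturating terms:

* **occupancy** θ(L) = L^h / (K^h + L^h) — Hill binding of the sensed ligand
  (or protein) at concentration L, with half-occupancy constant K (µM) and
  Hill coefficient h;
* **valency** v(c) = [c/(c+κ)] / [2/(2+κ)] — diminishing returns from adding
  aptamer copies, normalized so the 2-copy reference device has v = 1.
  One copy is markedly weaker, a third copy adds little;
* **efficacy** — the structural composite score of the design in (0, 1];
* the device ceiling — maximal fractional repression Emax_r in [0, 1) for
  roadblock devices, maximal fold-activation Fmax ≥ 1 for eIF4G-recruitment
  devices.

Relative expression under repression:  E = 1 − Emax_r · v(c) · efficacy · θ(L)
Fold-activation:                       F = 1 + (Fmax − 1) · v(c) · efficacy · θ

``calibrate`` fits (K, h, Emax_r | Fmax) to dose-response tables with a
deterministic multi-start grid followed by local least squares.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

ALLOWED_COPIES = (1, 2, 3)
REFERENCE_COPIES = 2  # valency normalization anchor


class RegulationError(ValueError):
    """Raised for out-of-range parameters or unidentifiable fits."""


@dataclass(frozen=True)
class RegulationParams:
    """Occupancy/efficacy parameters of one device.

    K: µM at half-occupancy; h: Hill coefficient; Emax_r: maximal fractional
    repression; Fmax: maximal fold-activation; kappa: valency
    half-saturation (copies).
    """

    K: float = 300.0
    h: float = 1.3
    Emax_r: float = 0.9
    Fmax: float = 15.0
    kappa: float = 0.5

    def __post_init__(self):
        if self.K <= 0:
            raise RegulationError(f"K must be > 0 (got {self.K})")
        if self.h <= 0:
            raise RegulationError(f"h must be > 0 (got {self.h})")
        if not (0 <= self.Emax_r < 1):
            raise RegulationError(f"Emax_r must be in [0, 1) (got {self.Emax_r})")
        if self.Fmax < 1:
            raise RegulationError(f"Fmax must be >= 1 (got {self.Fmax})")
        if self.kappa <= 0:
            raise RegulationError(f"kappa must be > 0 (got {self.kappa})")


@dataclass(frozen=True)
class DoseResponsePoint:
    """One measured (dose µM, relative response) pair."""

    dose: float
    response: float

    def __post_init__(self):
        if self.dose < 0:
            raise RegulationError(f"dose must be >= 0 (got {self.dose})")
        if self.response <= 0:
            raise RegulationError(f"response must be > 0 (got {self.response})")


def occupancy(L: float, params: RegulationParams) -> float:
    """Hill occupancy θ = L^h / (K^h + L^h) ∈ [0, 1)."""
    if L < 0:
        raise RegulationError(f"concentration must be >= 0 (got {L})")
    if L == 0:
        return 0.0
    r = (L / params.K) ** params.h
    return r / (1.0 + r)


def valency_scale(copies: int, kappa: float = 0.5) -> float:
    """Saturating copy-number scale, v(2) = 1 by convention.

    v(c) = [c/(c+κ)] / [2/(2+κ)].  Strictly increasing in c with shrinking
    gaps, reproducing the observed ordering: one copy much weaker than two,
    a third copy only marginally stronger.
    """
    if copies not in ALLOWED_COPIES:
        raise RegulationError(f"copies must be one of {ALLOWED_COPIES} (got {copies})")
    if kappa <= 0:
        raise RegulationError(f"kappa must be > 0 (got {kappa})")
    raw = copies / (copies + kappa)
    ref = REFERENCE_COPIES / (REFERENCE_COPIES + kappa)
    return raw / ref


def repression_output(
    efficacy: float, copies: int, L: float, params: RegulationParams
) -> float:
    """Relative expression under a roadblock repressor.

    E = 1 − Emax_r · v(copies) · efficacy · θ(L); equals 1 at L = 0.
    """
    _check_efficacy(efficacy)
    theta = occupancy(L, params)
    v = valency_scale(copies, params.kappa)
    return 1.0 - params.Emax_r * v * efficacy * theta


def activation_output(
    efficacy: float, copies: int, theta_sensor: float, params: RegulationParams
) -> float:
    """Fold-activation of an eIF4G-recruitment device.

    F = 1 + (Fmax − 1) · v(copies) · efficacy · θ_sensor.  Pass
    ``theta_sensor = 1`` for a constitutive (ungated) activator.
    """
    _check_efficacy(efficacy)
    if not (0 <= theta_sensor <= 1):
        raise RegulationError(f"theta_sensor must be in [0, 1] (got {theta_sensor})")
    v = valency_scale(copies, params.kappa)
    return 1.0 + (params.Fmax - 1.0) * v * efficacy * theta_sensor


def _check_efficacy(efficacy: float) -> None:
    if not (0 <= efficacy <= 1):
        raise RegulationError(f"efficacy must be in [0, 1] (got {efficacy})")


# ---------------------------------------------------------------------------
# calibration


def _model_response(doses: np.ndarray, K: float, h: float, ceil: float, mode: str) -> np.ndarray:
    with np.errstate(divide="ignore"):
        r = np.where(doses > 0, (doses / K) ** h, 0.0)
    theta = r / (1.0 + r)
    if mode == "repression":
        return 1.0 - ceil * theta  # ceil = Emax_r
    return 1.0 + (ceil - 1.0) * theta  # ceil = Fmax


def calibrate(
    points: Sequence[DoseResponsePoint],
    mode: str,
    fixed: Optional[dict] = None,
) -> tuple[RegulationParams, dict]:
    """Fit (K, h, Emax_r | Fmax) to a dose-response table.

    Deterministic multi-start: a 3×3×3 grid of log-spaced starting values
    feeds a bounded local least-squares fit; the best finishing point wins.
    ``fixed`` pins any subset of {"K", "h", "Emax_r", "Fmax"}.  Returns the
    fitted params (kappa left at its default) and diagnostics with keys
    ``rmse``, ``residuals``, ``converged``.
    """
    if mode not in ("repression", "activation"):
        raise RegulationError(f"mode must be repression|activation (got {mode!r})")
    if len(points) < 4:
        raise RegulationError(f"need >= 4 dose-response points (got {len(points)})")
    doses = np.array([p.dose for p in points], dtype=float)
    resp = np.array([p.response for p in points], dtype=float)
    if np.allclose(resp, resp[0]):
        raise RegulationError("all responses equal: parameters unidentifiable")

    fixed = dict(fixed or {})
    ceil_name = "Emax_r" if mode == "repression" else "Fmax"
    names = [n for n in ("K", "h", ceil_name) if n not in fixed]

    pos = doses[doses > 0]
    k_grid = np.geomspace(max(pos.min(), 1e-6), pos.max(), 3) if len(pos) else np.array([1.0, 10.0, 100.0])
    h_grid = np.array([0.7, 1.3, 2.5])
    if mode == "repression":
        c_grid = np.array([0.3, 0.6, 0.95])
        c_bounds = (1e-6, 1.0 - 1e-9)
    else:
        c_grid = np.array([2.0, 8.0, 25.0])
        c_bounds = (1.0, 1e4)
    grids = {"K": k_grid, "h": h_grid, ceil_name: c_grid}
    bounds = {"K": (1e-9, 1e9), "h": (0.05, 10.0), ceil_name: c_bounds}

    def unpack(x: np.ndarray) -> dict:
        full = dict(fixed)
        full.update(dict(zip(names, x)))
        return full

    def residuals(x: np.ndarray) -> np.ndarray:
        p = unpack(x)
        return _model_response(doses, p["K"], p["h"], p[ceil_name], mode) - resp

    lo = np.array([bounds[n][0] for n in names])
    hi = np.array([bounds[n][1] for n in names])

    best = None
    if names:
        starts = [np.array([g for g in combo]) for combo in _grid_product([grids[n] for n in names])]
        for x0 in starts:
            x0 = np.clip(x0, lo, hi)
            sol = least_squares(residuals, x0, bounds=(lo, hi), method="trf")
            if best is None or sol.cost < best.cost:
                best = sol
        x_fit = best.x
        converged = bool(best.success)
        res = residuals(x_fit)
    else:  # everything fixed: nothing to fit, just report fit quality
        x_fit = np.array([])
        converged = True
        res = residuals(x_fit)

    p = unpack(x_fit)
    params = RegulationParams(
        K=float(p.get("K", 300.0)),
        h=float(p.get("h", 1.3)),
        Emax_r=float(p.get("Emax_r", 0.0)) if mode == "repression" else 0.0,
        Fmax=float(p.get("Fmax", 1.0)) if mode == "activation" else 1.0,
    )
    diagnostics = {
        "rmse": float(np.sqrt(np.mean(res**2))),
        "residuals": res.tolist(),
        "converged": converged,
        "mode": mode,
    }
    return params, diagnostics


def _grid_product(grids: list) -> Iterable[tuple]:
    from itertools import product

    return product(*grids)


def simulate_dose_response(
    doses: Sequence[float],
    params: RegulationParams,
    mode: str,
    noise_cv: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> list[DoseResponsePoint]:
    """Generate a dose-response table from known parameters, optionally with
    multiplicative lognormal-free Gaussian noise of coefficient ``noise_cv``
    (used for calibration round-trip and recovery tests)."""
    d = np.asarray(doses, dtype=float)
    ceil = params.Emax_r if mode == "repression" else params.Fmax
    resp = _model_response(d, params.K, params.h, ceil, mode)
    if noise_cv > 0:
        if rng is None:
            raise RegulationError("noise requested without an rng")
        resp = resp * (1.0 + noise_cv * rng.standard_normal(len(d)))
        resp = np.clip(resp, 1e-6, None)
    return [DoseResponsePoint(float(x), float(y)) for x, y in zip(d, resp)]
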