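"""Model calibration: 1982 steady state and 1982-2013 curve fitting.

Calibration has two stages.

1.  **Steady-state anchoring.**  The pre-campaign (1982) era is treated as an
    equilibrium: the chain with time-constant 1982 probabilities must be
    stationary at outputs matching three anchors — the 1982 diagnostic
    incidence, the 1982 melanoma mortality, and the diagnosed-thin-melanoma
    prevalence.  The detection level D0, the progression ratio p and the
    late-stage probabilities (q, t4..t7) are fixed at their configured
    values; the intrinsic incidence I0, the Stage-1 progression rate r, the
    incidence-partition fractions f23/f4 and the background death rate d are
    adjusted by bounded least squares inside per-parameter boxes around
    their seeds (see :data:`FREE_BOUNDS`), with a weak pull toward the
    seeds to select among equally good solutions.  (d must be free: at stationarity the identity
    incidence = mortality + d * diagnosed-prevalence pins it near 0.0069,
    slightly above its whole-population seed of 0.006.)

2.  **Curve fitting.**  With the 1982 state as initial condition, the model
    is run 1982-2013 under a candidate monotone detection curve D(t) and an
    intrinsic-incidence parabola I(t) = a + b u + c u^2 (u = t/31, a pinned
    to the calibrated I0).  (b, c) are found by exhaustive search on a
    100 x 100 log-spaced grid spanning two orders of magnitude per axis
    (both signs of c), scoring each candidate by the pooled RMS relative
    deviation between the model's annual incidence/mortality output and the
    emulated observed series.

Repeating stage 2 over ten (D0, p) configurations and a small family of
D(t) candidates yields the ten best-fit models the scenario analyses use.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from . import model_core as mc
from .curves import (CurveSet, CurveSpec, constant_curve, curve_from_dict,
                     curve_to_dict, evaluate_curve, make_curve,
                     quadratic_curve, HORIZON)
from .model_core import ParameterSet, PER_100K
from .synthetic_aihw import AnchorSet, build_observed_series, OBS_YEARS

#: The ten model configurations explored: two 1982 detection levels times
#: five progression ratios.
D0_VALUES = (0.01, 0.05)
P_VALUES = (2.0, 5.0, 15.0, 50.0, 125.0)
CONFIG_GRID = tuple((d0, p) for d0 in D0_VALUES for p in P_VALUES)

#: Monotone families tried for D(t).
D_FAMILIES = ("linear", "parabola_up", "parabola_down", "sigmoid")

#: Candidate 2013 detection levels per 1982 level (each a different maximal
#: increase in secondary prevention).
DEFAULT_D31 = {0.05: (0.075, 0.10, 0.15), 0.01: (0.02, 0.05, 0.10)}

#: Parameters adjusted by the 1982 steady-state calibration.
FREE_PARAMS = ("I0", "r", "f23", "f4", "d")

#: Search box per free parameter, as multiples of its seed.  I0 and d are
#: well-determined by data (overall incidence scale; whole-population death
#: rate) and stay within +/-50% of their seeds.  r and the partition
#: fractions are only loosely pinned by published data and vary strongly
#: with the (D0, p) geometry — at D0 = 0.01 the undiagnosed Stage-1 pool is
#: five times larger, so matching the 1982 mortality anchor needs r well
#: below half its seed — hence their wider leash.
FREE_BOUNDS = {
    "I0": (0.5, 1.5),
    "r": (0.05, 3.0),
    "f23": (0.0, 2.0),
    "f4": (0.0, 2.0),
    "d": (0.5, 1.5),
}


class CalibrationError(RuntimeError):
    """No acceptable parameter set inside the search box."""


def default_parameters(d0: float, p: float) -> ParameterSet:
    """Seed parameter set for one (D0, p) configuration.

    The fixed values are the model's standard configuration (q = 0.37,
    d = 0.006, t4 = 0.2, t5 = 0.9, t6 = 0.1, t7 = 0.168); the free seeds
    are I0 = 0.00031, r = 0.00375 and a Stage-1-dominated incidence split
    f23 = 0.03, f4 = 0.01.
    """
    return ParameterSet(I0=3.1e-4, D0=d0, O0=0.0, r=3.75e-3, p=p,
                        q=0.37, d=6e-3, t4=0.2, t5=0.9, t6=0.1, t7=0.168,
                        f23=0.03, f4=0.01)


def calibrate_1982(anchors: AnchorSet,
                   template: ParameterSet,
                   rtol: float = 5e-3,
                   reg: float = 1e-3,
                   strict: bool = True) -> tuple[ParameterSet, np.ndarray, np.ndarray]:
    """Anchor the 1982 steady state to the observed-era starting rates.

    Returns ``(params, state, residuals)``: the calibrated parameter set,
    its stationary occupancy vector, and the three relative anchor
    residuals (incidence, mortality, D1 prevalence).

    With ``strict=True`` a best fit whose worst anchor residual exceeds
    ``rtol`` raises :class:`CalibrationError` reporting that residual;
    non-strict mode returns the best compromise.
    """
    targets = np.array([anchors.inc_1982, anchors.mort_1982,
                        anchors.prevalence_D1_1982])
    seeds = np.array([getattr(template, k) for k in FREE_PARAMS])

    def unpack(x) -> ParameterSet:
        return template.with_updates(**dict(zip(FREE_PARAMS, x * seeds)))

    def residuals(x):
        try:
            out = mc.steady_state_outputs(unpack(x))
        except (ValueError, mc.InfeasibleParameterError):
            return np.full(3 + len(x), 1e3)
        got = np.array([out["incidence"], out["mortality"],
                        out["d1_prevalence"]])
        return np.concatenate([got / targets - 1.0, reg * (x - 1.0)])

    lb = np.array([FREE_BOUNDS[k][0] for k in FREE_PARAMS])
    ub = np.array([FREE_BOUNDS[k][1] for k in FREE_PARAMS])
    sol = least_squares(residuals, np.ones(len(FREE_PARAMS)),
                        bounds=(lb, ub), xtol=1e-14, ftol=1e-14,
                        gtol=1e-14, method="trf")
    params = unpack(sol.x)
    res = residuals(sol.x)[:3]
    worst = float(np.max(np.abs(res)))
    if strict and worst > rtol:
        raise CalibrationError(
            f"no steady state inside the +/-50% box matches all anchors for "
            f"D0={template.D0}, p={template.p}: best worst-case residual "
            f"{worst:.3%} (rtol {rtol:.1%})")
    state = mc.steady_state(params, method="solve")
    return params, state, res


def fit_error(model_inc: pd.Series, model_mort: pd.Series,
              obs_inc: pd.Series, obs_mort: pd.Series) -> float:
    """Pooled RMS relative deviation between model and observed series.

    Incidence and mortality contribute one relative-deviation term per year
    each (64 terms for 1982-2013); the result is dimensionless and
    invariant to rescaling both series of a pair by a common factor.
    """
    pairs = ((model_inc, obs_inc), (model_mort, obs_mort))
    devs = []
    for model, obs in pairs:
        m = np.asarray(model, float)
        o = np.asarray(obs, float)
        if m.shape != o.shape:
            raise ValueError(f"series length mismatch: {m.shape} vs {o.shape}")
        devs.append(m / o - 1.0)
    return float(np.sqrt(np.mean(np.concatenate(devs) ** 2)))


@dataclass
class FitResult:
    """Outcome of one curve fit for one (D0, p) configuration."""

    D0: float
    p: float
    I_curve: CurveSpec
    D_curve: CurveSpec
    error: float
    residuals: pd.DataFrame           # per-year relative deviations
    anchor_residuals: np.ndarray = field(
        default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        if self.error < 0:
            raise ValueError("fit error cannot be negative")


@dataclass
class CalibratedModel:
    """A fully calibrated model: parameters, curves, 1982 state and its fit."""

    params: ParameterSet
    curves: CurveSet
    initial_state: np.ndarray
    fit: FitResult
    anchors: AnchorSet

    def to_json(self, path=None) -> str:
        payload = {
            "params": self.params.to_dict(),
            "curves": {k: curve_to_dict(getattr(self.curves, k))
                       for k in ("I_curve", "D_curve", "O_curve")},
            "initial_state": list(self.initial_state),
            "error": self.fit.error,
            "anchor_residuals": list(self.fit.anchor_residuals),
            "anchors": {k: getattr(self.anchors, k)
                        for k in ("inc_1982", "mort_1982", "mort_2013",
                                  "inc_total_1982_2013",
                                  "mort_total_1982_2013", "inc_peak_year",
                                  "prevalence_D1_1982",
                                  "projection_level_inc",
                                  "projection_level_mort")},
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, path) -> "CalibratedModel":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        params = ParameterSet(**payload["params"])
        curves = CurveSet(**{k: curve_from_dict(v)
                             for k, v in payload["curves"].items()})
        anchors = AnchorSet(**payload["anchors"])
        initial = np.asarray(payload["initial_state"])
        fit = cls._rebuild_fit(params, curves, initial, anchors,
                               payload["error"],
                               np.asarray(payload["anchor_residuals"]))
        return cls(params, curves, initial, fit, anchors)

    @staticmethod
    def _rebuild_fit(params, curves, initial, anchors, error, anchor_res):
        return FitResult(params.D0, params.p, curves.I_curve, curves.D_curve,
                         error, pd.DataFrame(), anchor_res)


def _batch_series(params: ParameterSet,
                  d_vals: np.ndarray,
                  i_grid: np.ndarray,
                  initial: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Annual incidence/mortality for many I(t) schedules at once.

    ``i_grid`` has shape (G, T): G candidate intrinsic-incidence schedules
    over T years, all sharing the detection schedule ``d_vals``.  Only the
    Baseline row of the transition matrix depends on I(t), so each year is
    one dense 8x8 propagation plus a rank-one correction per candidate —
    this is what makes the 100x100 grid search a sub-second operation.

    Returns ``(incidence, mortality, feasible)`` with the first two of
    shape (G, T), per 100,000.  Candidates whose I(t) leaves [0, 1 - d]
    anywhere are flagged infeasible (their outputs are NaN).
    """
    G, T = i_grid.shape
    feasible = np.all((i_grid >= 0.0) & (i_grid + params.d <= 1.0), axis=1)
    state = np.tile(np.asarray(initial, float), (G, 1))
    inc = np.empty((G, T))
    mort = np.empty((G, T))
    f1, f23, f4 = params.f1, params.f23, params.f4
    for t in range(T):
        M0 = mc.build_transition_matrix(params, i_val=0.0, d_val=d_vals[t])
        s1 = state[:, mc.U1] * d_vals[t]
        s23 = state[:, mc.U23] * params.t4
        s4 = state[:, mc.U4] * params.t5
        inc[:, t] = (s1 + s23 + s4) * PER_100K
        mort[:, t] = state[:, mc.D4] * params.q * PER_100K
        base = state[:, mc.BASELINE].copy()
        iv = i_grid[:, t]
        state = state @ M0
        state[:, mc.BASELINE] -= base * iv
        state[:, mc.U1] += base * iv * f1
        state[:, mc.U23] += base * iv * f23
        state[:, mc.U4] += base * iv * f4
    inc[~feasible] = np.nan
    mort[~feasible] = np.nan
    return inc, mort, feasible


def _coarse_bc_estimates(i0: float, obs_inc: pd.Series) -> tuple[float, float]:
    """Order-of-magnitude centres for the (b, c) grid from endpoint slopes.

    The intrinsic incidence roughly shadows the relative rise of the
    diagnostic incidence, so the linear coefficient is seeded from the
    series' overall relative change and the curvature at the same scale.
    """
    rel_rise = float(obs_inc.iloc[-1] / obs_inc.iloc[0]) - 1.0
    b0 = max(abs(i0 * rel_rise), i0 * 0.1)
    return b0, b0


def grid_fit_I(params: ParameterSet,
               D_curve: CurveSpec,
               obs_inc: pd.Series,
               obs_mort: pd.Series,
               initial: np.ndarray,
               n_b: int = 100,
               n_c: int = 100,
               b_center: float | None = None,
               c_center: float | None = None,
               anchor_residuals: np.ndarray | None = None) -> FitResult:
    """Exhaustive (b, c) grid search for the intrinsic-incidence parabola.

    The grid is log-spaced over two orders of magnitude per axis:
    b in [B/10, 10B] (b >= 0) and c in [-10C, -C/10] union [C/10, 10C],
    with (B, C) coarse endpoint-slope estimates.  Ties are broken toward
    the smaller |c|, then smaller |b| (the least-curved, flattest
    admissible curve).

    Raises
    ------
    CalibrationError
        If every grid point is infeasible.
    """
    years = np.asarray(obs_inc.index)
    T = len(years)
    if T != len(obs_mort):
        raise ValueError("observed incidence/mortality lengths differ")
    t_idx = years - years[0]
    u = t_idx / HORIZON
    d_vals = np.atleast_1d(evaluate_curve(D_curve, t_idx))

    if b_center is None or c_center is None:
        b0, c0 = _coarse_bc_estimates(params.I0, obs_inc)
        b_center = b_center if b_center is not None else b0
        c_center = c_center if c_center is not None else c0

    b_grid = np.geomspace(b_center / 10.0, b_center * 10.0, n_b)
    half = np.geomspace(c_center / 10.0, c_center * 10.0, n_c // 2)
    c_grid = np.concatenate([-half[::-1], half])

    B, C = np.meshgrid(b_grid, c_grid, indexing="ij")
    bc = np.column_stack([B.ravel(), C.ravel()])
    i_grid = params.I0 + bc[:, [0]] * u[None, :] + bc[:, [1]] * (u ** 2)[None, :]

    inc, mort, feasible = _batch_series(params, d_vals, i_grid, initial)
    if not np.any(feasible):
        raise CalibrationError("all (b, c) grid points are infeasible")

    dev = np.concatenate([inc / np.asarray(obs_inc, float) - 1.0,
                          mort / np.asarray(obs_mort, float) - 1.0], axis=1)
    errors = np.sqrt(np.mean(dev ** 2, axis=1))
    errors[~feasible] = np.inf
    order = np.lexsort((np.abs(bc[:, 0]), np.abs(bc[:, 1]), errors))
    best = order[0]
    b_best, c_best = bc[best]

    residuals = pd.DataFrame(
        {"incidence": inc[best] / np.asarray(obs_inc, float) - 1.0,
         "mortality": mort[best] / np.asarray(obs_mort, float) - 1.0},
        index=pd.Index(years, name="year"))
    i_curve = quadratic_curve(params.I0, float(b_best), float(c_best))
    return FitResult(params.D0, params.p, i_curve, D_curve,
                     float(errors[best]), residuals,
                     anchor_residuals if anchor_residuals is not None
                     else np.zeros(3))


def candidate_d_curves(d0: float,
                       d31_values=None,
                       families=D_FAMILIES) -> list[CurveSpec]:
    """The detection-curve candidates tried for one configuration."""
    if d31_values is None:
        d31_values = DEFAULT_D31[d0]
    return [make_curve(fam, d0, d31)
            for fam in families for d31 in d31_values]


def fit_configuration(anchors: AnchorSet,
                      d0: float,
                      p: float,
                      observed: tuple[pd.Series, pd.Series] | None = None,
                      d31_values=None,
                      families=D_FAMILIES,
                      n_grid: int = 100,
                      strict: bool = False) -> CalibratedModel:
    """Calibrate 1982 and fit the best (D-curve, I-curve) pair for one
    (D0, p) configuration."""
    if observed is None:
        observed = build_observed_series(anchors)
    obs_inc, obs_mort = observed
    params, state, anchor_res = calibrate_1982(
        anchors, default_parameters(d0, p), strict=strict)
    best = None
    for d_curve in candidate_d_curves(d0, d31_values, families):
        fit = grid_fit_I(params, d_curve, obs_inc, obs_mort, state,
                         n_b=n_grid, n_c=n_grid, anchor_residuals=anchor_res)
        if best is None or fit.error < best.error:
            best = fit
    curves = CurveSet(I_curve=best.I_curve, D_curve=best.D_curve,
                      O_curve=constant_curve(0.0))
    return CalibratedModel(params, curves, state, best, anchors)


def select_best_model(anchors: AnchorSet | None = None,
                      configs=CONFIG_GRID,
                      observed: tuple[pd.Series, pd.Series] | None = None,
                      d31_values=None,
                      families=D_FAMILIES,
                      n_grid: int = 100) -> list[CalibratedModel]:
    """Best-fit models for every (D0, p) configuration, in config order."""
    anchors = anchors if anchors is not None else AnchorSet()
    if observed is None:
        observed = build_observed_series(anchors)
    return [fit_configuration(anchors, d0, p, observed=observed,
                              d31_values=d31_values, families=families,
                              n_grid=n_grid)
            for d0, p in configs]


def model_series(model: CalibratedModel,
                 years=OBS_YEARS) -> tuple[pd.Series, pd.Series]:
    """The fitted model's annual incidence and mortality over ``years``."""
    traj = mc.run_trajectory(model.params, model.curves, years,
                             model.initial_state)
    out = mc.annual_outputs(traj)
    return out["diagnostic_incidence"], out["melanoma_mortality"]
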