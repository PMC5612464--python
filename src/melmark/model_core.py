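"""Time-inhomogeneous Markov cohort model of melanoma progression.

The population is closed and tracked as occupancy fractions of eight states:

======  =========================================================
index   state
======  =========================================================
0       Baseline (no invasive melanoma, or in-situ disease only)
1       Undiagnosed Stage 1 (thin invasive, < 2 mm)
2       Undiagnosed Stage 2/3 (thick or node-positive)
3       Undiagnosed Stage 4 (distant metastatic)
4       Diagnosed (treated) Stage 1
5       Diagnosed (treated) Stage 2/3
6       Diagnosed (treated) Stage 4
7       Death
======  =========================================================

One iteration is one calendar year.  The transition matrix is row-stochastic;
the diagonal absorbs whatever probability the off-diagonal edges do not use.
Death recycles to Baseline with probability 1, which keeps the population
constant and makes "deaths per year" equal to the inflow to the Death state.
Melanoma-specific death occurs only from diagnosed Stage 4 (probability q per
year); every other state loses mass to Death at the background rate d.

Over-diagnosis is a counting overlay, not a transition: a fraction O(t) of
each year's Stage-1 diagnoses are lesions with no life-threatening potential
whose bearers remain, dynamically, at Baseline.  The overlay inflates the
diagnostic-incidence tally and nothing else, which is exactly the
epidemiological signature of over-diagnosis (incidence up, mortality flat).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .curves import CurveSet, evaluate_curve

# State indices.
BASELINE, U1, U23, U4, D1, D23, D4, DEATH = range(8)
N_STATES = 8
STATE_NAMES = ("baseline", "u1", "u23", "u4", "d1", "d23", "d4", "death")

#: Scale of all reported rates (cases per 100,000 persons).
PER_100K = 1e5

_ATOL = 1e-12


class InfeasibleParameterError(ValueError):
    """A transition-matrix row would need probabilities summing above 1."""


@dataclass(frozen=True)
class ParameterSet:
    """One configuration of the eleven model parameters plus the I-partition.

    Parameters
    ----------
    I0 : float
        Intrinsic incidence at t = 0: probability per person per year of
        developing undiagnosed invasive melanoma from Baseline.
    D0 : float
        Detection likelihood at t = 0: probability per year of a Stage-1
        diagnosis given undiagnosed Stage-1 disease (secondary prevention).
    O0 : float
        Over-diagnosis fraction at t = 0: proportion of Stage-1 diagnoses
        that are over-diagnoses.
    r : float
        Probability per year of undiagnosed Stage 1 progressing to
        undiagnosed Stage 2/3; the direct Stage-1 -> Stage-4 route runs at
        r/3, and the treated (diagnosed) counterparts at r/p and r/3p.
    p : float
        Ratio (>= 1) of undiagnosed to diagnosed Stage-1 progression;
        quantifies how much treatment slows progression.
    q : float
        Probability per year of melanoma death given diagnosed Stage 4
        (tertiary prevention acts by lowering q).
    d : float
        Probability per year of death from non-melanoma causes, any state.
    t4, t5, t6, t7 : float
        Fixed progression probabilities: U23->D23, U4->D4, U23->U4 and
        D23->D4 respectively.
    f23, f4 : float
        Fractions of the intrinsic incidence I(t) routed directly to
        undiagnosed Stage 2/3 and Stage 4 (aggressive or occult disease
        first noticed late); the rest, f1 = 1 - f23 - f4, enters at
        undiagnosed Stage 1.
    """

    I0: float
    D0: float
    O0: float
    r: float
    p: float
    q: float
    d: float
    t4: float
    t5: float
    t6: float
    t7: float
    f23: float
    f4: float

    def __post_init__(self):
        for name in ("I0", "D0", "O0", "r", "q", "d", "t4", "t5", "t6",
                     "t7", "f23", "f4"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} is not a probability in [0, 1]")
        if self.p < 1.0:
            raise ValueError(f"p={self.p} must be >= 1 (treatment cannot "
                             "accelerate progression)")
        if self.f23 + self.f4 >= 0.5:
            raise ValueError("f23 + f4 must stay below 0.5: Stage-1 entry "
                             "must dominate the intrinsic-incidence split")
        if self.r + self.r / 3.0 + self.D0 + self.d > 1.0 + _ATOL:
            raise InfeasibleParameterError(
                "undiagnosed Stage-1 row infeasible: r + r/3 + D0 + d > 1")

    @property
    def f1(self) -> float:
        return 1.0 - self.f23 - self.f4

    def with_updates(self, **kw) -> "ParameterSet":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("I0", "D0", "O0", "r", "p", "q", "d",
                 "t4", "t5", "t6", "t7", "f23", "f4")}


class FluxTally(NamedTuple):
    """Per-year event counts per 100,000 persons."""

    stage1_diagnoses: float
    stage23_diagnoses: float
    stage4_diagnoses: float
    overdiagnoses: float
    melanoma_deaths: float
    other_deaths: float

    @property
    def diagnostic_incidence(self) -> float:
        """All melanoma diagnoses counted in the year, over-diagnoses included."""
        return (self.stage1_diagnoses + self.stage23_diagnoses
                + self.stage4_diagnoses + self.overdiagnoses)


@dataclass
class Trajectory:
    """A model run: one state vector and one flux tally per simulated year.

    ``states[i]`` is the occupancy at the *start* of ``years[i]`` (so
    ``states[0]`` is the initial condition) and ``tallies[i]`` counts the
    events of that year; ``final_state`` is the occupancy after the last
    step.
    """

    years: np.ndarray
    states: np.ndarray          # (n_years, 8), start-of-year occupancies
    tallies: list
    final_state: np.ndarray

    def __post_init__(self):
        if np.any(np.diff(self.years) != 1):
            raise ValueError("trajectory years must be consecutive")
        for s in self.states:
            validate_state_vector(s)
        validate_state_vector(self.final_state)

    def __len__(self) -> int:
        return len(self.years)

    def __iter__(self):
        return iter(zip(self.years, self.states, self.tallies))

    def to_frame(self) -> pd.DataFrame:
        """Tabular view: year, 8 occupancy columns, 6 tally columns."""
        occ = pd.DataFrame(self.states, columns=list(STATE_NAMES))
        tal = pd.DataFrame(self.tallies, columns=list(FluxTally._fields))
        out = pd.concat([occ, tal], axis=1)
        out.insert(0, "year", self.years)
        return out

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def validate_state_vector(state: np.ndarray) -> np.ndarray:
    """Check an 8-state occupancy vector: non-negative, sums to 1."""
    state = np.asarray(state, dtype=float)
    if state.shape != (N_STATES,):
        raise ValueError(f"state vector must have shape (8,), got {state.shape}")
    if np.any(state < -_ATOL):
        raise ValueError(f"negative occupancy in state vector: {state}")
    if abs(state.sum() - 1.0) > 1e-9:
        raise ValueError(f"state vector mass {state.sum()} != 1")
    return state


def build_transition_matrix(params: ParameterSet,
                            i_val: float | None = None,
                            d_val: float | None = None,
                            o_val: float | None = None) -> np.ndarray:
    """Assemble the 8x8 row-stochastic transition matrix for one year.

    ``i_val`` and ``d_val`` override the time-dependent intrinsic incidence
    and detection likelihood (defaulting to the parameter-set values at
    t = 0).  ``o_val`` is accepted for interface symmetry but never enters
    the matrix: over-diagnosis is a counting overlay applied at tally time,
    so the disease dynamics are bit-identical for any O(t).

    Raises
    ------
    InfeasibleParameterError
        If any row's off-diagonal probabilities sum above 1 (the row is
        named in the message).
    """
    i_val = params.I0 if i_val is None else float(i_val)
    d_val = params.D0 if d_val is None else float(d_val)
    if not 0.0 <= i_val <= 1.0:
        raise InfeasibleParameterError(f"I(t)={i_val} is not a probability")
    if not 0.0 <= d_val <= 1.0:
        raise InfeasibleParameterError(f"D(t)={d_val} is not a probability")

    r, p, q, d = params.r, params.p, params.q, params.d
    M = np.zeros((N_STATES, N_STATES))

    M[BASELINE, U1] = i_val * params.f1
    M[BASELINE, U23] = i_val * params.f23
    M[BASELINE, U4] = i_val * params.f4

    M[U1, D1] = d_val
    M[U1, U23] = r
    M[U1, U4] = r / 3.0

    M[U23, D23] = params.t4
    M[U23, U4] = params.t6

    M[U4, D4] = params.t5

    M[D1, D23] = r / p
    M[D1, D4] = r / (3.0 * p)

    M[D23, D4] = params.t7

    M[D4, DEATH] = q  # + d added below

    # Background mortality from every living state; Death recycles fully.
    for s in range(DEATH):
        M[s, DEATH] += d
    M[DEATH, BASELINE] = 1.0

    # Diagonals absorb the remainder; any overdraw is infeasible.
    for s in range(DEATH):
        off = M[s].sum()
        if off > 1.0 + _ATOL:
            raise InfeasibleParameterError(
                f"row {STATE_NAMES[s]!r} infeasible: off-diagonal "
                f"probabilities sum to {off:.6g} > 1")
        M[s, s] = 1.0 - off
    return M


def step(state: np.ndarray, matrix: np.ndarray, *,
         d_val: float, o_val: float = 0.0) -> tuple[np.ndarray, FluxTally]:
    """Advance the cohort one year and tally the year's fluxes.

    Tallies are attributed from the start-of-year occupancy times the edge
    probability (no intra-year chaining).  ``d_val`` is needed to split the
    diagnosed-Stage-4 outflow into melanoma deaths (rate q) and background
    deaths (rate d); ``o_val`` adds the over-diagnosis overlay,
    o_val x (Stage-1 diagnosis flux), to the counting tally only.
    """
    state = np.asarray(state, dtype=float)
    nxt = state @ matrix

    s1 = state[U1] * matrix[U1, D1] * PER_100K
    s23 = state[U23] * matrix[U23, D23] * PER_100K
    s4 = state[U4] * matrix[U4, D4] * PER_100K
    over = o_val * s1
    mel = state[D4] * (matrix[D4, DEATH] - d_val) * PER_100K
    other = (1.0 - state[DEATH]) * d_val * PER_100K
    return nxt, FluxTally(s1, s23, s4, over, mel, other)


def steady_state(params: ParameterSet,
                 i_val: float | None = None,
                 d_val: float | None = None,
                 method: str = "power",
                 tol: float = 1e-12,
                 max_iter: int = 10 ** 6) -> np.ndarray:
    """Stationary occupancy of the time-constant chain (Death recycling on).

    ``method='power'`` iterates the chain to convergence by repeated matrix
    squaring (robust to the chain's slow modes, e.g. the treated-Stage-1
    pool draining at r/p per year), stopping when one more doubling changes
    the matrix by less than ``tol`` in L-inf; ``max_iter`` caps the
    effective number of single-year steps.  ``method='solve'`` solves the
    stationary linear system directly.  The two agree to ~1e-10 and the
    direct solve is what the hot loops use.

    Raises
    ------
    RuntimeError
        If the iteration fails to converge within ``max_iter`` steps.
    """
    M = build_transition_matrix(params, i_val=i_val, d_val=d_val)
    if method == "solve":
        return _stationary_solve(M)
    if method != "power":
        raise ValueError(f"unknown steady-state method {method!r}")
    P = M
    for _ in range(max(1, int(np.ceil(np.log2(max_iter))))):
        nxt = P @ P
        if np.max(np.abs(nxt - P)) < tol:
            pi = np.clip(nxt[BASELINE], 0.0, None)
            return pi / pi.sum()
        P = nxt
    raise RuntimeError(f"steady state did not converge within {max_iter} "
                       f"effective iterations (tol={tol})")


def _stationary_solve(matrix: np.ndarray) -> np.ndarray:
    """Stationary distribution via the null space of (M^T - I)."""
    A = matrix.T - np.eye(N_STATES)
    A[-1, :] = 1.0
    b = np.zeros(N_STATES)
    b[-1] = 1.0
    pi = np.linalg.solve(A, b)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def steady_state_outputs(params: ParameterSet,
                         i_val: float | None = None,
                         d_val: float | None = None,
                         o_val: float | None = None) -> dict:
    """Headline annual rates of the stationary model, per 100,000.

    Returns diagnostic incidence (over-diagnoses included), melanoma
    mortality, all-cause mortality and the diagnosed-Stage-1 prevalence —
    the quantities the 1982 calibration anchors and the sensitivity
    analysis report on.
    """
    o_val = params.O0 if o_val is None else float(o_val)
    d_use = params.D0 if d_val is None else float(d_val)
    pi = steady_state(params, i_val=i_val, d_val=d_val, method="solve")
    M = build_transition_matrix(params, i_val=i_val, d_val=d_val)
    _, tally = step(pi, M, d_val=params.d, o_val=o_val)
    return {
        "incidence": tally.diagnostic_incidence,
        "mortality": tally.melanoma_deaths,
        "all_cause_mortality": tally.melanoma_deaths + tally.other_deaths,
        "d1_prevalence": pi[D1] * PER_100K,
        "state": pi,
        "d_val": d_use,
    }


def run_schedule(params: ParameterSet,
                 years: Iterable[int],
                 i_vals: np.ndarray,
                 d_vals: np.ndarray,
                 o_vals: np.ndarray,
                 initial: np.ndarray,
                 q_vals: np.ndarray | None = None) -> Trajectory:
    """Iterate the cohort over explicit per-year probability schedules.

    This is the engine under :func:`run_trajectory` and the scenario
    machinery: each year's matrix is rebuilt from that year's I, D (and
    optionally q) values, the cohort is stepped, and fluxes tallied.
    """
    years = np.asarray(list(years), dtype=int)
    n = len(years)
    for name, arr in (("i_vals", i_vals), ("d_vals", d_vals),
                      ("o_vals", o_vals)):
        if len(arr) != n:
            raise ValueError(f"{name} has length {len(arr)}, expected {n}")
    state = validate_state_vector(initial).copy()
    states = np.empty((n, N_STATES))
    tallies = []
    for k in range(n):
        pk = params if q_vals is None else params.with_updates(q=float(q_vals[k]))
        M = build_transition_matrix(pk, i_val=i_vals[k], d_val=d_vals[k])
        states[k] = state
        state, tally = step(state, M, d_val=pk.d, o_val=float(o_vals[k]))
        tallies.append(tally)
    return Trajectory(years, states, tallies, state)


def run_trajectory(params: ParameterSet,
                   curves: CurveSet,
                   years: Iterable[int],
                   initial: np.ndarray,
                   year0: int = 1982,
                   extend: bool = False) -> Trajectory:
    """Run the cohort over calendar ``years``, rebuilding the matrix each
    year from the curve values at that year.

    ``year0`` anchors the curves' t = 0; with ``extend=True`` curves past
    their horizon evaluate as constants at their final value (projection
    era), otherwise an out-of-range year raises.
    """
    years = list(years)
    t_idx = np.asarray([y - year0 for y in years])
    i_vals = np.atleast_1d(evaluate_curve(curves.I_curve, t_idx, extend=extend))
    d_vals = np.atleast_1d(evaluate_curve(curves.D_curve, t_idx, extend=extend))
    o_vals = np.atleast_1d(evaluate_curve(curves.O_curve, t_idx, extend=extend))
    return run_schedule(params, years, i_vals, d_vals, o_vals, initial)


def annual_outputs(traj: Trajectory) -> dict[str, pd.Series]:
    """Year-indexed annual rate series (per 100,000) from a trajectory.

    Keys: ``diagnostic_incidence`` (all diagnoses including the
    over-diagnosis overlay), ``melanoma_mortality``, ``all_cause_mortality``
    and ``d1_prevalence`` (start-of-year diagnosed-Stage-1 occupancy).
    """
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    idx = pd.Index(traj.years, name="year")
    tal = pd.DataFrame(traj.tallies, index=idx)
    return {
        "diagnostic_incidence": (tal.stage1_diagnoses + tal.stage23_diagnoses
                                 + tal.stage4_diagnoses + tal.overdiagnoses
                                 ).rename("rate_per_100k"),
        "melanoma_mortality": tal.melanoma_deaths.rename("rate_per_100k"),
        "all_cause_mortality": (tal.melanoma_deaths + tal.other_deaths
                                ).rename("rate_per_100k"),
        "d1_prevalence": pd.Series(traj.states[:, D1] * PER_100K, index=idx,
                                   name="rate_per_100k"),
    }
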