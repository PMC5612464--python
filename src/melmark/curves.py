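"""Parametric time courses for the model's time-dependent transition probabilities.

Three probabilities of the cohort model change over the study period: the
intrinsic incidence I(t) (probability per year of developing undiagnosed
invasive melanoma), the detection likelihood D(t) (probability per year of a
Stage-1 diagnosis given undiagnosed Stage-1 disease, i.e. the level of
secondary prevention), and the over-diagnosis fraction O(t).

All curves live on a rescaled time axis ``u = t / 31`` where ``t`` is the
year index on the 1982-anchored grid (u = 0 is 1982, u = 1 is 2013).  Four
low-order families are supported — a straight line, concave-up and
concave-down parabolas, and a logistic sigmoid — which is deliberately
restrictive: higher-degree polynomials invite overfitting when only two
smooth annual series constrain them.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

#: Number of annual steps between the first (1982) and last (2013) observed
#: year; the rescaled axis is u = t / HORIZON.
HORIZON = 31

FAMILIES = ("linear", "parabola_up", "parabola_down", "sigmoid", "quadratic")


class CurveError(ValueError):
    """Raised for unattainable shapes or out-of-range evaluations."""


@dataclass(frozen=True)
class CurveSpec:
    """A single parametric time course v(u) on u in [0, 1].

    For the polynomial families ``coeffs`` holds (a, b, c) with
    v(u) = a + b*u + c*u**2.  For ``sigmoid`` it holds (midpoint, steepness)
    of a logistic rescaled to interpolate the endpoints exactly.

    Attributes
    ----------
    family : str
        One of :data:`FAMILIES`.
    v_start, v_end : float
        Values at u = 0 and u = 1.
    coeffs : tuple of float
        Family-specific coefficients (see above).
    monotone : bool
        Whether the curve is guaranteed non-decreasing on [0, 1].
    horizon : int
        Year-grid length used to rescale integer year indices.
    """

    family: str
    v_start: float
    v_end: float
    coeffs: tuple
    monotone: bool = False
    horizon: int = HORIZON

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise CurveError(f"unknown curve family {self.family!r}")

    def __call__(self, u):
        """Evaluate at rescaled time ``u`` (scalar or array)."""
        u = np.asarray(u, dtype=float)
        if self.family == "sigmoid":
            m, k = self.coeffs
            s = 1.0 / (1.0 + np.exp(-k * (u - m)))
            s0 = 1.0 / (1.0 + np.exp(k * m))
            s1 = 1.0 / (1.0 + np.exp(-k * (1.0 - m)))
            out = self.v_start + (self.v_end - self.v_start) * (s - s0) / (s1 - s0)
        else:
            a, b, c = self.coeffs
            out = a + b * u + c * u * u
        return out if out.shape else float(out)


@dataclass(frozen=True)
class CurveSet:
    """The three time courses one model run needs: I(t), D(t) and O(t)."""

    I_curve: CurveSpec
    D_curve: CurveSpec
    O_curve: CurveSpec

    def replace(self, **kw) -> "CurveSet":
        return replace(self, **kw)


def constant_curve(value: float, horizon: int = HORIZON) -> CurveSpec:
    """A curve fixed at ``value`` for all times."""
    return CurveSpec("linear", value, value, (value, 0.0, 0.0),
                     monotone=True, horizon=horizon)


def quadratic_curve(a: float, b: float, c: float,
                    horizon: int = HORIZON) -> CurveSpec:
    """Raw quadratic v(u) = a + b*u + c*u**2 (used for fitted I(t))."""
    return CurveSpec("quadratic", a, a + b + c, (a, b, c), horizon=horizon)


def make_curve(family: str, v_start: float, v_end: float,
               shape: float | None = None, horizon: int = HORIZON) -> CurveSpec:
    """Build a monotone curve through (0, v_start) and (1, v_end).

    Parameters
    ----------
    family : str
        ``linear``, ``parabola_up``, ``parabola_down`` or ``sigmoid``.
    v_start, v_end : float
        Endpoint probabilities, both in [0, 1].
    shape : float, optional
        Family-specific shape parameter: the parabola vertex position
        (<= 0 for concave-up, >= 1 for concave-down; defaults 0 and 1)
        or the sigmoid steepness (default 8, midpoint fixed at 0.5).

    Monotone non-decreasing requires ``v_end >= v_start``; a decreasing
    request raises :class:`CurveError` because these families model
    detection/incidence levels that only ratchet upwards over the study
    period.
    """
    for name, v in (("v_start", v_start), ("v_end", v_end)):
        if not 0.0 <= v <= 1.0:
            raise CurveError(f"{name}={v} outside [0, 1]")
    if v_end < v_start:
        raise CurveError(
            f"monotone non-decreasing {family} curve unattainable: "
            f"v_end={v_end} < v_start={v_start}")
    if v_end == v_start:
        return constant_curve(v_start, horizon)

    if family == "linear":
        coeffs = (v_start, v_end - v_start, 0.0)
    elif family in ("parabola_up", "parabola_down"):
        s = shape if shape is not None else (0.0 if family == "parabola_up" else 1.0)
        if family == "parabola_up" and s > 0.0:
            raise CurveError("concave-up monotone parabola needs vertex <= 0")
        if family == "parabola_down" and s < 1.0:
            raise CurveError("concave-down monotone parabola needs vertex >= 1")
        # v(u) = v_start + k*((u - s)^2 - s^2); k from v(1) = v_end.
        k = (v_end - v_start) / (1.0 - 2.0 * s)
        coeffs = (v_start, -2.0 * k * s, k)
    elif family == "sigmoid":
        k = shape if shape is not None else 8.0
        if k <= 0:
            raise CurveError("sigmoid steepness must be positive")
        return CurveSpec("sigmoid", v_start, v_end, (0.5, k),
                         monotone=True, horizon=horizon)
    else:
        raise CurveError(f"unknown curve family {family!r}")
    return CurveSpec(family, v_start, v_end, coeffs, monotone=True,
                     horizon=horizon)


def evaluate_curve(curve: CurveSpec, year_index, extend: bool = False):
    """Evaluate a curve at an integer year index t, at u = t / horizon.

    With ``extend=True`` indices past the horizon evaluate at u = 1
    (constant extension used for the projection era); otherwise they raise.
    Negative indices always raise.
    """
    t = np.asarray(year_index, dtype=float)
    if np.any(t < 0):
        raise CurveError(f"year index {year_index} before the curve's start")
    if np.any(t > curve.horizon):
        if not extend:
            raise CurveError(
                f"year index {year_index} beyond horizon {curve.horizon} "
                "(pass extend=True for constant extension)")
        t = np.minimum(t, curve.horizon)
    return curve(t / curve.horizon)


def curve_to_dict(curve: CurveSpec) -> dict:
    return {"family": curve.family, "v_start": curve.v_start,
            "v_end": curve.v_end, "coeffs": list(curve.coeffs),
            "monotone": curve.monotone, "horizon": curve.horizon}


def curve_from_dict(d: dict) -> CurveSpec:
    return CurveSpec(d["family"], d["v_start"], d["v_end"],
                     tuple(d["coeffs"]), d.get("monotone", False),
                     d.get("horizon", HORIZON))
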