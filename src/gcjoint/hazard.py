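"""Proportional-hazards machinery for the survival submodel.

The hazard of death for female i at age t is

    h_i(t) = h0(t) * exp( gamma' w_i(t) + f(alpha, M_i(t)) )

where h0 is a baseline hazard (a cubic B-spline on the log scale in the
fitted model; Gompertz in the simulator so closed-form oracles exist),
w_i(t) are yearly exogenous covariates held piecewise constant within
birthday-aligned years of life, and f is one of three association
structures linking the fGC trajectory history M_i(t) to survival:
current value (alpha * m(t)), current slope (alpha * m'(t)), or cumulative
area under the curve (alpha * integral of m from adult entry to t).

Cumulative hazards integrate with fixed-order Gauss-Legendre quadrature per
year-of-life segment: the integrand is smooth within segments and jumps only
at birthdays, so per-segment quadrature is essentially exact.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline
from scipy.optimize import brentq

ASSOC_MODES = ("value", "slope", "auc", "none")
GL_NODES = 15

#: Lower limit of the cumulative (AUC) association integral: the fixed
#: adulthood age. Using each female's own (staggered) entry age instead
#: would make the feature depend on when observation happened to begin,
#: not on the female's glucocorticoid history; trajectories of females
#: entering later are linearly extrapolated back to this age.
AUC_START = 5.0

_gl_x, _gl_w = np.polynomial.legendre.leggauss(GL_NODES)


@dataclass
class AssociationSpec:
    """Association structure f(alpha, M_i(t)) between trajectory and hazard."""
    mode: str = "none"
    alpha: float = 0.0

    def __post_init__(self):
        if self.mode not in ASSOC_MODES:
            raise ValueError(f"mode must be one of {ASSOC_MODES}, got {self.mode!r}")
        if self.mode == "none":
            self.alpha = 0.0


@dataclass
class SurvivalRecord:
    """Entry/exit/event triple with the yearly exogenous covariate path."""
    female_id: object
    entry_age: float
    exit_age: float
    event: bool
    w_edges: np.ndarray          # (S+1,) year-of-life boundaries covering [entry, exit]
    W: np.ndarray                # (S, q) piecewise-constant covariate rows
    w_columns: tuple = ()

    def __post_init__(self):
        self.w_edges = np.asarray(self.w_edges, float)
        self.W = np.atleast_2d(np.asarray(self.W, float))
        if not (self.exit_age > self.entry_age >= 5.0 - 1e-9):
            raise ValueError(
                f"{self.female_id}: need exit > entry >= 5, got "
                f"entry={self.entry_age}, exit={self.exit_age}")
        if self.w_edges[0] > self.entry_age + 1e-9 or self.w_edges[-1] < self.exit_age - 1e-9:
            raise ValueError(f"{self.female_id}: covariate path does not cover [entry, exit]")

    def w_at(self, t):
        """Piecewise-constant covariate row(s) at age(s) t."""
        t = np.asarray(t, float)
        s = np.clip(np.searchsorted(self.w_edges, t, side="right") - 1,
                    0, self.W.shape[0] - 1)
        return self.W[s]


class GompertzBaseline:
    """h0(t) = a * exp(b * t); closed-form cumulative hazard."""

    def __init__(self, a: float, b: float):
        if a <= 0:
            raise ValueError("Gompertz a must be > 0")
        self.a, self.b = float(a), float(b)

    def log_h0(self, t):
        return np.log(self.a) + self.b * np.asarray(t, float)

    def cumulative(self, t0, t1):
        if self.b == 0:
            return self.a * (t1 - t0)
        return self.a / self.b * (np.exp(self.b * t1) - np.exp(self.b * t0))


@dataclass
class BaselineHazardSpline:
    """Cubic B-spline for log h0(t) with two internal knots (by default).

    ``knots`` is the full knot vector (boundary knots repeated degree+1
    times); ``coefs`` the coefficient vector, length len(knots) - degree - 1.
    """
    knots: np.ndarray
    coefs: np.ndarray
    degree: int = 3

    def __post_init__(self):
        self.knots = np.asarray(self.knots, float)
        self.coefs = np.asarray(self.coefs, float)
        internal = self.knots[self.degree + 1:len(self.knots) - self.degree - 1]
        if len(internal) > 1 and np.any(np.diff(internal) <= 0):
            raise ValueError("internal knots must be strictly increasing")
        if len(self.coefs) != len(self.knots) - self.degree - 1:
            raise ValueError("coefficient length does not match knot vector")

    @classmethod
    def make_knots(cls, lo: float, hi: float, internal, degree: int = 3) -> np.ndarray:
        internal = np.sort(np.asarray(internal, float))
        if np.any(internal <= lo) or np.any(internal >= hi):
            raise ValueError("internal knots must lie strictly inside the age range")
        return np.r_[[lo] * (degree + 1), internal, [hi] * (degree + 1)]

    def basis(self, t) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, float))
        lo, hi = self.knots[self.degree], self.knots[-self.degree - 1]
        tc = np.clip(t, lo, hi - 1e-10)
        return BSpline.design_matrix(tc, self.knots, self.degree).toarray()

    def log_h0(self, t):
        out = self.basis(t) @ self.coefs
        return out if np.ndim(t) else float(out[0])


@dataclass
class HazardModel:
    """Bundle of baseline + exogenous coefficients + association structure."""
    baseline: object
    gamma: np.ndarray
    assoc: AssociationSpec = field(default_factory=AssociationSpec)

    def __post_init__(self):
        self.gamma = np.atleast_1d(np.asarray(self.gamma, float))


def association_term(traj, t, spec: AssociationSpec):
    """f(alpha, M_i(t)) for one of the three association structures.

    value -> alpha * m(t); slope -> alpha * dm/dt; auc -> alpha times the
    integral of m from the fixed adulthood age (:data:`AUC_START`) to t;
    none -> 0.
    """
    t = np.asarray(t, float)
    if np.any(t < traj.entry - 1e-9):
        raise ValueError("association_term: t precedes trajectory entry age")
    if spec.mode == "none":
        return np.zeros(t.shape) if t.ndim else 0.0
    if spec.mode == "value":
        return spec.alpha * traj.value(t)
    if spec.mode == "slope":
        return spec.alpha * traj.derivative(t)
    return spec.alpha * (traj.integral(t) - traj.integral(AUC_START))


def log_hazard(t, record: SurvivalRecord, traj, model: HazardModel):
    """log h_i(t) = log h0(t) + gamma' w_i(t) + f(alpha, M_i(t)).

    ``w_i`` is piecewise constant within years of life, so the log hazard
    jumps by gamma' * delta(w) at birthdays.
    """
    t = np.asarray(t, float)
    if np.any(t < record.entry_age - 1e-9) or np.any(t > record.exit_age + 1e-9):
        raise ValueError("log_hazard: t outside [entry, exit]")
    out = model.baseline.log_h0(t) + record.w_at(t) @ model.gamma \
        + association_term(traj, t, model.assoc)
    return out if t.ndim else float(out)


def _segment_edges(record: SurvivalRecord, t0: float, t1: float) -> np.ndarray:
    inner = record.w_edges[(record.w_edges > t0 + 1e-12) & (record.w_edges < t1 - 1e-12)]
    return np.concatenate([[t0], inner, [t1]])


def cumulative_hazard(record: SurvivalRecord, traj, model: HazardModel,
                      t, lower: float | None = None) -> float:
    """Integral of h_i from entry (or ``lower``) to t, by per-segment
    Gauss-Legendre quadrature."""
    t0 = record.entry_age if lower is None else float(lower)
    t = float(t)
    if t < t0 - 1e-12:
        raise ValueError("cumulative_hazard: t precedes lower limit")
    if t <= t0:
        return 0.0
    edges = _segment_edges(record, t0, t)
    lo, hi = edges[:-1], edges[1:]
    half = (hi - lo) / 2
    nodes = (lo[:, None] + hi[:, None]) / 2 + half[:, None] * _gl_x[None, :]
    flat = nodes.ravel()
    lh = model.baseline.log_h0(flat) + record.w_at(flat) @ model.gamma \
        + association_term(traj, flat, model.assoc)
    h = np.exp(lh)
    if not np.all(np.isfinite(h)):
        bad = flat[~np.isfinite(h)][0]
        raise FloatingPointError(f"non-finite hazard at age {bad:.4f} "
                                 f"for female {record.female_id}")
    return float(np.sum(h.reshape(nodes.shape) * _gl_w[None, :] * half[:, None]))


def survival_probability(record, traj, model, t, t0=None) -> float:
    """S(t | alive at t0) = exp(-(H(t) - H(t0)))."""
    return float(np.exp(-cumulative_hazard(record, traj, model, t, lower=t0)))


def sample_death_age(record: SurvivalRecord, traj, model: HazardModel,
                     u: float) -> float:
    """Invert the cumulative hazard: solve H(entry, T) = -log(u).

    Returns the death age, or +inf if the target exceeds H at the end of the
    covariate path (i.e. the female outlives the window).
    """
    target = -np.log(u)
    hi = float(record.w_edges[-1])
    H_hi = cumulative_hazard(record, traj, model, hi)
    if target >= H_hi:
        return np.inf
    f = lambda t: cumulative_hazard(record, traj, model, t) - target
    return float(brentq(f, record.entry_age, hi, xtol=1e-9))
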