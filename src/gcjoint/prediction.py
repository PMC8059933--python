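"""Dynamic conditional survival prediction for hypothetical females.

Given a fitted joint model, we build out-of-sample females who maintain a
chosen percentile of log fGC in every age class up to a landmark age t0
(continuous covariates held at age-specific means, categoricals at
reference), simulate their individual random effects conditional on those
pseudo-observations, and report the conditional survival curve
S(t | alive at t0) with pointwise 90% intervals across posterior draws.

The random-effect conditional given Gaussian pseudo-observations is exactly
Gaussian per posterior draw, so no approximation beyond the posterior draws
themselves is involved in the conditioning step.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .joint import JointFit

__all__ = ["TrajectorySpec", "SurvivalCurve", "percentile_trajectory",
           "conditional_survival", "median_survival_age"]


@dataclass
class TrajectorySpec:
    """Pseudo-observed fGC history and covariate settings for a hypothetical female."""
    ages_mid: np.ndarray        # midpoints of observed age classes (< t0)
    targets: np.ndarray         # target log fGC per observed age class
    X: np.ndarray               # design rows per age class, entry..max age
    X_lo: np.ndarray            # lower age bound per X row
    t0: float = 14.0
    entry: float = 5.0

    def __post_init__(self):
        if len(self.ages_mid) != len(self.targets):
            raise ValueError("ages_mid and targets must align")
        lo = np.floor(self.X_lo + 1e-9)
        if np.any(np.diff(lo) != 1):
            raise ValueError("age classes must be contiguous")


@dataclass
class SurvivalCurve:
    ages: np.ndarray
    median: np.ndarray
    lo90: np.ndarray
    hi90: np.ndarray
    t0: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages, "median": self.median,
                             "lo90": self.lo90, "hi90": self.hi90})


def percentile_trajectory(samples: pd.DataFrame, percentile: float, t0: float,
                          design, max_age: float | None = None,
                          entry: float = 5.0) -> TrajectorySpec:
    """Empirical per-age-class percentile of log fGC, as pseudo-observations.

    ``samples`` must have ``age`` and ``log_fgc``; ``design`` supplies the
    age-class mean design rows (continuous covariates at age-specific means,
    categorical dummies at reference). Empty age classes are linearly
    interpolated from neighbors with a warning.
    """
    if max_age is None:
        max_age = float(np.ceil(samples["age"].max()))
    classes = np.arange(int(entry), int(np.ceil(max_age)))
    y = samples["log_fgc"].to_numpy(float)
    cls = np.floor(samples["age"].to_numpy(float)).astype(int)
    cls_design = np.floor(design.age).astype(int)

    targets = np.full(len(classes), np.nan)
    X = np.full((len(classes), design.X.shape[1]), np.nan)
    cat_cols = [i for i, c in enumerate(design.columns)
                if c in ("pregnant", "lactating", "wet_season", "alpha")]
    icol = design.columns.index("intercept")
    acol = design.columns.index("age")
    for j, c in enumerate(classes):
        m = cls == c
        md = cls_design == c
        if m.sum() == 0 or md.sum() == 0:
            continue
        targets[j] = np.percentile(y[m], percentile)
        X[j] = design.X[md].mean(0)
        X[j, cat_cols] = 0.0
        X[j, icol] = 1.0
        X[j, acol] = c + 0.5
    empty = ~np.isfinite(targets)
    if empty.any():
        warnings.warn(f"percentile_trajectory: {int(empty.sum())} empty age "
                      "class(es) interpolated from neighbors")
        good = np.nonzero(~empty)[0]
        for j in np.nonzero(empty)[0]:
            targets[j] = np.interp(j, good, targets[good])
            for k in range(X.shape[1]):
                X[j, k] = np.interp(j, good, X[good, k])
    obs = classes + 0.5 < t0
    return TrajectorySpec(ages_mid=classes[obs] + 0.5, targets=targets[obs],
                          X=X, X_lo=classes.astype(float), t0=float(t0),
                          entry=float(entry))


def _integration_nodes(edges: np.ndarray, n_gl: int = 15):
    from .hazard import _gl_w, _gl_x
    lo, hi = edges[:-1], edges[1:]
    half = (hi - lo) / 2
    t = (lo[:, None] + hi[:, None]) / 2 + half[:, None] * _gl_x[None, :]
    w = half[:, None] * np.broadcast_to(_gl_w, t.shape)
    return t.ravel(), w.ravel(), np.repeat(np.arange(len(lo)), n_gl)


def conditional_survival(fit: JointFit, spec: TrajectorySpec,
                         age_grid: np.ndarray, rng=None) -> SurvivalCurve:
    """S(t | alive at t0) for the hypothetical female, across posterior draws.

    Per draw: the 2-dim random effect is drawn from its exact Gaussian
    conditional given the pseudo-observations (with the draw's sigma^2 as
    observation noise), the trajectory and hazard are rebuilt, and
    S(t | t0) = exp(-(H(t) - H(t0))) is evaluated on the grid. Exogenous
    survival covariates sit at their (standardized) population mean of zero.
    """
    grid = np.asarray(age_grid, float)
    if abs(grid[0] - spec.t0) > 1e-9:
        raise ValueError("age grid must start at the conditioning age t0")
    rng = np.random.default_rng(0 if rng is None else rng) \
        if not isinstance(rng, np.random.Generator) else rng

    names = fit.names
    d = fit.draws
    p = len(fit.map_params.beta)
    beta_d = d[[n for n in names if n.startswith("beta[")]].to_numpy()
    sd0 = d["sd_b0"].to_numpy()
    sd1 = d["sd_b1"].to_numpy()
    rho = d["rho_b"].to_numpy()
    sig2 = d["sigma"].to_numpy() ** 2
    alpha_d = d["alpha"].to_numpy() if "alpha" in d.columns else np.zeros(len(d))
    c_d = d[[n for n in names if n.startswith("c[")]].to_numpy()
    ndraw = len(d)
    mode = fit.mode

    acol = fit.data.age_col
    Xna = spec.X.copy()
    Xna[:, acol] = 0.0
    # conditional Gaussian of b given pseudo-observations
    Z = np.column_stack([np.ones_like(spec.ages_mid), spec.ages_mid])
    obs_rows = np.searchsorted(spec.X_lo, np.floor(spec.ages_mid)) \
        if len(spec.ages_mid) else np.array([], int)
    Xobs = spec.X[obs_rows]
    b_draw = np.zeros((ndraw, 2))
    for i in range(ndraw):
        S = np.array([[sd0[i] ** 2, rho[i] * sd0[i] * sd1[i]],
                      [rho[i] * sd0[i] * sd1[i], sd1[i] ** 2]])
        prec = np.linalg.inv(S + 1e-12 * np.eye(2)) + Z.T @ Z / sig2[i]
        V = np.linalg.inv(prec)
        r = spec.targets - Xobs @ beta_d[i]
        mu = V @ (Z.T @ r) / sig2[i]
        b_draw[i] = rng.multivariate_normal(mu, V)

    # trajectory pieces per draw: const (ndraw, S), slope (ndraw,)
    const = beta_d @ Xna.T + b_draw[:, [0]]
    slope = beta_d[:, acol] + b_draw[:, 1]
    seg_lo = spec.X_lo
    seg_hi = np.append(spec.X_lo[1:], spec.X_lo[-1] + 1.0)
    # integration edges: union of year boundaries and grid points
    edges = np.unique(np.concatenate([grid, seg_lo[(seg_lo > grid[0]) & (seg_lo < grid[-1])]]))
    t_nodes, w_nodes, _ = _integration_nodes(edges)
    seg_of = np.clip(np.searchsorted(seg_lo, t_nodes, side="right") - 1, 0, len(seg_lo) - 1)

    B = fit.data.baseline.basis(t_nodes)
    log_h0 = c_d @ B.T                                     # (ndraw, nodes)
    m_nodes = const[:, seg_of] + slope[:, None] * t_nodes[None, :]
    if mode == "value":
        f = alpha_d[:, None] * m_nodes
    elif mode == "slope":
        f = alpha_d[:, None] * np.broadcast_to(slope[:, None], m_nodes.shape)
    elif mode == "auc":
        # exact piecewise integral of m from entry to each node
        widths = seg_hi - seg_lo
        area = const * widths[None, :] + slope[:, None] * (seg_hi ** 2 - seg_lo ** 2)[None, :] / 2
        cum = np.cumsum(area, axis=1) - area
        I = cum[:, seg_of] + const[:, seg_of] * (t_nodes - seg_lo[seg_of])[None, :] \
            + slope[:, None] * (t_nodes ** 2 - seg_lo[seg_of] ** 2)[None, :] / 2
        f = alpha_d[:, None] * I
    else:
        f = np.zeros_like(m_nodes)
    h = np.exp(np.clip(log_h0 + f, -700, 700)) * w_nodes[None, :]
    # cumulative hazard at every edge, then pick out the grid points
    n_seg_int = len(edges) - 1
    h_seg = h.reshape(ndraw, n_seg_int, -1).sum(2)
    H_edges = np.concatenate([np.zeros((ndraw, 1)), np.cumsum(h_seg, 1)], axis=1)
    gidx = np.searchsorted(edges, grid)
    H_grid = H_edges[:, gidx]
    S_grid = np.exp(-(H_grid - H_grid[:, [0]]))
    med = np.median(S_grid, axis=0)
    lo, hi = np.quantile(S_grid, [0.05, 0.95], axis=0)
    return SurvivalCurve(ages=grid, median=med, lo90=lo, hi90=hi, t0=spec.t0)


def median_survival_age(curve: SurvivalCurve) -> float:
    """Age at which the median conditional survival curve crosses 0.5
    (linear interpolation); NaN if it never does within the grid."""
    s = curve.median
    below = np.nonzero(s <= 0.5)[0]
    if len(below) == 0:
        return float("nan")
    j = below[0]
    if j == 0:
        return float(curve.ages[0])
    a0, a1 = curve.ages[j - 1], curve.ages[j]
    s0, s1 = s[j - 1], s[j]
    return float(a0 + (s0 - 0.5) / (s0 - s1) * (a1 - a0))
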