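"""Linear mixed-effects submodel of log fGC with individual intercepts and age slopes.

The longitudinal submodel is

    y_ij = x_ij' beta + b0_i + b1_i * age_ij + eps_ij,   eps ~ N(0, sigma2)
    (b0_i, b1_i)' ~ N(0, Sigma_b)

fitted by maximum (marginal) likelihood: the four variance parameters are
optimized on an unconstrained scale with beta profiled out by GLS, using the
2x2 Woodbury identity per female so the fit is O(n) in the number of
samples. Conditional random effects are BLUPs. The same machinery (and the
resulting individual trajectory functions m_i(t)) is shared with the joint
survival model.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "LongitudinalDesign", "MixedModelFit", "TrajectoryFunction",
    "fit_lmm", "predict_m", "r2_nakagawa", "build_trajectories",
]


@dataclass
class LongitudinalDesign:
    """Aligned response / design arrays for the longitudinal submodel."""
    y: np.ndarray | None
    X: np.ndarray
    columns: list[str]
    age: np.ndarray
    female_labels: np.ndarray
    fid: np.ndarray            # 0..n_females-1 code per row
    zconsts: dict = field(default_factory=dict)
    dates: pd.DatetimeIndex | None = None
    n_dropped: int = 0

    @property
    def n_females(self) -> int:
        return len(self.female_labels)

    def __post_init__(self):
        if self.y is not None and len(self.y) != self.X.shape[0]:
            raise ValueError("response and design row counts differ")
        if len(self.age) != self.X.shape[0] or len(self.fid) != self.X.shape[0]:
            raise ValueError("design rows misaligned")


@dataclass
class MixedModelFit:
    beta: np.ndarray
    beta_cov: np.ndarray
    columns: list[str]
    Sigma_b: np.ndarray
    sigma2: float
    b: np.ndarray              # (n_females, 2) conditional modes (BLUPs)
    female_labels: np.ndarray
    loglik: float
    converged: bool
    zconsts: dict = field(default_factory=dict)

    def beta_interval(self, level: float = 0.90) -> np.ndarray:
        from scipy.stats import norm
        z = norm.ppf(0.5 + level / 2)
        se = np.sqrt(np.diag(self.beta_cov))
        return np.column_stack([self.beta - z * se, self.beta + z * se])

    def summary(self) -> pd.DataFrame:
        lo, hi = self.beta_interval().T
        return pd.DataFrame({"estimate": self.beta,
                             "se": np.sqrt(np.diag(self.beta_cov)),
                             "lo90": lo, "hi90": hi}, index=self.columns)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _group_stats(design: LongitudinalDesign):
    X, y, a, fid = design.X, design.y, design.age, design.fid
    n = design.n_females
    ones = np.ones_like(a)
    # per-female Z'Z entries, Z'X (2,p), Z'y (2,)
    n_i = np.bincount(fid, minlength=n)
    sa = np.bincount(fid, weights=a, minlength=n)
    saa = np.bincount(fid, weights=a * a, minlength=n)
    ZtZ = np.stack([np.stack([n_i.astype(float), sa], -1),
                    np.stack([sa, saa], -1)], 1)           # (n,2,2)
    p = X.shape[1]
    ZtX = np.empty((n, 2, p))
    for j in range(p):
        ZtX[:, 0, j] = np.bincount(fid, weights=X[:, j], minlength=n)
        ZtX[:, 1, j] = np.bincount(fid, weights=a * X[:, j], minlength=n)
    Zty = np.stack([np.bincount(fid, weights=y, minlength=n),
                    np.bincount(fid, weights=a * y, minlength=n)], -1)
    return dict(n_i=n_i, ZtZ=ZtZ, ZtX=ZtX, Zty=Zty,
                XtX=X.T @ X, Xty=X.T @ y, yty=float(y @ y), N=len(y))


def _unpack_phi(phi):
    sd0, sd1 = np.exp(phi[0]), np.exp(phi[1])
    rho = np.tanh(phi[2])
    sigma2 = np.exp(2 * phi[3])
    Sigma = np.array([[sd0 ** 2, rho * sd0 * sd1],
                      [rho * sd0 * sd1, sd1 ** 2]])
    return Sigma, sigma2


def _profiled(phi, st):
    """(-2 * profile loglik, beta, cov_beta, per-female A_i) at variance params."""
    Sigma, s2 = _unpack_phi(phi)
    n = st["ZtZ"].shape[0]
    # A_i = (Sigma^-1 + Z'Z / s2)^-1  (2x2, vectorized)
    Sinv = np.linalg.inv(Sigma + 1e-12 * np.eye(2))
    M = Sinv[None, :, :] + st["ZtZ"] / s2
    det = M[:, 0, 0] * M[:, 1, 1] - M[:, 0, 1] * M[:, 1, 0]
    A = np.empty_like(M)
    A[:, 0, 0] = M[:, 1, 1] / det
    A[:, 1, 1] = M[:, 0, 0] / det
    A[:, 0, 1] = -M[:, 0, 1] / det
    A[:, 1, 0] = -M[:, 1, 0] / det
    # log|V_i| = n_i log s2 + log|Sigma| + log|M_i|
    sgn, logdet_S = np.linalg.slogdet(Sigma + 1e-12 * np.eye(2))
    logdetV = st["N"] * np.log(s2) + n * logdet_S + np.sum(np.log(det))
    # X'V^-1X = (X'X - sum_i ZtX_i' A_i ZtX_i / s2) / s2  etc.
    AZX = np.einsum("nij,njp->nip", A, st["ZtX"])
    XVX = (st["XtX"] - np.einsum("nip,niq->pq", st["ZtX"], AZX) / s2) / s2
    AZy = np.einsum("nij,nj->ni", A, st["Zty"])
    XVy = (st["Xty"] - np.einsum("nip,ni->p", st["ZtX"], AZy) / s2) / s2
    yVy = (st["yty"] - np.einsum("ni,ni->", st["Zty"], AZy) / s2) / s2
    beta = np.linalg.solve(XVX, XVy)
    quad = yVy - beta @ XVy
    m2ll = logdetV + quad + st["N"] * np.log(2 * np.pi)
    return m2ll, beta, XVX, A


def fit_lmm(design: LongitudinalDesign, phi0=None) -> MixedModelFit:
    """Fit the mixed model by marginal maximum likelihood.

    Raises on a singular fixed-effect design, naming the collinear columns.
    """
    if design.y is None:
        raise ValueError("design has no response")
    if design.n_females < 2:
        raise ValueError("need at least 2 females")
    X = design.X
    s = np.linalg.svd(X, compute_uv=False)
    if s[-1] < 1e-10 * s[0]:
        # identify a collinear column by rank-revealing QR on the columns
        bad = []
        for j in range(X.shape[1]):
            others = np.delete(X, j, axis=1)
            r = X[:, j] - others @ np.linalg.lstsq(others, X[:, j], rcond=None)[0]
            if np.linalg.norm(r) < 1e-8 * max(1.0, np.linalg.norm(X[:, j])):
                bad.append(design.columns[j])
        raise ValueError(f"singular design; collinear columns: {bad or 'unknown'}")

    st = _group_stats(design)
    sd_y = float(np.std(design.y))
    if phi0 is None:
        phi0 = np.array([np.log(0.3 * sd_y + 1e-6), np.log(0.03 * sd_y + 1e-6),
                         0.0, np.log(0.8 * sd_y + 1e-6)])

    def nll(phi):
        try:
            return 0.5 * _profiled(phi, st)[0]
        except np.linalg.LinAlgError:  # pragma: no cover
            return 1e12

    # keep variance parameters away from exact singularity (degenerate
    # zero-noise data would otherwise destroy the GLS conditioning)
    lo = np.log(max(1e-4 * sd_y, 1e-10))
    bounds = [(lo, np.log(10 * sd_y + 1e-6)),
              (np.log(1e-7), np.log(sd_y + 1e-6)),
              (-5.0, 5.0),
              (lo, np.log(3 * sd_y + 1e-6))]
    res = optimize.minimize(nll, phi0, method="L-BFGS-B", bounds=bounds,
                            options=dict(maxiter=300))
    m2ll, beta, XVX, A = _profiled(res.x, st)
    Sigma, s2 = _unpack_phi(res.x)
    # BLUPs: b_i = A_i Z_i'(y_i - X_i beta) / s2
    resid_Zt = st["Zty"] - np.einsum("nip,p->ni", st["ZtX"], beta)
    b = np.einsum("nij,nj->ni", A, resid_Zt) / s2
    return MixedModelFit(
        beta=beta, beta_cov=np.linalg.inv(XVX), columns=list(design.columns),
        Sigma_b=Sigma, sigma2=s2, b=b, female_labels=design.female_labels,
        loglik=-0.5 * m2ll, converged=bool(res.success), zconsts=dict(design.zconsts),
    )


def r2_nakagawa(fit: MixedModelFit, design: LongitudinalDesign) -> tuple[float, float]:
    """Marginal and conditional R2 (variance decomposition for mixed models).

    marginal    = var(X beta) / (var(X beta) + var_random + sigma2)
    conditional = (var(X beta) + var_random) / (same denominator)

    where var_random is the mean over observations of z' Sigma_b z with
    z = (1, age).
    """
    eta = design.X @ fit.beta
    var_f = float(np.var(eta))
    a = design.age
    S = fit.Sigma_b
    var_r = float(np.mean(S[0, 0] + 2 * S[0, 1] * a + S[1, 1] * a * a))
    tot = var_f + var_r + fit.sigma2
    return var_f / tot, (var_f + var_r) / tot


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

@dataclass
class TrajectoryFunction:
    """Individual noise-free trajectory m_i(t), piecewise linear in age.

    ``m(t) = const[s] + slope * t`` on the year-of-life segment
    ``[edges[s], edges[s+1])``; ``const`` absorbs the non-age fixed effects
    for that year plus the individual's random intercept, ``slope`` is the
    fixed age slope plus the individual's random slope. Supports value,
    derivative, and (exact piecewise) integral queries.
    """
    female_id: object
    edges: np.ndarray          # (S+1,), edges[0] = entry age
    const: np.ndarray          # (S,)
    slope: float
    _cum: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        self.edges = np.asarray(self.edges, float)
        self.const = np.asarray(self.const, float)
        lo, hi = self.edges[:-1], self.edges[1:]
        seg = self.const * (hi - lo) + self.slope * (hi * hi - lo * lo) / 2
        self._cum = np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def entry(self) -> float:
        return float(self.edges[0])

    def _seg(self, t):
        return np.clip(np.searchsorted(self.edges, t, side="right") - 1,
                       0, len(self.const) - 1)

    def value(self, t):
        t = np.asarray(t, float)
        return self.const[self._seg(t)] + self.slope * t

    def derivative(self, t):
        return np.broadcast_to(self.slope, np.shape(np.asarray(t))).astype(float)

    def integral(self, t, lower: float | None = None):
        """Exact integral of m over [lower, t] (default lower = entry age)."""
        t = np.asarray(t, float)
        s = self._seg(t)
        lo = self.edges[s]
        out = self._cum[s] + self.const[s] * (t - lo) + self.slope * (t * t - lo * lo) / 2
        if lower is not None and lower != self.entry:
            out = out - self.integral(np.asarray(lower, float))
        return out


def predict_m(fit: MixedModelFit, female, t, covariate_path) -> np.ndarray:
    """Evaluate m_i(t) = X_i(t) beta + b0_i + b1_i t at times ``t``.

    ``covariate_path(t)`` must return design rows (len(t), p) in the fit's
    column order, or a precomputed array. Unknown females get the
    population-level prediction (b_i = 0); callers can detect this via the
    returned ``known`` flag.
    """
    t = np.atleast_1d(np.asarray(t, float))
    X = covariate_path(t) if callable(covariate_path) else np.asarray(covariate_path, float)
    if X.ndim == 1:
        X = X[None, :]
    idx = np.nonzero(fit.female_labels == female)[0]
    known = len(idx) > 0
    b = fit.b[idx[0]] if known else np.zeros(2)
    m = X @ fit.beta + b[0] + b[1] * t
    return (m, known)


def build_trajectories(beta, b, female_labels, year_table: pd.DataFrame,
                       columns: list[str], age_col: str = "age") -> dict:
    """Build per-female :class:`TrajectoryFunction` objects.

    ``year_table`` holds one design row per female-year segment with columns
    ``female_id``, ``lo``, ``hi`` (segment age bounds) and the design columns
    (evaluated at the segment midpoint; its ``age`` entry is ignored because
    age enters continuously through the slope).
    """
    beta = np.asarray(beta, float)
    ai = columns.index(age_col)
    beta_noage = beta.copy()
    beta_noage[ai] = 0.0
    out = {}
    lab_index = {f: i for i, f in enumerate(female_labels)}
    for f, grp in year_table.groupby("female_id", sort=False):
        grp = grp.sort_values("lo")
        Xg = grp[columns].to_numpy(float)
        bi = b[lab_index[f]] if f in lab_index else np.zeros(2)
        const = Xg @ beta_noage + bi[0]
        edges = np.concatenate([grp["lo"].to_numpy(float), [float(grp["hi"].iloc[-1])]])
        out[f] = TrajectoryFunction(female_id=f, edges=edges, const=const,
                                    slope=float(beta[ai] + bi[1]))
    return out
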