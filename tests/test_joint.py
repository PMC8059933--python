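"""Joint posterior: brute-force oracle equivalence, separability, diagnostics."""
import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad
from scipy.interpolate import BSpline
from scipy.stats import multivariate_normal, norm

from gcjoint.hazard import AUC_START, BaselineHazardSpline
from gcjoint.joint import (JointData, JointFit, JointParams, MCMCConfig,
                           PriorSpec, build_joint_data, diagnostics, fit_joint,
                           joint_log_posterior)
from gcjoint.longitudinal import LongitudinalDesign

COLS = ["intercept", "age", "x1"]
WCOLS = ["w1", "w2"]


def tiny_fixture(seed=0, n_f=3):
    """Hand-buildable joint dataset: 3 females, 2-4 year segments each."""
    rng = np.random.default_rng(seed)
    entries = [5.0, 6.3, 5.5][:n_f]
    exits = [8.7, 9.0, 7.2][:n_f]
    events = [True, False, True][:n_f]
    ys, Xs, ages, fids = [], [], [], []
    yt_rows = []
    records = []
    from gcjoint.hazard import SurvivalRecord
    for i in range(n_f):
        k = rng.integers(3, 6)
        a = np.sort(rng.uniform(entries[i], exits[i], k))
        x1 = rng.normal(0, 1, k)
        X = np.column_stack([np.ones(k), a, x1])
        Xs.append(X)
        ages.append(a)
        fids.append(np.full(k, i))
        ys.append(rng.normal(4.0, 0.5, k))
        lo = entries[i]
        edges = [lo]
        while lo < exits[i] - 1e-9:
            hi = min(np.floor(lo + 1e-9) + 1, exits[i])
            yt_rows.append({"female_id": f"f{i}", "lo": lo, "hi": hi,
                            "intercept": 1.0, "age": (lo + hi) / 2,
                            "x1": rng.normal(0, 1)})
            edges.append(hi)
            lo = hi
        W = rng.normal(0, 1, (len(edges) - 1, 2))
        records.append(SurvivalRecord(f"f{i}", entries[i], exits[i], events[i],
                                      np.array(edges), W, tuple(WCOLS)))
    design = LongitudinalDesign(
        y=np.concatenate(ys), X=np.vstack(Xs), columns=list(COLS),
        age=np.concatenate(ages),
        female_labels=np.array([f"f{i}" for i in range(n_f)]),
        fid=np.concatenate(fids))
    year_table = pd.DataFrame(yt_rows)
    knots = BaselineHazardSpline.make_knots(5.0, 9.5, [6.5, 7.5])
    return design, year_table, records, knots


def tiny_params(seed=1, n_f=3, alpha=0.4):
    rng = np.random.default_rng(seed)
    return JointParams(
        beta=np.array([4.0, 0.02, 0.3]),
        Sigma_b=np.array([[0.04, 0.002], [0.002, 0.001]]),
        sigma2=0.25,
        gamma=np.array([0.3, -0.2]),
        alpha=alpha,
        coefs=rng.normal(-2.5, 0.5, 6),
        b=rng.normal(0, 0.2, (n_f, 2)) * [1.0, 0.1],
    )


def oracle_logpost(params, design, year_table, records, knots, mode, priors):
    """Term-by-term brute force, written independently of the engine."""
    b = params.b
    ll = 0.0
    # longitudinal Gaussian
    for j in range(len(design.y)):
        f = design.fid[j]
        mu = design.X[j] @ params.beta + b[f, 0] + b[f, 1] * design.age[j]
        ll += norm.logpdf(design.y[j], mu, np.sqrt(params.sigma2))
    # random effects
    for f in range(len(records)):
        ll += multivariate_normal.logpdf(b[f], np.zeros(2), params.Sigma_b)
    # survival
    spl = BSpline(knots, params.coefs, 3)
    lo_k, hi_k = knots[3], knots[-4]

    for f, rec in enumerate(records):
        rows = year_table[year_table["female_id"] == rec.female_id] \
            .sort_values("lo").reset_index(drop=True)

        def mfun(t):
            idx = int(np.clip(np.searchsorted(rows["lo"].to_numpy(), t,
                                              side="right") - 1, 0, len(rows) - 1))
            r = rows.iloc[idx]
            return (params.beta[0] * r["intercept"] + params.beta[1] * t
                    + params.beta[2] * r["x1"] + b[f, 0] + b[f, 1] * t)

        def gfun(t):
            if mode == "none":
                return 0.0
            if mode == "value":
                return mfun(t)
            if mode == "slope":
                return params.beta[1] + b[f, 1]
            val, _ = quad(mfun, AUC_START, t,
                          points=list(rows["lo"]) + [rec.entry_age],
                          limit=200, epsabs=1e-12, epsrel=1e-12)
            return val

        def wfun(t):
            s = int(np.clip(np.searchsorted(rec.w_edges, t, side="right") - 1,
                            0, rec.W.shape[0] - 1))
            return rec.W[s]

        def loghaz(t):
            base = float(spl(np.clip(t, lo_k, hi_k - 1e-10)))
            return base + wfun(t) @ params.gamma + params.alpha * gfun(t) \
                if mode != "none" else base + wfun(t) @ params.gamma

        H, _ = quad(lambda t: np.exp(loghaz(t)), rec.entry_age, rec.exit_age,
                    points=list(rec.w_edges[1:-1]), limit=400,
                    epsabs=1e-11, epsrel=1e-11)
        ll -= H
        if rec.event:
            ll += loghaz(rec.exit_age)
    # priors (documented forms)
    pr = priors
    ll += np.sum(norm.logpdf(params.beta, pr.beta_loc, pr.beta_scale)
                 - norm.logpdf(0, 0, pr.beta_scale))
    ll += -0.5 * np.sum(params.gamma ** 2) / pr.gamma_scale ** 2
    if mode != "none":
        ll += -0.5 * params.alpha ** 2 / pr.alpha_scale ** 2
    cbar = np.mean(params.coefs)
    ll += -0.5 * cbar ** 2 / pr.spline_level_scale ** 2
    ll += -0.5 * np.sum((params.coefs - cbar) ** 2) / pr.spline_scale ** 2
    sd0 = np.sqrt(params.Sigma_b[0, 0])
    sd1 = np.sqrt(params.Sigma_b[1, 1])
    ll += -0.5 * (sd0 ** 2 + sd1 ** 2) / pr.sd_scale ** 2
    ll += -0.5 * params.sigma2 / pr.sigma_scale ** 2
    return ll


@pytest.fixture(scope="module")
def tiny():
    design, year_table, records, knots = tiny_fixture()
    data = {}
    for mode in ("value", "slope", "auc", "none"):
        data[mode] = build_joint_data(design, year_table, records,
                                      assoc_mode=mode, knots=knots,
                                      standardize_w=False)
    priors = PriorSpec(beta_loc=np.zeros(3), beta_scale=2.5)
    return design, year_table, records, knots, data, priors


class TestOracleEquivalence:
    @pytest.mark.parametrize("mode", ["value", "slope", "auc", "none"])
    def test_matches_brute_force(self, tiny, mode):
        design, year_table, records, knots, data, priors = tiny
        params = tiny_params(alpha=0.4 if mode != "auc" else 0.12)
        got = joint_log_posterior(params, data[mode], mode=mode, priors=priors)
        want = oracle_logpost(params, design, year_table, records, knots,
                              mode, priors)
        assert got == pytest.approx(want, rel=1e-8)

    def test_alpha_zero_factorizes(self, tiny):
        """With alpha = 0 the posterior is the sum of the longitudinal-only
        and survival-only pieces computed independently."""
        design, year_table, records, knots, data, priors = tiny
        params = tiny_params(alpha=0.0)
        total = joint_log_posterior(params, data["value"], mode="value",
                                    priors=priors)
        # independent pieces via the oracle with the association removed
        surv_only = oracle_logpost(params, design, year_table, records, knots,
                                   "none", priors)
        alpha_prior = -0.5 * 0.0 ** 2 / priors.alpha_scale ** 2
        assert total == pytest.approx(surv_only + alpha_prior, rel=1e-8)

    def test_single_censored_female_constant_hazard(self):
        """One censored female under a flat baseline: the survival term is
        exactly -c * (exit - entry)."""
        design, year_table, records, knots = tiny_fixture(n_f=3)
        rec = records[1]          # censored female
        assert not rec.event
        data1 = build_joint_data(
            LongitudinalDesign(y=design.y[design.fid == 1][:0],
                               X=design.X[:0], columns=COLS, age=design.age[:0],
                               female_labels=np.array([rec.female_id]),
                               fid=np.array([], int)),
            year_table[year_table["female_id"] == rec.female_id],
            [rec], assoc_mode="none", knots=knots, standardize_w=False)
        logc = -1.3
        priors = PriorSpec(beta_loc=np.zeros(3), beta_scale=2.5)
        p = tiny_params(n_f=1, alpha=0.0)
        p.coefs = np.full(6, logc)
        p.gamma = np.zeros(2)
        base = joint_log_posterior(p, data1, mode="none", priors=priors)
        p2 = tiny_params(n_f=1, alpha=0.0)
        p2.coefs = np.full(6, logc)
        p2.gamma = np.zeros(2)
        p2.b = p.b
        # same params but with hazard switched off via an enormous negative
        # baseline: the difference isolates the survival integral
        p2.coefs = np.full(6, -200.0)
        off = joint_log_posterior(p2, data1, mode="none", priors=priors)
        prior_diff = (-0.5 * np.mean(p.coefs) ** 2 / priors.spline_level_scale ** 2
                      + 0.5 * np.mean(p2.coefs) ** 2 / priors.spline_level_scale ** 2)
        surv_term = base - off - prior_diff
        assert surv_term == pytest.approx(
            -np.exp(logc) * (rec.exit_age - rec.entry_age), rel=1e-8)

    def test_invalid_parameters_rejected(self, tiny):
        *_, data, priors = tiny
        p = tiny_params()
        p.sigma2 = -1.0
        with pytest.raises(ValueError):
            joint_log_posterior(p, data["value"], mode="value", priors=priors)
        p = tiny_params()
        p.Sigma_b = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError):
            joint_log_posterior(p, data["value"], mode="value", priors=priors)


class TestFitJoint:
    def test_smoke_small_cohort(self, small_sim):
        sim = small_sim
        data = build_joint_data(sim.fgc.design, sim.fgc.year_table,
                                sim.records, assoc_mode="value")
        fit = fit_joint(data, mcmc_config=MCMCConfig(chains=2, iterations=400,
                                                     warmup=200, seed=1),
                        maxiter=40)
        assert len(fit.draws) == 2 * 200
        assert set(fit.names) <= set(fit.draws.columns)
        s = fit.summary()
        assert (s["lo90"] <= s["lo75"]).all() and (s["lo75"] <= s["lo50"]).all()
        assert (s["hi50"] <= s["hi75"]).all() and (s["hi75"] <= s["hi90"]).all()
        assert np.isfinite(fit.map_params.alpha)

    def test_seeded_draws_reproducible(self, small_sim):
        sim = small_sim
        data = build_joint_data(sim.fgc.design, sim.fgc.year_table,
                                sim.records, assoc_mode="none")
        kw = dict(mcmc_config=MCMCConfig(chains=2, iterations=300, warmup=150,
                                         seed=9), maxiter=30)
        f1 = fit_joint(data, **kw)
        f2 = fit_joint(data, **kw)
        pd.testing.assert_frame_equal(f1.draws, f2.draws)


def _fake_fit(draws_by_chain, seed=0):
    chains = len(draws_by_chain)
    per = len(draws_by_chain[0])
    df = pd.DataFrame({"x": np.concatenate(draws_by_chain)})
    df.insert(0, "chain", np.repeat(np.arange(chains), per))
    df.insert(1, "draw", np.tile(np.arange(per), chains))
    return JointFit(draws=df, names=["x"], map_params=None, theta_map=None,
                    cov=None, data=None, mode="none",
                    mcmc=MCMCConfig(chains=chains, iterations=per, warmup=0,
                                    seed=seed), converged=True)


class TestDiagnostics:
    def test_iid_chains_pass(self):
        rng = np.random.default_rng(0)
        fit = _fake_fit([rng.normal(0, 1, 800) for _ in range(4)])
        out = diagnostics(fit)
        assert out.loc["x", "rhat"] < 1.01
        assert bool(out.loc["x", "pass"])
        # ESS of i.i.d. draws is close to the draw count
        assert out.loc["x", "ess"] == pytest.approx(3200, rel=0.2)

    def test_disjoint_chains_flagged(self):
        fit = _fake_fit([np.zeros(300) + 1e-9 * np.arange(300),
                         np.ones(300) + 1e-9 * np.arange(300)])
        out = diagnostics(fit)
        assert out.loc["x", "rhat"] > 1.5
        assert not bool(out.loc["x", "pass"])

    def test_single_chain_warns(self):
        rng = np.random.default_rng(1)
        fit = _fake_fit([rng.normal(0, 1, 400)])
        with pytest.warns(UserWarning):
            out = diagnostics(fit)
        assert "rhat" not in out.columns
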