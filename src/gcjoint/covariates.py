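"""Environmental, social and life-history covariates of fecal glucocorticoid (fGC) levels.

This module builds every fixed-effect predictor of the longitudinal log-fGC
submodel, plus the annual rainfall anomaly used in the survival submodel,
from raw tabular records (daily weather, agonistic interactions, group
rosters, reproductive-state intervals).

Conventions
-----------
* Seasons are defined by calendar month: the dry season runs June-October,
  the wet season November-May.
* "3 months" of rainfall is a 90-day window ending the day *before* sample
  collection; the long-term mean for an anomaly uses every year of the
  record, including the focal year.
* The 30-day temperature window ends at and *includes* the sample day; up to
  5 missing days are tolerated.
* Proportional dominance rank is the fraction of same-group adult females
  the focal female dominated in the monthly hierarchy (0 = lowest,
  1 = alpha).
"""
from __future__ import annotations

import itertools
import logging
import warnings

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

DRY_MONTHS = frozenset({6, 7, 8, 9, 10})

#: Column order of the fixed-effect design matrix for the longitudinal submodel.
DESIGN_COLUMNS = [
    "intercept",
    "age",
    "pregnant",
    "lactating",
    "wet_season",
    "alpha",
    "z_rain_anom_3mo",
    "z_tmax_30d",
    "z_group_size",
    "z_group_size_sq",
    "z_rank",
    "z_time_to_extraction",
    "z_time_to_assay",
]

#: Raw sample-table columns that the design builder consumes.
RAW_COVARIATE_COLUMNS = [
    "age",
    "state",
    "season",
    "rain_anom_3mo",
    "tmax_30d",
    "group_size",
    "rank",
    "is_alpha",
    "time_to_extraction",
    "time_to_assay",
]


def season_of(date) -> str:
    """Return ``"dry"`` for June-October dates and ``"wet"`` otherwise."""
    month = pd.Timestamp(date).month
    return "dry" if month in DRY_MONTHS else "wet"


# ---------------------------------------------------------------------------
# rainfall / temperature windows
# ---------------------------------------------------------------------------

def _as_daily_series(daily: pd.Series | pd.DataFrame, column: str) -> pd.Series:
    if isinstance(daily, pd.DataFrame):
        daily = daily.set_index("date")[column] if "date" in daily.columns else daily[column]
    s = daily.copy()
    s.index = pd.DatetimeIndex(s.index)
    return s.sort_index()


def _interval_sums(values: np.ndarray, index: pd.DatetimeIndex,
                   starts: pd.DatetimeIndex, ends: pd.DatetimeIndex) -> np.ndarray:
    """Sum of a daily series over [start, end) for many intervals at once."""
    csum = np.concatenate([[0.0], np.cumsum(values)])
    i0 = index.searchsorted(starts, side="left")
    i1 = index.searchsorted(ends, side="left")
    return csum[i1] - csum[i0]


def _covered(index: pd.DatetimeIndex, starts, ends) -> np.ndarray:
    lo, hi = index[0], index[-1] + pd.Timedelta(days=1)
    return (pd.DatetimeIndex(starts) >= lo) & (pd.DatetimeIndex(ends) <= hi)


def rainfall_anomaly_3mo(daily_rain, dates, window_days: int = 90):
    """90-day rainfall anomaly preceding (and excluding) each sample date.

    The anomaly is the rainfall total over the ``window_days`` ending the day
    before ``date``, minus the long-term mean of the same calendar window
    across every year of the record (focal year included).

    Parameters
    ----------
    daily_rain : Series of daily rainfall (mm) indexed by date, or a
        DataFrame with ``date``/``rain`` columns.
    dates : scalar date or sequence of dates.

    Returns a float for scalar input, else an ndarray; windows not fully
    covered by the record yield NaN with a warning.
    """
    rain = _as_daily_series(daily_rain, "rain")
    scalar = np.isscalar(dates) or isinstance(dates, (str, pd.Timestamp, np.datetime64))
    dts = pd.DatetimeIndex([dates] if scalar else dates)
    ends = dts  # exclusive: window is [date - window, date - 1]
    starts = ends - pd.Timedelta(days=window_days)

    vals = rain.to_numpy(float)
    idx = rain.index
    focal = _interval_sums(vals, idx, starts, ends)
    ok = _covered(idx, starts, ends)

    first_year = idx[0].year
    last_year = idx[-1].year
    totals = np.zeros(len(dts))
    counts = np.zeros(len(dts))
    for k in range(-(last_year - first_year), last_year - first_year + 1):
        try:
            s_k = starts + pd.DateOffset(years=k)
        except (OverflowError, pd.errors.OutOfBoundsDatetime):  # pragma: no cover
            continue
        e_k = s_k + pd.Timedelta(days=window_days)
        cov = _covered(idx, s_k, e_k)
        sums = _interval_sums(vals, idx, pd.DatetimeIndex(s_k), pd.DatetimeIndex(e_k))
        totals += np.where(cov, sums, 0.0)
        counts += cov
    with np.errstate(invalid="ignore"):
        anom = focal - totals / counts
    anom = np.where(ok & (counts > 0), anom, np.nan)
    if np.any(~ok):
        warnings.warn("rainfall_anomaly_3mo: %d window(s) not covered by the "
                      "rainfall record; returning NaN" % int(np.sum(~ok)))
    return float(anom[0]) if scalar else anom


def annual_rainfall_anomaly(daily_rain, start_date, end_date):
    """Rainfall anomaly over one (possibly right-truncated) year of life.

    Total rainfall over ``[start_date, end_date)`` minus the long-term mean
    over the same calendar span in every year of the record.
    """
    rain = _as_daily_series(daily_rain, "rain")
    vals = rain.to_numpy(float)
    idx = rain.index
    start = pd.Timestamp(start_date)
    end = pd.Timestamp(end_date)
    if not _covered(idx, [start], [end])[0]:
        warnings.warn("annual_rainfall_anomaly: focal span not covered by record")
        return float("nan")
    focal = _interval_sums(vals, idx, pd.DatetimeIndex([start]), pd.DatetimeIndex([end]))[0]
    span = end - start
    total, count = 0.0, 0
    for k in range(-(idx[-1].year - idx[0].year), idx[-1].year - idx[0].year + 1):
        s_k = start + pd.DateOffset(years=k)
        e_k = s_k + span
        if _covered(idx, [s_k], [e_k])[0]:
            total += _interval_sums(vals, idx, pd.DatetimeIndex([s_k]), pd.DatetimeIndex([e_k]))[0]
            count += 1
    return float(focal - total / count)


def annual_rainfall_anomaly_batch(daily_rain, starts, ends) -> np.ndarray:
    """Vectorized :func:`annual_rainfall_anomaly` for many ``[start, end)``
    spans sharing one rainfall record (used by the synthetic-data generator)."""
    rain = _as_daily_series(daily_rain, "rain")
    vals = rain.to_numpy(float)
    idx = rain.index
    starts = pd.DatetimeIndex(starts)
    ends = pd.DatetimeIndex(ends)
    spans = ends - starts
    focal = _interval_sums(vals, idx, starts, ends)
    ok = _covered(idx, starts, ends)
    totals = np.zeros(len(starts))
    counts = np.zeros(len(starts))
    nyears = idx[-1].year - idx[0].year
    for k in range(-nyears, nyears + 1):
        s_k = starts + pd.DateOffset(years=k)
        e_k = s_k + spans
        cov = _covered(idx, s_k, e_k)
        sums = _interval_sums(vals, idx, s_k, e_k)
        totals += np.where(cov, sums, 0.0)
        counts += cov
    with np.errstate(invalid="ignore"):
        out = focal - totals / counts
    return np.where(ok & (counts > 0), out, np.nan)


def mean_max_temp_30d(daily_tmax, dates, window_days: int = 30, min_days: int = 25):
    """Mean daily maximum temperature over the 30 days ending at and
    including each date; NaN if fewer than ``min_days`` days are available."""
    tmax = _as_daily_series(daily_tmax, "tmax")
    scalar = np.isscalar(dates) or isinstance(dates, (str, pd.Timestamp, np.datetime64))
    dts = pd.DatetimeIndex([dates] if scalar else dates)
    ends = dts + pd.Timedelta(days=1)      # inclusive of sample day
    starts = ends - pd.Timedelta(days=window_days)
    vals = tmax.to_numpy(float)
    finite = np.isfinite(vals)
    sums = _interval_sums(np.where(finite, vals, 0.0), tmax.index, starts, ends)
    ndays = _interval_sums(finite.astype(float), tmax.index, starts, ends)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(ndays >= min_days, sums / ndays, np.nan)
    return float(out[0]) if scalar else out


# ---------------------------------------------------------------------------
# dominance hierarchy
# ---------------------------------------------------------------------------

def _inconsistencies(order: np.ndarray, wins: np.ndarray) -> tuple[int, int]:
    """(I, SI): number of dyads whose win record contradicts the order, and
    the summed rank distance of those dyads (I&SI-style objective)."""
    n = len(order)
    inc = 0
    si = 0
    for a in range(n):
        for b in range(a + 1, n):
            i, j = order[a], order[b]
            if wins[j, i] > wins[i, j]:
                inc += 1
                si += b - a
    return inc, si


def infer_order(wins: np.ndarray, exhaustive_max: int = 8, rng=None) -> np.ndarray:
    """Infer an ordinal dominance hierarchy from a decided-interaction matrix.

    ``wins[i, j]`` counts decided interactions that ``i`` won against ``j``.
    Returns indices ordered from top (alpha) to bottom. For N <= a small
    bound the inconsistency-minimizing order is found exhaustively; above it
    a David's-score seed is refined by pairwise-swap hill climbing.
    """
    wins = np.asarray(wins, float)
    n = wins.shape[0]
    if n == 1:
        return np.array([0])
    if n <= exhaustive_max:
        best, best_key = None, None
        for perm in itertools.permutations(range(n)):
            key = _inconsistencies(np.array(perm), wins)
            if best_key is None or key < best_key:
                best, best_key = np.array(perm), key
        return best
    # David's score seed
    tot = wins + wins.T
    with np.errstate(invalid="ignore", divide="ignore"):
        pij = np.where(tot > 0, wins / np.maximum(tot, 1), 0.5)
    np.fill_diagonal(pij, 0.0)
    w = pij.sum(1)
    l = pij.sum(0)
    ds = w + pij @ w - l - pij.T @ l
    order = np.argsort(-ds, kind="stable")
    improved = True
    key = _inconsistencies(order, wins)
    while improved:
        improved = False
        for a in range(n - 1):
            cand = order.copy()
            cand[a], cand[a + 1] = cand[a + 1], cand[a]
            ck = _inconsistencies(cand, wins)
            if ck < key:
                order, key, improved = cand, ck, True
    return order


def proportional_ranks(agonism: pd.DataFrame, month, roster_ids,
                       previous: pd.DataFrame | None = None) -> pd.DataFrame:
    """Monthly proportional dominance ranks for the adult females in a group.

    Parameters
    ----------
    agonism : DataFrame with columns ``date``, ``winner``, ``loser``
        (decided interactions only; undecided encounters must already have
        been discarded).
    month : anything accepted by ``pd.Period(..., "M")``.
    roster_ids : adult females present in the group that month.
    previous : ranks carried forward if the month has no interactions.

    Returns a DataFrame indexed by female id with ``rank`` in [0, 1] and
    ``is_alpha``; a single female receives rank 1 with a warning.
    """
    ids = list(roster_ids)
    n = len(ids)
    if n == 0:
        raise ValueError("empty roster")
    if n == 1:
        warnings.warn("proportional_ranks: single female; rank defined as 1")
        return pd.DataFrame({"rank": [1.0], "is_alpha": [True]}, index=ids)
    period = pd.Period(month, freq="M")
    dts = pd.PeriodIndex(pd.DatetimeIndex(agonism["date"]), freq="M")
    sub = agonism[(dts == period)
                  & agonism["winner"].isin(ids) & agonism["loser"].isin(ids)]
    if len(sub) == 0:
        if previous is not None:
            return previous.loc[previous.index.intersection(ids)].copy()
        out = pd.DataFrame({"rank": np.nan, "is_alpha": False}, index=ids)
        warnings.warn("proportional_ranks: no interactions and no previous "
                      "month; ranks missing")
        return out
    pos = {f: i for i, f in enumerate(ids)}
    wins = np.zeros((n, n))
    np.add.at(wins, (sub["winner"].map(pos).to_numpy(),
                     sub["loser"].map(pos).to_numpy()), 1.0)
    order = infer_order(wins)
    rank = np.empty(n)
    rank[order] = (n - 1 - np.arange(n)) / (n - 1)
    out = pd.DataFrame({"rank": rank, "is_alpha": rank == 1.0},
                       index=np.array(ids, dtype=object))
    return out


# ---------------------------------------------------------------------------
# reproductive state
# ---------------------------------------------------------------------------

LACTATION_PREGNANT_DAYS = 4  # parturition day + 3 following days coded pregnant


def reproductive_state_at(intervals, age: float) -> str:
    """Look up reproductive state at an age (decimal years).

    ``intervals`` is an iterable of ``(state, start_age, end_age)`` with
    half-open intervals partitioning the adult timeline. The first 4 days of
    each lactation interval (parturition day + 3) are recoded ``pregnant``
    because circulating steroids still reflect pregnancy there.
    """
    recode = LACTATION_PREGNANT_DAYS / 365.25
    for state, lo, hi in intervals:
        if lo <= age < hi:
            if state == "lactating" and age < lo + recode:
                return "pregnant"
            return state
    return "missing"


# ---------------------------------------------------------------------------
# design matrix
# ---------------------------------------------------------------------------

def zscore(x: np.ndarray, consts: tuple[float, float] | None = None):
    x = np.asarray(x, float)
    if consts is None:
        mu = float(np.mean(x))
        sd = float(np.std(x, ddof=0))
        if sd == 0:
            sd = 1.0
        consts = (mu, sd)
    return (x - consts[0]) / consts[1], consts


def build_fgc_design(samples: pd.DataFrame, zconsts: dict | None = None):
    """Assemble the fixed-effect design matrix of the longitudinal submodel.

    ``samples`` must carry the raw covariate columns in
    :data:`RAW_COVARIATE_COLUMNS` (and ``log_fgc`` plus ``female_id`` when a
    response is available). Continuous covariates are z-scored (group size
    squared after squaring, with its own constants); age stays in years and
    carries the random slope. Rows with unresolvable covariates are dropped
    with a count logged. Returns a :class:`~gcjoint.longitudinal.LongitudinalDesign`.
    """
    from .longitudinal import LongitudinalDesign

    df = samples.copy()
    df["group_size_sq"] = df["group_size"].astype(float) ** 2
    cont = {
        "z_rain_anom_3mo": "rain_anom_3mo",
        "z_tmax_30d": "tmax_30d",
        "z_group_size": "group_size",
        "z_group_size_sq": "group_size_sq",
        "z_rank": "rank",
        "z_time_to_extraction": "time_to_extraction",
        "z_time_to_assay": "time_to_assay",
    }
    need = list(cont.values()) + ["age", "state", "season", "is_alpha"]
    ok = np.ones(len(df), bool)
    for c in need:
        col = df[c]
        if col.dtype.kind in "fiub":
            ok &= np.isfinite(col.astype(float).to_numpy())
        else:
            ok &= col.notna().to_numpy() & (col != "missing").to_numpy()
    dropped = int(np.sum(~ok))
    if dropped:
        log.info("build_fgc_design: dropped %d samples with unresolvable covariates", dropped)
    df = df.loc[ok].reset_index(drop=True)
    if len(df) == 0:
        raise ValueError("no samples with complete covariates")

    consts = dict(zconsts) if zconsts else {}
    cols = {}
    cols["intercept"] = np.ones(len(df))
    cols["age"] = df["age"].to_numpy(float)
    cols["pregnant"] = (df["state"] == "pregnant").to_numpy(float)
    cols["lactating"] = (df["state"] == "lactating").to_numpy(float)
    cols["wet_season"] = (df["season"] == "wet").to_numpy(float)
    cols["alpha"] = df["is_alpha"].to_numpy(float)
    for zname, raw in cont.items():
        cols[zname], consts[zname] = zscore(df[raw].to_numpy(float), consts.get(zname))
    X = np.column_stack([cols[c] for c in DESIGN_COLUMNS])

    y = df["log_fgc"].to_numpy(float) if "log_fgc" in df.columns else None
    fem = df["female_id"].to_numpy() if "female_id" in df.columns else np.zeros(len(df), int)
    labels, fid = np.unique(fem, return_inverse=True)
    return LongitudinalDesign(
        y=y, X=X, columns=list(DESIGN_COLUMNS), age=cols["age"],
        female_labels=labels, fid=fid, zconsts=consts,
        dates=pd.DatetimeIndex(df["date"]) if "date" in df.columns else None,
        n_dropped=dropped,
    )
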