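"""Dyadic sociality indices (DSI_F, DSI_M) from grooming and observer effort.

For each female-year of life, every co-resident adult dyad gets a daily
grooming rate (events in either direction / co-residence days) and an
observer-effort value (focal samples on adult females during the
co-residence days / mean number of adult females present / co-residence
days). Bond strength is the residual of a population-wide OLS regression of
log daily rate on log effort (zero-grooming dyads are excluded: log 0 is
undefined and they cannot be "strongest" partners). DSI_F (DSI_M) is the
mean bond strength of the female's three strongest female (male) partners,
or of however many partners she has; remaining missing values are imputed
with age-class means.
"""
from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


def dyadic_rates(grooming: pd.DataFrame, coresidence: pd.DataFrame) -> pd.DataFrame:
    """Daily grooming rates per dyad.

    Parameters
    ----------
    grooming : columns ``id1``, ``id2``, ``count`` (direction is ignored:
        rows with giver/receiver swapped are pooled). Juvenile partners must
        already be excluded by the caller's roster filter; any dyad absent
        from ``coresidence`` (e.g. juveniles) is dropped.
    coresidence : columns ``id1``, ``id2``, ``coresidence_days`` and
        optionally ``partner_sex``; one row per co-resident adult dyad.

    Returns one record per co-resident dyad with ``grooming_count`` and
    ``daily_rate``; dyads with zero co-residence days are skipped.
    """
    co = coresidence.copy()
    co["key"] = [tuple(sorted((a, b))) for a, b in zip(co["id1"], co["id2"])]
    co = co[co["coresidence_days"] > 0]
    g = grooming.copy()
    if len(g):
        g["key"] = [tuple(sorted((a, b))) for a, b in zip(g["id1"], g["id2"])]
        counts = g.groupby("key")["count"].sum()
    else:
        counts = pd.Series(dtype=float)
    co["grooming_count"] = co["key"].map(counts).fillna(0).astype(float)
    co["daily_rate"] = co["grooming_count"] / co["coresidence_days"]
    return co.drop(columns=["key"]).reset_index(drop=True)


def observer_effort(focal_samples: float, mean_adult_females: float,
                    coresidence_days: float) -> float:
    """Observer effort for one dyad: the triple quotient
    (focal samples during the co-residence days) / (mean number of adult
    females present) / (co-residence days)."""
    if mean_adult_females <= 0:
        raise ValueError("no adult females present during co-residence days")
    if coresidence_days <= 0:
        raise ValueError("zero co-residence days")
    return focal_samples / mean_adult_females / coresidence_days


def bond_residuals(dyads: pd.DataFrame) -> pd.DataFrame:
    """OLS residuals of log daily grooming rate on log observer effort.

    The regression pools every dyad in the population for the year. Dyads
    with ``grooming_count`` < 1 are excluded from the fit and get no
    residual (NaN). If all efforts are identical the slope is undefined:
    residuals are centered log rates, with a warning.
    """
    out = dyads.copy()
    out["residual"] = np.nan
    fit = out[(out["grooming_count"] >= 1) & (out["effort"] > 0)]
    if len(fit) < 2:
        warnings.warn("bond_residuals: fewer than 2 groomed dyads; no residuals")
        return out
    x = np.log(fit["effort"].to_numpy(float))
    y = np.log(fit["daily_rate"].to_numpy(float))
    if np.ptp(x) < 1e-12:
        warnings.warn("bond_residuals: all efforts identical; slope set to 0")
        resid = y - y.mean()
    else:
        slope, icept = np.polyfit(x, y, 1)
        resid = y - (icept + slope * x)
    out.loc[fit.index, "residual"] = resid
    return out


def dsi(residuals: pd.DataFrame, female: str, partner_sex: str,
        top_k: int = 3) -> float:
    """Mean bond strength of the female's ``top_k`` strongest partners of a
    sex; fewer partners -> mean of those available; none -> NaN."""
    sub = residuals[
        ((residuals["id1"] == female) | (residuals["id2"] == female))
        & (residuals["partner_sex"] == partner_sex)
        & residuals["residual"].notna()]
    if len(sub) == 0:
        return float("nan")
    vals = np.sort(sub["residual"].to_numpy(float))[::-1]
    return float(np.mean(vals[:top_k]))


def dsi_table(residuals: pd.DataFrame, females, year_of_life=None) -> pd.DataFrame:
    """DSI_F and DSI_M for a list of focal females from one year's residuals."""
    rows = []
    for f in females:
        rows.append({"female_id": f,
                     "year_of_life": year_of_life,
                     "dsi_f": dsi(residuals, f, "F"),
                     "dsi_m": dsi(residuals, f, "M")})
    return pd.DataFrame(rows)


def impute_missing_dsi(table: pd.DataFrame, age_col: str = "year_of_life",
                       cols: tuple = ("dsi_f", "dsi_m")) -> pd.DataFrame:
    """Replace missing DSI values with the mean for that age class.

    The age class is the integer year of life. Classes with no observed
    values fall back to the global mean with a warning. Adds an
    ``imputed_<col>`` flag per column; the total imputation count is logged.
    """
    if len(table) == 0:
        raise ValueError("empty DSI table")
    out = table.copy()
    ages = np.floor(out[age_col].to_numpy(float)).astype(int)
    n_imputed = 0
    for c in cols:
        vals = out[c].to_numpy(float)
        miss = ~np.isfinite(vals)
        out[f"imputed_{c}"] = miss
        if not miss.any():
            continue
        if np.all(miss):
            raise ValueError(f"no observed values in column {c}")
        global_mean = float(np.nanmean(vals))
        for a in np.unique(ages[miss]):
            in_class = ages == a
            obs = vals[in_class & ~miss]
            if len(obs):
                fill = float(np.mean(obs))
            else:
                warnings.warn(f"impute_missing_dsi: age class {a} has no data; "
                              "using global mean")
                fill = global_mean
            vals[in_class & miss] = fill
        n_imputed += int(miss.sum())
        out[c] = vals
    log.info("impute_missing_dsi: imputed %d cells", n_imputed)
    out.attrs["n_imputed"] = n_imputed
    return out


# ---------------------------------------------------------------------------
# year-of-life pipeline over simulated behavior tables
# ---------------------------------------------------------------------------

def _monthly_presence(rosters: pd.DataFrame, month: pd.Period):
    start = month.to_timestamp()
    end = start + pd.offsets.MonthEnd(1)
    r = rosters.copy()
    r["start"] = pd.DatetimeIndex(r["start"])
    r["end"] = pd.DatetimeIndex(r["end"])
    days = (np.minimum(r["end"].values, end.to_datetime64())
            - np.maximum(r["start"].values, start.to_datetime64())) / np.timedelta64(1, "D")
    r["days"] = np.clip(days, 0, None)
    return r[r["days"] > 0]


def _population_dyads(grooming, effort, rosters, months, days, exclude_mask):
    """One dyad row per co-resident adult pair in every group, with the
    group's observer effort over the window (the bond-strength regression
    pools all dyads in the population, where effort varies across groups)."""
    frames = []
    for g, roster_g in rosters.groupby("group"):
        if exclude_mask is not None and all(exclude_mask(g, m) for m in months):
            continue
        use = [m for m in months
               if exclude_mask is None or not exclude_mask(g, m)]
        adult_f = roster_g.loc[roster_g["sex"] == "F", "id"].unique()
        adult_m = roster_g.loc[roster_g["sex"] == "M", "id"].unique()
        focal = float(effort.loc[(effort["group"] == g)
                                 & effort["month"].isin(use),
                                 "focal_samples"].sum())
        if focal <= 0 or len(adult_f) == 0:
            continue
        pairs = [(a, b, "F") for i, a in enumerate(adult_f)
                 for b in adult_f[i + 1:]]
        pairs += [(a, b, "M") for a in adult_f for b in adult_m]
        co = pd.DataFrame({"id1": [p[0] for p in pairs],
                           "id2": [p[1] for p in pairs],
                           "partner_sex": [p[2] for p in pairs],
                           "coresidence_days": float(days)})
        g_yr = grooming[(grooming["group"] == g)
                        & grooming["month"].isin(use)]
        dy = dyadic_rates(g_yr, co)
        dy["effort"] = focal / max(len(adult_f), 1) / dy["coresidence_days"]
        frames.append(dy)
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)


def dsi_from_tables(grooming: pd.DataFrame, effort: pd.DataFrame,
                    rosters: pd.DataFrame, females: pd.DataFrame,
                    exclude_mask=None) -> pd.DataFrame:
    """Compute per-female-year DSI_F/DSI_M from simulated behavior tables.

    ``females`` needs ``female_id``, ``birth_date``, ``entry_age``,
    ``censor_age``, ``group``. Years of life are birthday-aligned and may be
    right-truncated; for each window the log(rate)-on-log(effort) regression
    pools every co-resident adult dyad in the population. ``exclude_mask``
    is an optional callable ``(group, month_period) -> bool`` marking
    low-observation windows to drop (the study excludes a handful of such
    group-years).
    """
    grooming = grooming.copy()
    grooming["month"] = pd.PeriodIndex(grooming["month"], freq="M")
    effort = effort.copy()
    effort["month"] = pd.PeriodIndex(effort["month"], freq="M")
    rows = []
    for frow in females.itertuples():
        birth = pd.Timestamp(frow.birth_date)
        lo = frow.entry_age
        while lo < frow.censor_age - 1e-9:
            hi = min(np.floor(lo + 1e-9) + 1, frow.censor_age)
            start = birth + pd.Timedelta(days=round(lo * 365.25))
            end = birth + pd.Timedelta(days=round(hi * 365.25))
            months = list(pd.period_range(start, end, freq="M"))
            days = max((end - start).days, 1)
            dy = _population_dyads(grooming, effort, rosters, months, days,
                                   exclude_mask)
            if len(dy) == 0:
                rows.append({"female_id": frow.female_id,
                             "year_of_life": int(np.floor(lo)),
                             "dsi_f": np.nan, "dsi_m": np.nan})
                lo = hi
                continue
            dy = bond_residuals(dy)
            rows.append({"female_id": frow.female_id,
                         "year_of_life": int(np.floor(lo)),
                         "dsi_f": dsi(dy, frow.female_id, "F"),
                         "dsi_m": dsi(dy, frow.female_id, "M")})
            lo = hi
    return pd.DataFrame(rows)
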