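"""Fly demography: life tables, hazards, log-rank tests, mortality switches.

Days are 1-based integers. Censoring on day d removes live flies after that
day's deaths are recorded (flies sampled for expression profiling were alive
when collected). The instantaneous hazard estimate is the discrete-time
transform h(d) = -ln(1 - D/N) of the daily death probability, optionally
pooled over a centered window of days; it is NaN where nobody is at risk or
where everyone at risk dies (the transform diverges).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

VALID_STATUSES = {"death", "censored"}


class DemographyError(ValueError):
    """Invalid survival records or life table."""


def _check_events(events: pd.DataFrame) -> pd.DataFrame:
    for col in ("day", "status"):
        if col not in events.columns:
            raise DemographyError(f"events lack required column {col!r}")
    bad_status = set(events["status"]) - VALID_STATUSES
    if bad_status:
        raise DemographyError(f"unknown statuses: {sorted(bad_status)}")
    days = events["day"]
    if (days <= 0).any() or (days != days.astype(int)).any():
        raise DemographyError("event days must be positive integers")
    return events


def build_life_table(events: pd.DataFrame, cohort: str | None = None) -> pd.DataFrame:
    """Day-indexed life table (n_at_risk, deaths, censored) from fly records.

    ``events`` needs columns ``day`` and ``status`` (death/censored); if a
    ``cohort`` column with several cohorts is present, ``cohort`` selects one.
    Satisfies n_at_risk(d+1) = n_at_risk(d) - deaths(d) - censored(d).
    """
    events = _check_events(events)
    if cohort is not None:
        events = events[events["cohort"] == cohort]
        if events.empty:
            raise DemographyError(f"no events for cohort {cohort!r}")
    elif "cohort" in events.columns and events["cohort"].nunique() > 1:
        raise DemographyError(
            f"events mix cohorts {sorted(events['cohort'].unique())}; pass cohort=")
    if events.empty:
        raise DemographyError("no events")

    last = int(events["day"].max())
    days = pd.RangeIndex(1, last + 1, name="day")
    deaths = events.loc[events["status"] == "death", "day"].value_counts()
    censored = events.loc[events["status"] == "censored", "day"].value_counts()
    table = pd.DataFrame(0, index=days, columns=["n_at_risk", "deaths", "censored"])
    table["deaths"] = deaths.reindex(days, fill_value=0)
    table["censored"] = censored.reindex(days, fill_value=0)
    removed = (table["deaths"] + table["censored"]).cumsum().shift(fill_value=0)
    table["n_at_risk"] = len(events) - removed
    table.attrs["cohort"] = cohort if cohort is not None else (
        events["cohort"].iloc[0] if "cohort" in events.columns else None)
    return table


def hazard(life_table: pd.DataFrame, window: int = 1) -> pd.Series:
    """Daily instantaneous hazard -ln(1 - D/N) pooled over a centered window.

    D and N are deaths and flies-at-risk summed over the ``window`` days
    centered on each day (truncated at the table edges). NaN where N = 0 or
    D = N.
    """
    if window < 1:
        raise DemographyError("window must be >= 1")
    D = life_table["deaths"].rolling(window, center=True, min_periods=1).sum()
    N = life_table["n_at_risk"].rolling(window, center=True, min_periods=1).sum()
    frac = D / N
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -np.log(1.0 - frac)
    h = h.where((N > 0) & (frac < 1.0))
    h.name = "hazard"
    return h


def log_rank(events_a: pd.DataFrame, events_b: pd.DataFrame) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, two-sided p).

    Standard O/E/V sum over distinct death days with the hypergeometric
    variance; censored flies contribute to risk sets only. All flies are at
    risk from day 1.
    """
    events_a, events_b = _check_events(events_a), _check_events(events_b)
    if events_a.empty or events_b.empty:
        raise DemographyError("both groups must be nonempty")
    death_days = sorted(
        set(events_a.loc[events_a["status"] == "death", "day"]) |
        set(events_b.loc[events_b["status"] == "death", "day"]))
    if not death_days:
        raise DemographyError("no deaths in either group; log-rank undefined")

    day_a, day_b = events_a["day"].to_numpy(), events_b["day"].to_numpy()
    dead_a = events_a["status"].to_numpy() == "death"
    dead_b = events_b["status"].to_numpy() == "death"
    o_minus_e = 0.0
    var = 0.0
    for d in death_days:
        n_a = int((day_a >= d).sum())
        n_b = int((day_b >= d).sum())
        n = n_a + n_b
        d_a = int(((day_a == d) & dead_a).sum())
        d_b = int(((day_b == d) & dead_b).sum())
        d_tot = d_a + d_b
        if n <= 1 or d_tot == 0:
            continue
        e_a = d_tot * n_a / n
        o_minus_e += d_a - e_a
        var += d_tot * (n_a / n) * (n_b / n) * (n - d_tot) / (n - 1)
    if var == 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def max_lifespan(events: pd.DataFrame) -> float:
    """Mean death day of the longest-surviving 10% (censored flies excluded).

    The top group is the ceil(0.10 * n_deaths) latest deaths.
    """
    events = _check_events(events)
    deaths = np.sort(events.loc[events["status"] == "death", "day"].to_numpy())
    if deaths.size == 0:
        raise DemographyError("no deaths; maximum lifespan undefined")
    k = math.ceil(0.10 * deaths.size)
    return float(deaths[-k:].mean())


def _consecutive_run_start(days: np.ndarray, ok: np.ndarray, k: int) -> int | None:
    """First day starting a run of k consecutive calendar days all ok."""
    for i in range(len(days)):
        if not ok[i]:
            continue
        want = days[i] + np.arange(k)
        pos = np.searchsorted(days, want)
        if pos[-1] >= len(days):
            continue
        if np.array_equal(days[pos], want) and ok[pos].all():
            return int(days[i])
    return None


def detect_separation(hazard_a: pd.Series, hazard_b: pd.Series,
                      fold: float = 1.5, k: int = 3) -> int | None:
    """First day from which hazard_a / hazard_b >= fold for k consecutive days.

    Directional: the caller puts the higher-mortality cohort first. Days where
    either hazard is NaN, or the denominator is 0 alongside a 0 numerator, do
    not qualify. Returns None if no such day exists.
    """
    if fold <= 1:
        raise DemographyError("fold must be > 1")
    if k < 1:
        raise DemographyError("k must be >= 1")
    a, b = hazard_a.align(hazard_b, join="inner")
    defined = a.notna() & b.notna()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = a / b
    ratio = ratio.where(~((b == 0) & (a > 0)), np.inf)
    ok = (defined & (ratio >= fold)).to_numpy()
    days = np.asarray(a.index, dtype=int)
    return _consecutive_run_start(days, ok, k)


def detect_convergence(hazard_sf: pd.Series, hazard_rf: pd.Series,
                       switch_day: int, tol: float = 0.25, k: int = 2) -> int | None:
    """Days after the switch until the SF hazard matches the RF hazard.

    Returns the smallest lag L >= 0 such that |ln(h_SF / h_RF)| <= ln(1 + tol)
    on days switch_day + L, ..., switch_day + L + k - 1 (both hazards finite
    and positive on those days); None if the trajectories never converge.
    """
    if tol <= 0:
        raise DemographyError("tol must be > 0")
    if k < 1:
        raise DemographyError("k must be >= 1")
    sf, rf = hazard_sf.align(hazard_rf, join="inner")
    post = sf.index >= switch_day
    sf, rf = sf[post], rf[post]
    usable = sf.notna() & rf.notna() & (sf > 0) & (rf > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_ratio = np.log(sf / rf)
    ok = (usable & (np.abs(log_ratio) <= math.log1p(tol))).to_numpy()
    days = np.asarray(sf.index, dtype=int)
    start = _consecutive_run_start(days, ok, k)
    return None if start is None else int(start - switch_day)


def write_life_table(table: pd.DataFrame, hazard_series: pd.Series, path) -> None:
    out = table.copy()
    out["hazard"] = hazard_series
    out.to_csv(path, sep="\t")
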