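"""Study-design covariates: intervention calendars, weekends, weather, harmonics.

Each country ran a tiered escalation of COVID-19 non-pharmaceutical
interventions during February-April 2020, from level 0 (no measures) to
level 3 (stringent lockdown). The calendars below encode the official
transition dates; every 2019 date, and any date outside a calendar, maps to
level 0. ``annotate`` attaches to each retained participant-day the analysis
covariates used by the adjusted model: level, weekend flag, study-year
indicator, age, gender, site weather, and one sine/cosine harmonic pair
absorbing roughly-monthly periodic variability.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "CalendarEntry",
    "InterventionCalendar",
    "builtin_calendars",
    "load_calendars_yaml",
    "annotate",
    "harmonic_terms",
]

DEFAULT_HARMONIC_PERIOD_DAYS = 30.44  # mean Gregorian month length


@dataclass(frozen=True)
class CalendarEntry:
    start: dt.date
    end: dt.date  # inclusive
    level: int
    description: str = ""


@dataclass
class InterventionCalendar:
    """Country-keyed map from date to intervention level 0-3.

    Entries must tile their span without overlap or gap and appear in
    non-decreasing level order (interventions only escalated during the
    study window). Dates outside every entry are level 0.
    """

    site: str
    entries: list[CalendarEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.entries = sorted(self.entries, key=lambda e: e.start)
        prev: CalendarEntry | None = None
        for e in self.entries:
            if e.level not in (0, 1, 2, 3):
                raise ValueError(f"level {e.level} outside 0-3")
            if e.end < e.start:
                raise ValueError(f"entry ends before it starts: {e}")
            if prev is not None:
                if e.start != prev.end + dt.timedelta(days=1):
                    raise ValueError(
                        f"calendar {self.site}: gap/overlap between "
                        f"{prev.end} and {e.start}"
                    )
                if e.level < prev.level:
                    raise ValueError(
                        f"calendar {self.site}: level decreases at {e.start}"
                    )
            prev = e

    def assign(self, date: dt.date) -> int:
        for e in self.entries:
            if e.start <= date <= e.end:
                return e.level
        return 0

    def assign_series(self, dates: pd.Series) -> pd.Series:
        """Vectorised level assignment for a series of datetime64 dates."""
        out = pd.Series(0, index=dates.index, dtype="int64")
        d = pd.to_datetime(dates).dt.normalize()
        for e in self.entries:
            mask = (d >= pd.Timestamp(e.start)) & (d <= pd.Timestamp(e.end))
            out[mask] = e.level
        return out


def builtin_calendars() -> dict[str, InterventionCalendar]:
    """Official 2020 intervention calendars for Cyprus and Greece.

    Cyprus: baseline through March 12; level 1 (distancing, schools/bars
    closed) March 13-24; level 2 (retail closed, 3 movement permits/day)
    March 25-31; level 3 (one permit/day) April 1-26. Greece: baseline
    through March 10; level 1 March 11-15; level 2 (retail/worship closed)
    March 16-22; level 3 (movement restrictions) March 23-April 26.
    """
    cyprus = InterventionCalendar(
        site="Cyprus",
        entries=[
            CalendarEntry(dt.date(2020, 2, 3), dt.date(2020, 3, 12), 0, "baseline"),
            CalendarEntry(dt.date(2020, 3, 13), dt.date(2020, 3, 24), 1,
                          "social distancing, schools/bars/restaurants closed"),
            CalendarEntry(dt.date(2020, 3, 25), dt.date(2020, 3, 31), 2,
                          "retail/worship closed, 3 movement permits per day"),
            CalendarEntry(dt.date(2020, 4, 1), dt.date(2020, 4, 26), 3,
                          "stringent lockdown, one movement permit per day"),
        ],
    )
    greece = InterventionCalendar(
        site="Greece",
        entries=[
            CalendarEntry(dt.date(2020, 2, 3), dt.date(2020, 3, 10), 0, "baseline"),
            CalendarEntry(dt.date(2020, 3, 11), dt.date(2020, 3, 15), 1,
                          "social distancing, public events banned, schools closed"),
            CalendarEntry(dt.date(2020, 3, 16), dt.date(2020, 3, 22), 2,
                          "retail/worship closed, gatherings >10 banned"),
            CalendarEntry(dt.date(2020, 3, 23), dt.date(2020, 4, 26), 3,
                          "movement restrictions, subsistence/health only"),
        ],
    )
    return {"Cyprus": cyprus, "Greece": greece}


def load_calendars_yaml(path: str | Path) -> dict[str, InterventionCalendar]:
    """Load calendar overrides from YAML rows of (site, start, end, level)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    out: dict[str, list[CalendarEntry]] = {}
    for row in raw:
        out.setdefault(row["site"], []).append(
            CalendarEntry(
                start=_as_date(row["start"]),
                end=_as_date(row["end"]),
                level=int(row["level"]),
                description=str(row.get("description", "")),
            )
        )
    return {site: InterventionCalendar(site=site, entries=es) for site, es in out.items()}


def _as_date(v) -> dt.date:
    if isinstance(v, dt.date):
        return v
    return dt.date.fromisoformat(str(v))


def harmonic_terms(
    dates: pd.Series, period_days: float = DEFAULT_HARMONIC_PERIOD_DAYS
) -> tuple[pd.Series, pd.Series]:
    """Sine/cosine pair with argument 2*pi*(day of year)/period.

    The pair satisfies sin^2 + cos^2 = 1 and repeats exactly every
    ``period_days`` days, absorbing periodic variability of that scale.
    """
    doy = pd.to_datetime(dates).dt.dayofyear.astype(float)
    arg = 2.0 * np.pi * doy / float(period_days)
    return np.sin(arg), np.cos(arg)


def annotate(
    daily_metrics: pd.DataFrame,
    participants: pd.DataFrame,
    weather: pd.DataFrame,
    calendars: dict[str, InterventionCalendar] | None = None,
    harmonic_period_days: float = DEFAULT_HARMONIC_PERIOD_DAYS,
    weather_interp_limit_days: int = 2,
) -> pd.DataFrame:
    """Join analysis covariates onto the per-participant-day metrics table.

    Parameters
    ----------
    daily_metrics
        Output of sensor processing: one row per retained participant-day
        with columns participant_id, date, fraction_home, total_steps.
    participants
        Roster with participant_id, site, age_years, gender.
    weather
        Per (site, date) temp_c and rh_pct; gaps of up to
        ``weather_interp_limit_days`` days are linearly interpolated, days
        beyond that are dropped with a warning.
    calendars
        Site -> InterventionCalendar; defaults to the built-in 2020
        calendars. Dates not covered (all of 2019) are level 0.

    Returns
    -------
    DataFrame with columns participant_id, site, date, fraction_home,
    total_steps, level, weekend, year, year_2020, age_years, gender, male,
    temp_c, rh_pct, sin_t, cos_t, wk_lvl1..wk_lvl3.
    """
    if calendars is None:
        calendars = builtin_calendars()

    df = daily_metrics.copy()
    df["date"] = pd.to_datetime(df["date"]).dt.normalize()

    roster = participants.set_index("participant_id")
    missing = set(df["participant_id"]) - set(roster.index)
    if missing:
        raise ValueError(f"participants absent from roster: {sorted(missing)[:5]}")
    join_cols = [c for c in ("site", "age_years", "gender") if c not in df.columns]
    if join_cols:
        df = df.join(roster[join_cols], on="participant_id")

    # intervention level per site calendar; uncovered dates -> 0
    df["level"] = 0
    for site, grp in df.groupby("site"):
        cal = calendars.get(site)
        if cal is None:
            logger.warning("no calendar for site %s; all days level 0", site)
            continue
        df.loc[grp.index, "level"] = cal.assign_series(grp["date"]).values

    df["weekend"] = df["date"].dt.dayofweek >= 5
    df["year"] = df["date"].dt.year
    df["year_2020"] = (df["year"] == 2020).astype(int)
    df["male"] = (df["gender"].astype(str).str.upper().str[0] == "M").astype(int)
    df["sin_t"], df["cos_t"] = harmonic_terms(df["date"], harmonic_period_days)

    wx = _interpolated_weather(weather, weather_interp_limit_days)
    n_before = len(df)
    df = df.merge(wx, on=["site", "date"], how="left")
    gap = df["temp_c"].isna() | df["rh_pct"].isna()
    if gap.any():
        logger.warning(
            "dropping %d participant-days with weather gaps beyond the "
            "%d-day interpolation limit", int(gap.sum()), weather_interp_limit_days,
        )
        df = df[~gap].copy()
    logger.info("annotated %d of %d participant-days", len(df), n_before)

    for lvl in (1, 2, 3):
        df[f"wk_lvl{lvl}"] = (df["weekend"] & (df["level"] == lvl)).astype(int)
    df["weekend"] = df["weekend"].astype(int)
    return df.reset_index(drop=True)


def _interpolated_weather(weather: pd.DataFrame, limit_days: int) -> pd.DataFrame:
    """Per-site daily weather on a complete date grid, short gaps interpolated."""
    wx = weather.copy()
    wx["date"] = pd.to_datetime(wx["date"]).dt.normalize()
    parts = []
    for site, grp in wx.groupby("site"):
        grp = grp.set_index("date").sort_index()
        full = grp.reindex(pd.date_range(grp.index.min(), grp.index.max(), freq="D"))
        full[["temp_c", "rh_pct"]] = full[["temp_c", "rh_pct"]].interpolate(
            method="linear", limit=limit_days, limit_area="inside"
        )
        full["site"] = site
        parts.append(full.rename_axis("date").reset_index())
    return pd.concat(parts, ignore_index=True)[["site", "date", "temp_c", "rh_pct"]]
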