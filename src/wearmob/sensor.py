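"""Raw 5-minute smartwatch records -> validated per-participant-day metrics.

The daily outcomes are the two compliance endpoints of the analysis:

* ``fraction_home`` — the fraction of a 24-h day whose 5-min intervals fall
  inside a circular geofence (default radius 100 m) around the participant's
  residence. The denominator is fixed at 288 intervals (1,440 min) whatever
  the completeness of the record. Intervals without a GPS fix inherit the
  at-home/out-of-home label of the most recent valid fix (carry-forward,
  crossing midnight); a leading run with no prior fix takes the label of the
  next valid fix.
* ``total_steps`` — the sum of non-missing interval step counts over the day.

Days on which the watch was not worn are detected by the complete absence of
heart-rate samples and excluded, as are desert-dust-storm (DDS) advisory
days, on which the parent study actively altered participant behaviour.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AT_HOME",
    "OUT_HOME",
    "MISSING",
    "EARTH_RADIUS_M",
    "INTERVALS_PER_DAY",
    "haversine_m",
    "classify_interval",
    "classify_intervals",
    "carry_forward_fill",
    "impute_missing",
    "detect_wear_day",
    "aggregate_days",
    "apply_exclusions",
    "process",
    "ProcessResult",
]

AT_HOME = "AT_HOME"
OUT_HOME = "OUT_HOME"
MISSING = "MISSING"

EARTH_RADIUS_M = 6_371_000.0
INTERVALS_PER_DAY = 288
MINUTES_PER_INTERVAL = 5


def haversine_m(lat1, lon1, lat2, lon2):
    """Great-circle distance in metres on a sphere of radius 6,371 km.

    Accepts scalars or array-likes (broadcast); coordinates are WGS84
    decimal degrees. Raises for out-of-range coordinates.
    """
    lat1, lon1, lat2, lon2 = (np.asarray(x, dtype=float) for x in (lat1, lon1, lat2, lon2))
    for lat in (lat1, lat2):
        if np.any(np.abs(lat) > 90.0):
            raise ValueError("latitude outside [-90, 90]")
    for lon in (lon1, lon2):
        if np.any(np.abs(lon) > 180.0):
            raise ValueError("longitude outside [-180, 180]")
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlmb = np.radians(lon2 - lon1)
    a = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlmb / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    return d if d.ndim else float(d)


def classify_interval(lat, lon, home_lat, home_lon, radius_m: float = 100.0) -> str:
    """Classify one fix as AT_HOME / OUT_HOME / MISSING.

    The geofence boundary is inclusive: a fix at exactly ``radius_m`` metres
    counts as at home.
    """
    if radius_m <= 0:
        raise ValueError("radius_m must be positive")
    if lat is None or lon is None or (isinstance(lat, float) and np.isnan(lat)) or (
        isinstance(lon, float) and np.isnan(lon)
    ):
        return MISSING
    return AT_HOME if haversine_m(lat, lon, home_lat, home_lon) <= radius_m else OUT_HOME


def _validate_intervals(intervals: pd.DataFrame) -> pd.DataFrame:
    df = intervals.copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    ns = df["timestamp"].astype("int64")
    if not (ns % (MINUTES_PER_INTERVAL * 60 * 10**9) == 0).all():
        raise ValueError("timestamps not aligned to the 5-minute grid")
    dup = df.duplicated(subset=["participant_id", "timestamp"], keep="first")
    if dup.any():
        logger.warning(
            "dropping %d duplicate (participant, timestamp) rows (keeping first)",
            int(dup.sum()),
        )
        df = df[~dup]
    present = df["lat"].notna() & df["lon"].notna()
    if np.any(np.abs(df.loc[present, "lat"]) > 90.0) or np.any(
        np.abs(df.loc[present, "lon"]) > 180.0
    ):
        raise ValueError("coordinates out of range")
    if "steps" in df and np.any(df["steps"].dropna() < 0):
        raise ValueError("negative step counts")
    return df.sort_values(["participant_id", "timestamp"], kind="mergesort").reset_index(
        drop=True
    )


def classify_intervals(
    intervals: pd.DataFrame, participants: pd.DataFrame, radius_m: float = 100.0
) -> pd.DataFrame:
    """Validate interval records and attach a geofence classification.

    Returns the validated frame with an added ``loc_class`` column.
    """
    if radius_m <= 0:
        raise ValueError("radius_m must be positive")
    df = _validate_intervals(intervals)
    homes = participants.set_index("participant_id")[["home_lat", "home_lon"]]
    missing = set(df["participant_id"]) - set(homes.index)
    if missing:
        raise ValueError(f"no home location for participants {sorted(missing)[:5]}")
    df = df.join(homes, on="participant_id")
    has_fix = df["lat"].notna() & df["lon"].notna()
    dist = np.full(len(df), np.nan)
    if has_fix.any():
        sub = df[has_fix]
        dist[has_fix.to_numpy()] = haversine_m(
            sub["lat"].to_numpy(), sub["lon"].to_numpy(),
            sub["home_lat"].to_numpy(), sub["home_lon"].to_numpy(),
        )
    df["loc_class"] = MISSING
    df.loc[has_fix & (pd.Series(dist, index=df.index) <= radius_m), "loc_class"] = AT_HOME
    df.loc[has_fix & (pd.Series(dist, index=df.index) > radius_m), "loc_class"] = OUT_HOME
    return df.drop(columns=["home_lat", "home_lon"])


def carry_forward_fill(labels):
    """Fill MISSING labels in a time-ordered label sequence.

    Each MISSING takes the most recent preceding non-missing label; a leading
    MISSING run takes the first following non-missing label (backward fill).
    If no label is ever valid the sequence is returned unchanged.
    """
    s = pd.Series(list(labels), dtype="object")
    s = s.mask(s == MISSING)
    return s.ffill().bfill().fillna(MISSING).tolist()


def impute_missing(classified: pd.DataFrame) -> pd.DataFrame:
    """Carry-forward/backward imputation of MISSING geofence labels.

    Operates per participant over the participant's whole time-ordered
    record, so labels carry across midnight. Adds ``imputed`` (bool) and
    replaces ``loc_class``; participants with no valid fix anywhere keep
    MISSING and are flagged ``unresolvable``.
    """
    df = classified.copy()
    if (
        df.groupby("participant_id", sort=False)["timestamp"]
        .apply(lambda s: not s.is_monotonic_increasing)
        .any()
    ):
        raise ValueError("intervals not sorted by timestamp within participant")
    was_missing = df["loc_class"].eq(MISSING)
    lab = df["loc_class"].mask(df["loc_class"] == MISSING)
    filled = lab.groupby(df["participant_id"], sort=False).transform(
        lambda s: s.ffill().bfill()
    )
    df["loc_class"] = filled.fillna(MISSING)
    df["had_fix"] = ~was_missing
    df["imputed"] = was_missing & df["loc_class"].ne(MISSING)
    df["unresolvable"] = df["loc_class"].eq(MISSING)
    if df["unresolvable"].any():
        n = df.loc[df["unresolvable"], "participant_id"].nunique()
        logger.warning("%d participant(s) have no valid GPS fix at all", n)
    runs = was_missing.groupby((~was_missing).cumsum()).sum()
    if len(runs):
        logger.info("longest imputed run: %d intervals", int(runs.max()))
    return df


def detect_wear_day(heart_rates) -> bool:
    """A day counts as worn iff >= 1 non-missing heart-rate sample exists."""
    return bool(pd.Series(heart_rates).notna().any())


def aggregate_days(imputed: pd.DataFrame) -> pd.DataFrame:
    """Collapse imputed intervals to one row per participant-day.

    fraction_home = (# AT_HOME intervals x 5 min) / 1,440 min with the fixed
    24-h denominator; total_steps sums non-missing interval counts. Days with
    more than 288 rows are rejected. Days whose labels are unresolvable
    (participant never had a fix) get fraction_home = NaN.
    """
    df = imputed.copy()
    df["date"] = df["timestamp"].dt.normalize()
    g = df.groupby(["participant_id", "date"], sort=True)
    n = g.size()
    if (n > INTERVALS_PER_DAY).any():
        bad = n[n > INTERVALS_PER_DAY].index[0]
        raise ValueError(f"more than {INTERVALS_PER_DAY} intervals for {bad}")
    out = pd.DataFrame(
        {
            "n_intervals": n,
            "n_at_home": g["loc_class"].agg(lambda s: int((s == AT_HOME).sum())),
            "n_valid_gps": g["had_fix"].sum().astype(int),
            "n_imputed": g["imputed"].sum().astype(int),
            "total_steps": g["steps"].sum(min_count=0).fillna(0).astype(int),
            "wear_day": g["heart_rate"].agg(lambda s: bool(s.notna().any())),
            "unresolvable": g["unresolvable"].any(),
        }
    ).reset_index()
    out["fraction_home"] = out["n_at_home"] * MINUTES_PER_INTERVAL / 1440.0
    out.loc[out["unresolvable"], "fraction_home"] = np.nan
    return out


@dataclass
class ProcessResult:
    """Retained daily metrics plus an audit tally of every exclusion."""

    daily_metrics: pd.DataFrame
    tallies: dict[str, int]


def apply_exclusions(
    daily: pd.DataFrame, participants: pd.DataFrame, dds: pd.DataFrame | None = None
) -> ProcessResult:
    """Drop non-wear days, unresolvable days and DDS advisory days.

    ``dds`` has columns (site, date); it is matched through each
    participant's site. Returns the retained rows and per-reason counts.
    """
    df = daily.merge(
        participants[["participant_id", "site"]], on="participant_id", how="left"
    )
    tallies = {
        "nonwear_days": int((~df["wear_day"]).sum()),
        "unresolvable_days": int((df["wear_day"] & df["unresolvable"]).sum()),
    }
    keep = df["wear_day"] & ~df["unresolvable"]
    if dds is not None and len(dds):
        d = dds.copy()
        d["date"] = pd.to_datetime(d["date"]).dt.normalize()
        dds_keys = set(zip(d["site"], d["date"]))
        on_dds = pd.Series(
            [k in dds_keys for k in zip(df["site"], df["date"])], index=df.index
        )
        tallies["dds_days"] = int((keep & on_dds).sum())
        keep &= ~on_dds
    else:
        tallies["dds_days"] = 0
    out = df[keep].copy()
    out["dds_excluded"] = False
    tallies["retained_days"] = len(out)
    logger.info("exclusions: %s", tallies)
    return ProcessResult(daily_metrics=out.reset_index(drop=True), tallies=tallies)


def process(
    intervals: pd.DataFrame,
    participants: pd.DataFrame,
    dds: pd.DataFrame | None = None,
    radius_m: float = 100.0,
) -> ProcessResult:
    """Full sensor-processing stage: classify, impute, aggregate, exclude."""
    classified = classify_intervals(intervals, participants, radius_m=radius_m)
    imputed = impute_missing(classified)
    daily = aggregate_days(imputed)
    return apply_exclusions(daily, participants, dds=dds)
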