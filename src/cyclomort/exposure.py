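"""Cyclone exposure assignment from best-track data.

Exposure is dichotomous: a location is exposed on a calendar day if it lies
inside the R34 buffer (the radius of 34-kt sustained winds) of any track fix
dated that day.  Exposure over a lag window before a reference date is the
disjunction over the window's days.  Windows are closed day intervals before
the reference date: lag0 = [0, 30], lag1 = [31, 60], lag2 = [61, 90] and
lag02 = [0, 90], with day 0 being the reference date itself.

Tracks are densified to a sub-6-hourly cadence before matching so that a
fast-moving storm cannot step over a small buffer between fixes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0
NMI_TO_KM = 1.852
GALE_THRESHOLD_KT = 34.0

#: Closed day intervals (lower, upper) counted backwards from the reference
#: date; day 0 is the reference date.
LAG_WINDOWS: Mapping[str, tuple[int, int]] = {
    "lag0": (0, 30),
    "lag1": (31, 60),
    "lag2": (61, 90),
    "lag02": (0, 90),
}

#: Missing-value sentinels used by common best-track dialects.
_SENTINELS = {-999, -999.0, -99, 9999}


@dataclass(frozen=True)
class TrackFix:
    """One 6-hourly best-track observation."""

    storm_id: str
    timestamp: pd.Timestamp
    lat: float
    lon: float
    max_wind_kt: float
    r34_km: float


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km on a sphere of radius 6,371 km.

    All arguments in decimal degrees; broadcasts like numpy ufuncs.
    """
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(a, dtype=float))
                              for a in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def _check_coords(lat, lon) -> None:
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if np.any(~np.isfinite(lat)) or np.any(~np.isfinite(lon)):
        raise ValueError("non-finite coordinates")
    if np.any((lat < -90) | (lat > 90)):
        raise ValueError("latitude outside [-90, 90]")
    if np.any((lon <= -180) | (lon > 180)):
        raise ValueError("longitude outside (-180, 180]")


def point_in_buffer(lat: float, lon: float, fix: TrackFix) -> bool:
    """True iff the point lies within the fix's R34 buffer.

    The storm must be at gale intensity (max wind >= 34 kt) at the fix for a
    buffer to exist at all.
    """
    _check_coords(lat, lon)
    if fix.max_wind_kt < GALE_THRESHOLD_KT:
        return False
    return bool(haversine_km(lat, lon, fix.lat, fix.lon) <= fix.r34_km)


def read_tracks(source, r34_unit: str | None = None) -> pd.DataFrame:
    """Read a best-track CSV into the canonical track frame.

    Expected columns: storm_id, iso_time, lat, lon, wind_kt, r34 and
    optionally r34_unit ("km" or "nmi"; JTWC-native files carry nautical
    miles).  Rows whose radius or wind carries a missing-value sentinel are
    dropped.  Returns columns storm_id, time, lat, lon, wind_kt, r34_km
    sorted by storm and time.
    """
    df = pd.read_csv(source) if not isinstance(source, pd.DataFrame) else source.copy()
    cols = {c.lower().strip(): c for c in df.columns}
    out = pd.DataFrame({
        "storm_id": df[cols["storm_id"]].astype(str),
        "time": pd.to_datetime(df[cols["iso_time"] if "iso_time" in cols else cols["time"]]),
        "lat": pd.to_numeric(df[cols["lat"]], errors="coerce"),
        "lon": pd.to_numeric(df[cols["lon"]], errors="coerce"),
        "wind_kt": pd.to_numeric(df[cols["wind_kt"]], errors="coerce"),
        "r34": pd.to_numeric(df[cols["r34"]], errors="coerce"),
    })
    if r34_unit is None:
        r34_unit = str(df[cols["r34_unit"]].iloc[0]) if "r34_unit" in cols else "km"
    if r34_unit not in ("km", "nmi"):
        raise ValueError(f"unknown r34 unit {r34_unit!r}")
    factor = NMI_TO_KM if r34_unit == "nmi" else 1.0
    out["r34_km"] = out["r34"] * factor
    out = out.drop(columns="r34")
    for col in ("lat", "lon", "wind_kt", "r34_km"):
        out.loc[out[col].isin(_SENTINELS), col] = np.nan
    out = out.dropna(subset=["lat", "lon", "wind_kt", "r34_km"])
    out = out[out["r34_km"] > 0]
    _check_coords(out["lat"], out["lon"])
    return out.sort_values(["storm_id", "time"], kind="mergesort").reset_index(drop=True)


def interpolate_track(tracks: pd.DataFrame, step_minutes: int = 60) -> pd.DataFrame:
    """Linearly densify each storm's fixes to a step_minutes cadence.

    Position and R34 radius are interpolated in lat/lon/km; wind is
    interpolated linearly as well.  Endpoints are preserved exactly;
    single-fix storms pass through unchanged.
    """
    if step_minutes <= 0:
        raise ValueError("step_minutes must be positive")
    if tracks.empty:
        return tracks.copy()
    pieces = []
    step = pd.Timedelta(minutes=step_minutes)
    for storm_id, grp in tracks.groupby("storm_id", sort=False):
        grp = grp.sort_values("time", kind="mergesort")
        if len(grp) == 1:
            pieces.append(grp)
            continue
        t = grp["time"].to_numpy()
        if np.any(np.diff(t) <= np.timedelta64(0, "s")):
            raise ValueError(f"timestamps not strictly increasing for storm {storm_id}")
        new_times = [t[0]]
        for a, b in zip(t[:-1], t[1:]):
            cur = a + step
            while cur < b:
                new_times.append(cur)
                cur = cur + step
            new_times.append(b)
        new_times = pd.DatetimeIndex(new_times)
        t0 = t[0]
        xs = (t - t0) / np.timedelta64(1, "s")
        xn = (new_times.to_numpy() - t0) / np.timedelta64(1, "s")
        interp = {c: np.interp(xn, xs, grp[c].to_numpy(dtype=float))
                  for c in ("lat", "lon", "wind_kt", "r34_km")}
        pieces.append(pd.DataFrame({"storm_id": storm_id, "time": new_times, **interp}))
    return pd.concat(pieces, ignore_index=True)


def assign_exposure(lat: float, lon: float, reference_date,
                    tracks: pd.DataFrame,
                    windows: Mapping[str, tuple[int, int]] = LAG_WINDOWS) -> dict[str, bool]:
    """Classify exposure of one location over each lag window.

    A window is exposed iff any fix whose calendar date falls in
    [reference_date - upper, reference_date - lower] (both bounds inclusive)
    places the location inside its R34 buffer at gale intensity.  Tracks
    should already be densified.  An empty track table yields all-False.
    """
    _check_coords(lat, lon)
    ref = pd.Timestamp(reference_date).normalize()
    out = {label: False for label in windows}
    if tracks.empty:
        return out
    fix_day = tracks["time"].dt.normalize()
    for label, (lo, hi) in windows.items():
        start = ref - pd.Timedelta(days=hi)
        end = ref - pd.Timedelta(days=lo)
        sel = (fix_day >= start) & (fix_day <= end) & (tracks["wind_kt"] >= GALE_THRESHOLD_KT)
        if not sel.any():
            continue
        sub = tracks.loc[sel]
        d = haversine_km(lat, lon, sub["lat"].to_numpy(), sub["lon"].to_numpy())
        out[label] = bool(np.any(d <= sub["r34_km"].to_numpy()))
    return out


def exposure_events(locations: pd.DataFrame, tracks: pd.DataFrame) -> pd.DataFrame:
    """Per-location calendar days of cyclone exposure.

    locations needs columns (cluster_id, lat, lon); tracks should be
    densified.  Returns unique (cluster_id, day, storm_id) rows: the given
    location was inside storm_id's R34 buffer on that calendar day.  This is
    the batch primitive behind window exposure and gridded exposure counts.
    """
    if tracks.empty or locations.empty:
        return pd.DataFrame(columns=["cluster_id", "day", "storm_id"])
    trk = tracks[tracks["wind_kt"] >= GALE_THRESHOLD_KT]
    if trk.empty:
        return pd.DataFrame(columns=["cluster_id", "day", "storm_id"])
    loc_lat = locations["lat"].to_numpy(dtype=float)
    loc_lon = locations["lon"].to_numpy(dtype=float)
    _check_coords(loc_lat, loc_lon)
    days = trk["time"].dt.normalize().to_numpy()
    storm = trk["storm_id"].to_numpy()
    flat = []
    # chunk over fixes to bound the distance-matrix size
    chunk = max(1, int(2_000_000 / max(len(locations), 1)))
    for i0 in range(0, len(trk), chunk):
        sl = slice(i0, i0 + chunk)
        d = haversine_km(loc_lat[:, None], loc_lon[:, None],
                         trk["lat"].to_numpy()[None, sl], trk["lon"].to_numpy()[None, sl])
        hit_loc, hit_fix = np.nonzero(d <= trk["r34_km"].to_numpy()[None, sl])
        if hit_loc.size:
            flat.append(pd.DataFrame({
                "cluster_id": locations["cluster_id"].to_numpy()[hit_loc],
                "day": days[sl][hit_fix],
                "storm_id": storm[sl][hit_fix],
            }))
    if not flat:
        return pd.DataFrame(columns=["cluster_id", "day", "storm_id"])
    return (pd.concat(flat, ignore_index=True)
            .drop_duplicates()
            .sort_values(["cluster_id", "day", "storm_id"], kind="mergesort")
            .reset_index(drop=True))


def window_weather(weather: pd.DataFrame, reference_date,
                   window: tuple[int, int]) -> tuple[float, float]:
    """Aggregate a cluster's monthly weather over one lag window.

    weather holds that cluster's monthly series with columns
    (year, month, temp_c, precip_mm).  The window's calendar span
    [reference_date - upper, reference_date - lower] is mapped to the set of
    calendar months it overlaps; the mean of monthly mean temperatures and
    the sum of monthly precipitation over those months are returned.
    Raises KeyError if any overlapped month is missing from the series.
    """
    ref = pd.Timestamp(reference_date).normalize()
    lo, hi = window
    start, end = ref - pd.Timedelta(days=hi), ref - pd.Timedelta(days=lo)
    months = pd.period_range(start.to_period("M"), end.to_period("M"), freq="M")
    idx = weather.set_index(["year", "month"])
    temps, precs = [], []
    for p in months:
        key = (p.year, p.month)
        if key not in idx.index:
            raise KeyError(f"weather series missing {p.year}-{p.month:02d}")
        row = idx.loc[key]
        temps.append(float(row["temp_c"]))
        precs.append(float(row["precip_mm"]))
    return float(np.mean(temps)), float(np.sum(precs))


def build_exposure_profiles(members: pd.DataFrame, clusters: pd.DataFrame,
                            tracks: pd.DataFrame, weather: pd.DataFrame,
                            windows: Mapping[str, tuple[int, int]] = LAG_WINDOWS,
                            step_minutes: int = 60) -> pd.DataFrame:
    """Exposure flags and windowed weather for every matched-set member.

    members needs (cluster_id, reference_date) columns (others pass
    through).  Tracks are densified here.  Output adds, per window label W,
    ``exposed_W`` (0/1), ``temp_W`` (degC) and ``precip_W`` (mm), and asserts
    the nesting invariant exposed_lag02 == lag0 | lag1 | lag2 when all three
    monthly windows are requested.
    """
    out = members.copy()
    out["reference_date"] = pd.to_datetime(out["reference_date"]).dt.normalize()
    dense = interpolate_track(read_tracks(tracks) if isinstance(tracks, str) else tracks,
                              step_minutes=step_minutes)
    loc = clusters[["cluster_id", "lat", "lon"]].drop_duplicates("cluster_id")
    events = exposure_events(loc, dense)
    exp_days = {cid: grp["day"].unique() for cid, grp in events.groupby("cluster_id")}

    ref = out["reference_date"].to_numpy()
    cids = out["cluster_id"].to_numpy()
    for label, (lo, hi) in windows.items():
        flags = np.zeros(len(out), dtype=int)
        for cid in np.unique(cids):
            days = exp_days.get(cid)
            if days is None or len(days) == 0:
                continue
            days = np.sort(days)
            m = cids == cid
            start = ref[m] - np.timedelta64(hi, "D")
            end = ref[m] - np.timedelta64(lo, "D")
            i = np.searchsorted(days, start, side="left")
            hit = (i < len(days)) & (days[np.minimum(i, len(days) - 1)] <= end)
            flags[m] = hit.astype(int)
        out[f"exposed_{label}"] = flags

    wkey = weather["year"].to_numpy() * 12 + weather["month"].to_numpy()
    wx = {(c, k): (t, p) for c, k, t, p in zip(
        weather["cluster_id"], wkey, weather["temp_c"], weather["precip_mm"])}
    ref_idx = out["reference_date"]
    for label, (lo, hi) in windows.items():
        start_p = (ref_idx - pd.Timedelta(days=hi)).dt.to_period("M")
        end_p = (ref_idx - pd.Timedelta(days=lo)).dt.to_period("M")
        k0 = (start_p.dt.year * 12 + start_p.dt.month).to_numpy()
        k1 = (end_p.dt.year * 12 + end_p.dt.month).to_numpy()
        temps = np.empty(len(out))
        precs = np.empty(len(out))
        for i, (cid, a, b) in enumerate(zip(cids, k0, k1)):
            t_acc, p_acc = 0.0, 0.0
            for k in range(a, b + 1):
                try:
                    t, p = wx[(cid, k)]
                except KeyError:
                    y, m = divmod(k - 1, 12)
                    raise KeyError(f"weather series missing {y}-{m + 1:02d} "
                                   f"for cluster {cid}") from None
                t_acc += t
                p_acc += p
            temps[i] = t_acc / (b - a + 1)
            precs[i] = p_acc
        out[f"temp_{label}"] = temps
        out[f"precip_{label}"] = precs

    if {"lag0", "lag1", "lag2", "lag02"} <= set(windows):
        union = (out["exposed_lag0"] | out["exposed_lag1"] | out["exposed_lag2"])
        if not (out["exposed_lag02"] == union).all():
            raise AssertionError("window nesting violated: lag02 != lag0|lag1|lag2")
    return out
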