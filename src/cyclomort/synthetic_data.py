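"""Seeded synthetic cohorts, cyclone tracks, weather and burden grids.

The generator emulates the statistical structure the analysis assumes —
multi-child families with realistic birth spacing, under-five death ages
concentrated in infancy, survey clusters scattered over a bounding box,
gale-force storm tracks crossing it, and a configurable multiplicative
effect of recent cyclone exposure on the monthly odds of death — without
any claim of demographic or meteorological realism.  Everything is driven
by one integer seed and is bit-reproducible.

Death ages are assigned through a discrete per-month hazard calibrated so
that the marginal distribution of death ages over the five yearly bins
matches the configured weights; when a child's cluster is cyclone-exposed
in a calendar month, the odds of death in that month are multiplied by
``true_or``.  This makes the generating process exactly the multiplicative
odds model the conditional logistic analysis estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exposure import exposure_events, interpolate_track

KM_PER_DEG_LAT = 111.19

WATER_LEVELS = ("piped_or_bottled", "well", "natural", "other")
WATER_PROBS = (0.32, 0.45, 0.13, 0.10)
TOILET_LEVELS = ("flush", "pit", "none", "other")
TOILET_PROBS = (0.28, 0.32, 0.35, 0.05)
EDUCATION_LEVELS = ("primary_or_none", "secondary", "high_school_plus")
EDUCATION_PROBS = (0.77, 0.21, 0.02)
HOUSING_LEVELS = ("unfinished", "finished")

#: Death-age bin weights (months 0-11, 12-23, 24-35, 36-47, 48-59) matching
#: the observed concentration of under-five deaths in infancy (~79% < 12 mo).
DEFAULT_DEATH_AGE_WEIGHTS = (0.7948, 0.1080, 0.0474, 0.0262, 0.0236)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic replicate."""

    n_mothers: int = 2000
    children_per_mother_range: tuple[int, int] = (2, 5)
    study_window: tuple[str, str] = ("2000-01-01", "2015-12-31")
    baseline_death_prob: float = 0.08
    death_age_distribution: tuple[float, ...] = DEFAULT_DEATH_AGE_WEIGHTS
    true_or: float = 1.0
    n_storms: int = 8
    r34_range_km: tuple[float, float] = (50.0, 200.0)
    storm_speed_kmh: float = 20.0
    bbox: tuple[float, float, float, float] = (5.0, 25.0, 100.0, 120.0)
    single_child_fraction: float = 0.10
    n_clusters: int | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_mothers <= 0 or self.n_storms < 0:
            raise ValueError("counts must be positive (n_storms may be 0)")
        if self.children_per_mother_range[0] < 1:
            raise ValueError("children_per_mother_range min must be >= 1")
        if not (0.0 <= self.baseline_death_prob <= 1.0):
            raise ValueError("baseline_death_prob must be a probability")
        if self.true_or <= 0:
            raise ValueError("true_or must be positive")
        w = np.asarray(self.death_age_distribution, float)
        if len(w) != 5 or np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise ValueError("death_age_distribution must be 5 non-negative "
                             "weights summing to 1")
        lat0, lat1, lon0, lon1 = self.bbox
        if lat0 >= lat1 or lon0 >= lon1:
            raise ValueError("degenerate bbox")
        start, end = (pd.Timestamp(t) for t in self.study_window)
        if start >= end:
            raise ValueError("empty study window")

    @property
    def window(self) -> tuple[pd.Timestamp, pd.Timestamp]:
        return pd.Timestamp(self.study_window[0]), pd.Timestamp(self.study_window[1])


def _stage_rng(config: SimConfig, stage: int) -> np.random.Generator:
    """Independent per-stage stream so stage reruns do not perturb others."""
    return np.random.default_rng(np.random.SeedSequence(config.seed).spawn(8)[stage])


def _country_of_lon(lon: np.ndarray, bbox) -> np.ndarray:
    """Three synthetic countries split by longitude terciles of the bbox."""
    lat0, lat1, lon0, lon1 = bbox
    edges = np.linspace(lon0, lon1, 4)
    idx = np.clip(np.searchsorted(edges, lon, side="right") - 1, 0, 2)
    return np.array(["C1", "C2", "C3"])[idx]


# ---------------------------------------------------------------------------
# tracks


def generate_tracks(config: SimConfig) -> pd.DataFrame:
    """Piecewise-linear storm tracks with 6-hourly fixes.

    Each storm starts on a random edge region of the bbox, moves at
    ``storm_speed_kmh`` with small random heading perturbations for 3-8
    days, carries a max wind of 35-120 kt, and an R34 radius random-walking
    within ``r34_range_km``.  Timestamps are strictly increasing per storm.
    """
    rng = _stage_rng(config, 1)
    lat0, lat1, lon0, lon1 = config.bbox
    start, end = config.window
    rows = []
    for s in range(config.n_storms):
        storm_id = f"STM{s:03d}"
        n_fix = int(rng.integers(12, 33))  # 3-8 days of 6-hourly fixes
        t0 = start + pd.Timedelta(
            seconds=float(rng.uniform(0, (end - start).total_seconds())))
        t0 = t0.floor("6h")
        lat = float(rng.uniform(lat0, lat1))
        lon = float(rng.uniform(lon0, lon0 + 0.2 * (lon1 - lon0)))
        heading = float(rng.uniform(-45, 45))  # roughly eastward
        wind = float(rng.uniform(40, 100))
        r34 = float(rng.uniform(*config.r34_range_km))
        step_km = config.storm_speed_kmh * 6.0
        for i in range(n_fix):
            rows.append((storm_id, t0 + pd.Timedelta(hours=6 * i), lat, lon,
                         max(35.0, wind), r34))
            heading += float(rng.normal(0, 12))
            rad = np.radians(heading)
            lat += step_km * np.sin(rad) / KM_PER_DEG_LAT
            lon += step_km * np.cos(rad) / (KM_PER_DEG_LAT *
                                            max(np.cos(np.radians(lat)), 0.2))
            # storms may leave the study box; only keep coordinates valid
            lat = float(np.clip(lat, -85.0, 85.0))
            lon = float(np.clip(lon, -179.9, 179.9))
            wind = float(np.clip(wind + rng.normal(0, 6), 35, 120))
            r34 = float(np.clip(r34 + rng.normal(0, 8), *config.r34_range_km))
    df = pd.DataFrame(rows, columns=["storm_id", "time", "lat", "lon",
                                     "wind_kt", "r34_km"])
    return df


# ---------------------------------------------------------------------------
# cohort


def _monthly_hazard(weights: np.ndarray, q: float) -> np.ndarray:
    """Per-month discrete hazard whose marginal death-age distribution over
    the five yearly bins equals ``weights`` and whose cumulative death
    probability by 60 months equals ``q``."""
    f = q * np.repeat(np.asarray(weights, float) / 12.0, 12)  # unconditional pmf
    surv = 1.0 - np.concatenate([[0.0], np.cumsum(f)[:-1]])
    return f / surv


def generate_clusters(config: SimConfig) -> pd.DataFrame:
    """Survey clusters scattered uniformly over the bbox."""
    rng = _stage_rng(config, 0)
    n = config.n_clusters or max(10, config.n_mothers // 25)
    lat0, lat1, lon0, lon1 = config.bbox
    lat = rng.uniform(lat0, lat1, n)
    lon = rng.uniform(lon0, lon1, n)
    country = _country_of_lon(lon, config.bbox)
    return pd.DataFrame({
        "cluster_id": [f"CL{i:04d}" for i in range(n)],
        "lat": lat, "lon": lon,
        "urban": rng.random(n) < 0.22,
        "country": country,
        "survey_id": [f"{c}-S1" for c in country],
    })


def generate_cohort(config: SimConfig, tracks: pd.DataFrame | None = None,
                    clusters: pd.DataFrame | None = None
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Children and clusters for one synthetic replicate.

    When ``tracks`` is given and ``true_or`` != 1, the monthly odds of death
    are multiplied by ``true_or`` in calendar months in which the child's
    cluster lies inside any storm's R34 buffer.  Children are censored at
    the survey interview date (window end); a study window shorter than 60
    months triggers a warning and right-censoring.
    """
    rng = _stage_rng(config, 2)
    if clusters is None:
        clusters = generate_clusters(config)
    start, end = config.window
    if end - start < pd.Timedelta(days=60 * 30.44):
        warnings.warn("study window shorter than 60 months: children are "
                      "censored at the window end", stacklevel=2)

    # family structure
    n = config.n_mothers
    single = rng.random(n) < config.single_child_fraction
    lo, hi = config.children_per_mother_range
    n_children = np.where(single, 1, rng.integers(max(lo, 2), hi + 1, n))
    cluster_idx = rng.integers(0, len(clusters), n)

    mother_rows = np.repeat(np.arange(n), n_children)
    order = np.concatenate([np.arange(1, k + 1) for k in n_children])
    spacing = rng.integers(18, 43, len(mother_rows))  # months between births
    months_from_first = np.concatenate(
        [np.concatenate([[0], np.cumsum(s[1:])]) for s in
         np.split(spacing, np.cumsum(n_children)[:-1])])

    span_m = np.maximum.reduceat(months_from_first, np.cumsum(n_children) - n_children)
    total_months = int((end.to_period("M") - start.to_period("M")).n)
    slack = np.maximum(total_months - 60 - span_m, 1)
    first_offset = (rng.random(n) * slack).astype(int)
    birth_month_idx = np.repeat(first_offset, n_children) + months_from_first
    start_p = pd.period_range(start, periods=1, freq="M")
    birth_period = start_p.repeat(len(birth_month_idx)) + birth_month_idx
    birth_day = rng.integers(1, 29, len(mother_rows))
    birth_date = birth_period.to_timestamp() + pd.to_timedelta(birth_day - 1, "D")

    # household covariates (shared within household)
    water = rng.choice(WATER_LEVELS, n, p=WATER_PROBS)
    toilet = rng.choice(TOILET_LEVELS, n, p=TOILET_PROBS)
    housing = rng.choice(HOUSING_LEVELS, n, p=(0.55, 0.45))
    edu = rng.choice(EDUCATION_LEVELS, n, p=EDUCATION_PROBS)
    mother_age_first = rng.uniform(16, 34, n)

    nn = len(mother_rows)
    children = pd.DataFrame({
        "child_id": [f"CH{i:06d}" for i in range(nn)],
        "mother_id": np.array([f"M{i:05d}" for i in range(n)])[mother_rows],
        "household_id": np.array([f"HH{i:05d}" for i in range(n)])[mother_rows],
        "cluster_id": clusters["cluster_id"].to_numpy()[cluster_idx][mother_rows],
        "birth_date": birth_date,
        "sex": rng.choice(["male", "female"], nn),
        "birth_order": order,
        "water_source": water[mother_rows],
        "toilet_type": toilet[mother_rows],
        "housing_material": housing[mother_rows],
        "maternal_education": edu[mother_rows],
        "country": clusters["country"].to_numpy()[cluster_idx][mother_rows],
        "survey_id": clusters["survey_id"].to_numpy()[cluster_idx][mother_rows],
        "residence": np.where(clusters["urban"].to_numpy()[cluster_idx][mother_rows],
                              "urban", "rural"),
    })
    first_birth_ts = (start_p.repeat(n) + first_offset).to_timestamp()
    children["maternal_birth_date"] = (
        first_birth_ts[mother_rows]
        - pd.to_timedelta((mother_age_first[mother_rows] * 365.25).astype(int), "D"))
    children["interview_date"] = end

    # per-cluster sorted exposure days, so the hazard multiplier can use the
    # exact lag-0 definition the analysis uses (any exposed day within the
    # 30 days up to the month-m reference date)
    exp_days: dict[str, np.ndarray] = {}
    if tracks is not None and not tracks.empty:
        dense = interpolate_track(tracks, step_minutes=60)
        ev = exposure_events(clusters[["cluster_id", "lat", "lon"]], dense)
        for cid, grp in ev.groupby("cluster_id"):
            exp_days[cid] = np.sort(grp["day"].to_numpy().astype("datetime64[D]"))

    # per-month survival simulation
    if config.baseline_death_prob == 0:
        children["died"] = False
        children["death_age_months"] = np.nan
        return children, clusters

    hazards = _monthly_hazard(np.asarray(config.death_age_distribution),
                              config.baseline_death_prob)
    odds_mult = config.true_or
    bp = birth_period  # PeriodIndex, monthly
    bp_key = bp.year * 12 + bp.month
    end_key = end.year * 12 + end.month
    months_observed = np.clip(end_key - bp_key, 0, 60)

    alive = np.ones(nn, dtype=bool)
    death_age = np.full(nn, -1, dtype=int)
    cids = children["cluster_id"].to_numpy()
    cluster_rows = {cid: np.flatnonzero(cids == cid) for cid in exp_days}
    from .matching import _shift_months
    for m in range(60):
        at_risk = alive & (m < months_observed)
        if not at_risk.any():
            break
        h = np.full(nn, hazards[m])
        if exp_days and odds_mult != 1.0:
            ref = _shift_months(children["birth_date"], m).to_numpy() \
                .astype("datetime64[D]")
            exp_flag = np.zeros(nn, dtype=bool)
            for cid, rows in cluster_rows.items():
                days = exp_days[cid]
                start_d = ref[rows] - np.timedelta64(30, "D")
                i = np.searchsorted(days, start_d, side="left")
                exp_flag[rows] = (i < len(days)) & \
                    (days[np.minimum(i, len(days) - 1)] <= ref[rows])
            o = h / (1.0 - h) * np.where(exp_flag, odds_mult, 1.0)
            h = o / (1.0 + o)
        u = rng.random(nn)
        dies = at_risk & (u < h)
        death_age[dies] = m
        alive &= ~dies
    children["died"] = death_age >= 0
    children["death_age_months"] = np.where(death_age >= 0, death_age, np.nan)
    return children, clusters


# ---------------------------------------------------------------------------
# weather and grid


def generate_weather(clusters: pd.DataFrame, study_window, seed: int,
                     margin_months: int = 6) -> pd.DataFrame:
    """Monthly mean temperature and cumulative precipitation per cluster.

    Temperature is a seasonal sinusoid plus a latitude gradient and noise;
    precipitation is gamma-distributed with a seasonal scale, hence
    non-negative everywhere.  The series extends ``margin_months`` before
    the window start so that 90-day windows of early reference dates are
    covered.
    """
    rng = np.random.default_rng(seed)
    start = pd.Timestamp(study_window[0]).to_period("M") - margin_months
    end = pd.Timestamp(study_window[1]).to_period("M") + 1
    periods = pd.period_range(start, end, freq="M")
    rows = []
    for _, cl in clusters.iterrows():
        phase = 2 * np.pi * (periods.month - 4) / 12.0
        temp = (26.0 - 0.15 * abs(cl["lat"]) + 4.0 * np.sin(phase)
                + rng.normal(0, 1.2, len(periods)))
        scale = 60.0 * (1.0 + 0.8 * np.sin(2 * np.pi * (periods.month - 6) / 12.0)) + 10.0
        precip = rng.gamma(2.0, scale / 2.0, len(periods))
        rows.append(pd.DataFrame({
            "cluster_id": cl["cluster_id"],
            "year": periods.year, "month": periods.month,
            "temp_c": temp, "precip_mm": precip,
        }))
    return pd.concat(rows, ignore_index=True)


def generate_grid(config: SimConfig, years, spacing_km: float = 10.0
                  ) -> pd.DataFrame:
    """Cell centroids at ~``spacing_km`` over the bbox with per-year
    under-five population and mortality rate (rate in [0.02, 0.10], shared
    within country-year as a national approximation)."""
    years = list(years)
    if not years:
        raise ValueError("years must be nonempty")
    rng = _stage_rng(config, 4)
    lat0, lat1, lon0, lon1 = config.bbox
    dlat = spacing_km / KM_PER_DEG_LAT
    midlat = 0.5 * (lat0 + lat1)
    dlon = spacing_km / (KM_PER_DEG_LAT * max(np.cos(np.radians(midlat)), 0.2))
    lats = np.arange(lat0 + dlat / 2, lat1, dlat)
    lons = np.arange(lon0 + dlon / 2, lon1, dlon)
    glon, glat = np.meshgrid(lons, lats)
    glat, glon = glat.ravel(), glon.ravel()
    country = _country_of_lon(glon, config.bbox)
    pop = rng.lognormal(mean=5.5, sigma=1.0, size=len(glat))
    rate = {(c, y): rng.uniform(0.02, 0.10)
            for c in ("C1", "C2", "C3") for y in years}
    frames = []
    for y in years:
        frames.append(pd.DataFrame({
            "cell_id": [f"G{i:06d}" for i in range(len(glat))],
            "lat": glat, "lon": glon, "year": y,
            "pop_u5": np.round(pop * (1.02 ** (y - years[0]))).astype(int),
            "mort_u5": np.array([rate[(c, y)] for c in country]),
            "country": country,
        }))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# direct matched-set simulator (calibration studies)


def simulate_matched_sets(n_sets: int, true_or: float, seed,
                          n_controls_range: tuple[int, int] = (1, 4),
                          exposure_prob: float = 0.25) -> pd.DataFrame:
    """Matched sets drawn directly from the conditional logistic model.

    Each set has one case and 1-4 controls; members receive i.i.d.
    Bernoulli exposure and the case is the member drawn with probability
    proportional to ``true_or ** exposed`` — exactly the conditional
    likelihood the fitter maximizes, so this is the reference generator for
    parameter-recovery and CI-calibration studies.  Only informative sets
    (within-set exposure variation) are kept; exactly ``n_sets`` are
    returned.  Output is analysis-shaped: set_id, role, exposed_lag0.
    """
    rng = np.random.default_rng(seed)
    beta = np.log(true_or)
    lo, hi = n_controls_range
    out_sets = []
    collected = 0
    sid = 0
    while collected < n_sets:
        batch = max(256, int((n_sets - collected) * 2.5))
        sizes = rng.integers(lo + 1, hi + 2, batch)  # members = controls + 1
        total = int(sizes.sum())
        x = (rng.random(total) < exposure_prob).astype(float)
        starts = np.cumsum(sizes) - sizes
        rep = np.repeat(np.arange(batch), sizes)
        # informative iff exposure varies within the set
        s = np.add.reduceat(x, starts)
        informative = (s > 0) & (s < sizes)
        # Gumbel-max draw of the case from the softmax over members
        g = rng.gumbel(size=total)
        score = beta * x + g
        grp_max = np.maximum.reduceat(score, starts)
        is_case = score == grp_max[rep]
        # guard against exact ties (measure zero): keep first max per set
        first = np.zeros(total, dtype=bool)
        idx = np.flatnonzero(is_case)
        _, firstpos = np.unique(rep[idx], return_index=True)
        first[idx[firstpos]] = True
        keep_rows = informative[rep]
        if keep_rows.any():
            k_idx = np.flatnonzero(informative)
            remap = {old: sid + j for j, old in enumerate(k_idx)}
            take = min(len(k_idx), n_sets - collected)
            chosen = set(k_idx[:take])
            sel = np.isin(rep, list(chosen))
            out_sets.append(pd.DataFrame({
                "set_id": [f"S{remap[g]:07d}" for g in rep[sel]],
                "role": np.where(first[sel], "case", "control"),
                "exposed_lag0": x[sel].astype(int),
            }))
            collected += take
            sid += take
    return pd.concat(out_sets, ignore_index=True)


def write_inputs(config: SimConfig, outdir, years=None) -> dict[str, str]:
    """Generate every input table and write the five canonical CSVs."""
    from pathlib import Path
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tracks = generate_tracks(config)
    clusters = generate_clusters(config)
    children, clusters = generate_cohort(config, tracks=tracks, clusters=clusters)
    weather = generate_weather(clusters, config.study_window,
                               seed=int(np.random.SeedSequence(config.seed)
                                        .spawn(8)[3].generate_state(1)[0] % (2**31)))
    if years is None:
        end_year = config.window[1].year
        years = range(end_year - 2, end_year + 1)
    grid = generate_grid(config, years)
    paths = {}
    for name, df in (("children", children), ("clusters", clusters),
                     ("tracks", tracks), ("weather", weather), ("grid", grid)):
        p = outdir / f"{name}.csv"
        df.to_csv(p, index=False, date_format="%Y-%m-%d %H:%M:%S"
                  if name == "tracks" else "%Y-%m-%d")
        paths[name] = str(p)
    return paths
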