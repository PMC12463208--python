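import numpy as np
import pandas as pd
import pytest

import cyclomort as cm

#: Model with only the exposure term — used wherever covariate adjustment
#: is irrelevant to the property under test.
EXPOSURE_ONLY = cm.ModelSpec(adjust_temperature=False,
                             adjust_precipitation=False,
                             adjust_time=False,
                             adjust_maternal_age=False)


@pytest.fixture(scope="session")
def small_sim():
    return cm.SimConfig(n_mothers=800, n_storms=6, seed=11,
                        bbox=(5.0, 15.0, 100.0, 110.0),
                        study_window=("2004-01-01", "2014-12-31"),
                        r34_range_km=(80.0, 250.0))


@pytest.fixture(scope="session")
def small_world(small_sim):
    """Tracks, clusters, children, weather for one small replicate."""
    tracks = cm.generate_tracks(small_sim)
    clusters = cm.generate_clusters(small_sim)
    children, clusters = cm.generate_cohort(small_sim, tracks=tracks,
                                            clusters=clusters)
    weather = cm.generate_weather(clusters, small_sim.study_window, seed=99)
    return {"tracks": tracks, "clusters": clusters, "children": children,
            "weather": weather, "config": small_sim}


@pytest.fixture(scope="session")
def small_analysis(small_world):
    from cyclomort.exposure import build_exposure_profiles
    children, _ = cm.apply_exclusions(small_world["children"],
                                      small_world["clusters"])
    sets, _ = cm.build_matched_sets(children)
    return build_exposure_profiles(sets, small_world["clusters"],
                                   small_world["tracks"],
                                   small_world["weather"])


def random_tracks(rng, n_storms=3, n_fix=8, bbox=(0.0, 10.0, 0.0, 10.0),
                  t0="2010-06-01"):
    """Small random track table for oracle comparisons."""
    rows = []
    lat0, lat1, lon0, lon1 = bbox
    start = pd.Timestamp(t0)
    for s in range(n_storms):
        t = start + pd.Timedelta(hours=int(rng.integers(0, 24 * 60)))
        lat = rng.uniform(lat0, lat1)
        lon = rng.uniform(lon0, lon1)
        for i in range(n_fix):
            rows.append((f"S{s}", t + pd.Timedelta(hours=6 * i),
                         lat + 0.3 * i * rng.uniform(0.5, 1.5),
                         lon + 0.3 * i * rng.uniform(0.5, 1.5),
                         rng.uniform(30, 90), rng.uniform(30, 150)))
    return pd.DataFrame(rows, columns=["storm_id", "time", "lat", "lon",
                                       "wind_kt", "r34_km"])
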