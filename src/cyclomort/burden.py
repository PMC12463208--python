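"""Attributable fraction and gridded excess under-five deaths.

With the fitted odds ratio read as a relative risk RR (defensible because
the outcome is rare), the attributable fraction among the exposed is
AF = (RR - 1) / RR, and excess deaths in grid cell g and year y are

    ED[g, y] = AF * P[g, y] * M[g, y] * C[g, y]

where P is the under-five population, M the under-five mortality rate
(national rate of the cell's country) and C the number of distinct cyclones
whose R34 buffer covered the cell centroid that year.  Uncertainty ranges
substitute the CI bounds of the odds ratio for RR.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exposure import exposure_events, interpolate_track

GRID_COLUMNS = ("cell_id", "lat", "lon", "year", "pop_u5", "mort_u5")


def attributable_fraction(rr: float) -> float:
    """(RR - 1) / RR: share of outcome among the exposed attributable to
    exposure.  Negative for protective RR < 1; rejects RR <= 0."""
    if rr <= 0:
        raise ValueError("relative risk must be positive")
    return (rr - 1.0) / rr


def grid_exposure_counts(grid: pd.DataFrame, tracks: pd.DataFrame,
                         densify: bool = True,
                         step_minutes: int = 60) -> pd.DataFrame:
    """Count distinct storms covering each cell centroid per year.

    The same centroid hit by the same storm at several fixes (even in
    different months) counts once per year; a storm straddling New Year
    counts in each year it covers the cell.  Returns the grid with an
    ``n_exposures`` column (0 where no storm hit).
    """
    cells = grid[["cell_id", "lat", "lon"]].drop_duplicates("cell_id")
    cells = cells.rename(columns={"cell_id": "cluster_id"})
    trk = interpolate_track(tracks, step_minutes=step_minutes) if densify else tracks
    events = exposure_events(cells, trk)
    out = grid.copy()
    if events.empty:
        out["n_exposures"] = 0
        return out
    events = events.rename(columns={"cluster_id": "cell_id"})
    events["year"] = pd.to_datetime(events["day"]).dt.year
    counts = (events.drop_duplicates(["cell_id", "year", "storm_id"])
              .groupby(["cell_id", "year"]).size().rename("n_exposures").reset_index())
    out = out.merge(counts, on=["cell_id", "year"], how="left")
    out["n_exposures"] = out["n_exposures"].fillna(0).astype(int)
    return out


def excess_deaths(grid: pd.DataFrame, rr: float,
                  rr_low: float | None = None, rr_high: float | None = None
                  ) -> tuple[pd.DataFrame, dict]:
    """Per-cell-year excess deaths and totals.

    ``grid`` must carry pop_u5, mort_u5 and n_exposures.  Returns the grid
    with an ``excess_deaths`` column (plus ``excess_deaths_low``/``_high``
    when CI bounds are supplied) and a summary dict with totals overall, by
    year, and by country if a country column is present.
    """
    out = grid.copy()
    base = out["pop_u5"].to_numpy(float) * out["mort_u5"].to_numpy(float) \
        * out["n_exposures"].to_numpy(float)
    out["excess_deaths"] = attributable_fraction(rr) * base
    summary: dict = {
        "rr": rr,
        "attributable_fraction_pct": round(100.0 * attributable_fraction(rr), 2),
        "total_excess_deaths": float(out["excess_deaths"].sum()),
        "by_year": out.groupby("year")["excess_deaths"].sum().to_dict(),
    }
    if "country" in out.columns:
        summary["by_country"] = out.groupby("country")["excess_deaths"].sum().to_dict()
    for tag, r in (("low", rr_low), ("high", rr_high)):
        if r is not None:
            col = f"excess_deaths_{tag}"
            out[col] = attributable_fraction(r) * base
            summary[f"total_excess_deaths_{tag}"] = float(out[col].sum())
    return out, summary
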