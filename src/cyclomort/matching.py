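"""Exclusion criteria and sibling-matched case-control set construction.

Each under-five death defines a matched set: the deceased child is the case
and every sibling (same mother) that was alive when it reached the case's
death age is a control.  The control's reference date is its own birth date
shifted forward by the case's death age in completed months, so exposure is
evaluated for all set members at the same age.  Conditioning on the mother
removes time-invariant household-level confounding.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Columns a child table must carry.
REQUIRED_CHILD_COLUMNS = (
    "child_id", "mother_id", "household_id", "cluster_id", "birth_date",
    "died", "death_age_months",
)


def _shift_months(dates: pd.Series, months: np.ndarray) -> pd.Series:
    """Shift each date forward by a per-row number of calendar months.

    The day-of-month is preserved, clamped to the last day of the target
    month (Jan 31 + 1 month -> Feb 28/29).
    """
    dates = pd.to_datetime(dates)
    periods = dates.dt.to_period("M") + months
    starts = periods.dt.to_timestamp()
    day = np.minimum(dates.dt.day.to_numpy(), periods.dt.days_in_month.to_numpy())
    return starts + pd.to_timedelta(day - 1, unit="D")


def apply_exclusions(children: pd.DataFrame, clusters: pd.DataFrame,
                     exposed_countries: set[str] | None = None,
                     min_households_per_survey: int = 100,
                     earliest_interview_year: int = 1985,
                     ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the study's five exclusion criteria; return survivors and a log.

    1. households lacking coordinates, interview date, or child age;
    2. single-child households;
    3. abnormal records or interview dates before 1985;
    4. countries never matched to any cyclone over the exposure periods
       (skipped when exposed_countries is None);
    5. surveys with fewer than 100 interviewed households.

    Criteria are applied in order; the log counts rows removed at each step.
    """
    df = children.copy()
    df["birth_date"] = pd.to_datetime(df["birth_date"], errors="coerce")
    df["interview_date"] = pd.to_datetime(df.get("interview_date"), errors="coerce")
    log: dict[str, int] = {}

    coords_ok = df["cluster_id"].isin(
        clusters.dropna(subset=["lat", "lon"])["cluster_id"])
    age_known = (~df["died"].astype(bool)) | df["death_age_months"].notna()
    keep = coords_ok & df["interview_date"].notna() & age_known & df["birth_date"].notna()
    log["missing_key_information"] = int((~keep).sum())
    df = df[keep]

    sizes = df.groupby("household_id")["child_id"].transform("size")
    log["single_child_household"] = int((sizes <= 1).sum())
    df = df[sizes > 1]

    abnormal = (df["interview_date"].dt.year < earliest_interview_year)
    if "death_age_months" in df:
        abnormal |= df["died"].astype(bool) & (
            (df["death_age_months"] < 0) | (df["death_age_months"] > 59))
    abnormal |= df["birth_date"] > df["interview_date"]
    log["abnormal_or_pre1985"] = int(abnormal.sum())
    df = df[~abnormal]

    if exposed_countries is not None and "country" in df:
        m = df["country"].isin(exposed_countries)
        log["country_never_exposed"] = int((~m).sum())
        df = df[m]
    else:
        log["country_never_exposed"] = 0

    if "survey_id" in df:
        hh = df.groupby("survey_id")["household_id"].transform("nunique")
        small = hh < min_households_per_survey
        log["small_survey"] = int(small.sum())
        df = df[~small]
    else:
        log["small_survey"] = 0

    log["retained"] = int(len(df))
    return df.reset_index(drop=True), log


def build_matched_sets(children: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Construct one matched set per under-five death.

    Returns a long frame with one row per set member — columns ``set_id``,
    ``role`` ("case"/"control"), ``reference_date``, ``case_death_age`` plus
    all child columns — and a log of sets dropped for lack of controls.

    A sibling is control-eligible iff it is not the case, was already born
    at its reference date (birth_date + case death age, month arithmetic
    with end-of-month clamping), and was alive then: never died, or died at
    an age strictly greater than the case's death age.  A child may serve as
    control in several sets, one per deceased sibling.
    """
    df = children.copy()
    df["birth_date"] = pd.to_datetime(df["birth_date"])
    cases = df[df["died"].astype(bool)]
    if cases["death_age_months"].isna().any():
        bad = cases.loc[cases["death_age_months"].isna(), "child_id"].tolist()
        raise ValueError(f"cases with missing death age: {bad}")

    sib = df.merge(cases[["child_id", "mother_id", "death_age_months"]]
                   .rename(columns={"child_id": "case_id",
                                    "death_age_months": "case_death_age"}),
                   on="mother_id", how="inner")
    sib["case_death_age"] = sib["case_death_age"].astype(int)
    sib["reference_date"] = _shift_months(sib["birth_date"],
                                          sib["case_death_age"].to_numpy())
    is_case = sib["child_id"] == sib["case_id"]
    alive = (~sib["died"].astype(bool)) | (sib["death_age_months"] > sib["case_death_age"])
    # a control must have reached the case's death age by the survey,
    # otherwise its status at the reference date is unobservable
    observable = pd.Series(True, index=sib.index)
    if "interview_date" in sib:
        observable = sib["reference_date"] <= pd.to_datetime(sib["interview_date"])
    eligible = is_case | (alive & observable)
    sib = sib[eligible]
    sib["role"] = np.where(sib["child_id"] == sib["case_id"], "case", "control")

    n_controls = sib[sib["role"] == "control"].groupby("case_id").size()
    with_ctrl = set(n_controls.index)
    n_total = int(cases["child_id"].nunique())
    dropped = n_total - len(with_ctrl)
    sets = sib[sib["case_id"].isin(with_ctrl)].copy()
    sets = sets.rename(columns={"case_id": "set_id"})
    sets = sets.sort_values(["set_id", "role", "child_id"],
                            kind="mergesort").reset_index(drop=True)

    if "maternal_birth_date" in sets:
        mbd = pd.to_datetime(sets["maternal_birth_date"])
        sets["maternal_age"] = (sets["reference_date"] - mbd).dt.days / 365.25

    log = {"cases_total": n_total,
           "sets_built": len(with_ctrl),
           "sets_dropped_no_controls": dropped}
    return sets, log


def summarize(sets: pd.DataFrame) -> dict:
    """Descriptive summary of matched sets in the usual Table-1 layout.

    Returns counts of cases and controls, mean controls per case, the
    death-age bin distribution of cases, and per-covariate level counts for
    cases and controls.
    """
    cases = sets[sets["role"] == "case"]
    controls = sets[sets["role"] == "control"]
    n_cases, n_controls = len(cases), len(controls)
    out: dict = {
        "n_cases": n_cases,
        "n_controls": n_controls,
        "controls_per_case": round(n_controls / n_cases, 1) if n_cases else float("nan"),
    }
    bins = [0, 12, 24, 36, 48, 60]
    labels = ["0-11", "12-23", "24-35", "36-47", "48-59"]
    ages = pd.cut(cases["death_age_months"], bins=bins, labels=labels, right=False)
    counts = ages.value_counts().reindex(labels).fillna(0).astype(int)
    out["death_age_bins"] = {
        lab: {"n": int(c), "pct": round(100.0 * c / n_cases, 2) if n_cases else 0.0}
        for lab, c in counts.items()
    }
    for cov in ("residence", "sex", "maternal_education", "water_source",
                "toilet_type", "housing_material"):
        if cov in sets.columns:
            out[cov] = {
                "cases": cases[cov].value_counts().to_dict(),
                "controls": controls[cov].value_counts().to_dict(),
            }
    return out
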