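"""Flowering-phenology isolation from repeated presence/absence surveys.

A survey records, at each census date, whether each monitored tree was in
flower.  Censuses are aggregated to periods (calendar months by default,
matching the temporal index of the RI4S2 formula; the raw census cadence is
also available), a tree counting as flowering in a period if it was flagged
in at least one census of that period.  The directional phenological RI is
then RI4S2 on the aggregated series: because the index weights transfer
probabilities by flowering abundance, the two directions generally differ,
and the rarer population can score negative (gene flow into it enhanced by
the commoner population's abundance).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .ri_core import FloweringSeries, ri_temporal

__all__ = ["read_survey", "aggregate_survey", "ri_phenology", "series_to_frame"]

_REQUIRED = ("date", "tree_id", "population", "flowering")


def read_survey(path: str | Path) -> pd.DataFrame:
    """Read a flowering-survey CSV (date, tree_id, population, flowering 0/1)."""
    df = pd.read_csv(path, parse_dates=["date"])
    return validate_survey(df)


def validate_survey(survey: pd.DataFrame) -> pd.DataFrame:
    missing = set(_REQUIRED) - set(survey.columns)
    if missing:
        raise ValueError(f"survey lacks columns {sorted(missing)}")
    if survey.empty:
        raise ValueError("survey is empty")
    if survey.duplicated(["date", "tree_id"]).any():
        raise ValueError("duplicate (date, tree_id) census records")
    pops = survey["population"].unique()
    if len(pops) != 2:
        raise ValueError(f"survey must contain exactly two populations, found {list(pops)}")
    flw = survey["flowering"]
    if not flw.isin([0, 1, True, False]).all():
        raise ValueError("flowering column must be 0/1")
    return survey


def aggregate_survey(
    survey: pd.DataFrame,
    focal: str,
    period: str = "month",
) -> FloweringSeries:
    """Aggregate censuses into a FloweringSeries from the focal population's view.

    Per period, A_i counts the distinct focal trees flowering in at least one
    census of the period; the census totals are the numbers of distinct trees
    ever surveyed per population.  Trees without a record in a period are
    treated as not flowering.
    """
    survey = validate_survey(survey)
    pops = list(survey["population"].unique())
    if focal not in pops:
        raise ValueError(f"unknown population label {focal!r}; survey has {pops}")
    other = pops[0] if pops[1] == focal else pops[1]

    df = survey.copy()
    dates = pd.to_datetime(df["date"])
    if period == "month":
        df["period"] = dates.dt.to_period("M").astype(str)
    elif period == "census":
        df["period"] = dates.dt.strftime("%Y-%m-%d")
    else:
        raise ValueError("period must be 'month' or 'census'")

    totals = df.groupby("population")["tree_id"].nunique()
    flowering = df[df["flowering"].astype(bool)]
    counts = (
        flowering.groupby(["period", "population"])["tree_id"].nunique().unstack(fill_value=0)
    )
    periods = sorted(df["period"].unique())
    counts = counts.reindex(index=periods, columns=pops, fill_value=0).fillna(0).astype(int)
    return FloweringSeries(
        periods=tuple(periods),
        A=tuple(counts[focal]),
        B=tuple(counts[other]),
        A_total=int(totals[focal]),
        B_total=int(totals[other]),
    )


def ri_phenology(survey: pd.DataFrame, period: str = "month") -> dict[str, float]:
    """Directional phenological RI4S2 for both populations of a survey."""
    pops = list(validate_survey(survey)["population"].unique())
    return {pop: ri_temporal(aggregate_survey(survey, focal=pop, period=period)) for pop in pops}


def series_to_frame(series: FloweringSeries, focal: str = "A", other: str = "B") -> pd.DataFrame:
    """Flowering series as a tidy per-period table (export helper)."""
    return pd.DataFrame(
        {
            "period": series.periods,
            f"n_flowering_{focal}": series.A,
            f"n_flowering_{other}": series.B,
            f"prop_flowering_{focal}": [a / series.A_total for a in series.A],
            f"prop_flowering_{other}": [b / series.B_total for b in series.B],
        }
    )
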