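"""Per-period explanatory variables.

Three covariates drive the temporal analysis: the proportion of migratory
bird species in each period's network, the richness of fruiting plant
species, and period-level fruit abundance summarized from the ordinal ripe
fruit abundance index (FAI). FAI scores each fruiting plant individual into
five categories: 1 = 1-10 fruits, 2 = 11-100, 3 = 101-1,000,
4 = 1,001-10,000, 5 = more than 10,000.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

from .errors import InvalidDataError, UndefinedMetricError
from .io_model import InteractionMatrix, TemporalNetworkSeries, TraitTable

FAI_COLUMNS = ["period", "plant_id", "individual_id", "fai_category"]


@dataclass(frozen=True)
class FAIRecord:
    period_label: str
    plant_id: str
    individual_id: str
    fai_category: int

    def __post_init__(self):
        if self.fai_category not in (1, 2, 3, 4, 5):
            raise InvalidDataError(
                f"fai_category must be in 1..5, got {self.fai_category}"
            )


def fai_frame(records: Iterable[FAIRecord] | pd.DataFrame) -> pd.DataFrame:
    """Normalize a FAI record collection into the canonical DataFrame."""
    if isinstance(records, pd.DataFrame):
        missing = [c for c in FAI_COLUMNS if c not in records.columns]
        if missing:
            raise InvalidDataError(f"FAI table missing columns {missing}")
        df = records[FAI_COLUMNS].copy()
    else:
        df = pd.DataFrame(
            [
                (r.period_label, r.plant_id, r.individual_id, r.fai_category)
                for r in records
            ],
            columns=FAI_COLUMNS,
        )
    bad = ~df["fai_category"].isin([1, 2, 3, 4, 5])
    if bad.any():
        raise InvalidDataError(
            f"fai_category outside 1..5 at rows {list(df.index[bad])[:5]}"
        )
    return df


def read_fai(path: str | Path) -> pd.DataFrame:
    return fai_frame(pd.read_csv(path, dtype={"period": str, "plant_id": str, "individual_id": str}))


def proportion_migratory(matrix: InteractionMatrix, traits: TraitTable) -> float:
    """Share of a period's bird species classified as migratory.

    Stopover species and winter residents both count as migratory; the
    denominator is every bird species in the period's network, so plant
    composition cannot affect the value.
    """
    n_mig = sum(traits.is_migratory(b) for b in matrix.birds)
    return n_mig / matrix.n_birds


def fruit_richness(records, period: str) -> int:
    """Number of distinct plant species bearing ripe fruit in the period."""
    df = fai_frame(records)
    return int(df.loc[df["period"] == period, "plant_id"].nunique())


def species_mean_fai(records, plant_id: str, period: str) -> float:
    """Mean FAI category over one species' fruiting individuals in a period."""
    df = fai_frame(records)
    sub = df[(df["period"] == period) & (df["plant_id"] == plant_id)]
    if sub.empty:
        raise UndefinedMetricError(
            f"no FAI records for {plant_id!r} in period {period!r}"
        )
    return float(sub["fai_category"].mean())


def period_fruit_abundance(records, period: str, *, aggregate: str = "mean") -> float:
    """Period-level fruit abundance from species-mean FAI values.

    The default is the unweighted mean over fruiting species, keeping the
    value on the bounded 1-5 FAI scale; ``aggregate="sum"`` accumulates
    instead. An empty period has abundance 0.
    """
    df = fai_frame(records)
    sub = df[df["period"] == period]
    if sub.empty:
        return 0.0
    per_species = sub.groupby("plant_id")["fai_category"].mean()
    if aggregate == "mean":
        return float(per_species.mean())
    if aggregate == "sum":
        return float(per_species.sum())
    raise InvalidDataError(f"unknown aggregate {aggregate!r}")


def covariate_table(
    series: TemporalNetworkSeries,
    records,
    *,
    abundance_aggregate: str = "mean",
) -> pd.DataFrame:
    """Assemble the per-period covariate table.

    Columns: ``period, prop_migratory, fruit_richness, fruit_abundance``,
    one row per period in series order.
    """
    df = fai_frame(records)
    rows = []
    for m in series.matrices:
        rows.append(
            {
                "period": m.period_label,
                "prop_migratory": proportion_migratory(m, series.traits),
                "fruit_richness": fruit_richness(df, m.period_label),
                "fruit_abundance": period_fruit_abundance(
                    df, m.period_label, aggregate=abundance_aggregate
                ),
            }
        )
    return pd.DataFrame(rows, columns=["period", "prop_migratory", "fruit_richness", "fruit_abundance"])
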