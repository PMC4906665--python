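"""Core data structures for temporal quantitative bipartite networks.

A study is described by three tables: a trait table (one row per species,
plants and birds), one quantitative interaction matrix per sampling period
(rows = plants, columns = birds, cells = estimated number of fruits eaten),
and the ordered collection of those matrices. Interaction intensity is
assembled from two field sources: direct fruit counts from focal
observations, and fruit numbers extrapolated from seed counts in fecal
samples (seeds divided by the species' mean seeds-per-fruit).

The canonical interchange format is a long edge list CSV with columns
``period,plant,bird,intensity``; a wide per-period CSV dialect (plants as
rows, birds as columns) is also supported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    EmptyNetworkError,
    InvalidDataError,
    InvalidParameterError,
    ParseError,
    SpeciesLookupError,
)

LEVELS = ("plant", "bird")
MIGRATORY_STATUSES = ("resident", "migratory", "not_applicable")


@dataclass(frozen=True)
class SpeciesRecord:
    """One species of either trophic level.

    ``migratory_status`` is ``not_applicable`` exactly for plants;
    ``seeds_per_fruit`` (mean seed count per fruit) is defined exactly for
    plants. Both stopover species and winter residents count as migratory.
    """

    species_id: str
    name: str
    level: str
    migratory_status: str = "not_applicable"
    seeds_per_fruit: float | None = None

    def __post_init__(self):
        if self.level not in LEVELS:
            raise InvalidDataError(f"level must be one of {LEVELS}, got {self.level!r}")
        if self.migratory_status not in MIGRATORY_STATUSES:
            raise InvalidDataError(
                f"migratory_status must be one of {MIGRATORY_STATUSES}, "
                f"got {self.migratory_status!r}"
            )
        if (self.level == "plant") != (self.migratory_status == "not_applicable"):
            raise InvalidDataError(
                f"species {self.species_id!r}: migratory_status "
                f"{self.migratory_status!r} inconsistent with level {self.level!r}"
            )
        if (self.level == "plant") != (self.seeds_per_fruit is not None):
            raise InvalidDataError(
                f"species {self.species_id!r}: seeds_per_fruit must be given "
                "for plants and only for plants"
            )
        if self.seeds_per_fruit is not None and not self.seeds_per_fruit > 0:
            raise InvalidDataError(
                f"species {self.species_id!r}: seeds_per_fruit must be positive"
            )


class TraitTable:
    """Mapping from species_id to :class:`SpeciesRecord` with CSV round-trip."""

    def __init__(self, records: Iterable[SpeciesRecord]):
        self._records: dict[str, SpeciesRecord] = {}
        for rec in records:
            if rec.species_id in self._records:
                raise InvalidDataError(f"duplicate species_id {rec.species_id!r}")
            self._records[rec.species_id] = rec

    def __getitem__(self, species_id: str) -> SpeciesRecord:
        try:
            return self._records[species_id]
        except KeyError:
            raise SpeciesLookupError(species_id) from None

    def __contains__(self, species_id: str) -> bool:
        return species_id in self._records

    def __iter__(self):
        return iter(self._records.values())

    def __len__(self):
        return len(self._records)

    def is_migratory(self, species_id: str) -> bool:
        rec = self[species_id]
        if rec.level != "bird":
            raise InvalidDataError(f"{species_id!r} is not a bird")
        return rec.migratory_status == "migratory"

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "species_id": r.species_id,
                "name": r.name,
                "level": r.level,
                "migratory_status": r.migratory_status,
                "seeds_per_fruit": r.seeds_per_fruit,
            }
            for r in sorted(self._records.values(), key=lambda r: r.species_id)
        ]
        return pd.DataFrame(
            rows,
            columns=["species_id", "name", "level", "migratory_status", "seeds_per_fruit"],
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "TraitTable":
        df = pd.read_csv(path, dtype={"species_id": str, "name": str})
        records = []
        for _, row in df.iterrows():
            spf = row.get("seeds_per_fruit")
            spf = None if (spf is None or (isinstance(spf, float) and math.isnan(spf))) else float(spf)
            records.append(
                SpeciesRecord(
                    species_id=str(row["species_id"]),
                    name=str(row["name"]),
                    level=str(row["level"]),
                    migratory_status=str(row["migratory_status"]),
                    seeds_per_fruit=spf,
                )
            )
        return cls(records)


@dataclass
class InteractionMatrix:
    """One sampling period's quantitative plant x bird matrix.

    ``weights[i, j]`` is the estimated number of fruits of plant
    ``plants[i]`` eaten by bird ``birds[j]`` during the period. Every row
    and column must carry at least one positive entry: a species belongs to
    a period's network only if it interacted in that period.
    """

    period_label: str
    plants: list[str]
    birds: list[str]
    weights: np.ndarray

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (len(self.plants), len(self.birds)):
            raise InvalidDataError(
                f"period {self.period_label!r}: weights shape {self.weights.shape} "
                f"does not match {len(self.plants)} plants x {len(self.birds)} birds"
            )
        if self.weights.size == 0:
            raise EmptyNetworkError(f"period {self.period_label!r}: empty matrix")
        if not np.all(np.isfinite(self.weights)):
            raise InvalidDataError(f"period {self.period_label!r}: non-finite weight")
        if np.any(self.weights < 0):
            raise InvalidDataError(f"period {self.period_label!r}: negative weight")
        if np.any(self.weights.sum(axis=1) == 0) or np.any(self.weights.sum(axis=0) == 0):
            raise InvalidDataError(
                f"period {self.period_label!r}: matrix has an all-zero row or "
                "column; species without interactions do not belong to the network"
            )
        if len(set(self.plants)) != len(self.plants) or len(set(self.birds)) != len(self.birds):
            raise InvalidDataError(f"period {self.period_label!r}: duplicate species id")

    @property
    def n_plants(self) -> int:
        return len(self.plants)

    @property
    def n_birds(self) -> int:
        return len(self.birds)

    @property
    def binary(self) -> np.ndarray:
        return (self.weights > 0).astype(float)

    def n_links(self) -> int:
        return int((self.weights > 0).sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.weights, index=self.plants, columns=self.birds)

    def cells(self) -> dict[tuple[str, str], float]:
        """Positive cells as a ``{(plant, bird): weight}`` mapping."""
        pi, bi = np.nonzero(self.weights)
        return {
            (self.plants[i], self.birds[j]): float(self.weights[i, j])
            for i, j in zip(pi, bi)
        }

    def sorted_copy(self) -> "InteractionMatrix":
        """Copy with species in lexicographic order (the on-disk order)."""
        pi = np.argsort(self.plants)
        bi = np.argsort(self.birds)
        return InteractionMatrix(
            period_label=self.period_label,
            plants=[self.plants[i] for i in pi],
            birds=[self.birds[j] for j in bi],
            weights=self.weights[np.ix_(pi, bi)],
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, InteractionMatrix):
            return NotImplemented
        return (
            self.period_label == other.period_label
            and set(self.plants) == set(other.plants)
            and set(self.birds) == set(other.birds)
            and self.cells() == other.cells()
        )


@dataclass
class TemporalNetworkSeries:
    """Ordered collection of per-period matrices plus the trait table."""

    matrices: list[InteractionMatrix]
    traits: TraitTable = field(default_factory=lambda: TraitTable([]))

    def __post_init__(self):
        labels = [m.period_label for m in self.matrices]
        if len(set(labels)) != len(labels):
            raise InvalidDataError(f"duplicate period labels in {labels}")
        if len(self.traits):
            for m in self.matrices:
                for sid in list(m.plants) + list(m.birds):
                    if sid not in self.traits:
                        raise SpeciesLookupError(sid, f"period {m.period_label}")

    @property
    def period_labels(self) -> list[str]:
        return [m.period_label for m in self.matrices]

    def __len__(self):
        return len(self.matrices)

    def __iter__(self):
        return iter(self.matrices)

    def __getitem__(self, period_label: str) -> InteractionMatrix:
        for m in self.matrices:
            if m.period_label == period_label:
                return m
        raise KeyError(period_label)

    def union_species(self) -> tuple[set[str], set[str]]:
        """(plants, birds) observed interacting in at least one period."""
        plants: set[str] = set()
        birds: set[str] = set()
        for m in self.matrices:
            plants.update(m.plants)
            birds.update(m.birds)
        return plants, birds

    def union_links(self) -> set[tuple[str, str]]:
        """Distinct realized (plant, bird) links across all periods."""
        links: set[tuple[str, str]] = set()
        for m in self.matrices:
            links.update(m.cells().keys())
        return links


# ---------------------------------------------------------------------------
# Fruit-count estimation and source merging


def estimate_fruits_from_seeds(
    seed_count: int | float,
    seeds_per_fruit: float,
    *,
    floor_minimum: float | None = 1.0,
) -> float:
    """Estimated number of fruits eaten, from seeds found in a defecation.

    The raw estimate is ``seed_count / seeds_per_fruit``. Whenever any seeds
    were found, the estimate is floored at ``floor_minimum`` (default 1):
    a defecation containing seeds evidences at least one fruit eaten. Pass
    ``floor_minimum=None`` to keep the raw quotient.
    """
    if not seeds_per_fruit > 0:
        raise InvalidParameterError(f"seeds_per_fruit must be positive, got {seeds_per_fruit}")
    if seed_count < 0:
        raise InvalidDataError(f"seed_count must be non-negative, got {seed_count}")
    if seed_count == 0:
        return 0.0
    est = seed_count / seeds_per_fruit
    if floor_minimum is not None:
        est = max(est, float(floor_minimum))
    return float(est)


def merge_observation_sources(
    focal_counts: Mapping[tuple[str, str], float],
    fecal_estimates: Mapping[tuple[str, str], float],
    *,
    period_label: str = "",
    on_empty: str = "raise",
) -> InteractionMatrix:
    """Combine focal-observation fruit counts with fecal-sample estimates.

    Cells are summed; species whose row or column ends up all-zero are
    dropped so the result satisfies the matrix invariants. ``on_empty``
    selects the degenerate-input behavior: ``"raise"`` (default) or
    ``"empty"`` which returns ``None`` for a linkless merge.
    """
    total: dict[tuple[str, str], float] = {}
    for source_name, source in (("focal", focal_counts), ("fecal", fecal_estimates)):
        for key, v in source.items():
            if v < 0:
                raise InvalidDataError(f"negative {source_name} cell at {key}: {v}")
            total[key] = total.get(key, 0.0) + float(v)
    total = {k: v for k, v in total.items() if v > 0}
    if not total:
        if on_empty == "empty":
            return None
        raise EmptyNetworkError(
            f"period {period_label!r}: no positive cells after merging sources"
        )
    plants = sorted({p for p, _ in total})
    birds = sorted({b for _, b in total})
    weights = np.zeros((len(plants), len(birds)))
    p_idx = {p: i for i, p in enumerate(plants)}
    b_idx = {b: j for j, b in enumerate(birds)}
    for (p, b), v in total.items():
        weights[p_idx[p], b_idx[b]] = v
    return InteractionMatrix(period_label, plants, birds, weights)


# ---------------------------------------------------------------------------
# Readers / writers

LONG_COLUMNS = ["period", "plant", "bird", "intensity"]


def _matrix_from_long(period: str, chunk: pd.DataFrame) -> InteractionMatrix:
    agg = chunk.groupby(["plant", "bird"], sort=True)["intensity"].sum()
    cells = {(p, b): float(v) for (p, b), v in agg.items()}
    return merge_observation_sources(cells, {}, period_label=period)


def write_series(
    series: TemporalNetworkSeries, path: str | Path, format: str = "long"
) -> None:
    """Serialize a series; ``long`` writes one CSV file, ``wide`` one CSV
    per period under a directory. Species are ordered lexicographically so
    output is byte-stable."""
    path = Path(path)
    if format == "long":
        rows = []
        for m in series.matrices:
            cells = m.cells()
            for (p, b) in sorted(cells):
                rows.append((m.period_label, p, b, cells[(p, b)]))
        df = pd.DataFrame(rows, columns=LONG_COLUMNS)
        df.to_csv(path, index=False)
    elif format == "wide":
        path.mkdir(parents=True, exist_ok=True)
        for m in series.matrices:
            sm = m.sorted_copy()
            df = sm.to_frame()
            df.index.name = "plant"
            df.to_csv(path / f"{m.period_label}.csv")
        order = pd.DataFrame({"period": series.period_labels})
        order.to_csv(path / "periods.csv", index=False)
    else:
        raise InvalidParameterError(f"unknown format {format!r}")


def read_series(
    path: str | Path,
    format: str = "long",
    traits: TraitTable | None = None,
) -> TemporalNetworkSeries:
    """Read a series written by :func:`write_series`.

    Duplicate ``(period, plant, bird)`` rows in long format are summed.
    If ``traits`` is given, every species id is cross-checked against it.
    """
    path = Path(path)
    matrices: list[InteractionMatrix] = []
    if format == "long":
        df = pd.read_csv(path, dtype={"period": str, "plant": str, "bird": str})
        missing = [c for c in LONG_COLUMNS if c not in df.columns]
        if missing:
            raise ParseError(f"{path}: missing columns {missing}")
        bad = pd.to_numeric(df["intensity"], errors="coerce")
        if bad.isna().any():
            row = int(bad.isna().idxmax()) + 2  # header + 1-based
            raise ParseError(f"{path}: non-numeric intensity at line {row}")
        df["intensity"] = bad
        for period in df["period"].drop_duplicates():
            matrices.append(_matrix_from_long(period, df[df["period"] == period]))
    elif format == "wide":
        order_file = path / "periods.csv"
        if order_file.exists():
            periods = pd.read_csv(order_file, dtype=str)["period"].tolist()
        else:
            periods = sorted(p.stem for p in path.glob("*.csv") if p.name != "periods.csv")
        for period in periods:
            f = path / f"{period}.csv"
            df = pd.read_csv(f, index_col=0)
            try:
                weights = df.to_numpy(dtype=float)
            except ValueError as e:
                raise ParseError(f"{f}: non-numeric cell ({e})") from None
            matrices.append(
                InteractionMatrix(
                    period_label=period,
                    plants=[str(x) for x in df.index],
                    birds=[str(x) for x in df.columns],
                    weights=weights,
                )
            )
    else:
        raise InvalidParameterError(f"unknown format {format!r}")
    return TemporalNetworkSeries(matrices=matrices, traits=traits or TraitTable([]))
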