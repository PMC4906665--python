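"""Species turnover of the network core and periphery between migration
regimes.

Periods are grouped a priori into high- and low-migration sets; the bird
species composition of the generalist core (and separately the periphery)
is compared between groups with PERMANOVA on Bray-Curtis dissimilarities.
Core and periphery membership is per period, so a species may appear in
both composition matrices on different rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidDataError, UndefinedMetricError
from .io_model import TemporalNetworkSeries
from .metrics import CorePeripheryResult, core_periphery

# The study's a-priori grouping of sampling periods by migrant proportion.
HIGH_MIGRATION_PERIODS = ("Jan14", "Mar14", "Sep14", "Oct14")
LOW_MIGRATION_PERIODS = ("Nov13", "May14", "Jun14", "Jul14", "Aug14", "Nov14")


def default_grouping(period_labels) -> dict[str, str]:
    """Map each period label to "high" or "low" migration, per the study design."""
    groups = {}
    for p in period_labels:
        if p in HIGH_MIGRATION_PERIODS:
            groups[p] = "high"
        elif p in LOW_MIGRATION_PERIODS:
            groups[p] = "low"
        else:
            raise InvalidDataError(f"period {p!r} has no default migration group")
    return groups


@dataclass
class CompositionMatrix:
    """Periods x species membership matrix for one stratum (core/periphery)."""

    periods: list[str]
    species: list[str]
    presence: np.ndarray  # periods x species, binary or abundance
    stratum: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.presence, index=self.periods, columns=self.species)


def composition_matrix(
    series: TemporalNetworkSeries,
    classifier_results: list[CorePeripheryResult] | None = None,
    stratum: str = "core",
    *,
    quantitative: bool = False,
) -> CompositionMatrix:
    """Binary membership of bird species in the stratum, per period.

    Columns are the union, in lexicographic order, of species ever
    classified into the stratum. ``quantitative=True`` replaces membership
    by the species' number of plant partners in that period.
    """
    if stratum not in ("core", "periphery"):
        raise InvalidDataError(f"stratum must be 'core' or 'periphery', got {stratum!r}")
    if classifier_results is None:
        classifier_results = [core_periphery(m) for m in series.matrices]
    members_per_period: list[set[str]] = []
    for res in classifier_results:
        members = res.core_species() if stratum == "core" else res.periphery_species()
        if not members:
            warnings.warn(
                f"period {res.period_label!r} has no {stratum} species; "
                "all-zero row retained"
            )
        members_per_period.append(members)
    species = sorted(set().union(*members_per_period)) if members_per_period else []
    presence = np.zeros((len(classifier_results), len(species)))
    sp_idx = {s: j for j, s in enumerate(species)}
    for i, (res, members) in enumerate(zip(classifier_results, members_per_period)):
        degs = dict(zip(res.birds, res.degrees))
        for s in members:
            presence[i, sp_idx[s]] = degs[s] if quantitative else 1.0
    return CompositionMatrix(
        periods=[r.period_label for r in classifier_results],
        species=species,
        presence=presence,
        stratum=stratum,
    )


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity 1 - 2*sum(min)/(sum(x)+sum(y)), in [0, 1].

    On binary vectors this reduces to the Sorensen dissimilarity.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InvalidDataError("vectors must have equal length")
    if np.any(x < 0) or np.any(y < 0):
        raise InvalidDataError("abundances must be non-negative")
    tot = x.sum() + y.sum()
    if tot == 0:
        raise UndefinedMetricError("Bray-Curtis undefined for two all-zero vectors")
    return float(1.0 - 2.0 * np.minimum(x, y).sum() / tot)


def dissimilarity_matrix(comp: CompositionMatrix) -> pd.DataFrame:
    """Square Bray-Curtis matrix over the composition rows.

    Pairs involving an all-zero row are undefined and stored as NaN
    (PERMANOVA refuses such matrices).
    """
    n = len(comp.periods)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                D[i, j] = D[j, i] = bray_curtis(comp.presence[i], comp.presence[j])
            except UndefinedMetricError:
                D[i, j] = D[j, i] = np.nan
    return pd.DataFrame(D, index=comp.periods, columns=comp.periods)


@dataclass
class PermanovaResult:
    stratum: str
    pseudo_f: float
    p_value: float
    r_squared: float
    df_among: int
    df_within: int
    permutations: int
    seed: int


def _pseudo_f(d2: np.ndarray, labels: np.ndarray, uniq: np.ndarray) -> tuple[float, float, float]:
    """(F, SS_among, SS_total) from squared distances and group labels."""
    n = len(labels)
    iu = np.triu_indices(n, k=1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g in uniq:
        idx = np.where(labels == g)[0]
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    ss_among = ss_total - ss_within
    df_among = len(uniq) - 1
    df_within = n - len(uniq)
    if ss_within <= 0:
        return float("inf") if ss_among > 0 else float("nan"), ss_among, ss_total
    f = (ss_among / df_among) / (ss_within / df_within)
    return f, ss_among, ss_total


def permanova(
    dissimilarity: pd.DataFrame | np.ndarray,
    groups,
    permutations: int = 999,
    seed: int = 0,
    *,
    stratum: str = "",
) -> PermanovaResult:
    """One-factor PERMANOVA on a dissimilarity matrix.

    The total sum of squares is partitioned into among- and within-group
    parts from squared inter-point dissimilarities; significance comes from
    random relabelings, with the add-one estimator
    ``p = (1 + #{F_perm >= F_obs}) / (1 + permutations)``.
    """
    D = np.asarray(dissimilarity, dtype=float)
    labels = np.asarray(list(groups))
    n = D.shape[0]
    if D.shape != (n, n) or labels.shape[0] != n:
        raise InvalidDataError("dissimilarity must be square and match the labels")
    if np.any(np.isnan(D)):
        raise InvalidDataError("dissimilarity contains undefined (NaN) entries")
    if np.any(D < 0):
        raise InvalidDataError("negative dissimilarities")
    if not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0):
        raise InvalidDataError("dissimilarity must be symmetric with zero diagonal")
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise UndefinedMetricError("PERMANOVA needs at least two groups")
    d2 = D**2
    f_obs, ss_among, ss_total = _pseudo_f(d2, labels, uniq)
    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(permutations):
        perm = rng.permutation(n)
        f_perm, _, _ = _pseudo_f(d2, labels[perm], uniq)
        if f_perm >= f_obs - 1e-12:
            n_ge += 1
    p = (1 + n_ge) / (1 + permutations)
    return PermanovaResult(
        stratum=stratum,
        pseudo_f=float(f_obs),
        p_value=float(p),
        r_squared=float(ss_among / ss_total) if ss_total > 0 else float("nan"),
        df_among=len(uniq) - 1,
        df_within=n - len(uniq),
        permutations=permutations,
        seed=seed,
    )


def turnover_analysis(
    series: TemporalNetworkSeries,
    grouping: dict[str, str] | None = None,
    permutations: int = 999,
    seed: int = 0,
    *,
    quantitative: bool = False,
) -> pd.DataFrame:
    """Full turnover test: core and periphery PERMANOVA reports.

    Returns one row per stratum with columns
    ``stratum,pseudo_f,r2,df_among,df_within,p,permutations,seed``.
    """
    if grouping is None:
        grouping = default_grouping(series.period_labels)
    cp = [core_periphery(m) for m in series.matrices]
    rows = []
    for stratum in ("core", "periphery"):
        comp = composition_matrix(series, cp, stratum, quantitative=quantitative)
        D = dissimilarity_matrix(comp)
        labels = [grouping[p] for p in comp.periods]
        res = permanova(D, labels, permutations=permutations, seed=seed, stratum=stratum)
        rows.append(
            {
                "stratum": stratum,
                "pseudo_f": res.pseudo_f,
                "r2": res.r_squared,
                "df_among": res.df_among,
                "df_within": res.df_within,
                "p": res.p_value,
                "permutations": permutations,
                "seed": seed,
            }
        )
    return pd.DataFrame(rows)
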