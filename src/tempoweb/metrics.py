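"""Network-level parameters of a quantitative bipartite matrix.

Six parameters characterize each period's plant-frugivore network:

* **network size** — number of plant plus bird species;
* **connectance** — realized fraction of possible links;
* **nestedness (NODF)** — paired overlap over decreasing-fill row and
  column pairs, 0 (no nesting) to 100 (perfectly nested);
* **specialization (H2')** — interaction-frequency entropy rescaled
  between its marginal-constrained extremes, 0 (no specialization) to 1;
* **interaction strength asymmetry (ISA)** — signed mean over realized
  links of the normalized difference between the bird's dependence on the
  plant and the plant's dependence on the bird; positive values mean birds
  depend more on plants than vice versa;
* **niche overlap** — Horn's entropy-based similarity of interaction
  profiles, averaged over species pairs at one level (birds by default).

A seventh analysis classifies each bird species into the generalist core
or the periphery by its standardized degree
``Gc = (k_i - k_mean) / sigma_k``: species more than one standard
deviation above the mean partner count form the core.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import UndefinedMetricError
from .io_model import InteractionMatrix, TemporalNetworkSeries

METRIC_COLUMNS = ["period", "size", "connectance", "nodf", "h2", "isa", "niche_overlap"]


def network_size(matrix: InteractionMatrix) -> int:
    return matrix.n_plants + matrix.n_birds


def connectance(matrix: InteractionMatrix) -> float:
    return float((matrix.weights > 0).sum() / matrix.weights.size)


def _nodf_pairs(B: np.ndarray) -> float:
    """Sum of paired-overlap terms over ordered row pairs of a 0/1 array.

    For rows i, j with marginal totals MT_i > MT_j > 0 the term is
    (shared presences)/MT_j; equal or increasing fills contribute zero.
    """
    mt = B.sum(axis=1)
    shared = B @ B.T
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(mt[None, :] > 0, shared / np.where(mt[None, :] > 0, mt[None, :], 1.0), 0.0)
    decreasing = mt[:, None] > mt[None, :]
    return float(frac[decreasing].sum())


def nodf(matrix: InteractionMatrix | np.ndarray) -> float:
    """NODF nestedness of the binarized matrix, in [0, 100].

    Matrices generated by probabilistic null models may contain empty rows
    or columns; those simply contribute zero overlap, and the score is
    still taken over the full dimensions.
    """
    B = matrix.binary if isinstance(matrix, InteractionMatrix) else (np.asarray(matrix) > 0).astype(float)
    P, A = B.shape
    n_pairs = P * (P - 1) / 2 + A * (A - 1) / 2
    if n_pairs == 0:
        raise UndefinedMetricError("NODF needs at least two rows or two columns")
    return 100.0 * (_nodf_pairs(B) + _nodf_pairs(B.T)) / n_pairs


def _entropy(masses: np.ndarray, total: float) -> float:
    """Shannon entropy of masses/total with the 0*ln0 = 0 convention."""
    p = np.asarray(masses, dtype=float) / total
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def _h2min_packing(row_totals: np.ndarray, col_totals: np.ndarray) -> list[float]:
    """Cell masses of the maximally aggregated table.

    Greedy packing: repeatedly place min(remaining row total, remaining
    column total) into the cell of the currently largest remaining row and
    column totals; ties broken by lowest index.
    """
    r = row_totals.astype(float).copy()
    c = col_totals.astype(float).copy()
    masses = []
    while r.max() > 1e-12 and c.max() > 1e-12:
        i = int(np.argmax(r))
        j = int(np.argmax(c))
        m = min(r[i], c[j])
        masses.append(m)
        r[i] -= m
        c[j] -= m
    return masses


def specialization_h2(matrix: InteractionMatrix) -> float:
    """Network-level specialization H2' in [0, 1].

    H2 is the Shannon entropy of the relative interaction frequencies
    p_ij = w_ij/m. It is rescaled between H2max — the entropy of the
    marginal-product expectation e_ij = r_i c_j / m, attained when species
    interact in proportion to their totals — and H2min, the entropy of the
    maximally aggregated table with the same marginals.
    """
    w = matrix.weights
    m = w.sum()
    if m <= 0:
        raise UndefinedMetricError("H2' undefined for zero total interaction weight")
    r = w.sum(axis=1)
    c = w.sum(axis=0)
    h2 = _entropy(w.ravel(), m)
    h2max = _entropy(np.outer(r, c).ravel(), m * m)
    h2min = _entropy(np.array(_h2min_packing(r, c)), m)
    if h2max - h2min <= 1e-12:
        return 0.0
    return float(np.clip((h2max - h2) / (h2max - h2min), 0.0, 1.0))


def interaction_strength_asymmetry(
    matrix: InteractionMatrix, *, signed: bool = True
) -> float:
    """Mean per-link asymmetry of mutual dependences.

    For each realized link the bird's dependence is the cell weight over
    the bird's (column) total, the plant's the cell over the plant's (row)
    total; the link asymmetry is their difference over the larger of the
    two. ``signed=False`` averages absolute asymmetries instead.
    """
    w = matrix.weights
    row_tot = w.sum(axis=1, keepdims=True)
    col_tot = w.sum(axis=0, keepdims=True)
    mask = w > 0
    d_bird = np.where(mask, w / col_tot, 0.0)   # bird depends on plant
    d_plant = np.where(mask, w / row_tot, 0.0)  # plant depends on bird
    denom = np.maximum(d_bird, d_plant)
    asym = np.where(mask, (d_bird - d_plant) / np.where(mask, denom, 1.0), 0.0)
    if not signed:
        asym = np.abs(asym)
    return float(asym[mask].mean())


def _horn_overlap(x: np.ndarray, y: np.ndarray) -> float:
    """Horn's overlap of two non-negative profiles, normalized to sum 1."""
    x = x / x.sum()
    y = y / y.sum()
    s = x + y

    def xlnx(v):
        v = v[v > 0]
        return (v * np.log(v)).sum()

    return float((xlnx(s) - xlnx(x) - xlnx(y)) / (2.0 * np.log(2.0)))


def niche_overlap(matrix: InteractionMatrix, level: str = "birds") -> float:
    """Mean pairwise Horn overlap of interaction profiles at one level."""
    if level == "birds":
        profiles = matrix.weights.T
    elif level == "plants":
        profiles = matrix.weights
    else:
        raise UndefinedMetricError(f"unknown level {level!r}")
    n = profiles.shape[0]
    if n < 2:
        raise UndefinedMetricError(f"niche overlap needs >=2 species at level {level!r}")
    vals = [
        _horn_overlap(profiles[i], profiles[j])
        for i in range(n)
        for j in range(i + 1, n)
    ]
    return float(np.mean(vals))


@dataclass
class CorePeripheryResult:
    """Standardized-degree classification of a period's bird species."""

    period_label: str
    birds: list[str]
    degrees: np.ndarray
    gc: np.ndarray
    classes: list[str]  # "core" | "periphery"
    degenerate: bool = False  # all degrees equal: sigma_k = 0

    def core_species(self) -> set[str]:
        return {b for b, c in zip(self.birds, self.classes) if c == "core"}

    def periphery_species(self) -> set[str]:
        return {b for b, c in zip(self.birds, self.classes) if c == "periphery"}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "period": self.period_label,
                "species_id": self.birds,
                "degree": self.degrees.astype(int),
                "gc": self.gc,
                "class": self.classes,
            }
        )


def core_periphery(matrix: InteractionMatrix) -> CorePeripheryResult:
    """Classify bird species into generalist core (Gc > 1) or periphery.

    ``k_i`` is bird i's number of plant partners; Gc standardizes it by the
    mean and sample (n-1) standard deviation over the period's birds.
    Gc exactly 1 falls in the periphery. When every bird has the same
    degree the scores are undefined; the result is flagged degenerate and
    everything is periphery.
    """
    if matrix.n_birds < 2:
        raise UndefinedMetricError("core-periphery needs >=2 bird species")
    k = (matrix.weights > 0).sum(axis=0).astype(float)
    sigma = k.std(ddof=1)
    if sigma == 0:
        gc = np.zeros_like(k)
        classes = ["periphery"] * matrix.n_birds
        return CorePeripheryResult(
            matrix.period_label, list(matrix.birds), k, gc, classes, degenerate=True
        )
    gc = (k - k.mean()) / sigma
    classes = ["core" if g > 1 else "periphery" for g in gc]
    return CorePeripheryResult(matrix.period_label, list(matrix.birds), k, gc, classes)


def metrics_row(matrix: InteractionMatrix) -> dict:
    """All network-level parameters of one matrix; undefined metrics are NaN."""
    row = {
        "period": matrix.period_label,
        "size": network_size(matrix),
        "connectance": connectance(matrix),
    }
    for name, fn in (
        ("nodf", nodf),
        ("h2", specialization_h2),
        ("isa", interaction_strength_asymmetry),
        ("niche_overlap", niche_overlap),
    ):
        try:
            row[name] = fn(matrix)
        except UndefinedMetricError:
            row[name] = np.nan
    return row


def metrics_table(series: TemporalNetworkSeries) -> pd.DataFrame:
    """One row of network-level parameters per period, in period order."""
    return pd.DataFrame([metrics_row(m) for m in series.matrices], columns=METRIC_COLUMNS)
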