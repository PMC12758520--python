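"""Significance-score (SS) based calling of differentially expressed genes.

The stage sequence mirrors a standard bulk RNA-seq post-processing flow:
low-count filtering and median-of-ratios normalization of the count matrix,
then — on the differential-expression results table — a composite
significance score per gene,

    SS = log2(fold change) * -log10(adjusted p),

a pi-value-style volcano statistic that weighs effect size and significance
together.  Genes with adjusted p below ``alpha`` are split by SS sign and each
sign group is clustered into two clusters on the 1-D SS axis; the boundary of
the extreme (large-|SS|) cluster — its smallest |SS| member — becomes the
calling threshold for that direction.  Genes passing both the adjusted-p
filter and their side's SS threshold are the called set ("SDEGs").

Both an exact 1-D two-means (global optimum by split-point scan) and classic
Lloyd iteration (via scikit-learn, seeded) are provided; in one dimension with
k = 2 the exact scan is cheap and removes initialization nondeterminism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    DegenerateInputError,
    InputError,
    NormalizationError,
    ThresholdError,
)

#: smallest adjusted p substituted for exact zeros before taking log10
DEFAULT_PADJ_FLOOR = 1e-320

#: adjusted-p admission cutoff applied before threshold derivation
DEFAULT_ALPHA = 0.05

#: canonical column names of a DE results table (DESeq2-style output schema)
DE_TABLE_COLUMNS = ["gene_id", "base_mean", "log2FoldChange", "pvalue", "padj", "stat"]


# ---------------------------------------------------------------------------
# count preprocessing
# ---------------------------------------------------------------------------

def filter_low_counts(counts: pd.DataFrame, threshold: float = 10.0) -> pd.DataFrame:
    """Drop genes whose mean raw count across samples is below ``threshold``.

    Parameters
    ----------
    counts
        Raw count matrix, genes x samples, nonnegative.
    threshold
        Row-mean cutoff; rows with mean strictly less than it are removed
        (a row at exactly the threshold is retained).

    Returns
    -------
    The filtered matrix with the original column order.
    """
    if counts.shape[0] == 0 or counts.shape[1] == 0:
        raise InputError("count matrix is empty")
    if (counts.to_numpy() < 0).any():
        raise InputError("count matrix contains negative values")
    keep = counts.mean(axis=1) >= threshold
    return counts.loc[keep]


@dataclass
class NormalizedCounts:
    """Median-ratio normalized matrix plus the per-sample size factors."""

    matrix: pd.DataFrame
    size_factors: pd.Series

    def denormalize(self) -> pd.DataFrame:
        """Reconstruct the raw counts (matrix * size_factors)."""
        return self.matrix * self.size_factors


def median_ratio_normalize(counts: pd.DataFrame) -> NormalizedCounts:
    """DESeq2-style median-of-ratios normalization.

    The reference set is the genes with strictly positive counts in every
    sample.  For sample ``j`` the size factor is the median over reference
    genes of ``count[g, j] / geometric_mean_over_samples(count[g, :])``,
    rescaled so the size factors have geometric mean 1 — the ratios between
    samples (the quantity the method estimates) are unchanged, and the
    rescaling makes normalization idempotent: renormalizing an already
    normalized matrix returns unit size factors.  Genes outside the
    reference set do not influence the size factors but are normalized like
    every other gene.
    """
    if counts.shape[0] == 0 or counts.shape[1] == 0:
        raise InputError("count matrix is empty")
    values = counts.to_numpy(dtype=float)
    reference = (values > 0).all(axis=1)
    if not reference.any():
        raise NormalizationError(
            "no gene has strictly positive counts in all samples; "
            "median-ratio normalization needs at least one all-positive reference gene"
        )
    log_ref = np.log(values[reference])
    log_geo_mean = log_ref.mean(axis=1, keepdims=True)
    log_sf = np.median(log_ref - log_geo_mean, axis=0)
    size_factors = np.exp(log_sf - log_sf.mean())
    sf = pd.Series(size_factors, index=counts.columns, name="size_factor")
    return NormalizedCounts(matrix=counts / sf, size_factors=sf)


# ---------------------------------------------------------------------------
# significance scores
# ---------------------------------------------------------------------------

def compute_significance_scores(
    de_table: pd.DataFrame, padj_floor: float = DEFAULT_PADJ_FLOOR
) -> pd.DataFrame:
    """Compute SS = log2FC * -log10(padj) for every gene in a DE table.

    ``de_table`` must carry ``gene_id``, ``log2FoldChange`` and ``padj``
    columns.  Adjusted p-values of exactly zero are floored at ``padj_floor``
    so the score stays finite while preserving the ranking.  Rows with missing
    ``padj`` (DESeq2 emits NA for independently filtered genes) are rejected:
    callers should drop or flag them first.

    Returns a frame with columns ``gene_id``, ``ss`` and ``direction``
    (``up``/``down``/``zero`` by the sign of the score).
    """
    for col in ("gene_id", "log2FoldChange", "padj"):
        if col not in de_table.columns:
            raise InputError(f"DE table lacks required column {col!r}")
    padj = de_table["padj"].to_numpy(dtype=float)
    if np.isnan(padj).any():
        raise InputError("padj contains missing values; drop NA rows before scoring")
    if ((padj < 0) | (padj > 1)).any():
        raise InputError("padj values must lie in [0, 1]")
    lfc = de_table["log2FoldChange"].to_numpy(dtype=float)
    ss = lfc * -np.log10(np.maximum(padj, padj_floor))
    direction = np.where(ss > 0, "up", np.where(ss < 0, "down", "zero"))
    return pd.DataFrame(
        {"gene_id": de_table["gene_id"].to_numpy(), "ss": ss, "direction": direction}
    )


# ---------------------------------------------------------------------------
# 1-D two-means clustering
# ---------------------------------------------------------------------------

def two_means_1d(
    values, method: str = "exact", seed: int = 0
) -> tuple[np.ndarray, tuple[float, float]]:
    """Cluster 1-D values into a low-mean and a high-mean cluster (k = 2).

    ``method="exact"`` scans every split point of the sorted values and
    returns the partition minimizing the within-cluster sum of squares — the
    global optimum, since an optimal 1-D 2-means partition is always an
    interval split.  ``method="lloyd"`` runs standard k-means (scikit-learn,
    seeded) for parity with interactive statistics tools.

    Returns ``(labels, (mean_low, mean_high))`` where ``labels`` is an array
    of ``"low"``/``"high"`` aligned with the input order and ``high`` is the
    cluster with the larger mean.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise InputError("two_means_1d expects a 1-D array")
    if np.unique(x).size < 2:
        raise DegenerateInputError(
            "two_means_1d needs at least 2 distinct values"
        )
    if method == "exact":
        low_mask = _exact_split_mask(x)
    elif method == "lloyd":
        from sklearn.cluster import KMeans

        km = KMeans(n_clusters=2, n_init=10, random_state=seed)
        assign = km.fit_predict(x.reshape(-1, 1))
        low_cluster = int(np.argmin(km.cluster_centers_.ravel()))
        low_mask = assign == low_cluster
    else:
        raise InputError(f"unknown clustering method {method!r}")
    mean_low = float(x[low_mask].mean())
    mean_high = float(x[~low_mask].mean())
    labels = np.where(low_mask, "low", "high")
    return labels, (mean_low, mean_high)


def _exact_split_mask(x: np.ndarray) -> np.ndarray:
    """Boolean mask of the low cluster for the optimal 1-D 2-means split.

    Scans the n-1 candidate splits of the sorted sequence using prefix sums:
    WCSS(split at i) = (S2_left - S1_left^2/i) + (S2_right - S1_right^2/(n-i)).
    """
    order = np.argsort(x, kind="stable")
    xs = x[order]
    n = xs.size
    c1 = np.cumsum(xs)
    c2 = np.cumsum(xs * xs)
    i = np.arange(1, n)  # left cluster sizes
    left_ss = c2[:-1] - c1[:-1] ** 2 / i
    right_sum = c1[-1] - c1[:-1]
    right_ss = (c2[-1] - c2[:-1]) - right_sum**2 / (n - i)
    best = int(np.argmin(left_ss + right_ss))
    low_mask = np.zeros(n, dtype=bool)
    low_mask[order[: best + 1]] = True
    return low_mask


def wcss(x, low_mask) -> float:
    """Within-cluster sum of squares of a 2-cluster partition (test utility)."""
    x = np.asarray(x, dtype=float)
    low_mask = np.asarray(low_mask, dtype=bool)
    total = 0.0
    for part in (x[low_mask], x[~low_mask]):
        if part.size:
            total += float(((part - part.mean()) ** 2).sum())
    return total


# ---------------------------------------------------------------------------
# threshold derivation and calling
# ---------------------------------------------------------------------------

@dataclass
class ThresholdPair:
    """Up/down SS cut points with the cluster assignments behind them.

    ``up_threshold`` is the smallest SS in the extreme cluster on the positive
    side; ``down_threshold`` the (negative) SS of smallest magnitude in the
    extreme cluster on the negative side.  ``alpha`` is the adjusted-p cutoff
    that admitted genes into the clustering.
    """

    up_threshold: float
    down_threshold: float
    up_assignments: pd.Series
    down_assignments: pd.Series
    alpha: float = DEFAULT_ALPHA

    def __post_init__(self):
        if not (self.up_threshold > 0 > self.down_threshold):
            raise InputError(
                "threshold signs invalid: need up_threshold > 0 > down_threshold, "
                f"got {self.up_threshold} and {self.down_threshold}"
            )


def derive_ss_thresholds(
    ss_table: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    method: str = "exact",
    seed: int = 0,
) -> ThresholdPair:
    """Derive the up and down SS thresholds by per-side two-means clustering.

    ``ss_table`` must carry ``gene_id``, ``ss`` and ``padj``.  Genes with
    ``padj < alpha`` are split into the positive-SS and negative-SS groups;
    each group's |SS| values are clustered into two clusters, and the
    threshold is the smallest |SS| of the high-|SS| cluster (the boundary
    where the null-like and changed clusters meet), signed per side.
    """
    for col in ("gene_id", "ss", "padj"):
        if col not in ss_table.columns:
            raise InputError(f"ss table lacks required column {col!r}")
    admitted = ss_table[ss_table["padj"] < alpha]

    sides = {}
    for name, sign in (("up", 1.0), ("down", -1.0)):
        side = admitted[np.sign(admitted["ss"]) == sign]
        magnitudes = np.abs(side["ss"].to_numpy(dtype=float))
        if np.unique(magnitudes).size < 2:
            raise ThresholdError(
                f"{name} side has fewer than 2 distinct SS values below alpha={alpha}; "
                "cannot derive a cluster threshold"
            )
        labels, _ = two_means_1d(magnitudes, method=method, seed=seed)
        threshold = sign * float(magnitudes[labels == "high"].min())
        sides[name] = (
            threshold,
            pd.Series(labels, index=side["gene_id"].to_numpy(), name=f"{name}_cluster"),
        )

    return ThresholdPair(
        up_threshold=sides["up"][0],
        down_threshold=sides["down"][0],
        up_assignments=sides["up"][1],
        down_assignments=sides["down"][1],
        alpha=alpha,
    )


@dataclass
class SdegCallSet:
    """Per-gene significance calls plus summary bookkeeping."""

    calls: pd.DataFrame  # gene_id, ss, padj, call
    n_up: int
    n_down: int
    background_size: int
    thresholds: ThresholdPair = field(repr=False)

    @property
    def n_total_sdeg(self) -> int:
        return self.n_up + self.n_down

    @property
    def sdeg_fraction(self) -> float:
        """Called genes as a fraction of the background (table) size."""
        return self.n_total_sdeg / self.background_size

    def gene_ids(self, direction: str | None = None) -> list[str]:
        """Called gene ids; ``direction`` restricts to 'sdeg_up'/'sdeg_down'."""
        mask = self.calls["call"] != "not_significant"
        if direction is not None:
            mask = self.calls["call"] == direction
        return list(self.calls.loc[mask, "gene_id"])


def call_sdegs(
    de_table: pd.DataFrame,
    thresholds: ThresholdPair,
    padj_floor: float = DEFAULT_PADJ_FLOOR,
) -> SdegCallSet:
    """Label each gene sdeg_up / sdeg_down / not_significant.

    A gene is called up when ``padj < alpha`` and its SS is at or above the up
    threshold, down when ``padj < alpha`` and SS at or below the down
    threshold.  Boundary genes are significant: the thresholds are defined as
    cluster minima, so the threshold SS itself belongs to the called cluster.
    """
    ss = compute_significance_scores(de_table, padj_floor=padj_floor)
    padj = de_table["padj"].to_numpy(dtype=float)
    admitted = padj < thresholds.alpha
    up = admitted & (ss["ss"].to_numpy() >= thresholds.up_threshold)
    down = admitted & (ss["ss"].to_numpy() <= thresholds.down_threshold)
    call = np.where(up, "sdeg_up", np.where(down, "sdeg_down", "not_significant"))
    calls = pd.DataFrame(
        {
            "gene_id": de_table["gene_id"].to_numpy(),
            "ss": ss["ss"].to_numpy(),
            "padj": padj,
            "call": call,
        }
    )
    return SdegCallSet(
        calls=calls,
        n_up=int(up.sum()),
        n_down=int(down.sum()),
        background_size=len(de_table),
        thresholds=thresholds,
    )
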