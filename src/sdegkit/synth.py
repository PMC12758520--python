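"""Synthetic inputs with planted ground truth for every pipeline stage.

The generators emulate the statistical structure the downstream stages
assume, not any particular biology:

* a differential-expression results table that is a mixture of null genes
  (log2 fold change near 0, p-values uniform before adjustment) and
  up/down-regulated genes (large |LFC|, very small p), so that the |SS|
  distribution is bimodal with a wide gap — the regime the two-means
  threshold derivation is designed for;
* negative-binomial count matrices for a two-group, two-batch design with
  known per-sample size factors;
* gene-set collections in which a few sets oversample the truly regulated
  genes at a stated enrichment factor.

P-values are generated directly (null: Uniform(0,1); regulated: p = 10^-u
with u uniform over a configurable range) and then BH-adjusted, rather than
by re-running a Wald test: the pipeline's contract with its upstream DE tool
is the results-table schema, not the test internals.

Every generator is a pure function of its configuration, including the
mandatory seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .enrich import GeneSetCollection, bh_adjust
from .errors import ConfigurationError
from .sdeg import DE_TABLE_COLUMNS

TRUTH_COLUMNS = ["gene_id", "status", "true_lfc"]


@dataclass
class SimConfig:
    """Parameters of the synthetic-data generators.

    The defaults describe the regime the calling stage assumes: 10% up- and
    10% down-regulated genes whose |log2 fold change| is at least 2 and whose
    adjusted p-values end up at or below ~1e-6, against a null background
    with |LFC| spread 0.2 and uniform raw p-values.  Count mode mirrors a
    16-sample design: two conditions with 8 replicates each, split across two
    experimental batches of 4 + 4.
    """

    seed: int
    n_genes: int = 2000
    pi_up: float = 0.10
    pi_down: float = 0.10
    #: sd of the null log2FC component
    lfc_scale_null: float = 0.2
    #: minimum |log2FC| of regulated genes; spread added on top
    alt_lfc_min: float = 2.0
    lfc_scale_alt: float = 0.25
    #: regulated raw p = 10^-u, u ~ Uniform(*this range); kept narrow so the
    #: regulated |SS| component forms a concentrated high cluster (the bimodal
    #: shape the two-means threshold step assumes)
    alt_neglog10p_range: tuple[float, float] = (8.0, 10.0)
    #: draw status counts from a multinomial instead of fixing them exactly
    stochastic_mixture: bool = False

    # --- count mode ---
    n_per_group: int = 8
    nb_dispersion: float = 0.1
    #: lognormal parameters of per-gene base mean expression
    base_mean_log_mean: float = 5.0
    base_mean_log_sd: float = 1.5
    size_factors: tuple[float, ...] | None = None
    #: multiplicative batch factor applied to batch 2 (1.0 = no batch effect)
    batch_factor: float = 1.0

    # --- gene-set mode ---
    n_sets: int = 50
    set_size_range: tuple[int, int] = (20, 100)
    n_spiked_sets: int = 2
    #: spiked sets sample regulated genes at spike_factor x the background rate
    spike_factor: float = 5.0

    def __post_init__(self):
        if not isinstance(self.seed, (int, np.integer)):
            raise ConfigurationError("seed must be an integer (no implicit entropy)")
        if not (0 <= self.pi_up <= 1 and 0 <= self.pi_down <= 1):
            raise ConfigurationError("mixture proportions must lie in [0, 1]")
        if self.pi_up + self.pi_down > 1:
            raise ConfigurationError(
                f"pi_up + pi_down = {self.pi_up + self.pi_down} exceeds 1"
            )
        for name in ("n_genes", "n_per_group", "n_sets"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.n_per_group < 2:
            raise ConfigurationError("need at least 2 replicates per condition")
        if self.nb_dispersion <= 0:
            raise ConfigurationError("negative-binomial dispersion must be positive")
        if self.set_size_range[0] < 1 or self.set_size_range[0] > self.set_size_range[1]:
            raise ConfigurationError("invalid set_size_range")
        lo, hi = self.alt_neglog10p_range
        if not (0 < lo <= hi):
            raise ConfigurationError("alt_neglog10p_range must be positive and ordered")


def _assign_status(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    n = config.n_genes
    if config.stochastic_mixture:
        draws = rng.multinomial(
            n, [config.pi_up, config.pi_down, 1 - config.pi_up - config.pi_down]
        )
        n_up, n_down = int(draws[0]), int(draws[1])
    else:
        n_up = int(np.floor(n * config.pi_up))
        n_down = int(np.floor(n * config.pi_down))
    status = np.array(["up"] * n_up + ["down"] * n_down + ["null"] * (n - n_up - n_down))
    return rng.permutation(status)


def _true_lfc(status: np.ndarray, config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    n = status.size
    lfc = rng.normal(0.0, config.lfc_scale_null, size=n)
    alt = status != "null"
    magnitude = config.alt_lfc_min + np.abs(rng.normal(0.0, config.lfc_scale_alt, alt.sum()))
    sign = np.where(status[alt] == "up", 1.0, -1.0)
    lfc[alt] = sign * magnitude
    # a null gene whose draw lands exactly at 0 stays 0 by definition
    return lfc


def simulate_de_table(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a DE results table and its aligned ground truth.

    Returns ``(de_table, truth)``: the table carries the canonical columns
    ``gene_id, base_mean, log2FoldChange, pvalue, padj, stat``; the truth
    frame carries ``gene_id, status, true_lfc`` in the same row order.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    gene_ids = np.array([f"G{i:06d}" for i in range(n)])
    status = _assign_status(config, rng)
    lfc = _true_lfc(status, config, rng)

    pvalue = rng.uniform(0.0, 1.0, size=n)
    alt = status != "null"
    lo, hi = config.alt_neglog10p_range
    pvalue[alt] = 10.0 ** (-rng.uniform(lo, hi, size=alt.sum()))
    padj = bh_adjust(pvalue)

    # Wald-style rank statistic consistent with the two-sided p and LFC sign
    stat = stats.norm.isf(np.clip(pvalue, 1e-300, 1.0) / 2.0) * np.sign(lfc)
    base_mean = rng.lognormal(config.base_mean_log_mean, config.base_mean_log_sd, size=n)

    de_table = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "base_mean": base_mean,
            "log2FoldChange": lfc,
            "pvalue": pvalue,
            "padj": padj,
            "stat": stat,
        },
        columns=DE_TABLE_COLUMNS,
    )
    truth = pd.DataFrame({"gene_id": gene_ids, "status": status, "true_lfc": lfc})
    return de_table, truth


def simulate_counts(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.Series, pd.Series, pd.Series, pd.DataFrame]:
    """Generate a negative-binomial count matrix for a 2-group, 2-batch design.

    Returns ``(counts, groups, batches, size_factors, truth)``.  Counts are
    genes x samples; regulated genes have a group mean ratio of
    ``2**true_lfc``; per-sample size factors multiply every mean; an optional
    batch factor multiplies batch-2 samples (off by default).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    m = config.n_per_group
    gene_ids = [f"G{i:06d}" for i in range(n)]
    status = _assign_status(config, rng)
    lfc = _true_lfc(status, config, rng)

    samples = [f"ground_{j + 1}" for j in range(m)] + [f"space_{j + 1}" for j in range(m)]
    groups = pd.Series(["ground"] * m + ["space"] * m, index=samples, name="group")
    # each batch holds half of each condition (4 + 4 in the default design)
    half = m // 2
    batch_of = lambda j: "batch1" if j < half else "batch2"  # noqa: E731
    batches = pd.Series([batch_of(j) for j in range(m)] * 2, index=samples, name="batch")

    if config.size_factors is None:
        sf = np.ones(2 * m)
    else:
        sf = np.asarray(config.size_factors, dtype=float)
        if sf.shape != (2 * m,) or (sf <= 0).any():
            raise ConfigurationError("size_factors must be 2*n_per_group positive values")
    size_factors = pd.Series(sf, index=samples, name="size_factor")

    base = rng.lognormal(config.base_mean_log_mean, config.base_mean_log_sd, size=n)
    if (base <= 0).any():
        raise ConfigurationError("base means must be positive")
    group_mult = np.where(groups.to_numpy() == "space", 2.0 ** lfc[:, None], 1.0)
    batch_mult = np.where(batches.to_numpy() == "batch2", config.batch_factor, 1.0)
    mu = base[:, None] * group_mult * sf[None, :] * batch_mult[None, :]

    r = 1.0 / config.nb_dispersion
    counts = rng.negative_binomial(r, r / (r + mu))
    counts = pd.DataFrame(counts, index=gene_ids, columns=samples)
    truth = pd.DataFrame({"gene_id": gene_ids, "status": status, "true_lfc": lfc})
    return counts, groups, batches, size_factors, truth


def simulate_gene_sets(
    background: list[str], config: SimConfig, truth: pd.DataFrame
) -> tuple[GeneSetCollection, list[str]]:
    """Sample a gene-set collection from ``background``, spiking a few sets.

    ``n_spiked_sets`` of the ``n_sets`` sets draw regulated (non-null) genes
    at ``spike_factor`` times their background rate (capped at 1); the rest
    are uniform draws.  Returns the collection and the spiked set names;
    use :meth:`GeneSetCollection.membership` for per-gene set lookups.
    """
    rng = np.random.default_rng(config.seed)
    background = list(dict.fromkeys(background))
    n_bg = len(background)
    if n_bg == 0:
        raise ConfigurationError("background is empty")
    if config.set_size_range[1] > n_bg:
        raise ConfigurationError(
            f"requested set size up to {config.set_size_range[1]} exceeds "
            f"background of {n_bg}"
        )
    if config.n_spiked_sets > config.n_sets:
        raise ConfigurationError("n_spiked_sets exceeds n_sets")

    truth_alt = set(truth.loc[truth["status"] != "null", "gene_id"])
    alt_pool = np.array([g for g in background if g in truth_alt])
    null_pool = np.array([g for g in background if g not in truth_alt])
    alt_rate = len(alt_pool) / n_bg
    bg_arr = np.array(background)

    lo, hi = config.set_size_range
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    spiked_names: list[str] = []
    for i in range(config.n_sets):
        size = int(rng.integers(lo, hi + 1))
        spiked = i < config.n_spiked_sets
        if spiked and config.spike_factor != 1.0 and len(alt_pool) > 0:
            target_rate = min(1.0, config.spike_factor * alt_rate)
            n_alt = min(int(round(size * target_rate)), len(alt_pool), size)
            members = list(rng.choice(alt_pool, size=n_alt, replace=False))
            if size - n_alt > 0:
                members += list(rng.choice(null_pool, size=size - n_alt, replace=False))
            name = f"SPIKE_{i:03d}"
            spiked_names.append(name)
        else:
            members = list(rng.choice(bg_arr, size=size, replace=False))
            name = f"RANDSET_{i:03d}"
            if spiked:  # spike factor 1.0: structurally a random set
                spiked_names.append(name)
        sets[name] = sorted(members)
        descriptions[name] = "spiked" if spiked else "random"
    return GeneSetCollection(sets=sets, descriptions=descriptions), spiked_names
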