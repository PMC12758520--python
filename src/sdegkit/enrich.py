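"""Gene-set enrichment: overrepresentation analysis, ESS, set cover, GSEA.

Overrepresentation analysis (ORA) is the hypergeometric upper tail of a
query list's overlap with each gene set, with everything — query, sets,
universe — first restricted to an explicit background list.  Background
restriction is mandatory: testing a tissue-derived query against a
whole-genome universe inflates enrichment, so the universe here is always
the genes the assay could have detected.

Per set, with background size N, set size K (within background), query size
n and overlap k, the report carries fold enrichment (k/n)/(K/N), the 2x2
odds ratio, the upper-tail p, BH and Bonferroni adjusted p, and the
enrichment significance score ESS = fold_enrichment * -log10(FDR) — a
composite that ranks sets by effect size and significance jointly.

Redundancy among significant sets is reduced by a greedy weighted set cover
that repeatedly picks the set with the largest (newly covered query genes) *
-log10(FDR) gain.

Pre-ranked GSEA is the weighted Kolmogorov-Smirnov running-sum statistic
over a ranked gene list, with a gene-label permutation null: the list order
is fixed and each permutation re-assigns the set to random positions.  NES
is ES divided by the mean |ES| of same-sign permutations; p-values and FDR
are sign-stratified.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InputError

logger = logging.getLogger(__name__)

#: epsilon floor for FDR = 0 inside -log10
DEFAULT_FDR_FLOOR = 1e-320

#: pinned column order of the tab-separated enrichment report
ORA_REPORT_COLUMNS = [
    "set_name", "k", "K", "n", "N",
    "fold_enrichment", "pvalue", "fdr", "bonferroni", "ess",
]


@dataclass
class GeneSetCollection:
    """Named gene sets with optional descriptions.

    Member lists are deduplicated (order preserved) and set names are unique
    by construction of the dict.
    """

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self.sets = {name: list(dict.fromkeys(members)) for name, members in self.sets.items()}

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def names(self) -> list[str]:
        return list(self.sets)

    def items(self):
        return self.sets.items()

    def description(self, name: str) -> str:
        return self.descriptions.get(name, "")

    def membership(self, gene_id: str) -> list[str]:
        """Names of the sets containing ``gene_id``."""
        return [name for name, members in self.sets.items() if gene_id in members]

    def subset(self, names) -> "GeneSetCollection":
        return GeneSetCollection(
            sets={n: self.sets[n] for n in names},
            descriptions={n: self.descriptions.get(n, "") for n in names},
        )


# ---------------------------------------------------------------------------
# multiple-testing corrections and composite scores
# ---------------------------------------------------------------------------

def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise InputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def bonferroni_adjust(pvalues) -> np.ndarray:
    """Bonferroni adjusted p-values (min(p * m, 1)), in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise InputError("p-values must lie in [0, 1]")
    return np.minimum(p * p.size, 1.0)


def ess_score(fold_enrichment: float, fdr: float, fdr_floor: float = DEFAULT_FDR_FLOOR) -> float:
    """ESS = fold_enrichment * -log10(FDR).

    An FDR of exactly 0 is floored at ``fdr_floor`` (with a warning) so the
    score stays finite.
    """
    if fold_enrichment < 0:
        raise InputError("fold_enrichment must be nonnegative")
    if not 0 <= fdr <= 1:
        raise InputError("fdr must lie in [0, 1]")
    if fdr == 0:
        warnings.warn(f"FDR of 0 floored at {fdr_floor} for ESS", stacklevel=2)
        fdr = fdr_floor
    return float(fold_enrichment * -np.log10(fdr))


# ---------------------------------------------------------------------------
# overrepresentation analysis
# ---------------------------------------------------------------------------

def ora(
    query,
    collection: GeneSetCollection,
    background,
    test: str = "hypergeometric",
    correction: str = "both",
    fdr_floor: float = DEFAULT_FDR_FLOOR,
) -> pd.DataFrame:
    """Overrepresentation of ``query`` in each set, against ``background``.

    Query genes absent from the background are dropped (with a logged
    count); set members outside the background do not count toward K.  The
    upper-tail p is P(X >= k) under Hypergeometric(N, K, n); the one-sided
    Fisher exact test on the same 2x2 table is numerically identical and is
    available as ``test="fisher"``.

    Both BH (``fdr``) and Bonferroni columns are always reported; the ESS
    composite uses the BH FDR unless ``correction="bonferroni"``.

    Returns a frame sorted by p ascending with columns
    ``set_name, k, K, n, N, fold_enrichment, odds_ratio, pvalue, fdr,
    bonferroni, ess, overlap_genes``.
    """
    if test not in ("hypergeometric", "fisher"):
        raise InputError(f"unknown test {test!r}")
    if correction not in ("bh", "bonferroni", "both"):
        raise InputError(f"unknown correction {correction!r}")
    bg = list(dict.fromkeys(background))
    if not bg:
        raise InputError("background is empty")
    bg_set = set(bg)
    query_unique = list(dict.fromkeys(query))
    query_in_bg = [g for g in query_unique if g in bg_set]
    dropped = len(query_unique) - len(query_in_bg)
    if dropped:
        logger.info("ora: dropped %d query genes outside the background", dropped)
    if not query_in_bg:
        raise InputError("query is empty after restriction to the background")

    N = len(bg)
    n = len(query_in_bg)
    q_set = set(query_in_bg)

    rows = []
    for name, members in collection.items():
        members_in_bg = [g for g in members if g in bg_set]
        K = len(members_in_bg)
        overlap = [g for g in members_in_bg if g in q_set]
        k = len(overlap)
        if test == "hypergeometric" or K == 0:
            p = float(stats.hypergeom.sf(k - 1, N, K, n))
        else:
            table = [[k, n - k], [K - k, N - K - (n - k)]]
            p = float(stats.fisher_exact(table, alternative="greater")[1])
        fold = (k / n) / (K / N) if K > 0 else 0.0
        a, b, c, d = k, n - k, K - k, N - K - (n - k)
        odds = (a * d) / (b * c) if b * c > 0 else np.inf if a * d > 0 else np.nan
        rows.append((name, k, K, n, N, fold, odds, min(p, 1.0), overlap))

    out = pd.DataFrame(
        rows,
        columns=["set_name", "k", "K", "n", "N", "fold_enrichment", "odds_ratio",
                 "pvalue", "overlap_genes"],
    )
    out["fdr"] = bh_adjust(out["pvalue"].to_numpy())
    out["bonferroni"] = bonferroni_adjust(out["pvalue"].to_numpy())
    ess_basis = out["bonferroni"] if correction == "bonferroni" else out["fdr"]
    out["ess"] = [
        ess_score(f, q, fdr_floor) for f, q in zip(out["fold_enrichment"], ess_basis)
    ]
    out = out.sort_values(["pvalue", "set_name"], kind="stable").reset_index(drop=True)
    return out[["set_name", "k", "K", "n", "N", "fold_enrichment", "odds_ratio",
                "pvalue", "fdr", "bonferroni", "ess", "overlap_genes"]]


# ---------------------------------------------------------------------------
# weighted set cover
# ---------------------------------------------------------------------------

@dataclass
class ReducedPathwayReport:
    """Greedy weighted-set-cover selection over significant ORA results."""

    selected: pd.DataFrame
    covered_genes: set
    coverage_fraction: float


def weighted_set_cover(
    results: pd.DataFrame,
    fdr_cutoff: float = 0.05,
    top_k: int | None = None,
    fdr_floor: float = DEFAULT_FDR_FLOOR,
) -> ReducedPathwayReport:
    """Pick few sets that cover the query genes of all significant sets.

    Candidates are the rows of an :func:`ora` report with ``fdr <
    fdr_cutoff``.  At each step the candidate maximizing
    ``(newly covered query genes) * -log10(fdr)`` is selected; ties break by
    smaller FDR, then lexicographic set name.  Selection stops when every
    query gene appearing in any candidate is covered, or after ``top_k``
    picks.  No candidate below the cutoff yields an empty (non-error) report.
    """
    if "overlap_genes" not in results.columns:
        raise InputError("results must carry overlap_genes (run ora first)")
    cand = results[results["fdr"] < fdr_cutoff]
    universe: set = set()
    for genes in cand["overlap_genes"]:
        universe.update(genes)
    if cand.empty or not universe:
        return ReducedPathwayReport(
            selected=results.iloc[0:0].copy(), covered_genes=set(), coverage_fraction=0.0
        )

    remaining = {
        row.set_name: (set(row.overlap_genes), float(row.fdr))
        for row in cand.itertuples(index=False)
    }
    covered: set = set()
    picks: list[str] = []
    while covered != universe and remaining:
        if top_k is not None and len(picks) >= top_k:
            break
        best_name, best_key = None, None
        for name, (genes, fdr) in remaining.items():
            gain = len(genes - covered) * -np.log10(max(fdr, fdr_floor))
            key = (-gain, fdr, name)  # maximize gain, then smaller fdr, then name
            if best_key is None or key < best_key:
                best_name, best_key = name, key
        gain = -best_key[0]
        if gain <= 0:
            break  # every remaining candidate is fully covered already
        covered |= remaining.pop(best_name)[0]
        picks.append(best_name)

    selected = (
        cand.set_index("set_name").loc[picks].reset_index()[cand.columns]
        if picks
        else cand.iloc[0:0].copy()
    )
    return ReducedPathwayReport(
        selected=selected,
        covered_genes=covered,
        coverage_fraction=len(covered) / len(universe),
    )


# ---------------------------------------------------------------------------
# pre-ranked GSEA
# ---------------------------------------------------------------------------

def _es_walk(
    positions: np.ndarray, weights: np.ndarray, n: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Extrema of the weighted KS running sum for batches of hit positions.

    ``positions``: (..., m) sorted 0-based hit indices; ``weights``: matching
    |stat|^alpha at those indices.  Returns ``(max_dev, min_dev, argmax_hit)``
    where the walk's local maxima sit just after a hit and local minima just
    before one.
    """
    m = positions.shape[-1]
    nr = weights.sum(axis=-1, keepdims=True)
    # a weight sum of 0 (all-zero stats) degenerates to equal hit steps
    nr = np.where(nr == 0, 1.0, nr)
    cum_hit = np.cumsum(weights, axis=-1) / nr
    miss_step = 1.0 / (n - m)
    misses_before = positions - np.arange(m)
    after_hit = cum_hit - misses_before * miss_step
    before_hit = after_hit - weights / nr
    max_dev = after_hit.max(axis=-1)
    min_dev = before_hit.min(axis=-1)
    argmax_hit = after_hit.argmax(axis=-1)
    return max_dev, min_dev, argmax_hit


def _signed_es(max_dev, min_dev):
    """Pick the deviation of larger magnitude; ties go to the positive side."""
    return np.where(max_dev >= -min_dev, max_dev, min_dev)


def preranked_gsea(
    ranked: pd.DataFrame,
    collection: GeneSetCollection,
    weight_exponent: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
    min_size: int = 5,
) -> pd.DataFrame:
    """Pre-ranked GSEA over a ranked gene list with a gene-label null.

    ``ranked`` is a two-column frame (``gene_id``, ``stat``) whose row order
    IS the ranking, best first (callers ranking by a Wald-type statistic
    should sort descending before the call).  Hit increments are
    ``|stat|^weight_exponent``; the null re-draws each set's positions
    uniformly ``n_perm`` times from a seeded generator.  Permutation
    p-values use the add-one convention (r+1)/(n+1) within the sign stratum;
    FDR is the sign-stratified NES q-value.

    Sets with fewer than ``min_size`` members in the list are skipped (logged);
    a set covering the entire list has no miss step and is skipped too.
    """
    if ranked.shape[1] < 2:
        raise InputError("ranked frame needs gene_id and stat columns")
    gene_col, stat_col = ranked.columns[:2]
    genes = ranked[gene_col].to_numpy()
    if len(set(genes)) != len(genes):
        raise InputError("ranked list contains duplicate gene ids")
    stat = ranked[stat_col].to_numpy(dtype=float)
    n = genes.size
    index_of = {g: i for i, g in enumerate(genes)}
    abs_pow = np.abs(stat) ** weight_exponent

    rng = np.random.default_rng(seed)
    rows = []
    perm_nes_pool: list[np.ndarray] = []
    for name, members in collection.items():
        pos = np.array(sorted(index_of[g] for g in members if g in index_of))
        m = pos.size
        if m == 0:
            logger.info("gsea: set %s has no members in the ranked list; skipped", name)
            continue
        if m < min_size:
            logger.info("gsea: set %s below min_size=%d; skipped", name, min_size)
            continue
        if m >= n:
            logger.info("gsea: set %s covers the whole list; skipped", name)
            continue
        max_dev, min_dev, arg = _es_walk(pos, abs_pow[pos], n)
        es = float(_signed_es(max_dev, min_dev))

        # leading edge: hits up to the positive extremum, or from the
        # negative extremum onward
        if es >= 0:
            lead = [genes[i] for i in pos[: int(arg) + 1]]
        else:
            before = (np.cumsum(abs_pow[pos]) - abs_pow[pos]) / max(abs_pow[pos].sum(), np.finfo(float).tiny) \
                - (pos - np.arange(m)) / (n - m)
            argmin = int(before.argmin())
            lead = [genes[i] for i in pos[argmin:]]

        perm_pos = np.empty((n_perm, m), dtype=int)
        for b in range(n_perm):
            perm_pos[b] = rng.choice(n, size=m, replace=False)
        perm_pos.sort(axis=1)
        pmax, pmin, _ = _es_walk(perm_pos, abs_pow[perm_pos], n)
        perm_es = _signed_es(pmax, pmin)

        same_sign = perm_es >= 0 if es >= 0 else perm_es < 0
        n_same = int(same_sign.sum())
        if n_same == 0:
            nes, pvalue, perm_nes = np.nan, np.nan, np.array([])
        else:
            mean_abs = np.abs(perm_es[same_sign]).mean()
            nes = es / mean_abs
            r = int((np.abs(perm_es[same_sign]) >= abs(es)).sum())
            pvalue = (r + 1) / (n_same + 1)
            perm_nes = perm_es[same_sign] / mean_abs
        perm_nes_pool.append(perm_nes)
        rows.append(
            {
                "set_name": name,
                "size": m,
                "es": es,
                "nes": nes,
                "pvalue": pvalue,
                "leading_edge": lead,
                "direction": "positive" if es >= 0 else "negative",
            }
        )

    out = pd.DataFrame(rows)
    if out.empty:
        return pd.DataFrame(
            columns=["set_name", "size", "es", "nes", "pvalue", "fdr",
                     "leading_edge", "direction"]
        )
    out["fdr"] = _gsea_fdr(out["nes"].to_numpy(), np.concatenate(perm_nes_pool))
    out = out.sort_values(["pvalue", "set_name"], kind="stable").reset_index(drop=True)
    return out[["set_name", "size", "es", "nes", "pvalue", "fdr",
                "leading_edge", "direction"]]


def _gsea_fdr(nes: np.ndarray, perm_nes: np.ndarray) -> np.ndarray:
    """Sign-stratified NES q-values.

    q(NES*) = [share of same-sign permutation NES at least as extreme,
    add-one] / [share of same-sign observed NES at least as extreme], capped
    at 1.  With a single set this reduces to its permutation p-value.
    """
    q = np.full(nes.shape, np.nan)
    for sign in (1, -1):
        obs_mask = (nes >= 0) if sign == 1 else (nes < 0)
        perm_mask = (perm_nes >= 0) if sign == 1 else (perm_nes < 0)
        perm_side = np.abs(perm_nes[perm_mask])
        n_perm_side = perm_side.size
        obs_side = np.abs(nes[obs_mask])
        for i in np.flatnonzero(obs_mask):
            if np.isnan(nes[i]) or n_perm_side == 0:
                continue
            num = ((perm_side >= abs(nes[i])).sum() + 1) / (n_perm_side + 1)
            den = (obs_side >= abs(nes[i])).sum() / obs_side.size
            q[i] = min(num / den, 1.0)
    return q
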