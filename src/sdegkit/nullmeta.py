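"""Matched random-list null controls and cross-study meta-signatures.

The random-list control replaces the query with lists sampled uniformly from
the same background, at the same size.  Because the background is itself
pre-filtered to the relevant gene type (e.g. detected protein-coding genes),
"matched" sampling reduces to uniform sampling without replacement.  Running
the enrichment engine over many such lists measures the pipeline's false
enrichment rate under the null — a well-calibrated engine flags (almost)
nothing at the FDR cutoff.

The meta-signature machinery combines differential-expression gene lists
from several independent studies into a nonredundant union (the combined
"meta-mission" list), intersects it with a query signature, and compares the
overlap proportion against matched random lists with a Pearson chi-square
test on the 2x2 proportions table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .enrich import GeneSetCollection, ora
from .errors import InputError


@dataclass
class RandomListSpec:
    """How to draw matched random gene lists from a background."""

    background: list[str]
    size: int
    n_replicates: int
    seed: int

    def __post_init__(self):
        self.background = list(dict.fromkeys(self.background))
        if self.size <= 0 or self.n_replicates < 0:
            raise InputError("size must be positive and n_replicates nonnegative")
        if self.size > len(self.background):
            raise InputError(
                f"requested list size {self.size} exceeds background of "
                f"{len(self.background)}"
            )


def generate_random_lists(spec: RandomListSpec) -> list[list[str]]:
    """Uniform without-replacement samples from the background.

    Replicate ``r`` is a pure function of ``(seed, r)``: each replicate gets
    its own generator keyed by the pair, so lists are reproducible and
    individually addressable.
    """
    bg = np.array(spec.background)
    out = []
    for r in range(spec.n_replicates):
        rng = np.random.default_rng([spec.seed, r])
        out.append(list(rng.choice(bg, size=spec.size, replace=False)))
    return out


@dataclass
class CalibrationReport:
    """False-enrichment accounting over matched random-list replicates."""

    per_replicate_flagged: list[int]
    n_sets_tested: int
    fdr_cutoff: float

    @property
    def false_enrichment_rate(self) -> float | None:
        """Flagged (replicate, set) pairs over all pairs tested; None if empty."""
        n_pairs = len(self.per_replicate_flagged) * self.n_sets_tested
        if n_pairs == 0:
            return None
        return sum(self.per_replicate_flagged) / n_pairs


def calibration_experiment(
    spec: RandomListSpec,
    collection: GeneSetCollection,
    fdr_cutoff: float = 0.05,
    test: str = "hypergeometric",
) -> CalibrationReport:
    """Run ORA for every random replicate and count sets passing the cutoff."""
    flagged: list[int] = []
    for random_list in generate_random_lists(spec):
        report = ora(random_list, collection, spec.background, test=test)
        flagged.append(int((report["fdr"] < fdr_cutoff).sum()))
    return CalibrationReport(
        per_replicate_flagged=flagged,
        n_sets_tested=len(collection),
        fdr_cutoff=fdr_cutoff,
    )


# ---------------------------------------------------------------------------
# meta-signatures
# ---------------------------------------------------------------------------

def _normalize_ids(ids, case_fold: bool) -> list[str]:
    out = []
    for g in ids:
        g = str(g).strip()
        if case_fold:
            g = g.casefold()
        if g:
            out.append(g)
    return out


@dataclass
class MetaSignature:
    """Nonredundant multi-study DEG union and its overlap with a query.

    ``combined_total`` counts duplicates across source lists;
    ``nonredundant`` is the deduplicated union.  After
    :func:`intersect_signature`, ``query_overlap`` holds the intersection
    with the query signature and ``overlap_proportion`` its share of the
    nonredundant union.  ``chisq_stat``/``chisq_p`` are filled by an explicit
    :func:`proportion_chisq` comparison.
    """

    source_sizes: dict[str, int]
    combined_total: int
    nonredundant: list[str]
    query_overlap: list[str] | None = None
    overlap_proportion: float | None = None
    chisq_stat: float | None = None
    chisq_p: float | None = None

    @property
    def n_nonredundant(self) -> int:
        return len(self.nonredundant)

    @property
    def nonredundant_fraction(self) -> float:
        """Unique genes as a share of the duplicate-counting total."""
        return self.n_nonredundant / self.combined_total


def combine_meta_mission(
    named_lists: dict[str, list[str]], case_fold: bool = False
) -> MetaSignature:
    """Union multiple studies' DEG lists into a nonredundant meta-list.

    ``combined_total`` sums the per-list sizes after within-list
    deduplication and id normalization (whitespace trim, optional case
    folding); the union preserves first-seen order for reproducible output.
    """
    if not named_lists or all(len(v) == 0 for v in named_lists.values()):
        raise InputError("need at least one nonempty DEG list")
    cleaned = {
        name: list(dict.fromkeys(_normalize_ids(ids, case_fold)))
        for name, ids in named_lists.items()
    }
    union: dict[str, None] = {}
    for ids in cleaned.values():
        for g in ids:
            union.setdefault(g)
    return MetaSignature(
        source_sizes={name: len(ids) for name, ids in cleaned.items()},
        combined_total=sum(len(ids) for ids in cleaned.values()),
        nonredundant=list(union),
    )


def intersect_signature(
    meta: MetaSignature, query, case_fold: bool = False
) -> MetaSignature:
    """Complete a meta-signature with its overlap against a query list."""
    query_ids = set(_normalize_ids(query, case_fold))
    if not query_ids:
        raise InputError("query list is empty")
    overlap = [g for g in meta.nonredundant if g in query_ids]
    return replace(
        meta,
        query_overlap=overlap,
        overlap_proportion=len(overlap) / len(meta.nonredundant),
    )


def proportion_chisq(
    k1: int, n1: int, k2: int, n2: int, continuity: bool = False
) -> tuple[float, float]:
    """Pearson chi-square comparing two proportions k1/n1 vs k2/n2 (1 df).

    Continuity (Yates) correction is off by default, matching the classical
    Pearson statistic.  Raises when an expected cell count is zero (the test
    is undefined there), naming the offending cell.
    """
    if n1 <= 0 or n2 <= 0:
        raise InputError("group sizes must be positive")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise InputError("counts must satisfy 0 <= k <= n in each group")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    expected = stats.contingency.expected_freq(table)
    if (expected == 0).any():
        i, j = np.argwhere(expected == 0)[0]
        raise InputError(
            f"expected count of 0 in cell (row {i}, col {j}); chi-square undefined"
        )
    res = stats.chi2_contingency(table, correction=continuity)
    return float(res.statistic), float(res.pvalue)
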