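"""Differential-expression filtering and four-group marker classification.

Given a white / beige / classical-brown expression matrix, genes passing a
fold-change + t-test filter (default >2-fold, P<0.05, raw p) are assigned
to one of four enrichment groups:

* ``WHITE`` — enriched in white adipocytes over both brown cell types,
* ``BEIGE_ONLY`` — enriched in beige cells over white and classical brown,
* ``COMMON_BROWN`` — enriched in both beige and classical brown over
  white, with beige and brown within a fold of each other,
* ``CLASSICAL_ONLY`` — enriched in classical brown over white and beige.

"Enriched over" is conjunctive: the fold against EACH other condition
must reach ``min_fold`` AND that contrast's p-value must reach ``max_p``.
Ties at exactly the threshold are included (≥ / ≤).  DE genes matching no
pattern stay ``UNCLASSIFIED``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Literal, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError, DomainError, InsufficientDataError
from .types import BEIGE, BROWN, CONDITIONS, WHITE, ExpressionMatrix, MarkerGroup

__all__ = [
    "DEThresholds",
    "MarkerGroupAssignment",
    "unpaired_t_test",
    "fold_change",
    "classify_gene",
    "discover_marker_groups",
    "overlap_fraction",
]

_PAIRS = tuple(combinations(CONDITIONS, 2))  # (white,beige) (white,brown) (beige,brown)


@dataclass
class DEThresholds:
    """Differential-expression filter settings (defaults: >2-fold, P<0.05,
    equal-variance Student's t, no multiplicity correction)."""

    min_fold: float = 2.0
    max_p: float = 0.05
    test_variant: Literal["student", "welch"] = "student"
    p_adjust: Literal["none", "BH"] = "none"

    def __post_init__(self) -> None:
        if self.min_fold <= 1:
            raise ConfigurationError("min_fold must exceed 1")
        if not 0 < self.max_p < 1:
            raise ConfigurationError("max_p must lie in (0, 1)")
        if self.test_variant not in ("student", "welch"):
            raise ConfigurationError(f"unknown test_variant {self.test_variant!r}")
        if self.p_adjust not in ("none", "BH"):
            raise ConfigurationError(f"unknown p_adjust {self.p_adjust!r}")


@dataclass
class MarkerGroupAssignment:
    """Per-gene labels plus the statistics behind them.

    ``table`` has one row per gene: condition means, pairwise folds
    (larger/smaller within each contrast), pairwise p-values, ``is_de``
    and ``label``.  ``counts`` holds DE-gene counts per label.
    """

    table: pd.DataFrame
    counts: dict[str, int]
    thresholds: DEThresholds

    def genes_in(self, group: MarkerGroup | str) -> list[str]:
        group = MarkerGroup(group)
        mask = (self.table["label"] == str(group)) & self.table["is_de"]
        return list(self.table.index[mask])

    @property
    def n_de(self) -> int:
        return int(self.table["is_de"].sum())


def unpaired_t_test(x, y, variant: Literal["student", "welch"] = "student") -> float:
    """Two-sided unpaired t-test p-value between two replicate groups.

    Degenerate inputs where both groups are constant and equal (zero
    pooled variance, zero difference) return p = 1 by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    if len(x) < 2 or len(y) < 2:
        raise InsufficientDataError("t-test needs at least 2 finite values per group")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        return 1.0 if x[0] == y[0] else 0.0
    res = stats.ttest_ind(x, y, equal_var=(variant == "student"))
    p = float(res.pvalue)
    return 1.0 if np.isnan(p) else p


def fold_change(mean_a: float, mean_b: float) -> float:
    """Linear-scale fold change ``mean_a / mean_b`` (means must be > 0)."""
    if mean_a <= 0 or mean_b <= 0 or not np.isfinite(mean_a) or not np.isfinite(mean_b):
        raise DomainError("fold change requires positive finite means")
    return float(mean_a) / float(mean_b)


def _norm_pair(pvals: Mapping, a: str, b: str) -> float:
    """Fetch a pairwise p-value regardless of key order."""
    for key in ((a, b), (b, a), frozenset((a, b))):
        if key in pvals:
            return float(pvals[key])
    raise ConfigurationError(f"missing p-value for contrast {a!r} vs {b!r}")


def classify_gene(
    condition_means: Mapping[str, float],
    pairwise_p: Mapping,
    thresholds: DEThresholds | None = None,
) -> MarkerGroup:
    """Assign one gene to an enrichment group from its three condition
    means and three pairwise p-values.

    Single-condition labels require fold ≥ ``min_fold`` and p ≤ ``max_p``
    against *each* other condition.  ``COMMON_BROWN`` requires beige and
    brown each enriched over white (fold + p) while differing from each
    other by less than ``min_fold`` in both directions.  Single-condition
    patterns are checked first, so a gene dominant in one brown cell type
    never lands in the common group.
    """
    th = thresholds or DEThresholds()
    m = {c: float(condition_means[c]) for c in CONDITIONS}
    if any(v <= 0 or not np.isfinite(v) for v in m.values()):
        raise DomainError("condition means must be positive (floor first)")
    f, a = th.min_fold, th.max_p

    def enriched(c1: str, c2: str) -> bool:
        return fold_change(m[c1], m[c2]) >= f and _norm_pair(pairwise_p, c1, c2) <= a

    for cond, label in (
        (WHITE, MarkerGroup.WHITE),
        (BEIGE, MarkerGroup.BEIGE_ONLY),
        (BROWN, MarkerGroup.CLASSICAL_ONLY),
    ):
        others = [c for c in CONDITIONS if c != cond]
        if all(enriched(cond, o) for o in others):
            return label

    if (
        enriched(BEIGE, WHITE)
        and enriched(BROWN, WHITE)
        and fold_change(max(m[BEIGE], m[BROWN]), min(m[BEIGE], m[BROWN])) < f
    ):
        return MarkerGroup.COMMON_BROWN
    return MarkerGroup.UNCLASSIFIED


def discover_marker_groups(
    matrix: ExpressionMatrix,
    thresholds: DEThresholds | None = None,
    epsilon: float | None = None,
) -> MarkerGroupAssignment:
    """Run the DE filter and group classification over a whole matrix.

    A gene is DE when any pairwise contrast shows fold ≥ ``min_fold`` (in
    either direction) with p ≤ ``max_p``.  Expression means are floored
    at ``epsilon`` (default: half the smallest positive value in the
    matrix) before folds are computed.
    """
    th = thresholds or DEThresholds()
    if "condition" not in matrix.samples.columns:
        raise ConfigurationError("sample metadata must carry a 'condition' column")
    present = set(matrix.sample_ids)
    groups: dict[str, list[str]] = {
        c: [s for s in matrix.samples.index if s in present and matrix.samples.loc[s, "condition"] == c]
        for c in CONDITIONS
    }
    missing = [c for c, s in groups.items() if len(s) < 2]
    if missing:
        raise ConfigurationError(
            f"each condition needs ≥2 replicates; missing/short: {missing}"
        )

    vals = matrix.values
    if epsilon is None:
        positive = vals.to_numpy()[vals.to_numpy() > 0]
        epsilon = float(positive.min()) / 2.0 if positive.size else 1e-12

    means = {c: vals[groups[c]].mean(axis=1).clip(lower=epsilon) for c in CONDITIONS}

    pcols: dict[tuple[str, str], np.ndarray] = {}
    for c1, c2 in _PAIRS:
        a, b = vals[groups[c1]].to_numpy(), vals[groups[c2]].to_numpy()
        pvals = np.array(
            [unpaired_t_test(a[i], b[i], th.test_variant) for i in range(len(vals))]
        )
        pcols[(c1, c2)] = pvals
    if th.p_adjust == "BH":
        from statsmodels.stats.multitest import multipletests

        flat = np.concatenate([pcols[p] for p in _PAIRS])
        adj = multipletests(flat, method="fdr_bh")[1]
        for k, pair in enumerate(_PAIRS):
            pcols[pair] = adj[k * len(vals) : (k + 1) * len(vals)]

    table = pd.DataFrame(index=vals.index.copy())
    for c in CONDITIONS:
        table[f"mean_{c}"] = means[c]
    de = np.zeros(len(vals), dtype=bool)
    for c1, c2 in _PAIRS:
        fc = (means[c1] / means[c2]).to_numpy()
        table[f"fold_{c1}_vs_{c2}"] = fc
        table[f"p_{c1}_vs_{c2}"] = pcols[(c1, c2)]
        de |= (np.maximum(fc, 1.0 / fc) >= th.min_fold) & (pcols[(c1, c2)] <= th.max_p)
    table["is_de"] = de

    labels = []
    for i, g in enumerate(vals.index):
        if not de[i]:
            labels.append(str(MarkerGroup.UNCLASSIFIED))
            continue
        gene_means = {c: float(means[c].iloc[i]) for c in CONDITIONS}
        gene_p = {pair: float(pcols[pair][i]) for pair in _PAIRS}
        labels.append(str(classify_gene(gene_means, gene_p, th)))
    table["label"] = labels

    counts = {
        str(gr): int(((table["label"] == str(gr)) & table["is_de"]).sum())
        for gr in MarkerGroup
    }
    return MarkerGroupAssignment(table=table, counts=counts, thresholds=th)


def overlap_fraction(count_common: int, count_group_total: int) -> tuple[float, int]:
    """Percentage of a group's genes shared with the other brown cell type.

    Returns ``(percentage, nearest-integer percentage)`` —
    e.g. 29 common of 323 classical-brown genes → (8.98…, 9).
    """
    if count_group_total <= 0:
        raise DomainError("group total must be positive")
    if not 0 <= count_common <= count_group_total:
        raise DomainError("need 0 ≤ common ≤ total")
    pct = 100.0 * count_common / count_group_total
    return pct, int(round(pct))
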