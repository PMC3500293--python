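"""Gene-set concordance: the statistical core of the pipeline.

Workflow: screen genes for outlier-ridden measurements (Tukey whisker
rule; genes with too many flagged samples are excluded, as UCP1 was),
build pairwise-complete Pearson correlation matrices, integrate the
correlations between an *anchor* gene (an established brown-fat marker —
PRDM16/PGC1α role) and each member of a marker set into a single
*gene-set correlation coefficient* via Fisher's z, and compare two
competing marker sets with a Z-test.  Average-linkage hierarchical
clustering on 1 − r distance orders genes for presentation.

Fisher integration
------------------
Each member correlation rᵢ (on nᵢ complete sample pairs) becomes
zᵢ = atanh(rᵢ); the integrated score is the inverse-variance weighted
mean z̄ = Σwᵢzᵢ/Σwᵢ with wᵢ = nᵢ − 3 (Var zᵢ ≈ 1/(nᵢ−3)), and the
gene-set coefficient is r̄ = tanh(z̄).  On a complete panel all weights
are equal and z̄ is the plain mean of the member z-scores.

Standard error of z̄ — two modes (member genes share samples and, under
the one-factor biology, a common driver, so their z-scores are *not*
independent):

* ``conservative`` (default): SE = 1/sqrt(ñ−3) with ñ the weighted mean
  member n — the set is treated as one effective correlated measurement.
* ``independent``: SE = 1/sqrt(Σwᵢ) — valid only if members were
  independent; anti-conservative here, provided for comparison.

The two-set comparison is Z = (z̄ₐ − z̄_b)/sqrt(SEₐ² + SE_b²) against the
standard normal, treating the two integrated coefficients as
independent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .exceptions import (
    ConfigurationError,
    DomainError,
    EmptySetError,
    InsufficientDataError,
    MismatchedPanelsError,
)
from .types import ExpressionMatrix

__all__ = [
    "pearson_r",
    "fisher_z",
    "inverse_fisher_z",
    "GeneSetCorrelation",
    "gene_set_correlation",
    "ConcordanceVerdict",
    "compare_set_correlations",
    "OutlierEntry",
    "detect_outliers",
    "OutlierReport",
    "filter_genes_by_outliers",
    "CorrelationMatrix",
    "correlation_matrix",
    "Dendrogram",
    "hierarchical_cluster",
    "log2_with_pseudocount",
]

SEMode = Literal["conservative", "independent"]

_R_CLAMP = 1.0 - 1e-6


def pearson_r(x, y) -> tuple[float, int]:
    """Sample Pearson correlation on pairwise-complete observations.

    Returns ``(r, n)`` with ``n`` the number of complete pairs.  ``r`` is
    NaN (an undefined-correlation flag, excluded downstream) when either
    vector has zero variance on the complete pairs.  Fewer than 3
    complete pairs raises :class:`InsufficientDataError`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    n = int(ok.sum())
    if n < 3:
        raise InsufficientDataError(f"need ≥3 complete pairs, got {n}")
    xs, ys = x[ok], y[ok]
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        return float("nan"), n
    r = float(np.corrcoef(xs, ys)[0, 1])
    return max(-1.0, min(1.0, r)), n


def fisher_z(r: float) -> float:
    """Fisher's variance-stabilizing transform z = ½ln((1+r)/(1−r)).

    |r| = 1 (duplicate-like genes) is clamped to 1 − 1e−6 with a warning
    rather than erroring; |r| > 1 is a domain error.
    """
    if not np.isfinite(r) or abs(r) > 1:
        raise DomainError(f"correlation must lie in [-1, 1], got {r}")
    if abs(r) == 1.0:
        warnings.warn("|r| = 1 clamped before Fisher transform", stacklevel=2)
        r = np.sign(r) * _R_CLAMP
    return float(np.arctanh(r))


def inverse_fisher_z(z: float) -> float:
    """Inverse Fisher transform, tanh(z)."""
    return float(np.tanh(z))


@dataclass
class GeneSetCorrelation:
    """Fisher-z integrated correlation of one anchor gene with a marker set.

    ``members`` rows: gene, r, n, z, weight (= n − 3).  ``r_bar`` is the
    gene-set correlation coefficient tanh(z̄).
    """

    anchor: str
    set_label: str
    members: pd.DataFrame
    z_bar: float
    r_bar: float
    se: float
    se_mode: SEMode
    sample_ids: tuple[str, ...]
    n_effective: float

    def to_json_dict(self) -> dict:
        return {
            "anchor": self.anchor,
            "set_label": self.set_label,
            "z_bar": self.z_bar,
            "r_bar": self.r_bar,
            "se": self.se,
            "se_mode": self.se_mode,
            "n_effective": self.n_effective,
            "members": self.members.to_dict(orient="records"),
        }


def log2_with_pseudocount(values: pd.DataFrame) -> pd.DataFrame:
    """log2 transform with pseudocount = half the smallest positive value."""
    arr = values.to_numpy(dtype=float)
    pos = arr[np.isfinite(arr) & (arr > 0)]
    pc = float(pos.min()) / 2.0 if pos.size else 1e-12
    return np.log2(values + pc)


def gene_set_correlation(
    anchor: str,
    gene_set: Sequence[str],
    matrix: ExpressionMatrix,
    set_label: str = "",
    se_mode: SEMode = "conservative",
    log2: bool = False,
) -> GeneSetCorrelation:
    """Integrate anchor-vs-member correlations into one coefficient.

    The anchor itself and members with undefined correlations (zero
    variance) are removed from the set; an empty usable set raises
    :class:`EmptySetError`.  ``log2`` correlates log2-transformed values
    (with pseudocount) instead of linear-scale expression.
    """
    values = log2_with_pseudocount(matrix.values) if log2 else matrix.values
    if anchor not in values.index:
        raise ConfigurationError(f"anchor gene {anchor!r} not in matrix")
    usable = [g for g in gene_set if g != anchor]
    if not usable:
        raise EmptySetError(f"set {set_label!r} empty after removing anchor")
    missing = [g for g in usable if g not in values.index]
    if missing:
        raise ConfigurationError(f"set members not in matrix: {missing}")

    ax = values.loc[anchor].to_numpy(dtype=float)
    rows = []
    for g in usable:
        r, n = pearson_r(ax, values.loc[g].to_numpy(dtype=float))
        if np.isnan(r):
            continue  # undefined correlation: excluded
        if n < 4:
            raise InsufficientDataError(
                f"member {g!r}: n = {n} leaves non-positive Fisher weight"
            )
        rows.append({"gene": g, "r": r, "n": n, "z": fisher_z(r), "weight": n - 3})
    if not rows:
        raise EmptySetError(
            f"set {set_label!r} has no member with a defined correlation"
        )
    members = pd.DataFrame(rows)

    w = members["weight"].to_numpy(dtype=float)
    z = members["z"].to_numpy(dtype=float)
    z_bar = float(np.sum(w * z) / np.sum(w))
    n_eff = float(np.sum(w * members["n"]) / np.sum(w))
    if se_mode == "conservative":
        se = 1.0 / np.sqrt(n_eff - 3.0)
    elif se_mode == "independent":
        se = 1.0 / np.sqrt(np.sum(w))
    else:
        raise ConfigurationError(f"unknown se_mode {se_mode!r}")

    return GeneSetCorrelation(
        anchor=anchor,
        set_label=set_label or ",".join(usable[:3]),
        members=members,
        z_bar=z_bar,
        r_bar=inverse_fisher_z(z_bar),
        se=float(se),
        se_mode=se_mode,
        sample_ids=tuple(matrix.sample_ids),
        n_effective=n_eff,
    )


@dataclass
class ConcordanceVerdict:
    """Z-test comparison of two gene-set correlation coefficients."""

    anchor: str
    set_a: str
    set_b: str
    z_statistic: float
    p_value: float
    winner: str
    se_mode: SEMode

    def to_json_dict(self) -> dict:
        return {
            "anchor": self.anchor,
            "set_a": self.set_a,
            "set_b": self.set_b,
            "z_statistic": self.z_statistic,
            "p_value": self.p_value,
            "winner": self.winner,
            "se_mode": self.se_mode,
            "note": "sets treated as independent; members share samples",
        }


def compare_set_correlations(
    a: GeneSetCorrelation, b: GeneSetCorrelation
) -> ConcordanceVerdict:
    """Z-test of two integrated correlation coefficients.

    Both must be computed for the same anchor on the same sample panel.
    Z is antisymmetric under swapping the sets; the winner is the set
    with the higher r̄.
    """
    if a.anchor != b.anchor:
        raise MismatchedPanelsError(f"anchors differ: {a.anchor!r} vs {b.anchor!r}")
    if a.sample_ids != b.sample_ids:
        raise MismatchedPanelsError("set correlations computed on different panels")
    if a.se_mode != b.se_mode:
        raise MismatchedPanelsError("SE modes differ between the two sets")
    z = (a.z_bar - b.z_bar) / float(np.hypot(a.se, b.se))
    p = float(2.0 * stats.norm.sf(abs(z)))
    winner = a.set_label if a.r_bar >= b.r_bar else b.set_label
    return ConcordanceVerdict(
        anchor=a.anchor,
        set_a=a.set_label,
        set_b=b.set_label,
        z_statistic=float(z),
        p_value=p,
        winner=winner,
        se_mode=a.se_mode,
    )


@dataclass
class OutlierEntry:
    """Tukey box-and-whisker summary of one gene across samples.

    Whisker edges are the outermost *data points* inside
    [Q1 − 1.5·IQR, Q3 + 1.5·IQR]; samples strictly outside the fences
    are flagged as outliers.  Quartiles use linear interpolation between
    order statistics (the "type 7" convention).
    """

    q1: float
    q3: float
    iqr: float
    lower_fence: float
    upper_fence: float
    whisker_low: float
    whisker_high: float
    flagged: tuple[str, ...]
    n: int
    outlier_fraction: float
    insufficient: bool = False


def detect_outliers(values, sample_ids: Sequence[str] | None = None) -> OutlierEntry:
    """Apply the 1.5·IQR whisker rule to one gene's per-sample values.

    Fewer than 4 finite values yields an entry flagged ``insufficient``
    with no outliers called.
    """
    v = np.asarray(values, dtype=float)
    ids = list(sample_ids) if sample_ids is not None else [str(i) for i in range(len(v))]
    if len(ids) != len(v):
        raise ConfigurationError("sample_ids length mismatch")
    ok = np.isfinite(v)
    n = int(ok.sum())
    if n < 4:
        return OutlierEntry(
            q1=float("nan"), q3=float("nan"), iqr=float("nan"),
            lower_fence=float("nan"), upper_fence=float("nan"),
            whisker_low=float("nan"), whisker_high=float("nan"),
            flagged=(), n=n, outlier_fraction=0.0, insufficient=True,
        )
    finite = v[ok]
    q1, q3 = np.percentile(finite, [25, 75])  # linear interpolation (type 7)
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = finite[(finite >= lo) & (finite <= hi)]
    flagged = tuple(
        i for i, val, keep in zip(ids, v, ok) if keep and (val < lo or val > hi)
    )
    return OutlierEntry(
        q1=float(q1), q3=float(q3), iqr=float(iqr),
        lower_fence=float(lo), upper_fence=float(hi),
        whisker_low=float(inside.min()), whisker_high=float(inside.max()),
        flagged=flagged, n=n, outlier_fraction=len(flagged) / n,
    )


@dataclass
class OutlierReport:
    """Per-gene whisker summaries plus the exclusion decisions."""

    table: pd.DataFrame  # gene-indexed: q1 q3 iqr fences whiskers n_flagged fraction excluded
    max_outlier_fraction: float
    entries: dict[str, OutlierEntry]

    @property
    def excluded_genes(self) -> list[str]:
        return list(self.table.index[self.table["excluded"]])


def filter_genes_by_outliers(
    matrix: ExpressionMatrix, max_outlier_fraction: float = 0.2
) -> tuple[ExpressionMatrix, OutlierReport]:
    """Drop genes whose outlier-sample fraction exceeds the threshold.

    This is the screening step that removed UCP1 from the original
    correlation analysis: a gene measured wildly in too many samples
    cannot support a meaningful correlation.  Genes with insufficient
    data for the whisker rule are retained, never excluded.
    """
    if not 0 <= max_outlier_fraction <= 1:
        raise ConfigurationError("max_outlier_fraction must lie in [0, 1]")
    entries: dict[str, OutlierEntry] = {}
    rows = []
    for gene in matrix.genes:
        e = detect_outliers(matrix.values.loc[gene].to_numpy(), matrix.sample_ids)
        entries[gene] = e
        excluded = (not e.insufficient) and e.outlier_fraction > max_outlier_fraction
        rows.append(
            {
                "gene": gene, "q1": e.q1, "q3": e.q3, "iqr": e.iqr,
                "lower_fence": e.lower_fence, "upper_fence": e.upper_fence,
                "whisker_low": e.whisker_low, "whisker_high": e.whisker_high,
                "n": e.n, "n_flagged": len(e.flagged),
                "outlier_fraction": e.outlier_fraction,
                "flagged_samples": ";".join(e.flagged),
                "insufficient": e.insufficient, "excluded": excluded,
            }
        )
    table = pd.DataFrame(rows).set_index("gene")
    kept = [g for g in matrix.genes if not table.loc[g, "excluded"]]
    report = OutlierReport(
        table=table, max_outlier_fraction=max_outlier_fraction, entries=entries
    )
    return matrix.subset_genes(kept), report


@dataclass
class CorrelationMatrix:
    """Symmetric pairwise-complete Pearson correlation matrix.

    ``r`` and ``n`` are gene × gene DataFrames; undefined correlations
    (zero variance) are NaN cells.
    """

    r: pd.DataFrame
    n: pd.DataFrame

    @property
    def genes(self) -> list[str]:
        return list(self.r.index)


def correlation_matrix(
    matrix: ExpressionMatrix, genes: Sequence[str] | None = None, log2: bool = False
) -> CorrelationMatrix:
    """All pairwise gene–gene Pearson correlations (pairwise-complete)."""
    genes = list(genes) if genes is not None else matrix.genes
    if len(matrix.sample_ids) < 3:
        raise InsufficientDataError("need ≥3 samples for a correlation matrix")
    values = log2_with_pseudocount(matrix.values) if log2 else matrix.values
    k = len(genes)
    r = np.eye(k)
    n = np.full((k, k), len(matrix.sample_ids), dtype=int)
    arrs = [values.loc[g].to_numpy(dtype=float) for g in genes]
    for i in range(k):
        n[i, i] = int(np.isfinite(arrs[i]).sum())
        for j in range(i + 1, k):
            rij, nij = pearson_r(arrs[i], arrs[j])
            r[i, j] = r[j, i] = rij
            n[i, j] = n[j, i] = nij
    return CorrelationMatrix(
        r=pd.DataFrame(r, index=genes, columns=genes),
        n=pd.DataFrame(n, index=genes, columns=genes),
    )


@dataclass
class Dendrogram:
    """Average-linkage merge tree on 1 − r distance.

    ``linkage`` is a scipy linkage matrix over ``labels`` (pre-sorted
    lexicographically for deterministic tie-breaking); ``heights`` are
    the merge distances, non-decreasing.
    """

    linkage: np.ndarray
    labels: list[str]

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    @property
    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in hierarchy.leaves_list(self.linkage)]

    def merges(self) -> list[tuple[frozenset, float]]:
        """Flat clusters formed at each merge, with merge heights."""
        clusters: dict[int, frozenset] = {
            i: frozenset([l]) for i, l in enumerate(self.labels)
        }
        out = []
        for step, (a, b, h, _cnt) in enumerate(self.linkage):
            merged = clusters[int(a)] | clusters[int(b)]
            clusters[len(self.labels) + step] = merged
            out.append((merged, float(h)))
        return out

    def to_newick(self) -> str:
        """Newick string; branch length = parent height − child height."""
        tree = hierarchy.to_tree(self.linkage)

        def walk(node, parent_height: float) -> str:
            bl = parent_height - (0.0 if node.is_leaf() else node.dist)
            if node.is_leaf():
                bl = parent_height
                return f"{self.labels[node.id]}:{bl:.10g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{bl:.10g}"

        inner = f"({walk(tree.left, tree.dist)},{walk(tree.right, tree.dist)})"
        return inner + ";"


def hierarchical_cluster(cm: CorrelationMatrix) -> Dendrogram:
    """UPGMA (average-linkage) clustering with d = 1 − r.

    Items are sorted lexicographically before linkage so equal-distance
    merges resolve deterministically.  Missing correlation cells must be
    filtered out beforehand (e.g. by the outlier screen).
    """
    labels = sorted(cm.genes)
    if len(labels) < 2:
        raise ConfigurationError("need at least 2 items to cluster")
    r = cm.r.loc[labels, labels].to_numpy(dtype=float)
    if np.isnan(r).any():
        raise ConfigurationError(
            "correlation matrix has undefined cells; filter genes first"
        )
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    condensed = d[np.triu_indices(len(labels), k=1)]
    link = hierarchy.linkage(condensed, method="average")
    return Dendrogram(linkage=link, labels=labels)
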