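"""Seeded synthetic expression data with known ground truth.

Two generators mirror the two experimental designs the pipeline analyzes:

* :func:`generate_cell_type_profiles` — a three-condition mouse adipocyte
  culture comparison (white, rosiglitazone-induced beige, classical brown)
  with marker-gene groups planted at a chosen enrichment fold, feeding the
  marker-discovery stage.

* :func:`generate_tissue_panel` — a human-like multi-depot tissue panel in
  which a single latent "beige activity" factor drives beige-selective
  genes, common brown genes and anchor genes (PRDM16/PGC1α role), while
  classical-brown-selective genes sit near the detection floor,
  independent of the factor.  This feeds the concordance stage.

* :func:`generate_ct_table` — raw qPCR Ct values consistent with a known
  relative expression, feeding the ΔΔCt stage.

All randomness flows from one top-level seed.  Per-gene sub-streams are
derived deterministically from (seed, block, gene index), so enlarging a
simulation does not reshuffle the genes already present.

Noise model
-----------
Replicate noise is multiplicative log-normal: a target linear-scale mean
``m`` with coefficient of variation ``cv`` is realized as
``m * exp(sigma*Z - sigma**2/2)`` with ``sigma = sqrt(ln(1+cv**2))``, so
the expectation stays exactly ``m``.  Expression is clipped below at a
configurable detection floor (default 1e-3 × baseline) — microarrays and
qPCR never report true zeros, and the floor keeps log transforms finite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DomainError
from .types import BEIGE, BROWN, CONDITIONS, WHITE, CtTable, ExpressionMatrix, GroundTruth, MarkerGroup

__all__ = [
    "CellTypeSimConfig",
    "TissuePanelSimConfig",
    "generate_cell_type_profiles",
    "generate_tissue_panel",
    "generate_ct_table",
    "add_factor_free_gene",
    "DEFAULT_MARKER_SETS",
    "DEFAULT_ANCHORS",
]

#: human-panel marker sets used as simulation defaults.  Beige-selective
#: and common brown genes carry names of the markers measured in the
#: study system; classical names beyond the known trio are synthetic
#: placeholders (CBM*).
DEFAULT_MARKER_SETS: dict[str, tuple[str, ...]] = {
    "beige": ("CITED1", "CD137", "TMEM26", "TBX1", "HOXC8", "HOXC9", "FGF21", "CA4"),
    "classical": ("ZIC1", "LHX8", "EPSTI1", "CBM4", "CBM5", "CBM6", "CBM7", "CBM8"),
    "common": ("UCP1", "CIDEA", "COX8B"),
}
DEFAULT_ANCHORS: tuple[str, ...] = ("PRDM16", "PGC1A")

# conditions elevated for each planted marker group
_GROUP_CONDITIONS: dict[MarkerGroup, tuple[str, ...]] = {
    MarkerGroup.WHITE: (WHITE,),
    MarkerGroup.BEIGE_ONLY: (BEIGE,),
    MarkerGroup.COMMON_BROWN: (BEIGE, BROWN),
    MarkerGroup.CLASSICAL_ONLY: (BROWN,),
}


def _cv_to_log_sd(cv: float) -> float:
    """Log-normal sigma giving coefficient of variation ``cv``."""
    return float(np.sqrt(np.log1p(cv**2)))


def _lognormal_noise(rng: np.random.Generator, sigma: float, size) -> np.ndarray:
    """Mean-1 multiplicative log-normal noise."""
    if sigma == 0:
        return np.ones(size)
    return np.exp(rng.normal(-0.5 * sigma**2, sigma, size=size))


@dataclass
class CellTypeSimConfig:
    """Design of a synthetic three-condition adipocyte culture experiment.

    Parameters
    ----------
    n_genes
        Total genes on the array; genes not claimed by a planted group are
        background (baseline in every condition).
    n_replicates_per_condition
        Biological replicates per condition (default 3 — typical for
        primary-culture microarray designs).
    planted_groups
        Mapping :class:`MarkerGroup` label → number of genes planted with
        that enrichment pattern.
    fold_effect
        Linear-scale enrichment fold of a planted gene in its elevated
        condition(s) relative to baseline; must exceed 1.
    noise_cv
        Replicate coefficient of variation of the multiplicative
        log-normal noise.
    baseline_mean
        Linear-scale expression floor level of un-elevated measurements.
    floor_frac
        Detection floor as a fraction of ``baseline_mean``.
    """

    n_genes: int = 1000
    n_replicates_per_condition: int = 3
    planted_groups: dict[MarkerGroup, int] = field(
        default_factory=lambda: {
            MarkerGroup.WHITE: 32,
            MarkerGroup.BEIGE_ONLY: 141,
            MarkerGroup.COMMON_BROWN: 29,
            MarkerGroup.CLASSICAL_ONLY: 294,
        }
    )
    fold_effect: float = 8.0
    noise_cv: float = 0.2
    baseline_mean: float = 100.0
    floor_frac: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        self.planted_groups = {MarkerGroup(k): int(v) for k, v in self.planted_groups.items()}
        bad = [g for g in self.planted_groups if g not in _GROUP_CONDITIONS]
        if bad:
            raise ConfigurationError(f"cannot plant group(s) {bad}")
        if sum(self.planted_groups.values()) > self.n_genes:
            raise ConfigurationError(
                f"planted groups need {sum(self.planted_groups.values())} genes "
                f"but n_genes={self.n_genes}"
            )
        if self.fold_effect <= 1:
            raise ConfigurationError("fold_effect must exceed 1")
        if self.noise_cv < 0:
            raise ConfigurationError("noise_cv must be non-negative")
        if self.baseline_mean <= 0:
            raise ConfigurationError("baseline_mean must be positive")
        if self.n_replicates_per_condition < 2:
            raise ConfigurationError("need at least 2 replicates per condition")


def generate_cell_type_profiles(
    config: CellTypeSimConfig,
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Simulate the three-condition culture comparison with planted markers.

    Returns a matrix with ``n_genes`` rows and ``3 × n_replicates`` columns
    (samples tagged white/beige/brown in the metadata) and the planted
    per-gene labels.  A planted gene's linear-scale mean is elevated by
    ``fold_effect`` in exactly the conditions its group implies.
    """
    cfg = config
    sigma = _cv_to_log_sd(cfg.noise_cv)
    floor = cfg.floor_frac * cfg.baseline_mean
    n_rep = cfg.n_replicates_per_condition

    labels: list[MarkerGroup] = []
    for group, count in cfg.planted_groups.items():
        labels.extend([group] * count)
    labels.extend([MarkerGroup.UNCLASSIFIED] * (cfg.n_genes - len(labels)))

    gene_ids = [f"G{i:05d}" for i in range(cfg.n_genes)]
    sample_ids = [f"{cond}_{r + 1}" for cond in CONDITIONS for r in range(n_rep)]
    cond_of_sample = [cond for cond in CONDITIONS for _ in range(n_rep)]

    values = np.empty((cfg.n_genes, 3 * n_rep))
    for i, group in enumerate(labels):
        elevated = _GROUP_CONDITIONS.get(group, ())
        means = np.array(
            [
                cfg.baseline_mean * (cfg.fold_effect if c in elevated else 1.0)
                for c in cond_of_sample
            ]
        )
        rng = np.random.default_rng([cfg.seed, 1, i])
        values[i] = means * _lognormal_noise(rng, sigma, means.shape)
    values = np.maximum(values, floor)

    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=gene_ids, columns=sample_ids),
        samples=pd.DataFrame({"condition": cond_of_sample}, index=pd.Index(sample_ids, name="sample_id")),
    )
    truth = GroundTruth(gene_labels=dict(zip(gene_ids, labels)))
    return matrix, truth


_DEPOTS = (
    "supraclavicular",
    "mediastinal",
    "retroperitoneal",
    "intraabdominal",
    "mesenteric",
    "thigh",
)


@dataclass
class TissuePanelSimConfig:
    """Design of a synthetic human-like multi-depot tissue panel.

    A single latent beige-activity factor (standard normal across
    tissues) drives, on log2 scale, every gene of the factor-loaded
    marker sets and every anchor gene with loading ``beige_loading``;
    residual noise is Gaussian with sd ``noise_sd`` (log2 units).  Genes
    of the remaining sets (classical-brown-selective role) sit at
    ``classical_level`` linear units — near the detection floor — with
    the same residual noise but no factor loading.

    Under this one-factor model the population correlation between any
    two factor-driven genes on log scale is λ²/(λ²+σ²).
    """

    n_tissues: int = 13
    marker_sets: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {k: tuple(v) for k, v in DEFAULT_MARKER_SETS.items()}
    )
    anchor_genes: tuple[str, ...] = DEFAULT_ANCHORS
    beige_loading: float = 0.9
    classical_level: float = 0.05
    noise_sd: float = 0.3
    base_log2: float = 4.0
    floor_frac: float = 1e-3
    factor_set_labels: tuple[str, ...] = ("beige", "common")
    seed: int = 0

    def __post_init__(self) -> None:
        self.marker_sets = {k: tuple(v) for k, v in self.marker_sets.items()}
        self.anchor_genes = tuple(self.anchor_genes)
        seen: dict[str, str] = {}
        for label, genes in self.marker_sets.items():
            for g in genes:
                if g in seen:
                    raise ConfigurationError(
                        f"marker sets must be disjoint: {g!r} in {seen[g]!r} and {label!r}"
                    )
                seen[g] = label
        for a in self.anchor_genes:
            if a in seen:
                raise ConfigurationError(f"anchor {a!r} also appears in set {seen[a]!r}")
        if not 0 <= self.beige_loading <= 1:
            raise ConfigurationError("beige_loading must lie in [0, 1]")
        if self.classical_level < 0:
            raise ConfigurationError("classical_level must be non-negative")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")
        if self.n_tissues < 3:
            raise ConfigurationError("need at least 3 tissues")
        unknown = [l for l in self.factor_set_labels if l not in self.marker_sets]
        if unknown:
            raise ConfigurationError(f"factor_set_labels not in marker_sets: {unknown}")


def generate_tissue_panel(
    config: TissuePanelSimConfig,
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Simulate a multi-depot tissue panel with one latent beige factor.

    Returns linear-scale expression (2^log2, clipped at the detection
    floor) for anchors + all marker-set genes across ``n_tissues``
    samples, and the latent factor value per tissue in the ground truth.
    """
    cfg = config
    floor = cfg.floor_frac * 2.0**cfg.base_log2

    tissue_ids = [f"T{i + 1:02d}" for i in range(cfg.n_tissues)]
    depots = [_DEPOTS[i % len(_DEPOTS)] for i in range(cfg.n_tissues)]
    patients = [chr(ord("A") + i % 26) for i in range(cfg.n_tissues)]

    factor = np.random.default_rng([cfg.seed, 0, 0]).standard_normal(cfg.n_tissues)

    factor_genes = [g for l in cfg.factor_set_labels for g in cfg.marker_sets[l]]
    floor_genes = [
        g
        for l, genes in cfg.marker_sets.items()
        if l not in cfg.factor_set_labels
        for g in genes
    ]
    genes = list(cfg.anchor_genes) + factor_genes + floor_genes

    labels: dict[str, MarkerGroup] = {}
    for label, gs in cfg.marker_sets.items():
        mg = {
            "beige": MarkerGroup.BEIGE_ONLY,
            "common": MarkerGroup.COMMON_BROWN,
            "classical": MarkerGroup.CLASSICAL_ONLY,
            "white": MarkerGroup.WHITE,
        }.get(label, MarkerGroup.UNCLASSIFIED)
        for g in gs:
            labels[g] = mg
    for a in cfg.anchor_genes:
        labels[a] = MarkerGroup.COMMON_BROWN  # anchors play the common brown role

    classical_log2 = np.log2(max(cfg.classical_level, floor))
    rows = np.empty((len(genes), cfg.n_tissues))
    for i, g in enumerate(genes):
        rng = np.random.default_rng([cfg.seed, 2, i])
        eps = rng.normal(0.0, cfg.noise_sd, cfg.n_tissues)
        if g in floor_genes:
            log2_expr = classical_log2 + eps
        else:
            log2_expr = cfg.base_log2 + cfg.beige_loading * factor + eps
        rows[i] = np.maximum(2.0**log2_expr, floor)

    matrix = ExpressionMatrix(
        values=pd.DataFrame(rows, index=genes, columns=tissue_ids),
        samples=pd.DataFrame(
            {"tissue": depots, "patient": patients},
            index=pd.Index(tissue_ids, name="sample_id"),
        ),
    )
    truth = GroundTruth(
        gene_labels=labels, tissue_factor=dict(zip(tissue_ids, factor.tolist()))
    )
    return matrix, truth


def add_factor_free_gene(
    matrix: ExpressionMatrix,
    gene_id: str,
    noise_sd: float = 0.3,
    base_log2: float = 4.0,
    seed: int = 0,
) -> ExpressionMatrix:
    """Append a gene independent of everything else in the panel.

    Used to build null configurations: an anchor carrying no loading on
    the latent factor, for calibration checks of the set-comparison
    Z-test.
    """
    if gene_id in matrix.values.index:
        raise ConfigurationError(f"gene {gene_id!r} already present")
    rng = np.random.default_rng([seed, 4, 0])
    vals = 2.0 ** (base_log2 + rng.normal(0.0, noise_sd, len(matrix.sample_ids)))
    values = matrix.values.copy()
    values.loc[gene_id] = vals
    return ExpressionMatrix(values=values, samples=matrix.samples)


def generate_ct_table(
    n_samples: int,
    true_rel_expression,
    reference_ct_mean: float = 20.0,
    ct_noise_sd: float = 0.0,
    seed: int = 0,
    target_gene: str = "TARGET",
    reference_gene: str = "TBP",
) -> CtTable:
    """Simulate raw qPCR Ct values for one target gene.

    With perfect amplification efficiency a transcript twice as abundant
    crosses threshold one cycle earlier, so
    ``Ct_target = Ct_reference − log2(true_rel_expression) + noise``.

    Parameters
    ----------
    true_rel_expression
        Per-sample true expression relative to the reference gene
        (length ``n_samples``, strictly positive).
    reference_ct_mean
        Mean reference-gene Ct (TBP role, typically ~20 cycles).
    ct_noise_sd
        Gaussian technical noise (cycles) added independently to target
        and reference Ct.
    """
    rel = np.asarray(true_rel_expression, dtype=float)
    if rel.shape != (n_samples,):
        raise ConfigurationError(
            f"true_rel_expression must have length {n_samples}, got shape {rel.shape}"
        )
    if np.any(rel <= 0) or not np.all(np.isfinite(rel)):
        raise DomainError("true_rel_expression must be positive and finite")

    rng = np.random.default_rng([seed, 3, 0])
    noise = lambda: (  # noqa: E731 - two independent draws, same sd
        rng.normal(0.0, ct_noise_sd, n_samples) if ct_noise_sd > 0 else np.zeros(n_samples)
    )
    ct_ref = reference_ct_mean + noise()
    ct_target = ct_ref - np.log2(rel) + noise()

    samples = [f"S{i + 1}" for i in range(n_samples)]
    ct = pd.DataFrame(
        {target_gene: ct_target, reference_gene: ct_ref},
        index=pd.Index(samples, name="sample_id"),
    )
    return CtTable(ct=ct, reference=reference_gene)
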