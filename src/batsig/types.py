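"""Core containers: expression matrices, Ct tables, marker-group labels.

An :class:`ExpressionMatrix` holds linear-scale, non-negative expression
values (microarray intensities or qPCR relative expression) as a genes ×
samples :class:`pandas.DataFrame`, plus a per-sample metadata table
(condition for cell cultures, tissue/patient for human panels).  Missing
measurements are carried as NaN and handled pairwise downstream, never
imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError

#: canonical condition labels of the three-culture experiment
WHITE = "white"
BEIGE = "beige"
BROWN = "brown"
CONDITIONS = (WHITE, BEIGE, BROWN)


class MarkerGroup(str, Enum):
    """Enrichment group of a gene in the three-condition comparison.

    WHITE          enriched in white adipocytes only
    BEIGE_ONLY     enriched in rosiglitazone-induced beige cells only
    COMMON_BROWN   enriched in both beige and classical brown adipocytes
    CLASSICAL_ONLY enriched in classical brown adipocytes only
    UNCLASSIFIED   not differentially expressed, or DE without a clean
                   single-group / common pattern
    """

    WHITE = "WHITE"
    BEIGE_ONLY = "BEIGE_ONLY"
    COMMON_BROWN = "COMMON_BROWN"
    CLASSICAL_ONLY = "CLASSICAL_ONLY"
    UNCLASSIFIED = "UNCLASSIFIED"

    def __str__(self) -> str:  # plain value in tables / JSON
        return self.value


@dataclass
class ExpressionMatrix:
    """Genes × samples linear-scale expression with sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per sample id.
    samples
        DataFrame indexed by sample id; typical columns are ``condition``
        (cell cultures) or ``tissue`` / ``patient`` (human panels).
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ConfigurationError(f"duplicate gene ids: {dups}")
        missing = [s for s in self.values.columns if s not in self.samples.index]
        if missing:
            raise ConfigurationError(f"samples without metadata: {missing}")
        vals = self.values.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if np.any(np.isinf(vals)):
            raise ConfigurationError("expression values must be finite or NaN")
        if finite.size and finite.min() < 0:
            raise ConfigurationError("expression values must be non-negative")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def condition_of(self, sample: str) -> str:
        col = "condition" if "condition" in self.samples.columns else "tissue"
        return str(self.samples.loc[sample, col])

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(genes)].copy(), self.samples)


@dataclass
class CtTable:
    """Raw qPCR cycle-threshold values.

    ``ct`` is samples × genes (the reference gene is one column).  A Ct is
    the PCR cycle at which fluorescence crosses threshold, so *lower* Ct
    means *more* transcript.  The reference gene (TBP role) normalizes
    loading; the optional calibrator sample anchors relative expression
    at 1.0.
    """

    ct: pd.DataFrame
    reference: str
    calibrator: str | None = None

    def __post_init__(self) -> None:
        if self.reference not in self.ct.columns:
            raise ConfigurationError(
                f"reference gene {self.reference!r} not in Ct table"
            )
        if self.calibrator is not None and self.calibrator not in self.ct.index:
            raise ConfigurationError(
                f"calibrator sample {self.calibrator!r} not in Ct table"
            )
        # a target Ct without the matching reference Ct cannot be normalized
        ref = self.ct[self.reference]
        targets = self.ct.drop(columns=[self.reference])
        orphan = targets.notna().any(axis=1) & ref.isna()
        if orphan.any():
            raise ConfigurationError(
                f"samples missing reference Ct: {list(self.ct.index[orphan])}"
            )

    @property
    def target_genes(self) -> list[str]:
        return [g for g in self.ct.columns if g != self.reference]


@dataclass
class GroundTruth:
    """Planted truth attached to a synthetic matrix.

    ``gene_labels`` maps gene id → :class:`MarkerGroup`; ``tissue_factor``
    maps tissue/sample id → latent beige-activity factor value (tissue
    panels only).
    """

    gene_labels: dict[str, MarkerGroup] = field(default_factory=dict)
    tissue_factor: dict[str, float] = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "gene_labels": {g: str(l) for g, l in self.gene_labels.items()},
            "tissue_factor": dict(self.tissue_factor),
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            gene_labels={g: MarkerGroup(l) for g, l in d.get("gene_labels", {}).items()},
            tissue_factor={t: float(v) for t, v in d.get("tissue_factor", {}).items()},
        )
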