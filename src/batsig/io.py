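"""Plain-text readers/writers for the pipeline's file formats.

Expression matrices travel as TSV (first column ``gene``, one column per
sample), sample metadata as TSV (first column ``sample_id``), marker
sets as GMT (set name, description, then gene ids, tab-separated — the
standard gene-set exchange format), Ct tables as long TSV
(sample / gene / ct), ground truth as JSON, anchors as one gene per
line.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .exceptions import ConfigurationError
from .types import CtTable, ExpressionMatrix, GroundTruth

__all__ = [
    "write_expression", "read_expression",
    "write_metadata", "read_metadata",
    "read_expression_matrix",
    "write_gmt", "read_gmt",
    "write_ground_truth", "read_ground_truth",
    "write_ct_table", "read_ct_table",
    "read_anchors", "write_anchors",
]


def write_expression(matrix: ExpressionMatrix, path) -> None:
    df = matrix.values.copy()
    df.index.name = "gene"
    df.to_csv(path, sep="\t")


def write_metadata(matrix: ExpressionMatrix, path) -> None:
    meta = matrix.samples.copy()
    meta.index.name = "sample_id"
    meta.to_csv(path, sep="\t")


def read_expression(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_metadata(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, dtype=str)


def read_expression_matrix(expr_path, meta_path) -> ExpressionMatrix:
    """Assemble an :class:`ExpressionMatrix` from its two TSV halves."""
    return ExpressionMatrix(values=read_expression(expr_path), samples=read_metadata(meta_path))


def write_gmt(sets: dict[str, list[str] | tuple[str, ...]], path, description: str = "batsig") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def read_gmt(path) -> dict[str, tuple[str, ...]]:
    sets: dict[str, tuple[str, ...]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ConfigurationError(f"malformed GMT line: {line!r}")
        sets[parts[0]] = tuple(g for g in parts[2:] if g)
    return sets


def write_ground_truth(truth: GroundTruth, path) -> None:
    Path(path).write_text(json.dumps(truth.to_json_dict(), indent=2, sort_keys=True) + "\n")


def read_ground_truth(path) -> GroundTruth:
    return GroundTruth.from_json_dict(json.loads(Path(path).read_text()))


def write_ct_table(ct: CtTable, path) -> None:
    long = ct.ct.stack().rename("ct").reset_index()
    long.columns = ["sample", "gene", "ct"]
    long.to_csv(path, sep="\t", index=False)


def read_ct_table(path, reference: str, calibrator: str | None = None) -> CtTable:
    long = pd.read_csv(path, sep="\t")
    required = {"sample", "gene", "ct"}
    if not required.issubset(long.columns):
        raise ConfigurationError(f"Ct TSV needs columns {sorted(required)}")
    wide = long.pivot(index="sample", columns="gene", values="ct")
    wide.index.name = "sample_id"
    return CtTable(ct=wide, reference=reference, calibrator=calibrator)


def read_anchors(path) -> list[str]:
    return [l.strip() for l in Path(path).read_text().splitlines() if l.strip()]


def write_anchors(anchors, path) -> None:
    Path(path).write_text("\n".join(anchors) + "\n")
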