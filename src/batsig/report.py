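"""Presentation-layer exports and end-to-end pipeline orchestration.

Everything here produces *data*, not graphics: min–max-scaled heatmap
matrices with invertible scaling metadata, 95% density-ellipse
parameters for scatter summaries, and a ``run_pipeline`` driver that
chains simulation → outlier screening → correlation → gene-set
concordance and writes every artifact plus a machine-readable run
manifest.  Reruns from the same config are byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .concordance import (
    Dendrogram,
    compare_set_correlations,
    correlation_matrix,
    filter_genes_by_outliers,
    gene_set_correlation,
    hierarchical_cluster,
    log2_with_pseudocount,
)
from .exceptions import ConfigurationError, DomainError, InsufficientDataError
from .io import (
    write_expression,
    write_gmt,
    write_ground_truth,
    write_metadata,
    read_expression_matrix,
    read_gmt,
)
from .simulate import TissuePanelSimConfig, generate_tissue_panel
from .types import ExpressionMatrix

__all__ = ["HeatmapExport", "export_heatmap", "DensityEllipse", "density_ellipse", "run_pipeline"]


@dataclass
class HeatmapExport:
    """Min–max scaled matrix plus the metadata needed to invert it.

    ``scope="global"`` scales every gene on one identical scale (the
    green–black–red convention for comparing absolute levels across a
    panel); ``scope="per_gene"`` scales each row independently.  A
    constant scope maps to 0.5 by convention.
    """

    scaled: pd.DataFrame
    metadata: dict

    def invert(self) -> pd.DataFrame:
        md = self.metadata
        if md["scope"] == "global":
            lo, hi = md["min"], md["max"]
            out = self.scaled * (hi - lo) + lo if hi > lo else self.scaled * 0 + lo
        else:
            out = self.scaled.copy()
            for g, (lo, hi) in md["per_gene_range"].items():
                row = self.scaled.loc[g]
                out.loc[g] = row * (hi - lo) + lo if hi > lo else lo
        if md["transform"] == "log2":
            out = 2.0**out - md["pseudocount"]
        return out


def export_heatmap(
    matrix: ExpressionMatrix,
    order: Dendrogram | None = None,
    scope: Literal["global", "per_gene"] = "global",
    transform: Literal["linear", "log2"] = "linear",
    color_scheme: str = "green-black-red",
) -> HeatmapExport:
    """Scale an expression matrix into [0, 1] for heatmap rendering."""
    if matrix.values.empty:
        raise ConfigurationError("cannot export an empty matrix")
    values = matrix.values
    pseudocount = 0.0
    if transform == "log2":
        arr = values.to_numpy(dtype=float)
        pos = arr[np.isfinite(arr) & (arr > 0)]
        pseudocount = float(pos.min()) / 2.0 if pos.size else 1e-12
        values = np.log2(values + pseudocount)
    if order is not None:
        rows = [g for g in order.leaf_order if g in values.index]
        rows += [g for g in values.index if g not in rows]
        values = values.loc[rows]

    meta: dict = {
        "scope": scope,
        "transform": transform,
        "pseudocount": pseudocount,
        "color_scheme": color_scheme,
        "row_order": list(values.index),
        "col_order": list(values.columns),
    }
    if scope == "global":
        lo = float(np.nanmin(values.to_numpy()))
        hi = float(np.nanmax(values.to_numpy()))
        meta["min"], meta["max"] = lo, hi
        scaled = (values - lo) / (hi - lo) if hi > lo else values * 0 + 0.5
    elif scope == "per_gene":
        ranges = {}
        rows = {}
        for g in values.index:
            row = values.loc[g]
            lo, hi = float(row.min()), float(row.max())
            ranges[g] = (lo, hi)
            rows[g] = (row - lo) / (hi - lo) if hi > lo else row * 0 + 0.5
        scaled = pd.DataFrame(rows).T.loc[values.index]
        scaled.columns = values.columns
        meta["per_gene_range"] = ranges
    else:
        raise ConfigurationError(f"unknown scaling scope {scope!r}")
    return HeatmapExport(scaled=scaled, metadata=meta)


@dataclass
class DensityEllipse:
    """Bivariate-normal density ellipse of a scatter plot.

    The boundary is {v : (v−μ)ᵀΣ⁻¹(v−μ) = q} with q the χ²(2) quantile
    at ``level`` (q = 5.991 at 95%).  Semi-axis lengths are
    sqrt(q·eigenvalue); ``angle`` is the major axis angle (radians,
    counter-clockwise from +x).  A singular covariance (perfectly
    collinear points) sets ``degenerate``.
    """

    center: tuple[float, float]
    covariance: np.ndarray
    level: float
    mahalanobis_q: float
    semi_axes: tuple[float, float]
    angle: float
    degenerate: bool

    def to_json_dict(self) -> dict:
        return {
            "center": list(self.center),
            "covariance": self.covariance.tolist(),
            "level": self.level,
            "mahalanobis_q": self.mahalanobis_q,
            "semi_axes": list(self.semi_axes),
            "angle": self.angle,
            "degenerate": self.degenerate,
        }


def density_ellipse(x, y, level: float = 0.95) -> DensityEllipse:
    """Fit the ``level`` density ellipse to paired observations."""
    if not 0 < level < 1:
        raise DomainError("level must lie in (0, 1)")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        raise InsufficientDataError("need ≥3 complete pairs for an ellipse")
    xs, ys = x[ok], y[ok]
    center = (float(xs.mean()), float(ys.mean()))
    cov = np.cov(np.vstack([xs, ys]))
    q = float(stats.chi2.ppf(level, df=2))
    eigval, eigvec = np.linalg.eigh(cov)
    degenerate = bool(eigval[0] <= 1e-12 * max(eigval[1], 1.0))
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    semi = tuple(float(np.sqrt(max(ev, 0.0) * q)) for ev in eigval)
    angle = float(np.arctan2(eigvec[1, 0], eigvec[0, 0]))
    return DensityEllipse(
        center=center, covariance=cov, level=level, mahalanobis_q=q,
        semi_axes=semi, angle=angle, degenerate=degenerate,
    )


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: dict | str | Path, out_dir=None) -> Path:
    """Run simulate → screen → correlate → concordance and write artifacts.

    ``config`` is a dict or a YAML path with keys:

    * ``seed`` — master seed (int)
    * either ``simulate_tissues`` (kwargs of :class:`TissuePanelSimConfig`)
      or ``expression`` + ``metadata`` + ``marker_sets`` (file paths)
    * ``anchors`` — list of anchor genes (default: simulation anchors)
    * ``max_outlier_fraction`` (default 0.2), ``se_mode``
      (default "conservative"), ``log2`` (default False)
    * ``out`` — output directory (overridden by ``out_dir``)

    Writes expression/metadata TSVs, marker GMT, outlier report,
    correlation matrix, per-set correlation JSON, verdict JSON, heatmap
    export, Newick dendrogram and ``manifest.json``.  Every seed,
    threshold and mode that affects output is recorded in the manifest,
    and a rerun with the same config is byte-identical.
    """
    if not isinstance(config, dict):
        import yaml

        config = yaml.safe_load(Path(config).read_text())
    cfg = dict(config)
    out = Path(out_dir or cfg.get("out") or "batsig_run")
    out.mkdir(parents=True, exist_ok=True)

    stage = "configure"
    try:
        seed = int(cfg.get("seed", 0))
        max_frac = float(cfg.get("max_outlier_fraction", 0.2))
        se_mode = cfg.get("se_mode", "conservative")
        use_log2 = bool(cfg.get("log2", False))

        if "simulate_tissues" in cfg:
            stage = "simulate"
            sim_kwargs = dict(cfg["simulate_tissues"])
            sim_kwargs.setdefault("seed", seed)
            sim_cfg = TissuePanelSimConfig(**sim_kwargs)
            matrix, truth = generate_tissue_panel(sim_cfg)
            marker_sets = {k: list(v) for k, v in sim_cfg.marker_sets.items()}
            anchors = list(cfg.get("anchors", sim_cfg.anchor_genes))
            write_ground_truth(truth, out / "ground_truth.json")
        else:
            stage = "load"
            for key in ("expression", "metadata", "marker_sets"):
                if key not in cfg:
                    raise ConfigurationError(f"config missing {key!r}")
                if not Path(cfg[key]).exists():
                    raise ConfigurationError(f"input path not found: {cfg[key]}")
            matrix = read_expression_matrix(cfg["expression"], cfg["metadata"])
            marker_sets = {k: list(v) for k, v in read_gmt(cfg["marker_sets"]).items()}
            anchors = list(cfg.get("anchors", []))
            if not anchors:
                raise ConfigurationError("config missing 'anchors'")

        write_expression(matrix, out / "expression.tsv")
        write_metadata(matrix, out / "metadata.tsv")
        write_gmt(marker_sets, out / "marker_sets.gmt")

        stage = "outlier_screen"
        screened, report = filter_genes_by_outliers(matrix, max_frac)
        report.table.to_csv(out / "outlier_report.tsv", sep="\t")

        stage = "correlation_matrix"
        cm = correlation_matrix(screened, log2=use_log2)
        cm.r.to_csv(out / "correlation_matrix.tsv", sep="\t")

        stage = "gene_set_correlation"
        set_corrs: dict[str, dict] = {}
        verdicts = []
        compare_labels = cfg.get("compare_sets")
        if compare_labels is None:
            compare_labels = [l for l in ("beige", "classical") if l in marker_sets]
        kept = set(screened.genes)
        for anchor in anchors:
            if anchor not in kept:
                continue
            per_anchor = {}
            for label, genes in marker_sets.items():
                usable = [g for g in genes if g in kept]
                if not usable:
                    continue
                gsc = gene_set_correlation(
                    anchor, usable, screened, set_label=label,
                    se_mode=se_mode, log2=use_log2,
                )
                per_anchor[label] = gsc
            set_corrs[anchor] = {l: g.to_json_dict() for l, g in per_anchor.items()}
            if len(compare_labels) == 2 and all(l in per_anchor for l in compare_labels):
                v = compare_set_correlations(
                    per_anchor[compare_labels[0]], per_anchor[compare_labels[1]]
                )
                verdicts.append(v.to_json_dict())
        _json_dump(set_corrs, out / "set_correlations.json")
        _json_dump(verdicts, out / "verdicts.json")

        stage = "cluster"
        if len(screened.genes) >= 2:
            dend = hierarchical_cluster(cm)
            (out / "dendrogram.nwk").write_text(dend.to_newick() + "\n")
        else:
            dend = None

        stage = "heatmap"
        hm = export_heatmap(
            screened, order=dend, scope=cfg.get("heatmap_scope", "global"),
            transform=cfg.get("heatmap_transform", "linear"),
        )
        scaled = hm.scaled.copy()
        scaled.index.name = "gene"
        scaled.to_csv(out / "heatmap.tsv", sep="\t")
        _json_dump(hm.metadata, out / "heatmap_meta.json")

        stage = "manifest"
        manifest = {
            "package": "batsig",
            "version": __version__,
            "config": _jsonable(cfg),
            "seed": seed,
            "max_outlier_fraction": max_frac,
            "se_mode": se_mode,
            "log2": use_log2,
            "anchors": anchors,
            "compare_sets": list(compare_labels),
            "excluded_genes": report.excluded_genes,
            "n_samples": len(matrix.sample_ids),
            "n_genes_input": len(matrix.genes),
            "n_genes_retained": len(screened.genes),
        }
        _json_dump(manifest, out / "manifest.json")
    except Exception as exc:
        exc.args = (f"pipeline stage {stage!r} failed: {exc}",)
        raise
    return out


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    return obj
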