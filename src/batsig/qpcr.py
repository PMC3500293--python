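"""Relative quantification of qPCR data by the ΔΔCt method.

ΔCt = Ct_target − Ct_reference normalizes RNA input per sample against an
endogenous control gene (TBP role); relative expression is
2^−(ΔCt_sample − ΔCt_calibrator), which sets the calibrator sample to
exactly 1.0 for every gene.  Amplification efficiency is assumed perfect
(doubling per cycle).  Without a calibrator the output is uncalibrated
2^−ΔCt — a per-gene scale factor that leaves downstream correlations
unchanged.

Missing Ct values propagate as NaN; they are never imputed and are later
handled by pairwise-complete correlation.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .types import CtTable, ExpressionMatrix

__all__ = ["delta_ct", "relative_expression"]


def delta_ct(ct_target: float, ct_reference: float) -> float:
    """Ct_target − Ct_reference; NaN if either measurement is missing."""
    if math.isnan(ct_target) or math.isnan(ct_reference):
        return float("nan")
    return float(ct_target) - float(ct_reference)


def relative_expression(
    ct: CtTable,
    calibrator: str | None = None,
    samples_meta: pd.DataFrame | None = None,
) -> ExpressionMatrix:
    """Convert a Ct table to linear-scale relative expression.

    Parameters
    ----------
    ct
        Raw Ct values (samples × genes, reference gene included).
    calibrator
        Sample whose expression is defined as 1.0 per gene; falls back to
        ``ct.calibrator``; ``None`` yields uncalibrated 2^−ΔCt.
    samples_meta
        Optional sample metadata to attach; defaults to a bare table with
        a ``condition`` column of "unknown".
    """
    calibrator = calibrator if calibrator is not None else ct.calibrator
    dct = ct.ct.drop(columns=[ct.reference]).sub(ct.ct[ct.reference], axis=0)
    if calibrator is not None:
        if calibrator not in dct.index:
            raise ConfigurationError(f"calibrator sample {calibrator!r} absent")
        if dct.loc[calibrator].isna().any():
            raise ConfigurationError(
                f"calibrator {calibrator!r} is missing Ct for some gene(s)"
            )
        dct = dct.sub(dct.loc[calibrator], axis=1)
    expr = np.power(2.0, -dct)

    values = expr.T  # genes × samples
    if samples_meta is None:
        samples_meta = pd.DataFrame(
            {"condition": ["unknown"] * len(expr.index)},
            index=expr.index.copy(),
        )
    return ExpressionMatrix(values=values, samples=samples_meta)
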