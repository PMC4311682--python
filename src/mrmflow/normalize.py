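"""Injection-order signal-drift correction.

MS response drifts over an analytical batch.  The QC-anchored method fits a
LOESS smoother (degree 1, tricube weights) to each feature's pooled-QC
abundances versus injection order, interpolates the smoothed QC levels with
a cubic spline, and rescales every sample by reference_level / drift(order).
The alternative is classical internal-standard ratio normalization.  The
QC-anchored method is impossible without QC injections — that is a hard
error, not a fallback.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from statsmodels.nonparametric.smoothers_lowess import lowess

from .model import PeakMatrix, SampleRecord

__all__ = [
    "DriftModel",
    "fit_drift",
    "apply_drift",
    "fit_drift_models",
    "normalize_internal_standard",
    "qc_rsd",
]

logger = logging.getLogger(__name__)


@dataclass
class DriftModel:
    feature_id: str
    qc_orders: np.ndarray
    qc_values: np.ndarray
    smoothed: np.ndarray
    reference_level: float
    _interp: Callable[[np.ndarray], np.ndarray]

    def drift(self, injection_order: np.ndarray | float) -> np.ndarray | float:
        """Evaluate the drift curve, clamped to the QC bracket."""
        x = np.clip(np.asarray(injection_order, dtype=float), self.qc_orders[0], self.qc_orders[-1])
        out = self._interp(x)
        return float(out) if np.isscalar(injection_order) else np.asarray(out)


def fit_drift(
    feature_id: str,
    qc_orders: np.ndarray,
    qc_values: np.ndarray,
    span: float = 0.5,
) -> DriftModel | None:
    """Fit the LOESS + cubic-spline drift curve for one feature.

    Needs >= 2 QC observations with positive abundance (otherwise the feature
    is left uncorrected and logged).  With fewer than 4 usable QCs the LOESS
    degenerates to the identity on the QC points and linear interpolation
    replaces the spline — a cubic through < 4 points is underdetermined.
    """
    orders = np.asarray(qc_orders, dtype=float)
    values = np.asarray(qc_values, dtype=float)
    ok = values > 0
    orders, values = orders[ok], values[ok]
    if len(orders) < 2:
        logger.warning("feature %s: <2 usable QC observations, left uncorrected", feature_id)
        return None
    srt = np.argsort(orders)
    orders, values = orders[srt], values[srt]
    if len(orders) >= 4:
        smoothed = lowess(values, orders, frac=span, it=0, return_sorted=False)
        interp = CubicSpline(orders, smoothed)
    else:
        smoothed = values.copy()
        interp = lambda x: np.interp(x, orders, smoothed)  # noqa: E731
    return DriftModel(
        feature_id=feature_id,
        qc_orders=orders,
        qc_values=values,
        smoothed=np.asarray(smoothed, dtype=float),
        reference_level=float(np.median(smoothed)),
        _interp=interp,
    )


def fit_drift_models(
    matrix: PeakMatrix, samples: list[SampleRecord], span: float = 0.5
) -> dict[str, DriftModel]:
    """Fit a drift model per feature from the study's QC injections."""
    qcs = [s for s in samples if s.sample_type == "QC" and s.sample_id in matrix.sample_ids]
    if not qcs:
        raise ValueError("QC-anchored drift normalization requires pooled QC injections")
    orders = np.array([s.injection_order for s in qcs], dtype=float)
    models = {}
    for fid in matrix.feature_ids:
        vals = matrix.values.loc[fid, [s.sample_id for s in qcs]].to_numpy(dtype=float)
        m = fit_drift(fid, orders, vals, span=span)
        if m is not None:
            models[fid] = m
    return models


def apply_drift(
    matrix: PeakMatrix,
    drift_models: dict[str, DriftModel],
    samples: list[SampleRecord],
) -> PeakMatrix:
    """Rescale every cell by reference_level / drift(injection order).

    Cells of features without a model, or where the drift curve evaluates to
    zero or below, are left uncorrected (logged).
    """
    order = {s.sample_id: s.injection_order for s in samples}
    out = matrix.copy()
    for fid in out.feature_ids:
        model = drift_models.get(fid)
        if model is None:
            continue
        for sid in out.sample_ids:
            d = model.drift(order[sid])
            if d <= 0:
                logger.warning("feature %s sample %s: non-positive drift, uncorrected", fid, sid)
                continue
            out.values.at[fid, sid] = matrix.values.at[fid, sid] * model.reference_level / d
    return out


def normalize_internal_standard(matrix: PeakMatrix, is_feature_id: str) -> PeakMatrix:
    """Ratio normalization against a spiked internal standard feature.

    value(s, f) <- value(s, f) / IS(s) * median(IS); samples with IS <= 0 are
    flagged in the log and left unnormalized.
    """
    if is_feature_id not in matrix.feature_ids:
        raise ValueError(f"internal standard feature {is_feature_id!r} not in the matrix")
    is_row = matrix.values.loc[is_feature_id]
    med = float(is_row[is_row > 0].median())
    out = matrix.copy()
    for sid in out.sample_ids:
        is_h = float(is_row[sid])
        if is_h <= 0:
            logger.warning("sample %s: internal standard height <= 0, left unnormalized", sid)
            continue
        out.values[sid] = matrix.values[sid] * (med / is_h)
    return out


def qc_rsd(matrix: PeakMatrix, qc_sample_ids: list[str]) -> pd.Series:
    """Per-feature relative standard deviation (%) over the QC injections.

    Undefined (NaN) with fewer than 2 QCs or a zero mean.
    """
    qc_ids = [s for s in qc_sample_ids if s in matrix.sample_ids]
    out = {}
    for fid in matrix.feature_ids:
        vals = matrix.values.loc[fid, qc_ids].to_numpy(dtype=float)
        if len(vals) < 2 or vals.mean() == 0:
            out[fid] = np.nan
        else:
            out[fid] = float(vals.std(ddof=1) / vals.mean() * 100.0)
    return pd.Series(out, name="qc_rsd_percent")
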