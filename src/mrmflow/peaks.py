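"""Smoothing, peak detection on the representative trace, and data-dependent
propagation across all aligned samples.

Peaks are detected once, on the aligned reference-QC chromatogram of each
transition (a pooled QC is expected to contain every detectable compound).
Each representative peak is then propagated to every sample by taking the
local maximum inside the representative's edges — so the resulting matrix is
rectangular by construction and "missing" peaks are gap-filled from the QC
peak's position and width rather than dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import (
    FLAG_DETECTED,
    FLAG_GAP_FILLED,
    Chromatogram,
    FeatureInfo,
    PeakMatrix,
    PeakObservation,
    TransitionKey,
)
import pandas as pd

__all__ = [
    "DetectionParams",
    "RepresentativePeak",
    "smooth",
    "detect_peaks",
    "data_dependent_detect",
    "build_peak_matrix",
]


@dataclass
class DetectionParams:
    smoothing_method: str = "linear_weighted_moving_average"
    smoothing_level: int = 2  # scans
    min_peak_width: int = 5  # scans
    min_peak_height: float = 100.0  # counts, apex above local baseline
    edge_mode: str = "representative_edges"  # or "local_minimum"

    def __post_init__(self):
        if self.smoothing_method != "linear_weighted_moving_average":
            raise ValueError(f"unsupported smoothing method {self.smoothing_method!r}")
        if self.smoothing_level < 0:
            raise ValueError("smoothing_level must be >= 0")
        if self.min_peak_width < 3:
            raise ValueError("min_peak_width must be >= 3 scans")
        if self.min_peak_height < 0:
            raise ValueError("min_peak_height must be >= 0")
        if self.edge_mode not in ("representative_edges", "local_minimum"):
            raise ValueError(f"unknown edge_mode {self.edge_mode!r}")


@dataclass
class RepresentativePeak:
    top_idx: int
    left_idx: int
    right_idx: int
    top_rt: float
    left_rt: float
    right_rt: float
    height: float
    area: float


def smooth(intensities: np.ndarray, level: int = 2) -> np.ndarray:
    """Linear weighted (triangular) moving average over +/- ``level`` scans.

    Weights are proportional to ``level + 1 - |j|`` and renormalized over the
    in-range window at the trace edges, so a constant signal is preserved and
    level 0 is the identity.
    """
    x = np.asarray(intensities, dtype=float)
    if level == 0:
        return x.copy()
    offsets = np.arange(-level, level + 1)
    w = (level + 1 - np.abs(offsets)).astype(float)
    num = np.convolve(x, w[::-1], mode="same")
    den = np.convolve(np.ones_like(x), w[::-1], mode="same")
    return num / den


def _local_minima(y: np.ndarray) -> np.ndarray:
    """Indices of local minima, always including both trace endpoints.

    Plateau points count (both neighbours >=), so flat baselines yield edges
    adjacent to the peak instead of stretching to the trace ends.
    """
    n = len(y)
    idx = [0]
    for i in range(1, n - 1):
        if y[i] <= y[i - 1] and y[i] <= y[i + 1]:
            idx.append(i)
    idx.append(n - 1)
    return np.asarray(idx)


def detect_peaks(
    chromatogram: Chromatogram, params: DetectionParams | None = None
) -> list[RepresentativePeak]:
    """Detect peaks on one (representative) trace.

    The trace is smoothed, local maxima are located, and each peak's edges
    are the nearest flanking local minima.  Peaks narrower than
    ``min_peak_width`` scans or rising less than ``min_peak_height`` above
    the higher edge are dropped.  Height and area are reported from the
    unsmoothed trace.
    """
    params = params or DetectionParams()
    raw = chromatogram.intensities
    t = chromatogram.times
    s = smooth(raw, params.smoothing_level)
    n = len(s)
    minima = _local_minima(s)
    peaks: list[RepresentativePeak] = []
    for i in range(1, n - 1):
        if not (s[i] > s[i - 1] and s[i] >= s[i + 1]):
            continue
        left = minima[minima < i]
        right = minima[minima > i]
        if len(left) == 0 or len(right) == 0:
            continue
        li, ri = int(left[-1]), int(right[0])
        if ri - li + 1 < params.min_peak_width:
            continue
        baseline = max(s[li], s[ri])
        if s[i] - baseline < params.min_peak_height:
            continue
        top = li + int(np.argmax(raw[li : ri + 1]))
        peaks.append(
            RepresentativePeak(
                top_idx=top,
                left_idx=li,
                right_idx=ri,
                top_rt=float(t[top]),
                left_rt=float(t[li]),
                right_rt=float(t[ri]),
                height=float(raw[top]),
                area=float(np.trapezoid(raw[li : ri + 1], t[li : ri + 1])),
            )
        )
    return peaks


def _descend(s: np.ndarray, start: int, step: int) -> int:
    """Walk from ``start`` in direction ``step`` while the trace descends."""
    i = start
    n = len(s)
    while 0 < i + step < n and s[i + step] <= s[i]:
        i += step
    return i


def data_dependent_detect(
    representative_peaks: list[RepresentativePeak],
    sample_chromatogram: Chromatogram,
    params: DetectionParams | None = None,
    feature_ids: list[str] | None = None,
) -> list[PeakObservation]:
    """Propagate representative peaks to one aligned sample.

    For every representative peak the sample's apex is the local maximum
    within the representative's edges; the edges default to the
    representative's (``representative_edges``) or, alternatively, are found
    by descending from the assigned apex to the flanking local minima
    (``local_minimum``).  An apex below ``min_peak_height`` is still
    reported, flagged gap_filled — the interpolation of peaks that exist but
    were not found in some biological samples.
    """
    params = params or DetectionParams()
    raw = sample_chromatogram.intensities
    t = sample_chromatogram.times
    out: list[PeakObservation] = []
    s = smooth(raw, params.smoothing_level) if params.edge_mode == "local_minimum" else None
    for j, rp in enumerate(representative_peaks):
        fid = feature_ids[j] if feature_ids else f"f{j}"
        li, ri = rp.left_idx, rp.right_idx
        top = li + int(np.argmax(raw[li : ri + 1]))
        if params.edge_mode == "local_minimum":
            li = _descend(s, top, -1)
            ri = _descend(s, top, +1)
        height = float(raw[top])
        out.append(
            PeakObservation(
                sample_id=sample_chromatogram.sample_id or "<sample>",
                feature_id=fid,
                top_rt=float(t[top]),
                left_rt=float(t[li]),
                right_rt=float(t[ri]),
                height=height,
                area=float(np.trapezoid(raw[li : ri + 1], t[li : ri + 1])),
                gap_filled=height < params.min_peak_height,
            )
        )
    return out


def build_peak_matrix(
    aligned: dict[TransitionKey, dict[str, Chromatogram]],
    reference_id: str,
    params: DetectionParams | None = None,
) -> PeakMatrix:
    """Detect on each transition's reference trace and propagate to all runs.

    Returns the rectangular features x samples height matrix with one
    PeakObservation per (representative peak, sample); cells whose apex fell
    below ``min_peak_height`` are flagged gap_filled.
    """
    params = params or DetectionParams()
    sample_ids = sorted({sid for per in aligned.values() for sid in per})
    features: list[FeatureInfo] = []
    heights: dict[str, dict[str, float]] = {}
    areas: dict[str, dict[str, float]] = {}
    flags: dict[str, dict[str, str]] = {}
    for key in sorted(aligned.keys()):
        per = aligned[key]
        if reference_id not in per:
            continue
        reps = detect_peaks(per[reference_id], params)
        if not reps:
            continue
        fids = []
        for rp in reps:
            fid = f"{key}@{rp.top_rt:.2f}"
            while fid in heights or fid in fids:
                fid += "'"
            fids.append(fid)
        for rp, fid in zip(reps, fids):
            features.append(
                FeatureInfo(
                    feature_id=fid,
                    transition=key,
                    top_rt=rp.top_rt,
                    left_rt=rp.left_rt,
                    right_rt=rp.right_rt,
                )
            )
            heights[fid], areas[fid], flags[fid] = {}, {}, {}
        for sid in sample_ids:
            chrom = per.get(sid)
            if chrom is None:
                for fid in fids:
                    heights[fid][sid] = 0.0
                    areas[fid][sid] = 0.0
                    flags[fid][sid] = FLAG_GAP_FILLED
                continue
            obs = data_dependent_detect(reps, chrom, params, feature_ids=fids)
            for o in obs:
                heights[o.feature_id][sid] = o.height
                areas[o.feature_id][sid] = o.area
                flags[o.feature_id][sid] = FLAG_GAP_FILLED if o.gap_filled else FLAG_DETECTED
    idx = [f.feature_id for f in features]
    values = pd.DataFrame(
        {sid: [heights[fid][sid] for fid in idx] for sid in sample_ids}, index=idx
    )
    flag_df = pd.DataFrame({sid: [flags[fid][sid] for fid in idx] for sid in sample_ids}, index=idx)
    area_df = pd.DataFrame({sid: [areas[fid][sid] for fid in idx] for sid in sample_ids}, index=idx)
    return PeakMatrix(features=features, values=values, flags=flag_df, areas=area_df)
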