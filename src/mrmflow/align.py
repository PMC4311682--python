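"""Reference selection by chromatographic centroid and COW alignment.

Retention times drift from run to run, so before peaks can be compared the
chromatograms must share a time axis.  The pipeline first picks one pooled-QC
run as the reference — the one whose "gravity" (intensity-weighted mean
retention time, averaged over transitions) is closest to the midpoint of the
QC gravities, i.e. a run sitting in the middle of the drift range — and then
warps every other run onto it with correlation optimized warping (COW): the
reference is cut into fixed-length segments and dynamic programming picks
query segment boundaries, each segment's length free to differ from nominal
by at most ``slack`` scans, to maximize the summed per-segment Pearson
correlation.  One warp is estimated per run on the summed signal over all
transitions (pseudo-TIC) and applied to every channel of that run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .model import Chromatogram, SampleRecord, TransitionKey

__all__ = [
    "UndefinedCentroidError",
    "CowParams",
    "WarpPath",
    "chromatographic_centroid",
    "select_reference",
    "cow_align",
    "align_study",
]

logger = logging.getLogger(__name__)


class UndefinedCentroidError(ValueError):
    """Raised for an all-zero trace, whose centroid is undefined."""


def chromatographic_centroid(chromatogram: Chromatogram) -> float:
    """Intensity-weighted mean retention time ("gravity") of a trace."""
    total = chromatogram.intensities.sum()
    if total <= 0:
        raise UndefinedCentroidError(
            f"all-zero chromatogram {chromatogram.transition} "
            f"(sample {chromatogram.sample_id}): centroid undefined"
        )
    return float(np.dot(chromatogram.intensities, chromatogram.times) / total)


def _aggregate_gravity(
    sample_id: str,
    store: dict[TransitionKey, dict[str, Chromatogram]],
) -> float | None:
    """Unweighted mean of per-transition centroids over channels with signal."""
    vals = []
    for per_sample in store.values():
        chrom = per_sample.get(sample_id)
        if chrom is None:
            continue
        try:
            vals.append(chromatographic_centroid(chrom))
        except UndefinedCentroidError:
            continue
    return float(np.mean(vals)) if vals else None


def select_reference(
    qc_samples: list[SampleRecord],
    store: dict[TransitionKey, dict[str, Chromatogram]],
    mode: str = "aggregate",
) -> str | dict[TransitionKey, str]:
    """Pick the QC run whose gravity is nearest the midpoint of QC gravities.

    ``mode='aggregate'`` (default) averages per-transition centroids into one
    gravity per file and returns a single sample id; ``mode='per_transition'``
    repeats the selection channel by channel and returns a dict.  Ties are
    broken by lowest injection order.
    """
    if not qc_samples:
        raise ValueError("reference selection needs at least one QC sample")
    order = {s.sample_id: s.injection_order for s in qc_samples}

    def _pick(gravities: dict[str, float]) -> str:
        lo, hi = min(gravities.values()), max(gravities.values())
        mid = 0.5 * (lo + hi)
        return min(gravities, key=lambda sid: (abs(gravities[sid] - mid), order[sid]))

    if mode == "per_transition":
        out: dict[TransitionKey, str] = {}
        for key, per_sample in store.items():
            grav = {}
            for s in qc_samples:
                chrom = per_sample.get(s.sample_id)
                if chrom is None:
                    continue
                try:
                    grav[s.sample_id] = chromatographic_centroid(chrom)
                except UndefinedCentroidError:
                    continue
            if grav:
                out[key] = _pick(grav)
        if not out:
            raise ValueError(
                "no QC sample has signal on any transition; choose a reference manually"
            )
        return out
    if mode != "aggregate":
        raise ValueError(f"unknown reference selection mode {mode!r}")
    gravities = {}
    for s in qc_samples:
        g = _aggregate_gravity(s.sample_id, store)
        if g is not None:
            gravities[s.sample_id] = g
    if not gravities:
        raise ValueError("no QC sample has signal on any transition; choose a reference manually")
    return _pick(gravities)


@dataclass
class CowParams:
    segment_size: float = 0.5  # minutes; set near the chromatographic peak width
    slack: int = 1  # scans of allowed per-segment length change
    border_limit: str = "constant"  # constant | extrapolate

    def __post_init__(self):
        if self.segment_size <= 0:
            raise ValueError("segment_size must be positive")
        if self.slack < 0:
            raise ValueError("slack must be >= 0")
        if self.border_limit not in ("constant", "extrapolate"):
            raise ValueError("border_limit must be 'constant' or 'extrapolate'")


@dataclass
class WarpPath:
    """Piecewise-linear time warp as matched (query, reference) boundary nodes."""

    query_indices: np.ndarray
    ref_indices: np.ndarray
    query_times: np.ndarray
    ref_times: np.ndarray

    def map_time(self, t: np.ndarray | float) -> np.ndarray | float:
        """Map reference time(s) to the corresponding query time(s)."""
        return np.interp(t, self.ref_times, self.query_times)

    def apply(self, chromatogram: Chromatogram, ref_times: np.ndarray) -> Chromatogram:
        """Resample ``chromatogram`` onto ``ref_times`` through this warp,
        padding out-of-range lookups with the edge intensity (constant border)."""
        tq = self.map_time(np.asarray(ref_times, dtype=float))
        vals = np.interp(tq, chromatogram.times, chromatogram.intensities)
        return Chromatogram(
            transition=chromatogram.transition,
            times=np.asarray(ref_times, dtype=float),
            intensities=vals,
            sample_id=chromatogram.sample_id,
        )


def _segment_correlation(ref_seg: np.ndarray, query: np.ndarray, a: int, b: int) -> float:
    """Pearson correlation between a reference segment and the query stretch
    [a, b] linearly interpolated onto the segment's length.  Zero variance on
    either side contributes 0 (keeps the DP objective finite on blank regions)."""
    n = len(ref_seg)
    pos = np.linspace(a, b, n)
    q = np.interp(pos, np.arange(len(query)), query)
    rs = ref_seg - ref_seg.mean()
    qs = q - q.mean()
    denom = np.sqrt((rs * rs).sum() * (qs * qs).sum())
    if denom == 0:
        return 0.0
    return float((rs * qs).sum() / denom)


def _boundaries(n_points: int, n_segments: int) -> np.ndarray:
    b = np.rint(np.linspace(0, n_points - 1, n_segments + 1)).astype(int)
    if np.any(np.diff(b) < 1):
        raise ValueError("trace too short for the requested number of segments")
    return b


def cow_align(
    query: Chromatogram,
    reference: Chromatogram,
    params: CowParams | None = None,
) -> tuple[Chromatogram, WarpPath, float]:
    """Align ``query`` to ``reference`` by correlation optimized warping.

    The reference is cut into fixed segments of ``segment_size`` minutes.
    Dynamic programming places the query boundaries so every warped segment's
    length differs from its nominal length by at most ``slack`` scans (and
    keeps >= 2 scans), maximizing the summed per-segment correlation.  Returns
    the query resampled onto the reference grid, the warp path, and the DP
    objective.
    """
    params = params or CowParams()
    dt = float(np.median(np.diff(reference.times)))
    seg_scans = int(round(params.segment_size / dt))
    if seg_scans < 3:
        raise ValueError(
            f"segment_size {params.segment_size} min is under 3 scans at {dt:.4g} min/scan; "
            "increase segment_size"
        )
    n_ref, n_q = len(reference), len(query)
    n_segments = max(1, int(round((n_ref - 1) / seg_scans)))
    ref_b = _boundaries(n_ref, n_segments)
    nominal = np.rint(np.linspace(0, n_q - 1, n_segments + 1)).astype(int)
    slack = params.slack

    # feasible positions for each query boundary
    feasible: list[np.ndarray] = []
    for i in range(n_segments + 1):
        dev = min(i, n_segments - i) * slack
        lo = max(i, nominal[i] - dev)  # >= i keeps every segment at >= 2 scans
        hi = min(n_q - 1 - (n_segments - i), nominal[i] + dev)
        if i == 0:
            lo = hi = 0
        if i == n_segments:
            lo = hi = n_q - 1
        if lo > hi:
            raise ValueError("no feasible warp: query too short for segment/slack settings")
        feasible.append(np.arange(lo, hi + 1))

    NEG = -np.inf
    score_prev = {0: 0.0}
    back: list[dict[int, int]] = []
    qi = query.intensities
    for i in range(1, n_segments + 1):
        ref_seg = reference.intensities[ref_b[i - 1] : ref_b[i] + 1]
        nom_len = nominal[i] - nominal[i - 1]
        score_cur: dict[int, float] = {}
        back_cur: dict[int, int] = {}
        nom_prev = nominal[i - 1]
        for p in feasible[i]:
            best, best_prev = NEG, None
            for p_prev, s_prev in score_prev.items():
                length = p - p_prev
                if length < 1 or abs(length - nom_len) > slack:
                    continue
                c = s_prev + _segment_correlation(ref_seg, qi, p_prev, p)
                # ties (e.g. in blank regions) resolve toward the unwarped path
                better = c > best or (
                    c == best
                    and best_prev is not None
                    and abs(p_prev - nom_prev) < abs(best_prev - nom_prev)
                )
                if best_prev is None or better:
                    best, best_prev = c, p_prev
            if best_prev is not None:
                score_cur[int(p)] = best
                back_cur[int(p)] = best_prev
        if not score_cur:
            raise ValueError("no feasible warp under the slack constraints")
        score_prev, _ = score_cur, back.append(back_cur)

    end = n_q - 1
    total = score_prev[end]
    path = [end]
    for i in range(n_segments - 1, -1, -1):
        path.append(back[i][path[-1]])
    q_idx = np.array(path[::-1], dtype=int)

    warp = WarpPath(
        query_indices=q_idx,
        ref_indices=ref_b,
        query_times=query.times[q_idx],
        ref_times=reference.times[ref_b],
    )
    aligned = warp.apply(query, reference.times)
    return aligned, warp, float(total)


def _pseudo_tic(
    sample_id: str,
    store: dict[TransitionKey, dict[str, Chromatogram]],
    grid: np.ndarray,
) -> Chromatogram | None:
    """Summed intensity across all of a run's transitions on a common grid."""
    acc = np.zeros_like(grid, dtype=float)
    found = False
    first_key = None
    for key, per_sample in store.items():
        chrom = per_sample.get(sample_id)
        if chrom is None:
            continue
        found = True
        first_key = first_key or key
        acc += np.interp(grid, chrom.times, chrom.intensities)
    if not found:
        return None
    return Chromatogram(transition=first_key, times=grid, intensities=acc, sample_id=sample_id)


def align_study(
    store: dict[TransitionKey, dict[str, Chromatogram]],
    reference_id: str,
    params: CowParams | None = None,
    mode: str = "per_file",
) -> tuple[dict[TransitionKey, dict[str, Chromatogram]], dict[str, WarpPath]]:
    """Align every run in the study to the reference run.

    ``mode='per_file'`` (default) estimates one warp per run on its
    pseudo-TIC and applies it to all of the run's channels; an empty run (no
    signal anywhere) falls back to the identity and is logged.
    ``mode='per_transition'`` warps each channel independently.
    Every aligned trace lives on the reference run's grid for its transition;
    the reference run itself is returned unchanged.
    """
    params = params or CowParams()
    sample_ids = sorted({sid for per in store.values() for sid in per})
    if reference_id not in sample_ids:
        raise ValueError(f"reference {reference_id!r} not present in the study")
    ref_grids = {key: per[reference_id].times for key, per in store.items() if reference_id in per}
    common_grid = next(iter(ref_grids.values()))
    aligned: dict[TransitionKey, dict[str, Chromatogram]] = {k: {} for k in store}
    warps: dict[str, WarpPath] = {}

    ref_tic = _pseudo_tic(reference_id, store, common_grid)
    for sid in sample_ids:
        if sid == reference_id:
            for key, per in store.items():
                if sid in per:
                    aligned[key][sid] = per[sid]
            continue
        if mode == "per_file":
            tic = _pseudo_tic(sid, store, common_grid)
            if tic is None or tic.intensities.sum() == 0 or ref_tic is None:
                logger.warning("run %s has no anchor signal; identity warp applied", sid)
                warp = None
            else:
                _, warp, _ = cow_align(tic, ref_tic, params)
            warps[sid] = warp
            for key, per in store.items():
                if sid not in per:
                    continue
                grid = ref_grids.get(key, common_grid)
                if warp is None:
                    chrom = per[sid]
                    vals = np.interp(grid, chrom.times, chrom.intensities)
                    aligned[key][sid] = Chromatogram(key, grid, vals, sample_id=sid)
                else:
                    aligned[key][sid] = warp.apply(per[sid], grid)
        elif mode == "per_transition":
            for key, per in store.items():
                if sid not in per or reference_id not in per:
                    continue
                a, w, _ = cow_align(per[sid], per[reference_id], params)
                aligned[key][sid] = a
        else:
            raise ValueError(f"unknown alignment mode {mode!r}")
    return aligned, warps
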