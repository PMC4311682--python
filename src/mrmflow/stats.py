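"""Final exports: PCA scores for class separation and the run summary."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .model import FLAG_GAP_FILLED, FLAG_PURE_ISOTOPE, PeakMatrix
from .identify import IdentificationResult
from .isotope import IsotopeAssignment

__all__ = ["PcaResult", "RunReport", "pca_scores", "summarize_run"]


@dataclass
class PcaResult:
    scores: pd.DataFrame  # samples x components
    explained_variance_ratio: np.ndarray
    loadings: pd.DataFrame  # features x components


def pca_scores(
    matrix: PeakMatrix,
    k: int = 2,
    scaling: str = "unit_variance",
    max_gap_fraction: float = 0.5,
) -> PcaResult:
    """Sample scores from a column-centered (optionally unit-variance) PCA.

    Features flagged pure_isotope anywhere, or gap-filled in more than
    ``max_gap_fraction`` of samples, are excluded — gap-filled zeros would
    otherwise dominate the variance.  The component sign is fixed by making
    the largest-magnitude loading positive, so scores are reproducible and
    invariant to feature order.
    """
    if scaling not in ("unit_variance", "none"):
        raise ValueError(f"unknown scaling {scaling!r}")
    keep = []
    n_samples = len(matrix.sample_ids)
    for fid in matrix.feature_ids:
        fl = matrix.flags.loc[fid]
        if (fl == FLAG_PURE_ISOTOPE).any():
            continue
        if (fl == FLAG_GAP_FILLED).sum() > max_gap_fraction * n_samples:
            continue
        keep.append(fid)
    X = matrix.values.loc[keep].to_numpy(dtype=float).T  # samples x features
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("PCA needs at least 2 samples and 2 usable features")
    sd = X.std(axis=0, ddof=0)
    if np.all(sd == 0):
        raise ValueError("constant matrix: PCA undefined")
    if scaling == "unit_variance":
        ok = sd > 0
        keep = [f for f, o in zip(keep, ok) if o]
        X = (X[:, ok] - X[:, ok].mean(axis=0)) / sd[ok]
    k = min(k, min(X.shape) - 0 if scaling == "none" else min(X.shape))
    k = min(k, np.linalg.matrix_rank(X - X.mean(axis=0)))
    k = max(k, 1)
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_.T  # features x k
    for c in range(k):
        j = int(np.argmax(np.abs(loadings[:, c])))
        if loadings[j, c] < 0:
            loadings[:, c] *= -1
            scores[:, c] *= -1
    comp_names = [f"PC{i + 1}" for i in range(k)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=matrix.sample_ids, columns=comp_names),
        explained_variance_ratio=pca.explained_variance_ratio_,
        loadings=pd.DataFrame(loadings, index=keep, columns=comp_names),
    )


@dataclass
class RunReport:
    n_features: int
    n_annotated: int
    n_unknown: int
    n_pure_isotope: int
    n_gap_filled_cells: int
    n_samples: int

    def to_text(self) -> str:
        return (
            f"features: {self.n_features}\n"
            f"annotated: {self.n_annotated}\n"
            f"unknown: {self.n_unknown}\n"
            f"pure isotopic peaks dismissed: {self.n_pure_isotope}\n"
            f"gap-filled cells: {self.n_gap_filled_cells}\n"
            f"samples: {self.n_samples}\n"
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def summarize_run(
    matrix: PeakMatrix,
    identifications: list[IdentificationResult] | None = None,
    isotope_assignments: list[IsotopeAssignment] | None = None,
) -> RunReport:
    """Accounting of the finished pipeline: annotated vs unknown features,
    pure-isotope dismissals, gap-filled cells."""
    identifications = identifications or []
    isotope_assignments = isotope_assignments or []
    dismissed = {
        fid
        for fid in matrix.feature_ids
        if (matrix.flags.loc[fid] == FLAG_PURE_ISOTOPE).any()
    }
    annotated = sum(1 for r in identifications if r.annotated and r.feature_id not in dismissed)
    n_feat = len(matrix.feature_ids)
    return RunReport(
        n_features=n_feat,
        n_annotated=annotated,
        n_unknown=n_feat - annotated - len(dismissed),
        n_pure_isotope=len(dismissed),
        n_gap_filled_cells=int((matrix.flags == FLAG_GAP_FILLED).to_numpy().sum()),
        n_samples=len(matrix.sample_ids),
    )
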