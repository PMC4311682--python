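"""Feature annotation against the user library by retention-time accuracy.

On a triple quadrupole the transition itself carries most of the specificity,
so identification reduces to matching retention time within a channel.  The
score is a Gaussian of the RT deviation,

    score = exp(-0.5 * ((rt_act - rt_lib) / sigma)**2),

ranging from 0 (inconsistent) to 1 (confident); features scoring at or above
the acceptance threshold (default 0.7) are annotated.  Isomer pairs sharing a
transition are disambiguated by a global greedy assignment: best score first,
each library entry used at most once.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .model import FeatureInfo, LibraryEntry

__all__ = ["IdentificationResult", "rt_accuracy", "annotate_features"]


def rt_accuracy(rt_act: float, rt_lib: float, tolerance: float) -> float:
    """Gaussian retention-time accuracy score in (0, 1]."""
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    z = (rt_act - rt_lib) / tolerance
    return math.exp(-0.5 * z * z)


@dataclass
class IdentificationResult:
    feature_id: str
    entry: LibraryEntry | None
    score: float
    candidates: list[tuple[LibraryEntry, float]] = field(default_factory=list)

    @property
    def annotated(self) -> bool:
        return self.entry is not None


def annotate_features(
    features: list[FeatureInfo],
    library: list[LibraryEntry],
    tolerance: float = 0.2,
    threshold: float = 0.7,
) -> list[IdentificationResult]:
    """Assign library entries to features, at most one each way.

    Candidates share the feature's transition key exactly.  Pairs scoring
    below ``threshold`` are never accepted.  Assignment is globally greedy by
    descending score, ties broken by smaller |RT deviation|, then library
    order — deterministic, and near-ties surface in the candidate lists for
    curation.  Accepted annotations (name, score, formula) are also written
    back onto the FeatureInfo objects.
    """
    by_key: dict = {}
    for j, e in enumerate(library):
        by_key.setdefault(e.transition, []).append((j, e))
    pairs = []  # (score, |dRT|, lib order, feature order, feature, entry)
    cand_lists: dict[str, list[tuple[LibraryEntry, float]]] = {f.feature_id: [] for f in features}
    for i, f in enumerate(features):
        for j, e in by_key.get(f.transition, []):
            s = rt_accuracy(f.top_rt, e.expected_rt, tolerance)
            cand_lists[f.feature_id].append((e, s))
            if s >= threshold:
                pairs.append((s, abs(f.top_rt - e.expected_rt), j, i, f, e))
    pairs.sort(key=lambda p: (-p[0], p[1], p[2], p[3]))
    taken_features: set[str] = set()
    taken_entries: set[int] = set()
    accepted: dict[str, tuple[LibraryEntry, float]] = {}
    for s, _, j, _, f, e in pairs:
        if f.feature_id in taken_features or j in taken_entries:
            continue
        taken_features.add(f.feature_id)
        taken_entries.add(j)
        accepted[f.feature_id] = (e, s)
    results = []
    for f in features:
        cands = sorted(cand_lists[f.feature_id], key=lambda c: -c[1])
        if f.feature_id in accepted:
            e, s = accepted[f.feature_id]
            f.annotation, f.annotation_score, f.formula = e.name, s, dict(e.formula)
            results.append(IdentificationResult(f.feature_id, e, s, cands))
        else:
            f.annotation, f.annotation_score, f.formula = None, float("nan"), None
            results.append(IdentificationResult(f.feature_id, None, 0.0, cands))
    return results
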