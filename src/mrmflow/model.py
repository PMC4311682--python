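"""Core domain types for MRM/SRM chromatogram processing.

An MRM (multiple-reaction-monitoring) experiment records, for each *transition*
(a fixed precursor m/z -> product m/z pair on a triple quadrupole), the ion
intensity as a function of retention time — one chromatogram per transition per
injection.  These types carry a study through the pipeline: raw traces, the
sample sheet, the user compound library, and the rectangular peak matrix that
downstream statistics consume.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "TransitionKey",
    "Chromatogram",
    "SampleRecord",
    "LibraryEntry",
    "PeakObservation",
    "FeatureInfo",
    "PeakMatrix",
    "parse_formula",
    "formula_to_string",
]

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")

# Cell flags: every matrix cell carries exactly one of these.
FLAG_DETECTED = "detected"
FLAG_GAP_FILLED = "gap_filled"
FLAG_PURE_ISOTOPE = "pure_isotope"


def parse_formula(formula: str) -> dict[str, int]:
    """Parse an elemental composition string like ``'C22H46NO7P'``.

    Returns a dict of element -> count.  Raises ``ValueError`` for strings
    that are not a plain element/count sequence or contain no atoms.
    """
    if not formula or not isinstance(formula, str):
        raise ValueError(f"empty or non-string formula: {formula!r}")
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(formula):
        if m.start() != pos:
            raise ValueError(f"unparseable formula {formula!r} at position {pos}")
        el, n = m.group(1), m.group(2)
        counts[el] = counts.get(el, 0) + (int(n) if n else 1)
        pos = m.end()
    if pos != len(formula):
        raise ValueError(f"unparseable formula {formula!r} at position {pos}")
    if not counts or sum(counts.values()) < 1:
        raise ValueError(f"formula {formula!r} contains no atoms")
    return counts


def formula_to_string(counts: dict[str, int]) -> str:
    order = ["C", "H", "N", "O", "P", "S"]
    keys = [e for e in order if e in counts] + sorted(set(counts) - set(order))
    return "".join(f"{e}{counts[e] if counts[e] != 1 else ''}" for e in keys)


@dataclass(frozen=True, order=True)
class TransitionKey:
    """A QqQ acquisition channel: precursor/product m/z at 1-decimal precision.

    Channels are configured, not measured, so matching across runs is exact
    equality on the rounded values rather than a tolerance window.
    """

    precursor_mz: float
    product_mz: float
    polarity: str = "positive"

    def __post_init__(self):
        object.__setattr__(self, "precursor_mz", round(float(self.precursor_mz), 1))
        object.__setattr__(self, "product_mz", round(float(self.product_mz), 1))
        pol = str(self.polarity).strip().lower()
        if pol not in ("positive", "negative"):
            raise ValueError(f"polarity must be positive/negative, got {self.polarity!r}")
        object.__setattr__(self, "polarity", pol)
        if self.precursor_mz <= 0 or self.product_mz <= 0:
            raise ValueError("transition m/z values must be positive")

    def __str__(self) -> str:
        sign = "+" if self.polarity == "positive" else "-"
        return f"{self.precursor_mz:g}>{self.product_mz:g}{sign}"


@dataclass
class Chromatogram:
    """One transition's intensity-vs-time trace for one run.

    ``times`` are minutes, strictly increasing; ``intensities`` are floored at
    zero on construction (detector baseline artifacts otherwise break the
    centroid and correlation math).
    """

    transition: TransitionKey
    times: np.ndarray
    intensities: np.ndarray
    sample_id: str | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.intensities.shape:
            raise ValueError("times and intensities must be 1-D arrays of equal length")
        if len(self.times) < 2:
            raise ValueError("a chromatogram needs at least 2 data points")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        self.intensities = np.maximum(self.intensities, 0.0)

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class SampleRecord:
    sample_id: str
    path: str
    class_label: str
    injection_order: int
    sample_type: str  # biological | QC | blank

    def __post_init__(self):
        st = str(self.sample_type).strip()
        norm = {"qc": "QC", "biological": "biological", "blank": "blank"}
        key = st.lower()
        if key not in norm:
            raise ValueError(f"sample_type must be biological/QC/blank, got {st!r}")
        self.sample_type = norm[key]
        self.injection_order = int(self.injection_order)
        if self.injection_order <= 0:
            raise ValueError("injection_order must be a positive integer")


@dataclass
class LibraryEntry:
    """One row of the user compound library: name, formula, transition, RT."""

    name: str
    formula: dict[str, int]
    transition: TransitionKey
    expected_rt: float

    def __post_init__(self):
        if isinstance(self.formula, str):
            self.formula = parse_formula(self.formula)
        if self.expected_rt <= 0:
            raise ValueError(f"expected_rt must be positive, got {self.expected_rt}")


@dataclass
class PeakObservation:
    """A peak propagated to one sample: apex, edges, height, area."""

    sample_id: str
    feature_id: str
    top_rt: float
    left_rt: float
    right_rt: float
    height: float
    area: float = 0.0
    gap_filled: bool = False

    def __post_init__(self):
        if not (self.left_rt <= self.top_rt <= self.right_rt):
            raise ValueError("peak edges must bracket the apex")
        if self.height < 0:
            raise ValueError("peak height must be non-negative")


@dataclass
class FeatureInfo:
    """Metadata for one feature (a representative peak on one transition)."""

    feature_id: str
    transition: TransitionKey
    top_rt: float
    left_rt: float
    right_rt: float
    annotation: str | None = None
    annotation_score: float = float("nan")
    formula: dict[str, int] | None = None


@dataclass
class PeakMatrix:
    """Rectangular features x samples table of peak heights with per-cell flags.

    ``values`` and ``flags`` are DataFrames indexed by feature_id with one
    column per sample_id; every cell carries exactly one flag from
    {detected, gap_filled, pure_isotope}.  ``areas`` mirrors ``values`` with
    trapezoidal peak areas (stored but unused by default — peak height is the
    recommended quantifier on QqQ instruments).
    """

    features: list[FeatureInfo]
    values: pd.DataFrame
    flags: pd.DataFrame
    areas: pd.DataFrame | None = None

    def __post_init__(self):
        ids = [f.feature_id for f in self.features]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate feature ids")
        if list(self.values.index) != ids or list(self.flags.index) != ids:
            raise ValueError("values/flags index must equal the feature id list")
        if list(self.values.columns) != list(self.flags.columns):
            raise ValueError("values and flags must share sample columns")
        valid = {FLAG_DETECTED, FLAG_GAP_FILLED, FLAG_PURE_ISOTOPE}
        bad = set(np.unique(self.flags.to_numpy())) - valid if self.flags.size else set()
        if bad:
            raise ValueError(f"unknown cell flags: {sorted(bad)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def feature_ids(self) -> list[str]:
        return [f.feature_id for f in self.features]

    def feature(self, feature_id: str) -> FeatureInfo:
        for f in self.features:
            if f.feature_id == feature_id:
                return f
        raise KeyError(feature_id)

    def copy(self) -> "PeakMatrix":
        return PeakMatrix(
            features=[replace(f) for f in self.features],
            values=self.values.copy(),
            flags=self.flags.copy(),
            areas=None if self.areas is None else self.areas.copy(),
        )
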