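"""Nominal-mass isotopologue distributions and isotopic-interference correction.

A triple quadrupole resolves only unit (nominal) mass, so the heavy-isotope
envelope of an abundant species shows up as peaks on the transitions k m/z
above its precursor that share the same product ion.  This module computes
the theoretical M+0..M+6 envelope of a molecular formula by full convolution
of the per-element isotope vectors (cross-terms such as 13C x 2H are kept —
at the fourth decimal of the M+2 ratio they are what separates two species
differing by two hydrogens), then uses it to classify candidate child peaks
as pure isotopic peaks, partial overlaps with a co-eluting isomer, or
unrelated signals, and to subtract the isotopic share from child abundances.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .model import FLAG_PURE_ISOTOPE, FeatureInfo, PeakMatrix, parse_formula

__all__ = [
    "DEFAULT_ISOTOPE_TABLE",
    "IsotopeDistribution",
    "IsotopeAssignment",
    "isotope_distribution",
    "enumerate_isotopologues",
    "find_isotope_candidates",
    "resolve_isotopes",
]

# IUPAC representative natural abundances, indexed by nominal-mass offset
# from the lightest isotope.
DEFAULT_ISOTOPE_TABLE: dict[str, list[float]] = {
    "C": [0.9893, 0.0107],
    "H": [0.999885, 0.000115],
    "N": [0.99636, 0.00364],
    "O": [0.99757, 0.00038, 0.00205],
    "P": [1.0],
    "S": [0.9499, 0.0075, 0.0425, 0.0, 0.0001],  # 32/33/34/36S
}


@dataclass
class IsotopeDistribution:
    """Relative abundances r_0..r_max at integer nominal-mass offsets,
    normalized so the monoisotopic term r_0 == 1."""

    ratios: np.ndarray

    def __post_init__(self):
        self.ratios = np.asarray(self.ratios, dtype=float)
        if self.ratios[0] != 1.0 or np.any(self.ratios < 0):
            raise ValueError("ratios must start at 1 and be non-negative")

    def __getitem__(self, k: int) -> float:
        return float(self.ratios[k])

    @property
    def max_offset(self) -> int:
        return len(self.ratios) - 1


def _validate_table(table: dict[str, list[float]]) -> None:
    for el, ab in table.items():
        if abs(sum(ab) - 1.0) > 1e-6:
            raise ValueError(f"isotope abundances for {el} must sum to 1")
        if any(a < 0 for a in ab):
            raise ValueError(f"negative abundance for {el}")


def isotope_distribution(
    formula: dict[str, int] | str,
    table: dict[str, list[float]] | None = None,
    max_offset: int = 6,
) -> IsotopeDistribution:
    """Theoretical nominal-mass envelope of ``formula`` up to ``max_offset``.

    The per-element abundance vectors are raised to the atom counts by
    repeated truncated convolution (the expansion of the product of
    per-atom isotope polynomials, binned at integer offsets) and divided by
    the monoisotopic term.
    """
    if isinstance(formula, str):
        formula = parse_formula(formula)
    table = DEFAULT_ISOTOPE_TABLE if table is None else table
    _validate_table(table)
    acc = np.array([1.0])
    for el, n in formula.items():
        if el not in table:
            raise ValueError(f"element {el!r} missing from the isotope table")
        if n < 0:
            raise ValueError(f"negative atom count for {el}")
        base = np.asarray(table[el], dtype=float)
        # exponentiation by squaring on truncated polynomials
        power = np.array([1.0])
        sq = base
        k = n
        while k:
            if k & 1:
                power = np.convolve(power, sq)[: max_offset + 1]
            k >>= 1
            if k:
                sq = np.convolve(sq, sq)[: max_offset + 1]
        acc = np.convolve(acc, power)[: max_offset + 1]
    if acc[0] <= 0:
        raise ValueError("monoisotopic abundance is zero; cannot normalize")
    out = np.zeros(max_offset + 1)
    out[: len(acc)] = acc / acc[0]
    return IsotopeDistribution(out)


def enumerate_isotopologues(
    formula: dict[str, int] | str,
    table: dict[str, list[float]] | None = None,
    max_offset: int = 6,
) -> IsotopeDistribution:
    """Exhaustive enumeration over all isotopologue tuples (oracle).

    Exponential in the atom count — only feasible for tiny formulas; used to
    cross-check the convolution route.
    """
    if isinstance(formula, str):
        formula = parse_formula(formula)
    table = DEFAULT_ISOTOPE_TABLE if table is None else table
    atoms: list[list[tuple[int, float]]] = []
    for el, n in formula.items():
        iso = list(enumerate(table[el]))
        atoms.extend([iso] * n)
    mass: dict[int, float] = {}
    for combo in itertools.product(*atoms):
        offset = sum(o for o, _ in combo)
        if offset > max_offset:
            continue
        prob = math.prod(a for _, a in combo)
        mass[offset] = mass.get(offset, 0.0) + prob
    out = np.zeros(max_offset + 1)
    for off, p in mass.items():
        out[off] = p
    return IsotopeDistribution(out / out[0])


@dataclass
class IsotopeAssignment:
    """Verdict for one candidate parent/child pair on one M+k ladder step."""

    parent_id: str
    child_id: str
    offset: int
    r_k: float
    expected_child_height: float  # study-median expectation, for reporting
    isotopic_fraction: float  # median share of child abundance explained
    verdict: str  # pure_isotope | partial_overlap | not_isotope


def find_isotope_candidates(
    features: list[FeatureInfo],
    max_offset: int = 6,
    coelution_tol_min: float = 1.0 / 60.0,
) -> list[tuple[FeatureInfo, FeatureInfo, int]]:
    """Candidate (parent, child, k) pairs for isotopic interference.

    Criteria: the child's precursor sits k in 1..max_offset nominal mass
    units above an annotated parent's precursor on the same product ion and
    polarity, and the peak tops co-elute within ``coelution_tol_min``
    (default 1 s).  Parents must carry a formula (an accepted annotation);
    without one no theoretical ratio exists.
    """
    out = []
    for parent in features:
        if parent.formula is None:
            continue
        for child in features:
            if child is parent:
                continue
            t_p, t_c = parent.transition, child.transition
            if t_c.product_mz != t_p.product_mz or t_c.polarity != t_p.polarity:
                continue
            k = round(t_c.precursor_mz - t_p.precursor_mz)
            if not (1 <= k <= max_offset):
                continue
            if abs(child.top_rt - parent.top_rt) > coelution_tol_min + 1e-12:
                continue
            out.append((parent, child, k))
    return out


def resolve_isotopes(
    candidates: list[tuple[FeatureInfo, FeatureInfo, int]],
    matrix: PeakMatrix,
    table: dict[str, list[float]] | None = None,
    purity_threshold: float = 0.05,
    per_feature_vote: bool = True,
) -> tuple[list[IsotopeAssignment], PeakMatrix]:
    """Estimate and subtract isotopic contributions; flag pure isotopic peaks.

    Per sample: expected child = parent height x r_k.  A child taller than
    its parent is not an isotopic peak and is left untouched.  Otherwise the
    expected share is subtracted; if the corrected abundance falls below
    ``purity_threshold`` of the observed child, the cell is a pure isotopic
    peak.  With ``per_feature_vote`` (default) the verdict is decided per
    feature by majority across samples, so a feature is either dismissed
    everywhere or corrected everywhere.
    """
    corrected = matrix.copy()
    assignments: list[IsotopeAssignment] = []
    for parent, child, k in candidates:
        dist = isotope_distribution(parent.formula, table=table, max_offset=max(6, k))
        r_k = dist[k]
        verdicts, fractions, expected_all = [], [], []
        new_child = corrected.values.loc[child.feature_id].copy()
        for sid in corrected.sample_ids:
            p_h = float(corrected.values.at[parent.feature_id, sid])
            c_h = float(corrected.values.at[child.feature_id, sid])
            expected = p_h * r_k
            expected_all.append(expected)
            if c_h > p_h or (p_h == 0 and c_h > 0):
                verdicts.append("not_isotope")
                fractions.append(0.0)
                continue
            if c_h == 0:
                verdicts.append("pure_isotope")
                fractions.append(0.0)
                new_child[sid] = 0.0
                continue
            frac = min(1.0, expected / c_h)
            corr = c_h - min(expected, c_h)
            fractions.append(frac)
            if corr <= purity_threshold * c_h:
                verdicts.append("pure_isotope")
                new_child[sid] = corr
            else:
                verdicts.append("partial_overlap")
                new_child[sid] = corr
        if per_feature_vote:
            order = ["pure_isotope", "partial_overlap", "not_isotope"]
            counts = {v: verdicts.count(v) for v in order}
            verdict = max(order, key=lambda v: counts[v])
        else:
            verdict = max(set(verdicts), key=verdicts.count) if verdicts else "not_isotope"
        if verdict == "not_isotope":
            pass  # leave the child untouched
        elif verdict == "pure_isotope":
            corrected.values.loc[child.feature_id] = new_child
            corrected.flags.loc[child.feature_id] = FLAG_PURE_ISOTOPE
        else:
            corrected.values.loc[child.feature_id] = new_child
        assignments.append(
            IsotopeAssignment(
                parent_id=parent.feature_id,
                child_id=child.feature_id,
                offset=k,
                r_k=r_k,
                expected_child_height=float(np.median(expected_all)) if expected_all else 0.0,
                isotopic_fraction=float(np.median(fractions)) if fractions else 0.0,
                verdict=verdict,
            )
        )
    return assignments, corrected
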