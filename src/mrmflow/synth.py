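"""Synthetic MRM studies with known ground truth.

Emulates the structure of a pooled-QC lipidomics batch: biological samples
from two or more classes with a pooled QC (the per-class mean composition)
injected at every ``qc_every``-th position, Gaussian chromatographic peaks,
a smooth monotone retention-time warp per run, a low-frequency multiplicative
intensity drift across the injection sequence, isomer pairs sharing a
transition, and M+k isotopic companion peaks emitted on the transition k m/z
above a parent with the theoretical intensity ratio.  Every generated
quantity (true heights, true apex positions, true warps) is returned as a
truth table so each pipeline stage can be tested against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .io import write_chromatogram_tsv, write_sample_sheet
from .isotope import isotope_distribution
from .model import Chromatogram, LibraryEntry, SampleRecord, TransitionKey

__all__ = [
    "RTDrift",
    "IntensityDrift",
    "SynthCompound",
    "SynthSpec",
    "Study",
    "default_compounds",
    "generate_study",
]

_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass
class RTDrift:
    """Per-run smooth monotone time warp.

    ``linear`` profile spreads the realized magnitude evenly from -max_shift
    to +max_shift across the injection sequence; ``random`` draws it
    uniformly.  Kinds: global ``shift``, linear ``stretch`` (zero at the run
    start, full shift at the end), and a two-knot monotone ``spline`` warp —
    spanning what COW with small slack can and cannot fully undo.
    """

    kind: str = "none"  # none | shift | stretch | spline
    max_shift: float = 0.0  # minutes
    profile: str = "linear"  # linear | random

    def __post_init__(self):
        if self.kind not in ("none", "shift", "stretch", "spline"):
            raise ValueError(f"unknown drift kind {self.kind!r}")
        if self.profile not in ("linear", "random"):
            raise ValueError(f"unknown drift profile {self.profile!r}")


@dataclass
class IntensityDrift:
    """Multiplicative response drift as a function of injection order."""

    kind: str = "none"  # none | linear
    decay: float = 0.0  # fraction lost over the whole batch

    def factor(self, order: int, n_runs: int) -> float:
        if self.kind == "none" or n_runs < 2:
            return 1.0
        return 1.0 - self.decay * (order - 1) / (n_runs - 1)


@dataclass
class SynthCompound:
    entry: LibraryEntry
    abundance: dict[str, float]  # class label -> true peak height
    peak_sd: float = 0.5 / _FWHM  # minutes; default 0.5 min FWHM
    drift_free: bool = False  # e.g. a spiked internal standard added post-drift
    isotope_partner_mz: float | None = None  # emit the M+k companion on this precursor


@dataclass
class SynthSpec:
    n_bio: int = 20
    qc_every: int = 5
    classes: tuple[str, ...] = ("A", "B")
    compounds: list[SynthCompound] = field(default_factory=lambda: default_compounds())
    rt_drift: RTDrift = field(default_factory=RTDrift)
    intensity_drift: IntensityDrift = field(default_factory=IntensityDrift)
    noise_sd: float = 0.0  # counts
    seed: int = 0
    t_start: float = 0.0
    t_end: float = 45.0
    dt: float = 0.05  # minutes per scan (~5 scans across a minimal peak)

    def __post_init__(self):
        if self.qc_every < 1:
            raise ValueError("qc_every must be >= 1")
        span = self.t_end - self.t_start
        if abs(self.rt_drift.max_shift) >= span / 4:
            raise ValueError("rt drift max_shift must stay below a quarter of the run span")
        if self.n_bio < 1:
            raise ValueError("n_bio must be >= 1")


@dataclass
class Study:
    samples: list[SampleRecord]
    store: dict[TransitionKey, dict[str, Chromatogram]]
    truth: pd.DataFrame  # per (sample, peak): true height and apex
    warps: dict[str, object]  # sample_id -> callable minute->minute
    library: list[LibraryEntry]

    @property
    def qc_samples(self) -> list[SampleRecord]:
        return [s for s in self.samples if s.sample_type == "QC"]


def default_compounds() -> list[SynthCompound]:
    """A small serum-like panel: a lyso-lipid isomer pair sharing a channel,
    an abundant ether lipid whose M+2 envelope lands on the channel two m/z
    up (plus a genuine isomer there), a drift-free internal standard, and a
    negative-mode free fatty acid."""
    return [
        SynthCompound(
            LibraryEntry("lysoPC 14:0 (sn-2)", "C22H46NO7P", TransitionKey(468.3, 184.1), 6.34),
            {"A": 30000.0, "B": 12000.0},
        ),
        SynthCompound(
            LibraryEntry("lysoPC 14:0 (sn-1)", "C22H46NO7P", TransitionKey(468.3, 184.1), 7.03),
            {"A": 8000.0, "B": 20000.0},
        ),
        SynthCompound(
            LibraryEntry("PC 38:5e", "C45H82NO7P", TransitionKey(794.6, 184.1), 25.41),
            {"A": 80000.0, "B": 60000.0},
            isotope_partner_mz=796.6,
        ),
        SynthCompound(
            LibraryEntry("PC 38:4e", "C45H84NO7P", TransitionKey(796.6, 184.1), 26.85),
            {"A": 15000.0, "B": 40000.0},
        ),
        SynthCompound(
            LibraryEntry("PC 24:0 (IS)", "C32H64NO8P", TransitionKey(622.4, 184.1), 17.70),
            {"A": 25000.0, "B": 25000.0},
            drift_free=True,
        ),
        SynthCompound(
            LibraryEntry(
                "FFA 16:0", "C16H32O2", TransitionKey(255.1, 255.1, "negative"), 11.02
            ),
            {"A": 18000.0, "B": 28000.0},
        ),
    ]


def _injection_sequence(spec: SynthSpec) -> list[SampleRecord]:
    samples: list[SampleRecord] = []
    placed_bio = 0
    order = 0
    while placed_bio < spec.n_bio:
        order += 1
        if spec.qc_every >= 1 and order % spec.qc_every == 0:
            samples.append(SampleRecord(f"QC{order:03d}", "", "QC", order, "QC"))
        else:
            cls = spec.classes[placed_bio % len(spec.classes)]
            placed_bio += 1
            samples.append(SampleRecord(f"S{order:03d}", "", cls, order, "biological"))
    return samples


def _make_warp(spec: SynthSpec, magnitude: float):
    t0, t1 = spec.t_start, spec.t_end
    kind = spec.rt_drift.kind
    if kind == "none" or magnitude == 0.0:
        return lambda t: np.asarray(t, dtype=float) + 0.0
    if kind == "shift":
        return lambda t: np.asarray(t, dtype=float) + magnitude
    if kind == "stretch":
        return lambda t: np.asarray(t, dtype=float) + magnitude * (
            np.asarray(t, dtype=float) - t0
        ) / (t1 - t0)
    # two-knot monotone spline warp
    k1, k2 = t0 + (t1 - t0) / 3.0, t0 + 2.0 * (t1 - t0) / 3.0
    x = np.array([t0, k1, k2, t1])
    y = np.array([t0, k1 + magnitude, k2 + 0.5 * magnitude, t1])
    if np.any(np.diff(y) <= 0):
        raise ValueError("spline warp magnitude breaks monotonicity")
    return PchipInterpolator(x, y)


def generate_study(spec: SynthSpec, outdir: str | Path | None = None) -> Study:
    """Generate a complete synthetic study; optionally write it to disk.

    With ``outdir`` set, emits one chromatogram-dialect TSV per run, the
    sample sheet, a compound library TSV, and the truth tables.  A fixed
    seed makes the output byte-identical across calls.
    """
    rng = np.random.default_rng(spec.seed)
    samples = _injection_sequence(spec)
    n_runs = len(samples)
    grid = spec.t_start + spec.dt * np.arange(int(round((spec.t_end - spec.t_start) / spec.dt)) + 1)

    # one peak record per (compound or companion) per transition
    peak_defs = []  # (transition, label, compound, height_by_class, is_companion, r_k)
    for c in spec.compounds:
        peak_defs.append((c.entry.transition, c.entry.name, c, 1.0))
        if c.isotope_partner_mz is not None:
            t = c.entry.transition
            partner = TransitionKey(c.isotope_partner_mz, t.product_mz, t.polarity)
            k = round(partner.precursor_mz - t.precursor_mz)
            if not (1 <= k <= 6):
                raise ValueError("isotope partner must sit 1..6 nominal masses above the parent")
            r_k = isotope_distribution(c.entry.formula)[k]
            peak_defs.append((partner, f"{c.entry.name} [M+{k}]", c, r_k))

    transitions = sorted({p[0] for p in peak_defs})
    qc_abundance = {
        c.entry.name: float(np.mean([c.abundance[cl] for cl in spec.classes]))
        for c in spec.compounds
    }

    # realized warp magnitudes
    mags = {}
    for s in samples:
        if spec.rt_drift.profile == "linear":
            frac = 0.0 if n_runs < 2 else 2.0 * (s.injection_order - 1) / (n_runs - 1) - 1.0
            mags[s.sample_id] = spec.rt_drift.max_shift * frac
        else:
            mags[s.sample_id] = float(rng.uniform(-spec.rt_drift.max_shift, spec.rt_drift.max_shift))
    warps = {s.sample_id: _make_warp(spec, mags[s.sample_id]) for s in samples}

    store: dict[TransitionKey, dict[str, Chromatogram]] = {t: {} for t in transitions}
    truth_rows = []
    for s in samples:
        warp = warps[s.sample_id]
        drift_factor = spec.intensity_drift.factor(s.injection_order, n_runs)
        traces = {t: np.zeros_like(grid) for t in transitions}
        for key, label, comp, ratio in peak_defs:
            base = (
                qc_abundance[comp.entry.name]
                if s.sample_type == "QC"
                else comp.abundance[s.class_label]
            )
            h = base * ratio * (1.0 if comp.drift_free else drift_factor)
            center = float(warp(comp.entry.expected_rt))
            traces[key] += h * np.exp(-0.5 * ((grid - center) / comp.peak_sd) ** 2)
            truth_rows.append(
                {
                    "sample_id": s.sample_id,
                    "injection_order": s.injection_order,
                    "sample_type": s.sample_type,
                    "class": s.class_label,
                    "peak": label,
                    "precursor_mz": key.precursor_mz,
                    "product_mz": key.product_mz,
                    "polarity": key.polarity,
                    "true_height": h,
                    "true_top_rt": center,
                    "unwarped_rt": comp.entry.expected_rt,
                }
            )
        for key in transitions:
            y = traces[key]
            if spec.noise_sd > 0:
                y = y + rng.normal(0.0, spec.noise_sd, size=y.shape)
            store[key][s.sample_id] = Chromatogram(
                transition=key, times=grid, intensities=y, sample_id=s.sample_id
            )

    truth = pd.DataFrame(truth_rows)
    library = [c.entry for c in spec.compounds]
    study = Study(samples=samples, store=store, truth=truth, warps=warps, library=library)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for s in samples:
            chroms = [store[t][s.sample_id] for t in transitions]
            write_chromatogram_tsv(chroms, outdir / f"{s.sample_id}.tsv")
            s.path = f"{s.sample_id}.tsv"  # relative to the sample sheet
        write_sample_sheet(samples, outdir / "samples.csv")
        lib_rows = pd.DataFrame(
            {
                "name": [e.name for e in library],
                "formula": [
                    "".join(f"{el}{n if n != 1 else ''}" for el, n in e.formula.items())
                    for e in library
                ],
                "precursor_mz": [e.transition.precursor_mz for e in library],
                "product_mz": [e.transition.product_mz for e in library],
                "rt_min": [e.expected_rt for e in library],
                "ion_mode": [e.transition.polarity for e in library],
            }
        )
        lib_rows.to_csv(outdir / "library.tsv", sep="\t", index=False)
        truth.to_csv(outdir / "truth_peaks.tsv", sep="\t", index=False)
        knots = np.linspace(spec.t_start, spec.t_end, 46)
        warp_rows = []
        for s in samples:
            w = warps[s.sample_id]
            for t in knots:
                warp_rows.append(
                    {"sample_id": s.sample_id, "time_min": t, "warped_min": float(w(t))}
                )
        pd.DataFrame(warp_rows).to_csv(outdir / "truth_warps.tsv", sep="\t", index=False)
    return study
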