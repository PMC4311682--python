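"""End-to-end batch pipeline: read -> select reference -> align -> detect ->
annotate -> resolve isotopes -> normalize -> PCA/report.

Configuration is a flat YAML mirroring the stage parameter blocks; every
effective parameter and the chosen reference are logged so a run is
self-describing, and identical config + inputs give identical outputs.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as mio
from .align import CowParams, align_study, select_reference
from .identify import annotate_features
from .isotope import find_isotope_candidates, resolve_isotopes
from .model import PeakMatrix
from .normalize import apply_drift, fit_drift_models, normalize_internal_standard, qc_rsd
from .peaks import DetectionParams, build_peak_matrix
from .stats import pca_scores, summarize_run

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    sample_sheet: str = "samples.csv"
    library: str = ""  # empty -> packaged serum lipid library
    output_dir: str = "mrmflow_out"
    seed: int = 0
    # alignment
    reference: str = "auto"
    segment_size: float = 0.5  # min
    slack: int = 1  # scans
    border_limit: str = "constant"
    alignment_mode: str = "per_file"
    # detection
    smoothing_level: int = 2  # scans
    min_peak_width: int = 5  # scans
    min_peak_height: float = 100.0  # counts
    edge_mode: str = "representative_edges"
    # identification
    rt_tolerance: float = 0.2  # min
    id_threshold: float = 0.7
    # isotopes
    max_isotope_offset: int = 6
    coelution_tol_sec: float = 1.0
    purity_threshold: float = 0.05
    # normalization
    normalization: str = "loess"  # loess | is | none
    loess_span: float = 0.5
    is_name: str = "PC 24:0; PC 12:0/12:0 (IS)"
    # stats
    pca_components: int = 2
    pca_scaling: str = "unit_variance"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as f:
            data = yaml.safe_load(f) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def cow_params(self) -> CowParams:
        return CowParams(self.segment_size, self.slack, self.border_limit)

    def detection_params(self) -> DetectionParams:
        return DetectionParams(
            smoothing_level=self.smoothing_level,
            min_peak_width=self.min_peak_width,
            min_peak_height=self.min_peak_height,
            edge_mode=self.edge_mode,
        )


@dataclass
class PipelineResult:
    reference_id: str
    matrix_raw: PeakMatrix
    matrix_corrected: PeakMatrix
    matrix_normalized: PeakMatrix
    identifications: list
    isotope_assignments: list
    report: object
    pca: object | None
    output_dir: Path


def _read_run(record) -> list:
    path = Path(record.path)
    if path.suffix.lower() == ".mzml":
        chroms = mio.read_mzml_srm(path)
    else:
        chroms = mio.read_chromatogram_tsv(path)
    for c in chroms:
        c.sample_id = record.sample_id
    return chroms


def _setup_logging(outdir: Path) -> None:
    root = logging.getLogger("mrmflow")
    for h in [h for h in root.handlers if isinstance(h, logging.FileHandler)]:
        root.removeHandler(h)
        h.close()
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root.setLevel(logging.INFO)
    root.addHandler(handler)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir)
    logger.info("pipeline parameters: %s", dataclasses.asdict(config))

    stage = "read"
    try:
        samples = mio.read_sample_sheet(config.sample_sheet)
        chroms = [c for s in samples for c in _read_run(s)]
        store = mio.group_by_transition(chroms)
        lib_path = config.library or mio.packaged_library_path()
        library = mio.read_library(lib_path)
        logger.info(
            "read %d runs, %d transitions, %d library entries",
            len(samples), len(store), len(library),
        )

        stage = "select_reference"
        if config.reference == "auto":
            qcs = [s for s in samples if s.sample_type == "QC"]
            reference_id = select_reference(qcs, store)
        else:
            reference_id = config.reference
        logger.info("reference run: %s", reference_id)

        stage = "align"
        aligned, warps = align_study(
            store, reference_id, config.cow_params(), mode=config.alignment_mode
        )
        warp_rows = []
        for sid, w in warps.items():
            if w is None:
                continue
            for rt, qt in zip(w.ref_times, w.query_times):
                warp_rows.append({"sample_id": sid, "ref_time_min": rt, "query_time_min": qt})
        pd.DataFrame(warp_rows).to_csv(outdir / "warp_paths.tsv", sep="\t", index=False)

        stage = "detect"
        matrix_raw = build_peak_matrix(aligned, reference_id, config.detection_params())
        logger.info("detected %d features", len(matrix_raw.features))

        stage = "identify"
        identifications = annotate_features(
            matrix_raw.features, library, tolerance=config.rt_tolerance,
            threshold=config.id_threshold,
        )
        mio.write_peak_matrix(matrix_raw, outdir / "peak_matrix_raw.tsv")
        pd.DataFrame(
            {
                "feature_id": [r.feature_id for r in identifications],
                "annotation": [r.entry.name if r.entry else "" for r in identifications],
                "score": [r.score for r in identifications],
                "n_candidates": [len(r.candidates) for r in identifications],
            }
        ).to_csv(outdir / "identifications.tsv", sep="\t", index=False)

        stage = "resolve_isotopes"
        candidates = find_isotope_candidates(
            matrix_raw.features,
            max_offset=config.max_isotope_offset,
            coelution_tol_min=config.coelution_tol_sec / 60.0,
        )
        assignments, matrix_corrected = resolve_isotopes(
            candidates, matrix_raw, purity_threshold=config.purity_threshold
        )
        mio.write_peak_matrix(matrix_corrected, outdir / "peak_matrix_corrected.tsv")
        pd.DataFrame(
            [
                {
                    "parent": a.parent_id,
                    "child": a.child_id,
                    "offset": a.offset,
                    "theoretical_ratio": a.r_k,
                    "isotopic_fraction": a.isotopic_fraction,
                    "verdict": a.verdict,
                }
                for a in assignments
            ]
        ).to_csv(outdir / "isotope_assignments.tsv", sep="\t", index=False)

        stage = "normalize"
        if config.normalization == "loess":
            qcs = [s for s in samples if s.sample_type == "QC"]
            if not qcs:
                raise ValueError(
                    "LOESS/cubic-spline normalization requires pooled QC injections"
                )
            models = fit_drift_models(matrix_corrected, samples, span=config.loess_span)
            matrix_normalized = apply_drift(matrix_corrected, models, samples)
        elif config.normalization == "is":
            is_fid = None
            for f in matrix_corrected.features:
                if f.annotation == config.is_name:
                    is_fid = f.feature_id
                    break
            if is_fid is None:
                raise ValueError(f"internal standard {config.is_name!r} not annotated in this study")
            matrix_normalized = normalize_internal_standard(matrix_corrected, is_fid)
        elif config.normalization == "none":
            matrix_normalized = matrix_corrected.copy()
        else:
            raise ValueError(f"unknown normalization method {config.normalization!r}")
        mio.write_peak_matrix(matrix_normalized, outdir / "peak_matrix_normalized.tsv")
        qc_ids = [s.sample_id for s in samples if s.sample_type == "QC"]
        if len(qc_ids) >= 2:
            qc_rsd(matrix_normalized, qc_ids).to_csv(outdir / "qc_rsd.tsv", sep="\t")

        stage = "report"
        pca = None
        try:
            pca = pca_scores(
                matrix_normalized, k=config.pca_components, scaling=config.pca_scaling
            )
            pca.scores.to_csv(outdir / "pca_scores.tsv", sep="\t")
        except ValueError as exc:
            logger.warning("PCA skipped: %s", exc)
        report = summarize_run(matrix_normalized, identifications, assignments)
        (outdir / "report.txt").write_text(report.to_text())
        report.to_frame().to_csv(outdir / "report.tsv", sep="\t", index=False)
    except Exception as exc:
        logger.error("pipeline failed at stage %s: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    return PipelineResult(
        reference_id=reference_id,
        matrix_raw=matrix_raw,
        matrix_corrected=matrix_corrected,
        matrix_normalized=matrix_normalized,
        identifications=identifications,
        isotope_assignments=assignments,
        report=report,
        pca=pca,
        output_dir=outdir,
    )
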