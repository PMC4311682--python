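"""Readers and writers: mzML SRM chromatograms, the long-format chromatogram
text dialect, the compound library TSV, sample sheets, and peak matrices.

The text dialect is a plain TSV with columns
``sample_id, precursor_mz, product_mz, polarity, time_min, intensity`` and is
defined to be in minutes; it exists so studies can be stored and regenerated
without binary formats.  mzML reading honours the time-unit accession and
skips non-SRM (e.g. TIC) chromatograms.
"""

from __future__ import annotations

import base64
import importlib.resources
import struct
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
from lxml import etree

from .model import (
    Chromatogram,
    FeatureInfo,
    LibraryEntry,
    PeakMatrix,
    SampleRecord,
    TransitionKey,
    formula_to_string,
    parse_formula,
)

__all__ = [
    "read_mzml_srm",
    "read_library",
    "packaged_library_path",
    "read_chromatogram_tsv",
    "write_chromatogram_tsv",
    "read_sample_sheet",
    "write_sample_sheet",
    "write_peak_matrix",
    "read_peak_matrix",
    "group_by_transition",
]

_DIALECT_COLUMNS = ["sample_id", "precursor_mz", "product_mz", "polarity", "time_min", "intensity"]


# ---------------------------------------------------------------- mzML
#
# Controlled-vocabulary accessions used below (PSI-MS / UO):
#   MS:1001473 selected reaction monitoring chromatogram
#   MS:1000827 isolation window target m/z      MS:1000130/1000129 positive/negative scan
#   MS:1000595 time array                       MS:1000515 intensity array
#   MS:1000523/1000521 64-/32-bit float         MS:1000574/1000576 zlib / no compression
#   UO:0000031 minute                           UO:0000010 second


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _cv_params(elem) -> list[dict]:
    return [dict(c.attrib) for c in elem if _local(c.tag) == "cvParam"]


def _find_child(elem, name):
    for c in elem:
        if _local(c.tag) == name:
            return c
    return None


def _has_accession(params: list[dict], accession: str) -> bool:
    return any(p.get("accession") == accession for p in params)


def _decode_binary_array(bda) -> tuple[np.ndarray, dict]:
    params = _cv_params(bda)
    binary = _find_child(bda, "binary")
    raw = base64.b64decode((binary.text or "").strip()) if binary is not None else b""
    if _has_accession(params, "MS:1000574"):  # zlib
        raw = zlib.decompress(raw)
    fmt = "f" if _has_accession(params, "MS:1000521") else "d"
    width = 4 if fmt == "f" else 8
    vals = np.array(struct.unpack(f"<{len(raw) // width}{fmt}", raw), dtype=float)
    return vals, {p.get("accession"): p for p in params}


def _isolation_target(elem) -> float | None:
    if elem is None:
        return None
    win = _find_child(elem, "isolationWindow")
    win = elem if win is None else win
    for p in _cv_params(win):
        if p.get("accession") == "MS:1000827" or "target m/z" in p.get("name", ""):
            return float(p["value"])
    return None


def read_mzml_srm(path: str | Path) -> list[Chromatogram]:
    """Read all SRM/MRM chromatograms from an mzML file.

    Non-SRM chromatograms (TIC, pressure traces, ...) are skipped.  Times are
    converted to minutes according to the declared unit accession.  An SRM
    chromatogram without precursor or product isolation targets is a hard
    error naming the chromatogram id.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    tree = etree.parse(str(path))
    out: list[Chromatogram] = []
    for chrom in tree.iter():
        if _local(chrom.tag) != "chromatogram":
            continue
        cid = chrom.get("id", "<unnamed>")
        params = _cv_params(chrom)
        if not (_has_accession(params, "MS:1001473") or cid.upper().startswith("SRM")):
            continue
        prec = _isolation_target(_find_child(chrom, "precursor"))
        prod = _isolation_target(_find_child(chrom, "product"))
        if prec is None or prod is None:
            raise ValueError(
                f"SRM chromatogram {cid!r} lacks precursor/product isolation targets"
            )
        polarity = "negative" if _has_accession(params, "MS:1000129") else "positive"
        times = intensities = None
        bdal = _find_child(chrom, "binaryDataArrayList")
        for bda in bdal if bdal is not None else []:
            if _local(bda.tag) != "binaryDataArray":
                continue
            vals, pmap = _decode_binary_array(bda)
            if "MS:1000595" in pmap:
                unit = pmap["MS:1000595"].get("unitAccession", "UO:0000031")
                times = vals / 60.0 if unit == "UO:0000010" else vals
            elif "MS:1000515" in pmap:
                intensities = vals
        if times is None or intensities is None:
            raise ValueError(f"SRM chromatogram {cid!r} lacks time or intensity arrays")
        out.append(
            Chromatogram(
                transition=TransitionKey(prec, prod, polarity),
                times=times,
                intensities=intensities,
                sample_id=path.stem,
            )
        )
    if not out:
        raise ValueError(f"{path} contains no SRM chromatograms")
    return out


# ---------------------------------------------------------------- library

def packaged_library_path() -> Path:
    """Path of the packaged serum-lipid reference library (284 transitions)."""
    return Path(importlib.resources.files("mrmflow") / "data" / "serum_lipid_library.tsv")


_LIB_ALIASES = {
    "name": "name",
    "formula": "formula",
    "molecular formula": "formula",
    "precursor_mz": "precursor_mz",
    "precursor m/z": "precursor_mz",
    "product_mz": "product_mz",
    "product m/z": "product_mz",
    "rt_min": "rt_min",
    "rt": "rt_min",
    "retention time [min]": "rt_min",
    "retention_time_min": "rt_min",
    "ion_mode": "ion_mode",
    "ion mode": "ion_mode",
    "polarity": "ion_mode",
}


def read_library(path: str | Path) -> list[LibraryEntry]:
    """Read a tab-separated compound library (name, formula, transition, RT).

    Instrument-only columns (dwell time, collision energy, biases) are
    ignored.  Duplicate (transition, RT) rows are allowed — isomer pairs
    share a channel.  Parse failures report the offending data row number.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = {}
    for c in df.columns:
        key = c.strip().lower()
        if key in _LIB_ALIASES:
            cols[_LIB_ALIASES[key]] = c
    missing = {"name", "formula", "precursor_mz", "product_mz", "rt_min", "ion_mode"} - set(cols)
    if missing:
        raise ValueError(f"library {path} is missing columns: {sorted(missing)}")
    entries: list[LibraryEntry] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        rec = dict(zip(df.columns, row))
        try:
            formula = parse_formula(str(rec[cols["formula"]]).strip())
            rt = float(rec[cols["rt_min"]])
            key = TransitionKey(
                float(rec[cols["precursor_mz"]]),
                float(rec[cols["product_mz"]]),
                str(rec[cols["ion_mode"]]),
            )
            entries.append(
                LibraryEntry(
                    name=str(rec[cols["name"]]).strip(),
                    formula=formula,
                    transition=key,
                    expected_rt=rt,
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"library {path}, data row {i}: {exc}") from exc
    return entries


# ---------------------------------------------------------------- text dialect

def write_chromatogram_tsv(chromatograms: list[Chromatogram], path: str | Path) -> None:
    frames = []
    for c in chromatograms:
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": c.sample_id,
                    "precursor_mz": c.transition.precursor_mz,
                    "product_mz": c.transition.product_mz,
                    "polarity": c.transition.polarity,
                    "time_min": c.times,
                    "intensity": c.intensities,
                }
            )
        )
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=_DIALECT_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_chromatogram_tsv(path: str | Path) -> list[Chromatogram]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = set(_DIALECT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path} is missing dialect columns: {sorted(missing)}")
    out = []
    keys = ["sample_id", "precursor_mz", "product_mz", "polarity"]
    for (sid, prec, prod, pol), grp in df.groupby(keys, sort=False):
        grp = grp.sort_values("time_min")
        out.append(
            Chromatogram(
                transition=TransitionKey(prec, prod, pol),
                times=grp["time_min"].to_numpy(),
                intensities=grp["intensity"].to_numpy(),
                sample_id=str(sid),
            )
        )
    return out


def group_by_transition(
    chromatograms: list[Chromatogram],
) -> dict[TransitionKey, dict[str, Chromatogram]]:
    """Index chromatograms as transition -> sample_id -> trace."""
    store: dict[TransitionKey, dict[str, Chromatogram]] = {}
    for c in chromatograms:
        per = store.setdefault(c.transition, {})
        if c.sample_id in per:
            raise ValueError(f"duplicate trace for {c.transition} in sample {c.sample_id}")
        per[c.sample_id] = c
    return store


# ---------------------------------------------------------------- sample sheet

def read_sample_sheet(path: str | Path) -> list[SampleRecord]:
    df = pd.read_csv(path)
    required = {"sample_id", "path", "class", "injection_order", "sample_type"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet {path} is missing columns: {sorted(missing)}")
    base = Path(path).parent
    records = [
        SampleRecord(
            sample_id=str(r["sample_id"]),
            # relative paths resolve against the sheet's own directory
            path=str(p if (p := Path(str(r["path"]))).is_absolute() else base / p),
            class_label=str(r["class"]),
            injection_order=int(r["injection_order"]),
            sample_type=str(r["sample_type"]),
        )
        for r in df.to_dict("records")
    ]
    orders = [r.injection_order for r in records]
    if len(set(orders)) != len(orders):
        raise ValueError("injection orders must be unique within a study")
    return records


def write_sample_sheet(samples: list[SampleRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "path": [s.path for s in samples],
            "class": [s.class_label for s in samples],
            "injection_order": [s.injection_order for s in samples],
            "sample_type": [s.sample_type for s in samples],
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------- peak matrix

_META_COLS = [
    "feature_id",
    "precursor_mz",
    "product_mz",
    "polarity",
    "top_rt",
    "left_rt",
    "right_rt",
    "annotation",
    "annotation_score",
    "formula",
]


def write_peak_matrix(matrix: PeakMatrix, path: str | Path) -> None:
    """Write a peak matrix as TSV: metadata columns, then per-sample
    ``height:``, ``flag:`` (and ``area:``) columns.  Lossless round trip."""
    rows = []
    for f in matrix.features:
        row = {
            "feature_id": f.feature_id,
            "precursor_mz": f.transition.precursor_mz,
            "product_mz": f.transition.product_mz,
            "polarity": f.transition.polarity,
            "top_rt": f.top_rt,
            "left_rt": f.left_rt,
            "right_rt": f.right_rt,
            "annotation": "" if f.annotation is None else f.annotation,
            "annotation_score": f.annotation_score,
            "formula": "" if f.formula is None else formula_to_string(f.formula),
        }
        for sid in matrix.sample_ids:
            row[f"height:{sid}"] = matrix.values.at[f.feature_id, sid]
            row[f"flag:{sid}"] = matrix.flags.at[f.feature_id, sid]
            if matrix.areas is not None:
                row[f"area:{sid}"] = matrix.areas.at[f.feature_id, sid]
        rows.append(row)
    cols = list(_META_COLS)
    for sid in matrix.sample_ids:
        cols += [f"height:{sid}", f"flag:{sid}"] + (
            [f"area:{sid}"] if matrix.areas is not None else []
        )
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_peak_matrix(path: str | Path) -> PeakMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"annotation": str, "formula": str},
                     float_precision="round_trip")
    sample_ids = [c.split(":", 1)[1] for c in df.columns if c.startswith("height:")]
    features = []
    for r in df.itertuples(index=False):
        rec = dict(zip(df.columns, r))
        ann = rec.get("annotation")
        ann = None if (ann is None or pd.isna(ann) or ann == "") else str(ann)
        formula = rec.get("formula")
        formula = (
            None if (formula is None or pd.isna(formula) or formula == "") else parse_formula(str(formula))
        )
        features.append(
            FeatureInfo(
                feature_id=str(rec["feature_id"]),
                transition=TransitionKey(rec["precursor_mz"], rec["product_mz"], rec["polarity"]),
                top_rt=float(rec["top_rt"]),
                left_rt=float(rec["left_rt"]),
                right_rt=float(rec["right_rt"]),
                annotation=ann,
                annotation_score=float(rec["annotation_score"]),
                formula=formula,
            )
        )
    idx = [f.feature_id for f in features]
    values = pd.DataFrame(
        {sid: df[f"height:{sid}"].to_numpy(dtype=float) for sid in sample_ids}, index=idx
    )
    flags = pd.DataFrame({sid: df[f"flag:{sid}"].astype(str).to_numpy() for sid in sample_ids}, index=idx)
    areas = None
    if any(c.startswith("area:") for c in df.columns):
        areas = pd.DataFrame(
            {sid: df[f"area:{sid}"].to_numpy(dtype=float) for sid in sample_ids}, index=idx
        )
    return PeakMatrix(features=features, values=values, flags=flags, areas=areas)
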