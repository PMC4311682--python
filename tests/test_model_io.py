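"""Domain types, formula parsing, and all readers/writers."""

import numpy as np
import pandas as pd
import pytest

from mrmflow import Chromatogram, FeatureInfo, PeakMatrix, SampleRecord, TransitionKey, parse_formula
from mrmflow.io import (
    group_by_transition,
    packaged_library_path,
    read_chromatogram_tsv,
    read_library,
    read_mzml_srm,
    read_peak_matrix,
    read_sample_sheet,
    write_chromatogram_tsv,
    write_peak_matrix,
    write_sample_sheet,
)
from mrmflow.model import FLAG_DETECTED, FLAG_PURE_ISOTOPE

from conftest import srm_chromatogram_xml, tic_chromatogram_xml, write_mzml


class TestTransitionKey:
    def test_rounds_to_one_decimal_and_compares_exactly(self):
        assert TransitionKey(468.34, 184.12) == TransitionKey(468.3, 184.1)
        assert TransitionKey(468.3, 184.1) != TransitionKey(468.4, 184.1)

    def test_polarity_normalized(self):
        assert TransitionKey(100, 50, "Positive").polarity == "positive"
        with pytest.raises(ValueError):
            TransitionKey(100, 50, "both")

    def test_rejects_nonpositive_mz(self):
        with pytest.raises(ValueError):
            TransitionKey(0.0, 50.0)


class TestFormulaParsing:
    @pytest.mark.parametrize(
        "formula,expected",
        [
            ("C22H46NO7P", {"C": 22, "H": 46, "N": 1, "O": 7, "P": 1}),
            ("H2O", {"H": 2, "O": 1}),
            ("C12H24O2", {"C": 12, "H": 24, "O": 2}),
        ],
    )
    def test_parses(self, formula, expected):
        assert parse_formula(formula) == expected

    @pytest.mark.parametrize("bad", ["", "c12", "C12H24-", "12C"])
    def test_rejects_garbage(self, bad):
        with pytest.raises(ValueError):
            parse_formula(bad)


class TestChromatogram:
    def test_floors_negative_intensities(self, key):
        c = Chromatogram(key, [1.0, 2.0, 3.0], [-5.0, 10.0, -1.0])
        assert (c.intensities >= 0).all()

    def test_rejects_non_increasing_times(self, key):
        with pytest.raises(ValueError):
            Chromatogram(key, [1.0, 1.0, 2.0], [0.0, 0.0, 0.0])

    def test_rejects_single_point(self, key):
        with pytest.raises(ValueError):
            Chromatogram(key, [1.0], [1.0])


class TestLibraryReader:
    def test_packaged_library_fully_parses(self):
        entries = read_library(packaged_library_path())
        n_rows = sum(1 for _ in open(packaged_library_path())) - 1
        assert len(entries) == n_rows

    def test_known_lyso_pc_row(self):
        entries = read_library(packaged_library_path())
        e = next(x for x in entries if x.name == "lysoPC 14:0 (sn-2)")
        assert e.formula == {"C": 22, "H": 46, "N": 1, "O": 7, "P": 1}
        assert e.transition == TransitionKey(468.3, 184.1, "positive")
        assert e.expected_rt == pytest.approx(6.34)

    def test_q1_equals_q3_channel_is_valid(self):
        entries = read_library(packaged_library_path())
        ffa = next(x for x in entries if "FFA 12:0" in x.name)
        assert ffa.transition.precursor_mz == ffa.transition.product_mz
        assert ffa.transition.polarity == "negative"

    def test_bad_formula_reports_row_number(self, tmp_path):
        p = tmp_path / "lib.tsv"
        p.write_text(
            "name\tformula\tprecursor_mz\tproduct_mz\trt_min\tion_mode\n"
            "good\tC2H4\t100\t50\t1.0\tpositive\n"
            "bad\t???\t100\t50\t2.0\tpositive\n"
        )
        with pytest.raises(ValueError, match="row 2"):
            read_library(p)


class TestChromatogramDialect:
    def test_round_trip_bit_exact(self, tmp_path, gaussian_trace):
        chroms = [
            gaussian_trace(sample_id="s1"),
            gaussian_trace(
                centers=(5.0,), transition=TransitionKey(794.6, 184.1), sample_id="s1"
            ),
        ]
        p = tmp_path / "run.tsv"
        write_chromatogram_tsv(chroms, p)
        back = read_chromatogram_tsv(p)
        assert len(back) == 2
        for orig, rb in zip(chroms, back):
            assert rb.transition == orig.transition
            assert np.array_equal(rb.times, orig.times)
            assert np.array_equal(rb.intensities, orig.intensities)

    def test_grouping_yields_one_trace_per_run_per_key(self, gaussian_trace):
        chroms = [gaussian_trace(sample_id=s) for s in ("a", "b")]
        store = group_by_transition(chroms)
        assert len(store) == 1
        assert set(next(iter(store.values()))) == {"a", "b"}
        with pytest.raises(ValueError):
            group_by_transition(chroms + [gaussian_trace(sample_id="a")])


class TestMzml:
    def test_reads_srm_and_skips_tic(self, tmp_path):
        t = np.linspace(0, 45, 20)
        y = np.arange(20.0)
        path = write_mzml(
            tmp_path / "a.mzML",
            [
                tic_chromatogram_xml(0, t, y),
                srm_chromatogram_xml(1, "SRM SIC Q1=468.3 Q3=184.1", 468.3, 184.1, t, y),
                srm_chromatogram_xml(
                    2, "SRM SIC Q1=255.1 Q3=255.1", 255.1, 255.1, t, y, polarity="negative"
                ),
            ],
        )
        chroms = read_mzml_srm(path)
        assert len(chroms) == 2
        assert chroms[0].transition == TransitionKey(468.3, 184.1, "positive")
        assert chroms[1].transition == TransitionKey(255.1, 255.1, "negative")

    def test_seconds_converted_to_minutes(self, tmp_path):
        t_sec = np.linspace(0, 45 * 60, 30)
        path = write_mzml(
            tmp_path / "b.mzML",
            [srm_chromatogram_xml(0, "SRM 1", 100.0, 50.0, t_sec, np.ones(30), time_unit="second")],
        )
        (c,) = read_mzml_srm(path)
        assert c.times[-1] == pytest.approx(45.0)

    def test_missing_product_metadata_is_hard_error(self, tmp_path):
        t = np.linspace(0, 10, 5)
        path = write_mzml(
            tmp_path / "c.mzML",
            [srm_chromatogram_xml(0, "SRM broken", 100.0, 50.0, t, np.ones(5), omit_product=True)],
        )
        with pytest.raises(ValueError, match="broken"):
            read_mzml_srm(path)

    def test_empty_file_is_error(self, tmp_path):
        path = write_mzml(tmp_path / "d.mzML", [])
        with pytest.raises(ValueError):
            read_mzml_srm(path)


class TestSampleSheet:
    def test_round_trip_and_duplicate_orders_rejected(self, tmp_path):
        samples = [
            SampleRecord("s1", "x1.tsv", "A", 1, "biological"),
            SampleRecord("q1", "q1.tsv", "QC", 2, "qc"),
        ]
        p = tmp_path / "samples.csv"
        write_sample_sheet(samples, p)
        back = read_sample_sheet(p)
        assert [s.sample_id for s in back] == ["s1", "q1"]
        assert back[1].sample_type == "QC"
        bad = tmp_path / "bad.csv"
        write_sample_sheet([samples[0], SampleRecord("s2", "y", "B", 1, "biological")], bad)
        with pytest.raises(ValueError, match="unique"):
            read_sample_sheet(bad)


def _tiny_matrix():
    k1, k2 = TransitionKey(468.3, 184.1), TransitionKey(794.6, 184.1)
    features = [
        FeatureInfo("f1", k1, 6.3, 6.1, 6.6, annotation="lysoPC 14:0 (sn-2)",
                    annotation_score=0.98, formula={"C": 22, "H": 46, "N": 1, "O": 7, "P": 1}),
        FeatureInfo("f2", k2, 25.4, 25.2, 25.7),
    ]
    values = pd.DataFrame({"s1": [10.0, 5.0], "s2": [11.0, 6.0], "s3": [9.0, 0.0]},
                          index=["f1", "f2"])
    flags = pd.DataFrame(
        {"s1": [FLAG_DETECTED] * 2, "s2": [FLAG_DETECTED, FLAG_PURE_ISOTOPE],
         "s3": [FLAG_DETECTED] * 2},
        index=["f1", "f2"],
    )
    return PeakMatrix(features=features, values=values, flags=flags)


class TestPeakMatrixIO:
    def test_round_trip_lossless(self, tmp_path):
        m = _tiny_matrix()
        p = tmp_path / "m.tsv"
        write_peak_matrix(m, p)
        back = read_peak_matrix(p)
        assert back.sample_ids == m.sample_ids
        pd.testing.assert_frame_equal(back.values, m.values)
        pd.testing.assert_frame_equal(back.flags, m.flags)
        f1 = back.feature("f1")
        assert f1.annotation == "lysoPC 14:0 (sn-2)"
        assert f1.formula == {"C": 22, "H": 46, "N": 1, "O": 7, "P": 1}
        assert back.flags.at["f2", "s2"] == FLAG_PURE_ISOTOPE

    def test_empty_matrix_round_trip(self, tmp_path):
        m = PeakMatrix(
            features=[],
            values=pd.DataFrame({"s1": [], "s2": []}, index=pd.Index([], dtype=object)),
            flags=pd.DataFrame({"s1": [], "s2": []}, index=pd.Index([], dtype=object)),
        )
        p = tmp_path / "empty.tsv"
        write_peak_matrix(m, p)
        back = read_peak_matrix(p)
        assert back.feature_ids == []
        assert back.sample_ids == ["s1", "s2"]

    def test_unknown_flag_rejected(self):
        m = _tiny_matrix()
        m.flags.at["f1", "s1"] = "bogus"
        with pytest.raises(ValueError, match="bogus"):
            PeakMatrix(m.features, m.values, m.flags)
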