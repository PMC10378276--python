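"""Triage pipeline: case screening, prioritization and batch behavior."""

from __future__ import annotations

import numpy as np
import pytest

from naevoscreen.classifier import ProbabilityMap
from naevoscreen.image_io import save_image
from naevoscreen.screening import (
    AllCasesFailedError,
    EmptyBatchError,
    ScreeningPipeline,
    TriageConfig,
    prioritize,
    run_batch,
    run_case,
)
from naevoscreen.synthetic import SyntheticSpec, generate_case


class StubPipeline(ScreeningPipeline):
    """Pipeline whose probability map is a fixed C2 fraction: the first
    ``fraction`` of pixels (row-major) score 1.0, the rest 0.0."""

    def __init__(self, fraction: float):
        super().__init__()
        self.fraction = fraction
        self.model_id_ = "stub"

    def predict_map(self, image):
        n = image.shape[0] * image.shape[1]
        flat = np.zeros(n)
        flat[: int(round(self.fraction * n))] = 1.0
        p_c2 = flat.reshape(image.shape[:2])
        return ProbabilityMap(p_c1=1 - p_c2, p_c2=p_c2)


@pytest.fixture
def plain_image(tmp_path):
    """A flat image with a detectable 100 px scale bar."""
    image = np.full((50, 200, 3), 220, dtype=np.uint8)
    image[40:43, 10:110] = 0
    path = tmp_path / "case.png"
    save_image(path, image)
    return path


@pytest.fixture(scope="session")
def fitted_pipeline(small_case, sparse_mask):
    pipe = ScreeningPipeline(n_trees=25, random_state=11,
                             max_pixels_per_class=300)
    return pipe.fit([small_case.image], [sparse_mask])


def _report(case_id, pct, suspected):
    """Minimal CaseReport stand-in for prioritization tests."""
    from naevoscreen.image_io import CalibrationInfo
    from naevoscreen.quantify import RedPixelQuantification
    from naevoscreen.screening import CaseReport

    return CaseReport(
        case_id=case_id,
        image_path=f"{case_id}.png",
        calibration=CalibrationInfo.from_scale_bar(10, 10, 5),
        quantification=RedPixelQuantification(
            red_threshold=0.38, red_pixel_count=0,
            equivalent_area_mm2=0.0, equivalent_area_pct=pct,
            total_area_mm2=1.0,
        ),
        suspected=suspected,
        model_id="m",
    )


class TestRunCase:
    def test_saturated_map_gives_full_percentage_and_flag(self, plain_image):
        report = run_case(plain_image, StubPipeline(1.0))
        assert report.quantification.equivalent_area_pct == pytest.approx(100.0)
        assert report.suspected
        assert report.recommended_followup != ""

    def test_boundary_percentage_is_not_suspected(self, plain_image):
        """Exactly 12% does not exceed the threshold (strict comparison)."""
        report = run_case(plain_image, StubPipeline(0.12))
        assert report.quantification.equivalent_area_pct == pytest.approx(12.0)
        assert not report.suspected

    def test_just_above_boundary_is_suspected(self, plain_image):
        report = run_case(plain_image, StubPipeline(0.121))
        assert report.suspected

    def test_calibration_from_detected_bar(self, plain_image):
        report = run_case(plain_image, StubPipeline(0.0))
        assert report.calibration.scale_bar_length_px == 100
        assert report.calibration.microns_per_pixel == pytest.approx(5.0)

    def test_manual_calibration_override(self, plain_image):
        config = TriageConfig(microns_per_pixel=2.0)
        report = run_case(plain_image, StubPipeline(0.0), config)
        assert report.calibration.microns_per_pixel == pytest.approx(2.0)

    def test_report_has_no_timestamp_by_default(self, plain_image):
        assert run_case(plain_image, StubPipeline(0.0)).timestamp is None


class TestPrioritize:
    def test_descending_percentage_with_suspected_first(self):
        reports = [_report("a", 5, False), _report("b", 13, True),
                   _report("c", 40, True)]
        assert [r.case_id for r in prioritize(reports)] == ["c", "b", "a"]

    def test_all_below_threshold_sorted_by_percentage(self):
        reports = [_report("a", 2, False), _report("b", 9, False),
                   _report("c", 5, False)]
        assert [r.case_id for r in prioritize(reports)] == ["b", "c", "a"]

    def test_ties_break_lexicographically(self):
        reports = [_report("zeta", 7, False), _report("alpha", 7, False)]
        assert [r.case_id for r in prioritize(reports)] == ["alpha", "zeta"]

    def test_prioritization_is_a_permutation(self):
        rng = np.random.default_rng(0)
        reports = [_report(f"c{i}", float(rng.uniform(0, 30)), bool(rng.random() > 0.5))
                   for i in range(20)]
        ordered = prioritize(reports)
        assert sorted(r.case_id for r in ordered) == sorted(
            r.case_id for r in reports
        )

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            prioritize([])


class TestTriageConfig:
    @pytest.mark.parametrize("threshold", [0, 100, -3])
    def test_threshold_bounds(self, threshold):
        with pytest.raises(ValueError):
            TriageConfig(triage_threshold=threshold)


class TestRunBatch:
    @staticmethod
    def _write_cases(tmp_path, fractions):
        for i, frac in enumerate(fractions):
            spec = SyntheticSpec(width=256, height=160, microns_per_pixel=2.5,
                                 anomalous_fraction=frac, seed=100 + i)
            save_image(tmp_path / f"case_{i}.png", generate_case(spec).image)

    def test_malignant_like_cases_ranked_first(self, tmp_path, fitted_pipeline):
        self._write_cases(tmp_path, [0.02, 0.03, 0.22, 0.28])
        reports, failures = run_batch(tmp_path, fitted_pipeline, out_dir=tmp_path / "out")
        assert not failures
        assert [r.case_id for r in reports[:2]] == ["case_3", "case_2"]
        for r in reports:
            assert r.suspected == (
                r.quantification.equivalent_area_pct > 12.0
            )
        assert (tmp_path / "out" / "worklist.csv").exists()
        assert (tmp_path / "out" / "summary.json").exists()

    def test_unreadable_file_is_isolated(self, tmp_path):
        image = np.full((50, 200, 3), 220, dtype=np.uint8)
        image[40:43, 10:110] = 0
        save_image(tmp_path / "good_a.png", image)
        save_image(tmp_path / "good_b.png", image)
        (tmp_path / "broken.png").write_bytes(b"not a png")
        reports, failures = run_batch(tmp_path, StubPipeline(0.5))
        assert len(reports) == 2
        assert len(failures) == 1 and failures[0]["case_id"] == "broken"

    def test_truth_masks_are_skipped(self, tmp_path):
        image = np.full((50, 200, 3), 220, dtype=np.uint8)
        image[40:43, 10:110] = 0
        save_image(tmp_path / "case.png", image)
        save_image(tmp_path / "case_truth.png", image)
        reports, _ = run_batch(tmp_path, StubPipeline(0.0))
        assert [r.case_id for r in reports] == ["case"]

    def test_empty_directory_raises(self, tmp_path):
        with pytest.raises(EmptyBatchError):
            run_batch(tmp_path, StubPipeline(0.0))

    def test_all_failed_raises_distinct_error(self, tmp_path):
        (tmp_path / "bad.png").write_bytes(b"junk")
        with pytest.raises(AllCasesFailedError):
            run_batch(tmp_path, StubPipeline(0.0))

    def test_rerun_is_byte_identical(self, tmp_path):
        image = np.full((50, 200, 3), 220, dtype=np.uint8)
        image[40:43, 10:110] = 0
        for name in ("a.png", "b.png"):
            save_image(tmp_path / name, image)
        run_batch(tmp_path, StubPipeline(0.3), out_dir=tmp_path / "o1")
        run_batch(tmp_path, StubPipeline(0.3), out_dir=tmp_path / "o2")
        assert (tmp_path / "o1" / "worklist.csv").read_bytes() == \
            (tmp_path / "o2" / "worklist.csv").read_bytes()
        assert (tmp_path / "o1" / "summary.json").read_text() == \
            (tmp_path / "o2" / "summary.json").read_text()


class TestPipelinePersistence:
    def test_save_load_preserves_predictions(self, tmp_path, fitted_pipeline,
                                             small_case):
        path = tmp_path / "pipeline.json"
        fitted_pipeline.save(path)
        loaded = ScreeningPipeline.load(path)
        a = fitted_pipeline.predict_map(small_case.image)
        b = loaded.predict_map(small_case.image)
        np.testing.assert_array_equal(a.p_c2, b.p_c2)
        assert loaded.model_id_ == fitted_pipeline.model_id_
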