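import json

import numpy as np
import pytest
from scipy import integrate, special

from kpiqa import (
    AffineSpec,
    BRAIN_WINDOW,
    DoseNoiseSpec,
    coefficient_of_variation,
    pearson_test,
    run_robustness_study,
    run_validity_study,
    to_eight_bit,
    write_report,
)
from kpiqa.study import StudyResult, read_report


def t_tail_oracle(t, df):
    """Two-sided p by numerical integration of the Student-t density."""
    norm = special.gamma((df + 1) / 2) / (np.sqrt(df * np.pi) * special.gamma(df / 2))

    def pdf(u):
        return norm * (1 + u * u / df) ** (-(df + 1) / 2)

    tail, _ = integrate.quad(pdf, abs(t), np.inf, epsabs=1e-13, epsrel=1e-13)
    return 2.0 * tail


class TestPearson:
    def test_perfect_anticorrelation(self):
        x = np.arange(10.0)
        r, p = pearson_test(x, -x)
        assert r == -1.0
        assert p == 0.0

    def test_direct_formula_small_example(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 2.0, 3.0, 5.0])
        r, _ = pearson_test(x, y)
        # hand evaluation of cov / (sx sy)
        assert r == pytest.approx(6.5 / np.sqrt(5.0 * 8.75), abs=1e-12)

    def test_p_matches_numerical_t_tail(self, rng):
        x = 5.0 + rng.normal(0, 1, 10)
        y = 3.0 + rng.normal(0, 1, 10)
        r, p = pearson_test(x, y)
        t = r * np.sqrt((len(x) - 2) / (1 - r * r))
        assert p == pytest.approx(t_tail_oracle(t, len(x) - 2), abs=1e-9)

    def test_matches_scipy_pearsonr(self, rng):
        x = rng.normal(size=15)
        y = 0.4 * x + rng.normal(size=15)
        from scipy import stats

        r, p = pearson_test(x, y)
        expected = stats.pearsonr(x, y)
        assert r == pytest.approx(expected.statistic, abs=1e-12)
        assert p == pytest.approx(expected.pvalue, rel=1e-9)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_test([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            pearson_test([1.0, 2.0], [3.0, 4.0])


class TestCoefficientOfVariation:
    def test_all_zero_series_is_stable(self):
        assert coefficient_of_variation([0.0, 0.0, 0.0]) == 0.0

    def test_simple_value(self):
        v = np.array([9.0, 10.0, 11.0])
        assert coefficient_of_variation(v) == pytest.approx(v.std(ddof=1) / 10.0)


@pytest.fixture(scope="module")
def validity_result(small_phantom):
    return run_validity_study(
        small_phantom, noise_series=(74.2, 27.4, 5.5), blur_kernels=(3, 7, 11),
        backends=("ref", "orb"), seed=11)


class TestValidityStudy:
    def test_record_layout(self, validity_result):
        res = validity_result
        assert [r.series for r in res.records] == ["noise"] * 3 + ["blur"] * 3
        for rec in res.records:
            for br in rec.backends.values():
                assert br.n_matches <= min(br.keypoints_ref, br.keypoints_tgt)
                if br.pi is not None:
                    assert 0 <= br.pi <= 512

    def test_correlations_reference_every_series(self, validity_result):
        series = {(c.series, c.backend) for c in validity_result.correlations}
        assert ("noise", "psnr") in series and ("blur", "psnr") in series

    def test_deterministic_given_seed(self, small_phantom):
        a = run_validity_study(small_phantom, noise_series=(27.4,),
                               blur_kernels=(3,), backends=("ref",), seed=5)
        b = run_validity_study(small_phantom, noise_series=(27.4,),
                               blur_kernels=(3,), backends=("ref",), seed=5)
        assert a.to_dict() == b.to_dict()

    def test_identity_condition_scores_perfect(self, small_phantom):
        # an undegraded pseudo-condition: astronomically high dose -> no noise
        scene = to_eight_bit(small_phantom, BRAIN_WINDOW)
        res = run_validity_study(
            scene, noise_series=(DoseNoiseSpec(ctdi=1e9, seed=1), 13.7),
            blur_kernels=(), backends=("ref",), seed=2)
        rec = res.records[0]
        assert rec.ssim == pytest.approx(1.0)
        assert rec.psnr == float("inf")
        assert rec.backends["ref"].pi == 0.0


class TestRobustnessStudy:
    def test_identity_translation_gives_zero_pi(self, small_phantom):
        res = run_robustness_study(
            small_phantom,
            affine_series={"translation": [AffineSpec(kind="translate", dx=0),
                                           AffineSpec(kind="translate", dx=8)]},
            backends=("ref",), seed=4, independent_target=False)
        rec0 = res.records[0]
        assert rec0.ssim == pytest.approx(1.0)
        assert rec0.backends["ref"].pi == 0.0

    def test_independent_target_keeps_pi_at_operating_level(self, small_phantom):
        res = run_robustness_study(
            small_phantom,
            affine_series={"translation": [AffineSpec(kind="translate", dx=2),
                                           AffineSpec(kind="translate", dx=20)]},
            backends=("ref",), seed=4, independent_target=True)
        pis = [r.backends["ref"].pi for r in res.records]
        assert all(p is not None and p > 0 for p in pis)
        assert res.provenance["independent_target"] is True


class TestReporting:
    def test_json_round_trip(self, validity_result, tmp_path):
        paths = write_report(validity_result, tmp_path, plots=False)
        back = read_report(paths["json"])
        assert back == StudyResult.from_dict(validity_result.to_dict())
        assert back.to_dict() == validity_result.to_dict()

    def test_conditions_csv_schema(self, small_phantom, tmp_path):
        import pandas as pd

        res = run_validity_study(small_phantom, noise_series=(27.4, 13.7, 5.5),
                                 blur_kernels=(), backends=("ref", "orb", "akaze"),
                                 seed=7)
        paths = write_report(res, tmp_path, plots=False)
        df = pd.read_csv(paths["conditions_csv"])
        assert len(df) == 3
        count_cols = [c for c in df.columns
                      if c.endswith("_keypoints") or c.endswith("_matchings")]
        assert len(count_cols) == 6  # keypoints + matchings per backend
        assert {"series", "label", "parameter", "ssim", "psnr"} <= set(df.columns)

    def test_validity_only_report_files(self, validity_result, tmp_path):
        paths = write_report(validity_result, tmp_path, plots=True)
        assert paths["json"].endswith("result_validity.json")
        assert all("validity" in p for p in paths["plots"])

    def test_reports_byte_identical_across_runs(self, small_phantom, tmp_path):
        out = []
        for run in ("a", "b"):
            res = run_validity_study(small_phantom, noise_series=(27.4, 5.5),
                                     blur_kernels=(3,), backends=("ref",), seed=9)
            paths = write_report(res, tmp_path / run, plots=False)
            out.append({k: open(p, "rb").read()
                        for k, p in paths.items() if isinstance(p, str)})
        assert out[0] == out[1]

    def test_every_reported_p_matches_t_tail_oracle(self, validity_result):
        for c in validity_result.correlations:
            t = c.r * np.sqrt((c.n - 2) / (1 - c.r * c.r))
            assert c.p == pytest.approx(t_tail_oracle(t, c.n - 2), abs=1e-9)
            assert c.significant == (c.p < 0.05)
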