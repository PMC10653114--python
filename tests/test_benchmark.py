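import numpy as np
import pytest

from neqpka.benchmark import (
    BenchmarkRecord,
    aue,
    class_breakdown,
    convergence_curve,
    metric_bootstrap,
    null_model,
    pearson,
)
from neqpka.cycle import PkaPrediction
from neqpka.synthetic import GeneratorSpec, gaussian_cft_pair


def record(residue, cls, expt, pred_pka, kind="standard", source="neq"):
    pred = PkaPrediction(
        pka=pred_pka, se=0.1, protein="P", residue=residue, res_class=cls,
        kind=kind, source=source,
    )
    return BenchmarkRecord(
        protein="P", residue=residue, res_class=cls,
        experimental_pka=expt, predictions={source: pred},
    )


class TestAue:
    def test_identical_lists(self):
        assert aue([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_constant_offset(self):
        assert aue([2.0, 3.0, 4.0], [1.0, 2.0, 3.0]) == 1.0

    def test_hand_arithmetic(self):
        assert aue([3.0, 5.0], [4.0, 4.0]) == pytest.approx(1.0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            aue([1.0], [1.0, 2.0])

    def test_shift_equivariance(self):
        p = np.array([3.1, 4.7, 5.0])
        e = np.array([3.0, 5.0, 4.5])
        assert aue(p + 2.2, e + 2.2) == pytest.approx(aue(p, e))


class TestPearson:
    def test_affine_is_one(self):
        e = np.array([1.0, 2.0, 5.0])
        assert pearson(2 * e + 3, e) == pytest.approx(1.0)

    def test_anticorrelated(self):
        e = np.array([1.0, 2.0, 5.0])
        assert pearson(-e, e) == pytest.approx(-1.0)

    def test_brute_force_value(self):
        assert pearson([1.0, 2.0, 3.0], [1.0, 3.0, 2.0]) == pytest.approx(0.5)

    def test_zero_variance_is_error_not_nan(self):
        with pytest.raises(ValueError, match="variance"):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestMetricBootstrap:
    def test_identical_errors_zero_se(self):
        records = [record(f"D{i}", "ASP", 4.0 + 0.1 * i, 4.5 + 0.1 * i) for i in range(10)]
        rep = metric_bootstrap(records, "neq", n_boot=100, seed=0)
        assert rep.aue == pytest.approx(0.5)
        assert rep.aue_se == pytest.approx(0.0, abs=1e-12)

    def test_same_seed_identical_report(self):
        rng = np.random.default_rng(4)
        records = [
            record(f"D{i}", "ASP", 4.0 + rng.normal(), 4.0 + rng.normal()) for i in range(20)
        ]
        a = metric_bootstrap(records, "neq", n_boot=200, seed=5)
        b = metric_bootstrap(records, "neq", n_boot=200, seed=5)
        assert a == b

    def test_aue_se_matches_half_normal_closed_form(self):
        # i.i.d. Gaussian errors: SD of the mean absolute error is
        # sigma*sqrt(1-2/pi)/sqrt(n)
        sigma, n = 0.8, 100
        rng = np.random.default_rng(17)
        records = [
            record(f"D{i}", "ASP", 4.0 + rng.normal(0, 1.5), 0.0) for i in range(n)
        ]
        records = [
            BenchmarkRecord(
                protein=r.protein, residue=r.residue, res_class=r.res_class,
                experimental_pka=r.experimental_pka,
                predictions={
                    "neq": PkaPrediction(
                        pka=r.experimental_pka + rng.normal(0, sigma), se=0.0,
                        protein=r.protein, residue=r.residue, res_class=r.res_class,
                        source="neq",
                    )
                },
            )
            for r in records
        ]
        rep = metric_bootstrap(records, "neq", n_boot=2000, seed=3)
        expected = sigma * np.sqrt(1 - 2 / np.pi) / np.sqrt(n)
        assert expected / 1.3 < rep.aue_se < expected * 1.3

    def test_mixed_kind_guard(self):
        records = [
            record("D1", "ASP", 4.0, 4.2),
            record("D2", "ASP", 4.1, 4.3, kind="conditional"),
            record("D3", "ASP", 4.3, 4.4),
        ]
        with pytest.raises(ValueError, match="mix prediction kinds"):
            metric_bootstrap(records, "neq", n_boot=50, seed=0)
        rep = metric_bootstrap(records, "neq", n_boot=50, seed=0, allow_mixed_kinds=True)
        assert rep.n == 3


class TestNullModel:
    def test_predicts_class_reference(self):
        preds = null_model([record("D1", "ASP", 3.0, 9.9)])
        assert preds[("P", "D1")].pka == 3.94
        assert preds[("P", "D1")].source == "null"

    def test_zero_error_when_experiment_at_reference(self):
        r = record("K1", "LYS", 10.4, 0.0)
        preds = null_model([r])
        assert abs(preds[("P", "K1")].pka - r.experimental_pka) == 0.0

    def test_null_aue_grows_linearly_with_shift(self):
        for d in (0.5, 1.0, 2.0):
            records = [record(f"E{i}", "GLU", 4.25 + d, 0.0) for i in range(5)]
            preds = null_model(records)
            errs = [abs(preds[r.key].pka - r.experimental_pka) for r in records]
            assert np.mean(errs) == pytest.approx(d)


class TestClassBreakdown:
    def test_single_class_matches_full_report(self):
        rng = np.random.default_rng(8)
        records = [
            record(f"D{i}", "ASP", 4.0 + rng.normal(), 4.0 + rng.normal()) for i in range(15)
        ]
        out = class_breakdown(records, "neq", n_boot=100, seed=0)
        assert out["ASP"].aue == pytest.approx(out["overall"].aue)
        assert out["ASP"].pearson == pytest.approx(out["overall"].pearson)

    def test_overall_is_mean_of_class_aues(self):
        # ASP residues all off by 1, LYS residues exact -> overall AUE 0.5
        records = [record(f"D{i}", "ASP", 4.0 + 0.3 * i, 5.0 + 0.3 * i) for i in range(5)]
        records += [record(f"K{i}", "LYS", 10.0 + 0.3 * i, 10.0 + 0.3 * i) for i in range(5)]
        out = class_breakdown(records, "neq", n_boot=100, seed=0)
        assert out["ASP"].aue == pytest.approx(1.0)
        assert out["LYS"].aue == pytest.approx(0.0)
        assert out["overall"].aue == pytest.approx(0.5)

    def test_residue_weighted_flag_pools(self):
        records = [record(f"D{i}", "ASP", 4.0 + 0.3 * i, 5.0 + 0.3 * i) for i in range(6)]
        records += [record(f"K{i}", "LYS", 10.0 + 0.3 * i, 10.0 + 0.3 * i) for i in range(3)]
        out = class_breakdown(records, "neq", n_boot=100, seed=0, residue_weighted=True)
        assert out["overall"].aue == pytest.approx(6 / 9)

    def test_record_order_irrelevant(self):
        rng = np.random.default_rng(9)
        records = [
            record(f"D{i}", "ASP", 4.0 + rng.normal(), 4.0 + rng.normal()) for i in range(12)
        ]
        a = class_breakdown(records, "neq", n_boot=100, seed=1)
        b = class_breakdown(records[::-1], "neq", n_boot=100, seed=1)
        assert a["overall"].aue == pytest.approx(b["overall"].aue)


@pytest.fixture(scope="module")
def workset():
    return gaussian_cft_pair(GeneratorSpec(8.0, 5.0, n_forward=100, n_reverse=100, seed=3))


class TestConvergenceCurve:

    def test_full_size_has_zero_sd(self, workset):
        table = convergence_curve(workset, [100], reps=10, seed=0)
        assert table.loc[0, "sd_dg"] == pytest.approx(0.0, abs=1e-12)

    def test_rejects_tiny_and_oversized_n(self, workset):
        with pytest.raises(ValueError, match=">= 2"):
            convergence_curve(workset, [1, 50], reps=5, seed=0)
        with pytest.raises(ValueError, match="exceeds"):
            convergence_curve(workset, [10, 500], reps=5, seed=0)

    def test_mean_near_truth(self, workset):
        table = convergence_curve(workset, [20, 50, 100], reps=20, seed=0)
        sd = max(table["sd_dg"].max(), 0.1)
        assert np.all(np.abs(table["mean_dg"] - 8.0) < 4 * sd + 1.0)
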