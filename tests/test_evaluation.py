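"""Evaluation surfaces: stratified RMSE, correlations, audits, curves."""

from types import SimpleNamespace

import numpy as np
import pytest

from orbpool.core import AtomicSystem, ElectronicReference, LabeledDataset
from orbpool.descriptors import DescriptorConfig
from orbpool.evaluation import (
    UnsupportedHeadError,
    _population_pearson,
    export_pseudoorbitals,
    intensivity_audit,
    learning_curve,
    stratified_rmse,
    weight_correlations,
)
from orbpool.model import LossConfig, ModelConfig, train
from orbpool.pooling import PoolingHead
from orbpool.tightbinding import GeneratorConfig, toy_monomer_fixtures


def _stub_model(head="wa", mode="max", predict=None):
    cfg = SimpleNamespace(
        pooling=PoolingHead(head, mode),
        descriptor=DescriptorConfig(element_channels=("C",), cutoff_radius=4.0),
    )
    return SimpleNamespace(config=cfg, model_id="stub", predict=predict)


def _fixture_dataset():
    """10 records; every stratum's targets are centered on zero so the
    constant predictor 0 has RMSE equal to the stratum population std."""
    spec = [
        (0.9, 1.0), (0.9, -1.0), (0.85, 2.0), (0.95, -2.0),   # localized
        (0.1, 0.5), (0.2, -0.5),                              # delocalized
        (0.5, 3.0), (0.5, -3.0), (0.6, 1.0), (0.6, -1.0),     # middle
    ]
    records = []
    for L, y in spec:
        records.append(
            (
                AtomicSystem(["C", "C"], np.array([[0, 0, 0], [1.4, 0, 0]])),
                ElectronicReference(y, localization_index=L),
            )
        )
    return LabeledDataset(records=records)


class TestStratifiedRmse:
    def test_perfect_model_has_zero_rmse(self):
        ds = _fixture_dataset()
        refs = iter([ref.target_energy for _, ref in ds] * 2)
        model = _stub_model(predict=lambda system, fractions=None: (next(refs), None))
        report = stratified_rmse(model, ds)
        assert report.rmse_overall == 0.0
        assert report.rmse_localized == 0.0
        assert report.rmse_delocalized == 0.0

    def test_constant_predictor_matches_population_std(self):
        ds = _fixture_dataset()
        model = _stub_model(predict=lambda system, fractions=None: (0.0, None))
        report = stratified_rmse(model, ds)
        assert report.rmse_localized == pytest.approx(np.sqrt(2.5), abs=1e-12)
        assert report.rmse_delocalized == pytest.approx(0.5, abs=1e-12)
        assert report.rmse_middle == pytest.approx(np.sqrt(5.0), abs=1e-12)
        assert report.n_records == {
            "overall": 10, "localized": 4, "delocalized": 2, "middle": 4,
        }

    def test_deterministic(self):
        ds = _fixture_dataset()
        model = _stub_model(predict=lambda system, fractions=None: (0.3, None))
        r1 = stratified_rmse(model, ds)
        r2 = stratified_rmse(model, ds)
        assert r1.rmse_overall == r2.rmse_overall

    def test_empty_stratum_reported_absent(self):
        ds = _fixture_dataset().subset([0, 1])  # localized only
        model = _stub_model(predict=lambda system, fractions=None: (0.0, None))
        report = stratified_rmse(model, ds)
        assert report.rmse_delocalized is None
        assert report.rmse_localized is not None


class TestWeightCorrelations:
    @staticmethod
    def _dataset_with_l(ls):
        records = []
        for l in ls:
            n = len(l)
            coords = np.zeros((n, 3))
            coords[:, 0] = 1.4 * np.arange(n)
            records.append(
                (
                    AtomicSystem(["C"] * n, coords),
                    ElectronicReference(
                        -7.0, localization_fractions=np.array(l),
                        localization_index=0.5,
                    ),
                )
            )
        return LabeledDataset(records=records)

    def test_weights_equal_fractions_give_r_one(self):
        ds = self._dataset_with_l([[0.5, 0.3, 0.2], [0.1, 0.2, 0.7]])
        it = iter([ref.localization_fractions for _, ref in ds])
        model = _stub_model(predict=lambda system, fractions=None: (0.0, next(it)))
        rs = weight_correlations(model, ds)
        np.testing.assert_allclose(rs, [1.0, 1.0], atol=1e-12)

    def test_uniform_weights_excluded(self):
        ds = self._dataset_with_l([[0.5, 0.3, 0.2]])
        model = _stub_model(
            predict=lambda system, fractions=None: (0.0, np.full(3, 1 / 3))
        )
        assert len(weight_correlations(model, ds)) == 0

    def test_small_molecules_excluded(self):
        ds = self._dataset_with_l([[0.7, 0.3]])
        model = _stub_model(
            predict=lambda system, fractions=None: (0.0, np.array([0.6, 0.4]))
        )
        assert len(weight_correlations(model, ds)) == 0

    def test_hand_computed_pearson(self):
        w = np.array([0.1, 0.2, 0.3, 0.25, 0.15])
        l = np.array([0.05, 0.25, 0.35, 0.2, 0.15])
        # frozen value from an independent covariance-formula evaluation
        assert _population_pearson(w, l) == pytest.approx(0.9192388155425119,
                                                          abs=1e-12)

    def test_unsupported_head(self):
        ds = self._dataset_with_l([[0.5, 0.3, 0.2]])
        model = _stub_model(head="avg")
        with pytest.raises(UnsupportedHeadError):
            weight_correlations(model, ds)


class TestIntensivityAudit:
    def test_avg_head_deviation_vanishes(self):
        fixtures = toy_monomer_fixtures()
        cfg = ModelConfig(
            descriptor=DescriptorConfig(element_channels=("C", "H", "O"),
                                        cutoff_radius=4.0, n_centers=8),
            pooling=PoolingHead("avg", "min"),
            energy_net_layers=(16,), seed=0,
        )
        model = train(fixtures, cfg, max_epochs=0)
        table = intensivity_audit(model, fixtures, ks=(3,))
        assert table["abs_deviation"].max() <= 1e-6

    def test_sum_head_ratio_is_k(self):
        fixtures = toy_monomer_fixtures()
        cfg = ModelConfig(
            descriptor=DescriptorConfig(element_channels=("C", "H", "O"),
                                        cutoff_radius=4.0, n_centers=8),
            pooling=PoolingHead("sum", "min"),
            energy_net_layers=(16,), seed=0,
        )
        model = train(fixtures, cfg, max_epochs=0)
        table = intensivity_audit(model, fixtures, ks=(3,))
        np.testing.assert_allclose(table["ratio"], 1.0, atol=1e-6)


def test_learning_curve_shape_and_determinism(small_descriptor):
    gen = GeneratorConfig(n_molecules=40, seed=2)
    cfgs = {
        name: ModelConfig(
            descriptor=small_descriptor, pooling=PoolingHead(name, "max"),
            energy_net_layers=(8,), weight_net_layers=(8,), seed=0,
        )
        for name in ("avg", "max")
    }
    kw = dict(sizes=[10, 20], seeds=[0, 1], n_test=20, max_epochs=3, patience=3)
    df = learning_curve(gen, cfgs, **kw)
    combos = df[["head", "size", "seed"]].drop_duplicates()
    assert len(combos) == 8  # 2 heads x 2 sizes x 2 seeds
    assert set(df["stratum"]) <= {"overall", "localized", "delocalized", "middle"}
    df2 = learning_curve(gen, cfgs, **kw)
    assert df.equals(df2)


def test_export_pseudoorbitals_roundtrip(tmp_path):
    from orbpool.core import read_extxyz

    fixtures = toy_monomer_fixtures()
    cfg = ModelConfig(
        descriptor=DescriptorConfig(element_channels=("C", "H", "O"),
                                    cutoff_radius=4.0, n_centers=8),
        pooling=PoolingHead("owa", "min"),
        energy_net_layers=(16,), weight_net_layers=(16,), seed=0,
    )
    model = train(fixtures, cfg, LossConfig(1.0, 1.0), max_epochs=5)
    path = tmp_path / "pseudo.extxyz"
    export_pseudoorbitals(model, fixtures, path)
    back = read_extxyz(path)
    assert back.pseudoorbital_weights is not None
    for w, (_, ref) in zip(back.pseudoorbital_weights, back):
        assert w.sum() == pytest.approx(1.0, abs=1e-6)
        assert ref.localization_fractions is not None
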