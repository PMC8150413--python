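"""Step encoding, prefix encoding, scaling, training and model persistence."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from swlplan import (
    ALLOWED_RATES,
    GeneratorBundle,
    PPCVector,
    TrainConfig,
    TreatmentStep,
    ValidationError,
    normalize_plan,
    split_dataset,
    train,
)
from swlplan.cases import StepSample, decompose_case
from swlplan.generator import (
    COUNT_SCALE,
    HEAD_SPECS,
    STEP_ENCODING_WIDTH,
    PPCScaler,
    decode_step,
    encode_prefix,
    encode_step,
    lstm_encode,
)
from swlplan.network import init_params
from swlplan.registry import sample_ppc

from .oracles import lstm_reference

steps_st = st.builds(
    TreatmentStep,
    st.integers(1, 9),
    st.sampled_from(ALLOWED_RATES),
    st.integers(1, 1000),
)


def zero_bundle(ppcs, seed=0):
    """A bundle with all-zero weights: maximally uninformative outputs."""
    scaler = PPCScaler.fit(ppcs)
    cfg = TrainConfig(hidden_width=4, fc_widths=(5, 4), epochs=1, seed=seed)
    nets = {}
    for name, (size, kind) in HEAD_SPECS.items():
        p = init_params(STEP_ENCODING_WIDTH, scaler.mean.shape[0], 4, (5, 4),
                        {name: size}, seed=seed)
        nets[name] = ({k: np.zeros_like(v) for k, v in p.items()}, {name: kind})
    return GeneratorBundle(nets=nets, scaler=scaler, config=cfg)


class TestStepEncoding:
    @given(steps_st)
    def test_roundtrip(self, step):
        assert decode_step(encode_step(step)) == step

    def test_width_and_structure(self):
        v = encode_step(TreatmentStep(3, 90, 250))
        assert v.shape == (14,)
        assert v[:9].sum() == 1.0 and v[2] == 1.0
        assert v[9:13].sum() == 1.0 and v[10] == 1.0
        assert v[13] == 0.25

    def test_decode_rejects_wrong_width(self):
        with pytest.raises(ValidationError):
            decode_step(np.zeros(13))

    def test_encode_prefix_shapes(self):
        assert encode_prefix(()).shape == (0, 14)
        steps = (TreatmentStep(1, 120, 100), TreatmentStep(2, 120, 100))
        assert encode_prefix(steps).shape == (2, 14)


class TestLSTMEncode:
    def test_empty_prefix_gives_zero_state(self):
        params = init_params(14, 12, 6, (8, 6), {"power": 9}, seed=0)
        h, c = lstm_encode((), params)
        np.testing.assert_array_equal(h, np.zeros(6))
        np.testing.assert_array_equal(c, np.zeros(6))

    def test_matches_reference_recurrence(self, table1_plan):
        params = init_params(14, 12, 5, (8, 6), {"power": 9}, seed=3)
        prefix = table1_plan.steps[:6]
        h, c = lstm_encode(prefix, params)
        h_ref, c_ref = lstm_reference(
            encode_prefix(prefix), params["lstm_W"], params["lstm_U"],
            params["lstm_b"],
        )
        np.testing.assert_allclose(h, h_ref, atol=1e-10)
        np.testing.assert_allclose(c, c_ref, atol=1e-10)


class TestPPCScaler:
    def test_continuous_fields_standardized_binary_untouched(self):
        rng = np.random.default_rng(0)
        ppcs = sample_ppc(rng, 400)
        scaler = PPCScaler.fit(ppcs)
        M = np.stack([scaler.transform(p) for p in ppcs])
        for j in (1, 2, 3):  # age, stone size, MAP
            assert abs(M[:, j].mean()) < 1e-9
            assert M[:, j].std() == pytest.approx(1.0, abs=1e-9)
        binary = [0, 4, 5, 6, 7]
        assert set(np.unique(M[:, binary])) <= {0.0, 1.0}

    def test_constant_column_does_not_divide_by_zero(self):
        ppc = PPCVector(0, 50.0, "renal_pelvis", 8.0, 95.0, 0, 0, 0, 0)
        scaler = PPCScaler.fit([ppc, ppc])
        out = scaler.transform(ppc)
        assert np.all(np.isfinite(out))


class TestUntrainedBundle:
    def test_zero_weights_give_uniform_heads(self, some_ppc):
        bundle = zero_bundle([some_ppc])
        power, rate, count = bundle.forward((), some_ppc)
        np.testing.assert_allclose(power, np.full(9, 1 / 9), atol=1e-12)
        np.testing.assert_allclose(rate, np.full(4, 1 / 4), atol=1e-12)
        assert count == 0.0

    def test_argmax_tie_break_is_lowest_index(self, some_ppc):
        bundle = zero_bundle([some_ppc])
        step = bundle.predict_step((), some_ppc)
        # uniform distributions decode to the first class; zero count clamps to 1
        assert step == TreatmentStep(1, 60, 1)

    def test_count_clamped_to_step_cap(self, some_ppc):
        bundle = zero_bundle([some_ppc])
        params, _ = bundle.nets["count"]
        params["head_count_b"][:] = 1.7  # 1700 shocks before clamping
        step = bundle.predict_step((), some_ppc)
        assert step.num_shocks == 1000
        _, _, count = bundle.forward((), some_ppc)
        assert count == pytest.approx(1.7)


def memorization_dataset(n_cases=12):
    """Identical plans across cases so the training split is memorizable."""
    ppc = PPCVector(0, 50.0, "lower_calyx", 9.0, 100.0, 0, 1, 0, 0)
    plan = normalize_plan(
        [(1, 120, 200), (2, 120, 200), (3, 90, 400), (4, 90, 400),
         (5, 120, 600)],
    )
    samples = []
    for c in range(n_cases):
        for s in decompose_case(plan, ppc):
            samples.append(StepSample(case_id=f"m{c}", prefix=s.prefix,
                                      ppc=s.ppc, target=s.target))
    return split_dataset(samples, 0.2, seed=0)


class TestTraining:
    def test_memorizes_a_deterministic_policy(self):
        ds = memorization_dataset()
        cfg = TrainConfig(hidden_width=8, fc_widths=(16, 8), epochs=250,
                          patience=250, seed=2)
        bundle = train(ds, cfg)
        for s in ds.train_samples:
            pred = bundle.predict_step(s.prefix, s.ppc)
            assert pred.power_level == s.target.power_level
            assert pred.shock_rate == s.target.shock_rate
            assert abs(pred.num_shocks - s.target.num_shocks) <= 25

    def test_same_seed_gives_identical_weights(self):
        ds = memorization_dataset(6)
        cfg = TrainConfig(hidden_width=4, fc_widths=(6, 5), epochs=5,
                          patience=5, seed=9)
        a = train(ds, cfg)
        b = train(ds, cfg)
        for group in a.nets:
            pa, _ = a.nets[group]
            pb, _ = b.nets[group]
            for k in pa:
                np.testing.assert_array_equal(pa[k], pb[k])

    def test_empty_training_split_rejected(self):
        ds = memorization_dataset(6)
        ds.split_labels = ["val"] * len(ds.split_labels)
        with pytest.raises(ValidationError, match="empty training split"):
            train(ds, TrainConfig(epochs=1))

    def test_prefix_order_changes_the_prediction(self, tiny_bundle, some_ppc):
        a = TreatmentStep(2, 120, 200)
        b = TreatmentStep(6, 120, 400)
        p1, r1, c1 = tiny_bundle.forward((a, b), some_ppc)
        p2, r2, c2 = tiny_bundle.forward((b, a), some_ppc)
        assert not (np.allclose(p1, p2) and np.allclose(r1, r2)
                    and np.isclose(c1, c2))


class TestPersistence:
    def test_save_load_roundtrip_preserves_predictions(self, tiny_bundle,
                                                       some_ppc, tmp_path):
        tiny_bundle.save(tmp_path / "model")
        loaded = GeneratorBundle.load(tmp_path / "model")
        assert loaded.config == tiny_bundle.config
        prefix = (TreatmentStep(1, 120, 200), TreatmentStep(2, 120, 200))
        p0, r0, c0 = tiny_bundle.forward(prefix, some_ppc)
        p1, r1, c1 = loaded.forward(prefix, some_ppc)
        np.testing.assert_array_equal(p0, p1)
        np.testing.assert_array_equal(r0, r1)
        assert c0 == c1


class TestTrainConfig:
    def test_roundtrip_dict(self):
        cfg = TrainConfig(hidden_width=16, fc_widths=(8, 4), seed=5)
        assert TrainConfig.from_dict(cfg.to_dict()) == cfg

    def test_rejects_nonpositive_hyperparameters(self):
        with pytest.raises(ValidationError):
            TrainConfig(epochs=0)
        with pytest.raises(ValidationError):
            TrainConfig(learning_rate=-1.0)
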