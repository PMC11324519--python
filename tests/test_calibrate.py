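"""Community sampling, isotonic calibration, the calibrator net, FDR."""

import numpy as np
import pytest

from mgeclass.calibrate import (
    CalibratorModel,
    CommunitySample,
    calibrate_scores,
    fdr_from_scores,
    isotonic_calibrate,
    isotonic_calibrate_multiclass,
    sample_communities,
    train_calibrator,
)


def _synthetic_pool(n=900, seed=0):
    """Scores drawn so that P(true class | score) is a known logistic."""
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 3, n)
    scores = np.full((n, 3), 0.0)
    for i in range(n):
        # own-class score beta-distributed toward 1, others share the rest
        s = rng.beta(5, 2)
        rest = (1 - s) * rng.dirichlet([1, 1])
        scores[i, y[i]] = s
        scores[i, (y[i] + 1) % 3] = rest[0]
        scores[i, (y[i] + 2) % 3] = rest[1]
    return scores, y


class TestSampleCommunities:
    def test_empty_request(self):
        scores, y = _synthetic_pool(100)
        assert sample_communities(scores, y, 0, (50, 100), seed=1) == []

    def test_dirichlet_mean(self):
        scores, y = _synthetic_pool(300)
        comms = sample_communities(scores, y, 3000, (50, 60), seed=2)
        true_props = np.array(
            [np.bincount(c.labels, minlength=3) / len(c.labels) for c in comms]
        )
        assert np.allclose(true_props.mean(axis=0), 1 / 3, atol=0.01)

    def test_seeded_determinism(self):
        scores, y = _synthetic_pool(200)
        a = sample_communities(scores, y, 5, (50, 80), seed=3)
        b = sample_communities(scores, y, 5, (50, 80), seed=3)
        for ca, cb in zip(a, b):
            assert np.array_equal(ca.scores, cb.scores)
            assert np.array_equal(ca.labels, cb.labels)

    def test_too_small_size_is_error(self):
        scores, y = _synthetic_pool(50)
        with pytest.raises(ValueError):
            sample_communities(scores, y, 1, (5, 100), seed=0)

    def test_composition_recomputable(self):
        scores, y = _synthetic_pool(200)
        (comm,) = sample_communities(scores, y, 1, (100, 200), seed=4)
        assert np.allclose(
            comm.composition, CommunitySample.composition_of(comm.scores)
        )
        assert comm.composition.sum() == pytest.approx(1.0)


class TestIsotonic:
    def test_well_calibrated_fixed_point(self):
        rng = np.random.default_rng(5)
        s = rng.random(20_000)
        truth = (rng.random(20_000) < s).astype(int)  # perfectly calibrated
        out = isotonic_calibrate(s, truth)
        # compare bin means
        for lo in np.arange(0, 1, 0.2):
            m = (s >= lo) & (s < lo + 0.2)
            assert out[m].mean() == pytest.approx(s[m].mean(), abs=0.02)

    def test_monotone_in_score(self):
        rng = np.random.default_rng(6)
        s = rng.random(500)
        truth = (rng.random(500) < s**2).astype(int)
        out = isotonic_calibrate(s, truth)
        order = np.argsort(s)
        assert np.all(np.diff(out[order]) >= -1e-12)

    def test_overconfident_fixture(self):
        rng = np.random.default_rng(7)
        n = 2000
        s = np.concatenate([np.full(n, 0.99), rng.random(n)])
        truth = np.concatenate(
            [(rng.random(n) < 0.6).astype(int), (rng.random(n) < 0.2).astype(int)]
        )
        out = isotonic_calibrate(s, truth)
        assert out[:n].mean() == pytest.approx(0.6, abs=0.05)

    def test_degenerate_truth_warns_identity(self):
        with pytest.warns(UserWarning):
            out = isotonic_calibrate([0.2, 0.5, 0.9], [1, 1, 1])
        assert np.allclose(out, [0.2, 0.5, 0.9])

    def test_constant_scores_error(self):
        with pytest.raises(ValueError):
            isotonic_calibrate([0.5, 0.5], [0, 1])


@pytest.fixture(scope="module")
def calibrator_world():
    scores, y = _synthetic_pool(1200, seed=8)
    comms = sample_communities(scores, y, 260, (100, 400), seed=9)
    model = train_calibrator(comms[:200], seed=0, epochs=25)
    return scores, y, comms, model


class TestCalibrator:
    def test_needs_enough_communities(self):
        scores, y = _synthetic_pool(200)
        comms = sample_communities(scores, y, 5, (50, 80), seed=0)
        with pytest.raises(ValueError):
            train_calibrator(comms, seed=0)

    def test_in_distribution_matches_isotonic_targets(self, calibrator_world):
        _, _, comms, model = calibrator_world
        comm = comms[210]
        target = isotonic_calibrate_multiclass(comm.scores, comm.labels)
        pred = model.predict(comm.composition, comm.scores)
        assert np.abs(pred - target).mean() < 0.05

    def test_monotone_on_probe_grid(self, calibrator_world):
        _, _, comms, model = calibrator_world
        comp = comms[0].composition
        grid = np.linspace(0.02, 0.98, 25)
        for c in range(3):
            raw = np.full((25, 3), 0.0)
            raw[:, c] = grid
            for o in range(3):
                if o != c:
                    raw[:, o] = (1 - grid) / 2
            out = model.predict(comp, raw)[:, c]
            assert np.all(np.diff(out) >= -1e-9)

    def test_deterministic_given_seed(self):
        scores, y = _synthetic_pool(500, seed=10)
        comms = sample_communities(scores, y, 120, (100, 200), seed=11)
        a = train_calibrator(comms, seed=5, epochs=5)
        b = train_calibrator(comms, seed=5, epochs=5)
        for pa, pb in zip(a.params, b.params):
            assert np.array_equal(pa.value, pb.value)

    def test_save_load_round_trip(self, calibrator_world, tmp_path):
        _, _, comms, model = calibrator_world
        p = tmp_path / "cal.json"
        model.save(p)
        back = CalibratorModel.load(p)
        raw = comms[0].scores[:20]
        assert np.allclose(
            back.predict(comms[0].composition, raw),
            model.predict(comms[0].composition, raw),
        )

    def test_batch_passthrough_below_ten(self, calibrator_world):
        _, _, comms, model = calibrator_world
        raw = comms[0].scores[:5]
        with pytest.warns(UserWarning):
            out = calibrate_scores(model, raw)
        assert np.array_equal(out, raw)

    def test_identical_rows_calibrate_identically(self, calibrator_world):
        _, _, comms, model = calibrator_world
        raw = np.tile([[0.2, 0.3, 0.5]], (30, 1))
        out = calibrate_scores(model, raw)
        assert np.allclose(out, out[0])
        assert np.allclose(out.sum(axis=1), 1.0, atol=1e-9)

    def test_host_dominated_batch_lowers_mge_scores(self, calibrator_world):
        scores, y, _, model = calibrator_world
        probe = np.array([0.2, 0.3, 0.5])
        chrom_comp = np.array([0.9, 0.05, 0.05])
        balanced_comp = np.array([1 / 3, 1 / 3, 1 / 3])
        out_chrom = model.predict(chrom_comp, probe[None, :])[0]
        out_bal = model.predict(balanced_comp, probe[None, :])[0]
        assert out_chrom[1] < out_bal[1]
        assert out_chrom[2] < out_bal[2]


class TestFdr:
    def test_arithmetic(self):
        assert fdr_from_scores([0.9, 0.9, 0.9], 0.8) == pytest.approx(0.1)

    def test_empty_acceptance(self):
        assert fdr_from_scores([0.1, 0.2], 0.8) is None

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            fdr_from_scores([0.5], 1.5)

    def test_well_calibrated_simulation(self):
        rng = np.random.default_rng(12)
        s = rng.random(20_000)
        truth = rng.random(20_000) < s  # scores ARE the true probabilities
        est = fdr_from_scores(s, 0.8)
        realized = float(np.mean(~truth[s >= 0.8]))
        assert est == pytest.approx(realized, abs=0.03)
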