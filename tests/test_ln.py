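"""LN baseline: spike-triggered moments, iSTAC, nonlinearities, tuning."""

import numpy as np
import pytest

from glidernet import ln


def _planted_ln(n=5000, d=64, seed=0, noise=0.0):
    """White Gaussian stimuli, rate = softplus of one filter's projection."""
    rng = np.random.default_rng(seed)
    stimuli = rng.normal(size=(n, d))
    f = rng.normal(size=d)
    f /= np.linalg.norm(f)
    proj = stimuli @ f
    rates = np.log1p(np.exp(2.0 * proj)) + noise * rng.normal(size=n) ** 2
    return stimuli, np.maximum(rates, 0.0), f


class TestSpikeTriggeredMoments:
    def test_constant_rates_reduce_to_raw_moments(self):
        rng = np.random.default_rng(0)
        stimuli = rng.normal(size=(500, 16))
        m = ln.spike_triggered_moments(stimuli, np.full(500, 3.0))
        assert np.allclose(m.sta, m.raw_mean, atol=1e-12)
        assert np.allclose(m.stc, m.raw_cov, atol=1e-12)

    def test_rate_scale_invariance(self):
        rng = np.random.default_rng(1)
        stimuli = rng.normal(size=(300, 8))
        rates = rng.gamma(2.0, 1.0, size=300)
        a = ln.spike_triggered_moments(stimuli, rates)
        b = ln.spike_triggered_moments(stimuli, 7.0 * rates)
        assert np.allclose(a.sta, b.sta)
        assert np.allclose(a.stc, b.stc)

    def test_single_pixel_drive_dominates_sta(self):
        rng = np.random.default_rng(2)
        stimuli = rng.normal(size=(20000, 32))
        rates = np.maximum(0.0, 2.0 + stimuli[:, 7])  # rate follows pixel 7
        m = ln.spike_triggered_moments(stimuli, rates)
        assert np.argmax(np.abs(m.sta)) == 7
        assert np.abs(m.sta[7]) > 3 * np.median(np.abs(m.sta))

    def test_zero_rates_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            ln.spike_triggered_moments(np.ones((10, 4)), np.zeros(10))


class TestIstacFilters:
    def test_no_divergence_means_no_information(self):
        rng = np.random.default_rng(3)
        stimuli = rng.normal(size=(4000, 10))
        m = ln.spike_triggered_moments(stimuli, np.full(4000, 2.0))
        _, info, _ = ln.istac_filters(m, 3)
        assert np.all(info < 0.02)

    def test_planted_filter_recovery(self):
        stimuli, rates, f = _planted_ln(n=20000, d=64, seed=4)
        m = ln.spike_triggered_moments(stimuli, rates)
        _, _, stim_filters = ln.istac_filters(m, 1)
        cos = abs(stim_filters[0] @ f) / np.linalg.norm(stim_filters[0])
        assert cos > 0.9

    def test_filters_orthonormal_and_info_monotone(self):
        stimuli, rates, _ = _planted_ln(n=4000, d=24, seed=5, noise=0.5)
        m = ln.spike_triggered_moments(stimuli, rates)
        filters, info, _ = ln.istac_filters(m, 6)
        gram = filters @ filters.T
        assert np.allclose(gram, np.eye(6), atol=1e-8)
        assert np.all(info >= 0.0)
        # greedy increments are non-increasing up to orthogonalization noise
        assert np.all(np.diff(info) <= 1e-3)

    def test_first_filter_beats_every_coordinate_axis(self):
        stimuli, rates, _ = _planted_ln(n=6000, d=12, seed=6)
        m = ln.spike_triggered_moments(stimuli, rates)
        _, info, _ = ln.istac_filters(m, 1)
        W, mu, Lam = ln._whiten(m)
        axis_infos = [
            ln._kl_objective(np.eye(12)[:, [i]], mu, Lam) for i in range(12)
        ]
        assert info[0] >= max(axis_infos) - 1e-9

    def test_too_many_filters_rejected(self):
        m = ln.spike_triggered_moments(np.random.default_rng(0).normal(size=(50, 4)),
                                       np.ones(50))
        with pytest.raises(ValueError, match="n_filters"):
            ln.istac_filters(m, 5)


class TestNonlinearity:
    def test_rate_independent_of_projection_is_flat(self):
        rng = np.random.default_rng(7)
        proj = rng.normal(size=20000)
        rates = rng.gamma(4.0, 2.0, size=20000)  # mean 8, independent of proj
        nl = ln.estimate_nonlinearity(proj, rates)
        inner = np.abs(nl.bin_centers) < 2.5  # bins with enough samples
        assert np.all(np.abs(nl.values[inner] - 8.0) < 1.0)

    def test_planted_monotone_rate_recovered(self):
        rng = np.random.default_rng(8)
        proj = rng.normal(size=20000)
        rates = np.maximum(0.0, 1.0 + 2.0 * proj)
        nl = ln.estimate_nonlinearity(proj, rates)
        inner = (np.abs(nl.bin_centers) < 2.0)  # well-populated bins
        assert np.all(np.diff(nl.values[inner]) >= -1e-9)

    def test_zero_rates_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            ln.estimate_nonlinearity(np.random.default_rng(0).normal(size=100),
                                     np.zeros(100))


class TestPredictionAndTuning:
    def test_flat_nonlinearity_predicts_constant(self):
        nl = ln.Nonlinearity(np.linspace(-4, 4, 25), np.full(25, 5.0))
        w = np.zeros(8)
        w[0] = 1.0
        pred = ln.ln_predict(np.random.default_rng(0).normal(size=(40, 8)),
                             w[None], [nl], np.zeros(8))
        assert np.allclose(pred, 5.0)

    def test_prediction_ignores_orthogonal_components(self):
        stimuli, rates, _ = _planted_ln(n=3000, d=16, seed=9)
        res = ln.LinearNonlinearModel(stimuli, rates).fit(n_filters=2)
        base = np.zeros((1, 16))
        # add a perturbation orthogonal to every stimulus filter
        rng = np.random.default_rng(10)
        v = rng.normal(size=16)
        F = res.stimulus_filters  # not mutually orthogonal in stimulus space
        v -= F.T @ np.linalg.solve(F @ F.T, F @ v)
        assert np.allclose(res.predict(base), res.predict(base + v), atol=1e-9)

    def test_planted_model_heldout_rate_correlation(self):
        stimuli, rates, f = _planted_ln(n=20000, d=32, seed=11)
        res = ln.LinearNonlinearModel(stimuli[:15000], rates[:15000]).fit(n_filters=1)
        pred = res.predict(stimuli[15000:])
        assert np.corrcoef(pred, rates[15000:])[0, 1] > 0.8

    def test_tuning_correlation_identities(self):
        labels = np.repeat(np.arange(7), 10)
        curve = np.repeat(np.arange(7.0), 10)
        assert ln.evaluate_tuning(curve, curve, labels) == pytest.approx(1.0)
        assert ln.evaluate_tuning(curve, -curve, labels) == pytest.approx(-1.0)
        with pytest.raises(ValueError, match="constant"):
            ln.evaluate_tuning(np.ones(70), curve, labels)

    def test_parity_selective_responder_defeats_ln_generalization(self):
        """An even-texture detector is fitted on the train set but the fit
        does not transfer to fresh textures: multipoint selectivity is not
        LN-expressible."""
        from glidernet.pipeline import flatten_stimuli, generate_class_ensembles
        from glidernet.surrogates import SurrogateNeuron, expected_rates

        neuron = SurrogateNeuron(
            neuron_id=0, baseline_rate=20.0,
            class_gains={"even": 0.6, "odd": -0.2}, example_sensitivity=0.35,
            transient_amp=0.3, tau=1.5, rf_corner=(4, 4),
        )
        train = generate_class_ensembles(300, 3, "lntr")
        test = generate_class_ensembles(300, 3, "lnte")
        s_tr, l_tr = flatten_stimuli(train)
        s_te, l_te = flatten_stimuli(test)

        def rates(grids):
            return np.concatenate(
                [expected_rates(neuron, g, c).mean(axis=1) for c, g in grids.items()]
            )

        r_tr = rates(train)
        train_curve = np.array([r_tr[l_tr == c].mean() for c in np.unique(l_tr)])
        res = ln.LinearNonlinearModel(s_tr, r_tr).fit(n_filters=8)
        fit_train = ln.evaluate_tuning(res.predict(s_tr), r_tr, l_tr, method="pearson")
        fit_test = ln.evaluate_tuning(
            res.predict(s_te), train_curve, l_te, method="pearson"
        )
        assert fit_train > 0.9
        assert fit_test < fit_train - 0.1

    def test_ln_expressible_responder_generalizes(self):
        # when the true mapping is LN, train and test tuning agree closely
        rng = np.random.default_rng(12)
        d = 16
        f = rng.normal(size=d)
        f /= np.linalg.norm(f)

        def responder(s):
            return np.log1p(np.exp(s @ f))

        train_s = rng.normal(size=(8000, d))
        test_s = rng.normal(size=(4000, d))
        labels_tr = np.repeat(np.arange(8), 1000)
        labels_te = np.repeat(np.arange(8), 500)
        # class structure: shift stimuli along f by class-dependent amounts
        shifts = np.linspace(-1, 1, 8)
        train_s += shifts[labels_tr][:, None] * f
        test_s += shifts[labels_te][:, None] * f
        res = ln.LinearNonlinearModel(train_s, responder(train_s)).fit(n_filters=1)
        r_train = ln.evaluate_tuning(res.predict(train_s), responder(train_s), labels_tr)
        r_test = ln.evaluate_tuning(res.predict(test_s), responder(test_s), labels_te)
        assert r_train > 0.9
        assert abs(r_train - r_test) < 0.05
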