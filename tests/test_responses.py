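"""Significance criterion, clustering, SI/OSI, latency and delay modulation."""

import numpy as np
import pytest
from scipy import stats
from scipy.optimize import linear_sum_assignment

from caltask import responses, synthetic
from caltask.core import TrialAlignedTraces
from caltask.responses import (
    choose_k, cluster_responses, compute_osi, compute_selectivity,
    criterion_chance_level, delay_modulation, estimate_latency,
    normalize_response, population_modal_latency, response_features,
    signed_rank_test,
)

classify_responses = responses.test_significance


class TestSignedRank:
    @pytest.mark.parametrize("n", [6, 10, 18, 25])
    def test_matches_scipy_exact(self, n):
        rng = np.random.default_rng(n)
        for _ in range(20):
            d = rng.standard_normal(n) + rng.uniform(-0.5, 0.5)
            p, direc = signed_rank_test(d)
            expected = stats.wilcoxon(d, method="exact").pvalue
            assert p == pytest.approx(expected, abs=1e-12)
            assert direc == np.sign(np.median(d))

    def test_vectorized_matches_looped(self):
        rng = np.random.default_rng(0)
        d = rng.standard_normal((7, 9, 12))
        p, _ = signed_rank_test(d, axis=-1)
        for i in range(7):
            for j in range(9):
                assert p[i, j] == pytest.approx(
                    stats.wilcoxon(d[i, j], method="exact").pvalue)

    def test_all_zero_slice_p_one(self):
        p, direc = signed_rank_test(np.zeros((2, 8)))
        assert (p == 1.0).all()
        assert (direc == 0).all()


class TestSignificanceCriterion:
    def test_noiseless_archetype_detected_all_delays(self, session_table):
        mix = {"StimOnly": 1.0,
               **{a: 0.0 for a in synthetic.ARCHETYPES[1:]}}
        tr, _ = synthetic.generate_traces(session_table, mix, n_neurons=2,
                                          noise_sd=0.02, seed=1)
        sig = classify_responses(tr)
        assert sig.significant.all()
        assert (sig.direction == 1).all()
        assert (sig.qualifying[("hit", 1)] + sig.qualifying[("CR", 1)]
                >= 3).any()

    def test_suppressed_archetype_direction(self, session_table):
        mix = {a: (1.0 if a == "SuppDelayEarly" else 0.0)
               for a in synthetic.ARCHETYPES}
        tr, _ = synthetic.generate_traces(session_table, mix, n_neurons=2,
                                          noise_sd=0.02, seed=2)
        sig = classify_responses(tr)
        assert sig.significant.all()
        assert (sig.direction == -1).all()

    def test_null_neurons_not_flagged(self, session_table):
        # full inclusion rule: the qualifying pattern must appear in both
        # the corrected and the uncorrected tensor
        rng = np.random.default_rng(3)
        t = synthetic.time_grid(1.0, 11.5, 5.0)
        shape = (500, len(session_table), t.size)
        tr = TrialAlignedTraces(dff=rng.standard_normal(shape), time_s=t,
                                table=session_table,
                                raw_dff=rng.standard_normal(shape))
        sig = classify_responses(tr)
        assert sig.significant.sum() == 0

    def test_raw_disagreement_vetoes(self, session_table):
        mix = {"StimOnly": 1.0,
               **{a: 0.0 for a in synthetic.ARCHETYPES[1:]}}
        tr, _ = synthetic.generate_traces(session_table, mix, n_neurons=2,
                                          noise_sd=0.02, seed=4)
        # replace the raw tensor with pure noise: criterion must fail
        rng = np.random.default_rng(5)
        tr.raw_dff = rng.standard_normal(tr.dff.shape)
        sig = classify_responses(tr)
        assert sig.significant.sum() == 0

    def test_chance_level_below_design_bound(self):
        p = criterion_chance_level(n_samples=60)
        assert p < 1e-9
        # longer traces stay under the bound too
        assert criterion_chance_level(n_samples=65) < 1e-9

    def test_chance_level_matches_binomial_composition(self):
        # independent recomputation of the union bound
        p_trace = stats.binom.sf(9, 60, 0.025)
        assert criterion_chance_level(60) == pytest.approx(
            2 * 2 * 3 * p_trace ** 2, rel=1e-12)


class TestNormalization:
    def test_enhanced_peak_is_one(self, small_traces):
        tr, _ = small_traces
        sig = classify_responses(tr)
        normed, norm = normalize_response(tr, sig)
        correct = tr.table["outcome"].isin(["hit", "CR"]).to_numpy()
        for i in np.flatnonzero(sig.enhanced)[:5]:
            avg = normed[i, correct].mean(axis=0)
            assert avg.max() == pytest.approx(1.0, abs=1e-9)

    def test_suppressed_trough_is_minus_one(self, small_traces):
        tr, _ = small_traces
        sig = classify_responses(tr)
        normed, _ = normalize_response(tr, sig)
        correct = tr.table["outcome"].isin(["hit", "CR"]).to_numpy()
        for i in np.flatnonzero(sig.suppressed)[:5]:
            avg = normed[i, correct].mean(axis=0)
            assert avg.min() == pytest.approx(-1.0, abs=1e-9)


class TestClustering:
    def test_archetype_recovery_at_least_ninety_percent(self, benchmark_traces):
        tr, truth = benchmark_traces
        sig = classify_responses(tr)
        feats = response_features(tr, sig)
        ok = np.isfinite(feats).all(axis=1)
        model = cluster_responses(feats[ok], k=6)
        arch = truth.archetype[ok]
        names = sorted(set(arch))
        C = np.zeros((6, len(names)))
        for lab, a in zip(model.labels, arch):
            C[lab - 1, names.index(a)] += 1
        r, c = linear_sum_assignment(-C)
        assert C[r, c].sum() / len(arch) >= 0.9

    def test_choose_k_finds_six_archetypes(self, benchmark_traces):
        tr, _ = benchmark_traces
        sig = classify_responses(tr)
        feats = response_features(tr, sig)
        assert choose_k(feats, range(1, 11)) == 6

    def test_choose_k_two_archetypes(self, session_table):
        mix = {a: 0.0 for a in synthetic.ARCHETYPES}
        mix.update({"StimOnly": 0.5, "RespOnly": 0.5})
        tr, _ = synthetic.generate_traces(session_table, mix, n_neurons=100,
                                          noise_sd=0.05, seed=31)
        sig = classify_responses(tr)
        feats = response_features(tr, sig)
        assert choose_k(feats, range(1, 7)) == 2

    def test_identical_neurons_single_cluster(self):
        feats = np.tile(np.sin(np.linspace(0, 3, 50)), (20, 1))
        feats = feats + 1e-6 * np.random.default_rng(0).standard_normal(feats.shape)
        assert choose_k(feats, range(1, 5)) == 1

    def test_duplicate_neuron_same_label(self, benchmark_traces):
        tr, _ = benchmark_traces
        sig = classify_responses(tr)
        feats = response_features(tr, sig)[:50]
        feats = np.vstack([feats, feats[3]])
        model = cluster_responses(feats, k=4)
        assert model.labels[3] == model.labels[-1]

    def test_k_one_returns_grand_mean(self):
        rng = np.random.default_rng(1)
        feats = rng.standard_normal((30, 40))
        model = cluster_responses(feats, k=1)
        assert (model.labels == 1).all()
        np.testing.assert_allclose(model.cluster_means[0], feats.mean(axis=0))

    def test_recategorization_never_decreases_correlation(self, benchmark_traces):
        tr, _ = benchmark_traces
        sig = classify_responses(tr)
        feats = response_features(tr, sig)
        model = cluster_responses(feats, k=6)
        # stored correlation is the max over cluster means by construction
        r = responses._corr_to_means(feats, model.cluster_means)
        np.testing.assert_allclose(model.correlation, r.max(axis=1),
                                   atol=1e-12)

    def test_k_exceeding_population_rejected(self):
        with pytest.raises(ValueError):
            cluster_responses(np.zeros((3, 10)), k=5)


class TestSelectivity:
    def test_formula_cases(self):
        # SI = (Rp − Rn)/(Rp + Rn)
        assert (0.3 - 0.0) / (0.3 + 0.0) == 1.0
        assert (0.3 - 0.1) / (0.3 + 0.1) == pytest.approx(0.5)

    def test_selective_neurons_score_high(self, session_table):
        mix = {"StimOnly": 1.0,
               **{a: 0.0 for a in synthetic.ARCHETYPES[1:]}}

        def fully_selective(rng):
            return 0.0

        spec = synthetic.ArchetypeSpec("StimOnly",
                                       selectivity_dist=fully_selective)
        tr, _ = synthetic.generate_traces(
            session_table, mix, n_neurons=5, noise_sd=0.01, seed=41,
            archetypes={**synthetic.default_archetypes(), "StimOnly": spec})
        sig = classify_responses(tr)
        sel = compute_selectivity(tr, sig)
        assert (sel.si > 0.9).all()

    def test_unselective_neurons_score_low(self, session_table):
        mix = {"StimOnly": 1.0,
               **{a: 0.0 for a in synthetic.ARCHETYPES[1:]}}
        spec = synthetic.ArchetypeSpec("StimOnly",
                                       selectivity_dist=lambda rng: 1.0)
        tr, _ = synthetic.generate_traces(
            session_table, mix, n_neurons=5, noise_sd=0.01, seed=42,
            archetypes={**synthetic.default_archetypes(), "StimOnly": spec})
        sig = classify_responses(tr)
        sel = compute_selectivity(tr, sig)
        assert (np.abs(sel.si) < 0.1).all()

    def test_si_bounded_and_scale_invariant(self, small_traces):
        tr, _ = small_traces
        sig = classify_responses(tr)
        sel = compute_selectivity(tr, sig)
        finite = np.isfinite(sel.si)
        assert ((sel.si[finite] >= 0) & (sel.si[finite] <= 1)).all()
        tr2 = TrialAlignedTraces(dff=3.0 * tr.dff, time_s=tr.time_s,
                                 table=tr.table, raw_dff=None,
                                 baseline_window=tr.baseline_window)
        sel2 = compute_selectivity(tr2, sig)
        np.testing.assert_allclose(sel.si[finite], sel2.si[finite],
                                   atol=1e-9)


class TestOSI:
    @pytest.mark.parametrize("responses_,expected", [
        ({0.0: 1.0, 90.0: 0.0}, 1.0),
        ({0.0: 1.0, 90.0: 1.0}, 0.0),
        ({0.0: 2.0, 90.0: 1.0}, 1 / 3),
    ])
    def test_arithmetic(self, responses_, expected):
        osi, theta = compute_osi(responses_)
        assert osi == pytest.approx(expected)

    def test_missing_orthogonal_rejected(self):
        with pytest.raises(ValueError):
            compute_osi({0.0: 1.0, 45.0: 0.5})


class TestLatency:
    def test_step_onset_recovered(self):
        t = np.round(np.arange(-1000, 5000) / 1000, 6)
        y = np.where((t >= 0.2) & (t < 2.2), 1.0, 0.0)
        assert estimate_latency(y, t) == pytest.approx(0.2, abs=1e-3)

    def test_short_excursion_rejected(self):
        t = np.round(np.arange(-1000, 5000) / 1000, 6)
        y = np.where((t >= 0.2) & (t < 1.1), 1.0, 0.0)
        assert estimate_latency(y, t) is None

    def test_shift_equivariance(self):
        t = np.round(np.arange(-1000, 6000) / 1000, 6)
        y1 = np.where((t >= 0.3) & (t < 2.3), 1.0, 0.0)
        y2 = np.where((t >= 1.1) & (t < 3.1), 1.0, 0.0)
        l1, l2 = estimate_latency(y1, t), estimate_latency(y2, t)
        assert l2 - l1 == pytest.approx(0.8, abs=2e-3)

    def test_suppressed_excursion_detected(self):
        t = np.round(np.arange(-1000, 5000) / 1000, 6)
        rng = np.random.default_rng(0)
        y = 0.01 * rng.standard_normal(t.size)
        y[(t >= 0.5) & (t < 2.0)] -= 1.0
        lat = estimate_latency(y, t)
        assert lat == pytest.approx(0.5, abs=0.01)

    def test_first_mode_of_bimodal_population(self):
        rng = np.random.default_rng(6)
        lat = np.concatenate([rng.normal(0.1, 0.02, 300),
                              rng.normal(1.0, 0.1, 200)])
        mode = population_modal_latency(lat)
        assert mode == pytest.approx(0.1, abs=0.05)


class TestDelayModulation:
    def test_delay_archetype_positive_dmi(self, session_table):
        mix = {"Delay": 1.0, **{a: 0.0 for a in synthetic.ARCHETYPES
                                if a != "Delay"}}
        tr, _ = synthetic.generate_traces(session_table, mix, n_neurons=10,
                                          noise_sd=0.02, seed=51)
        dm = delay_modulation(tr, sign="enhanced")
        assert dm.dmi == 1.0
        assert dm.n_pos == 10 and dm.n_neg == 0

    def test_dmi_arithmetic(self):
        # 3 positive, 1 negative -> (3-1)/(3+1)
        assert (3 - 1) / (3 + 1) == 0.5

    def test_suppressed_sign_flip(self, session_table):
        mix = {a: (1.0 if a == "SuppDelayEarly" else 0.0)
               for a in synthetic.ARCHETYPES}
        tr, _ = synthetic.generate_traces(session_table, mix, n_neurons=10,
                                          noise_sd=0.02, seed=52)
        dm = delay_modulation(tr, sign="suppressed")
        # suppressed delay cells integrate more negatively at longer delays
        assert dm.n_neg == 10
        assert dm.dmi == 1.0

    def test_single_delay_rejected(self):
        cfg = synthetic.SessionConfig(n_trials=40, delay_set=(6.0,), seed=1)
        table = synthetic.generate_session(cfg)
        mix = {a: 1 / 6 for a in synthetic.ARCHETYPES}
        tr, _ = synthetic.generate_traces(table, mix, n_neurons=4,
                                          noise_sd=0.05, seed=2)
        with pytest.raises(ValueError):
            delay_modulation(tr)
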