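"""Subset selection, priors, the variance barrier, and oscillation control."""

import numpy as np
import pytest
from scipy.stats import norm

import otgpd.hyperopt as ho
from otgpd import (
    AtomicConfiguration,
    KernelParams,
    Observation,
    PairTypeMap,
    SurrogateModel,
    barrier_strength,
    fps_select,
    intensive_emd,
    optimize_hyperparameters,
    oscillation_fraction,
    student_t_log_prior,
)
from otgpd.hyperopt import (
    BarrierConfig,
    BarrierDomainError,
    HyperoptConfig,
    PriorConfig,
    barrier_gradient_w0,
    barrier_term,
    effective_objective,
)
from otgpd.kernel import kernel_blocks
from otgpd.surfaces import make_morse_cluster, perturb_configuration


def _cluster_history(n, spread=0.35, seed0=0):
    _, base = make_morse_cluster(4)
    return [perturb_configuration(base, spread, seed0 + i) for i in range(n)]


class TestFPS:
    def test_small_history_returns_everything(self):
        configs = _cluster_history(4)
        assert fps_select(configs, 10) == [0, 1, 2, 3]

    def test_two_most_recent_always_retained(self):
        configs = _cluster_history(12)
        for msub in (2, 3, 5, 8):
            s = fps_select(configs, msub)
            assert 10 in s and 11 in s

    def test_third_pick_is_farthest_cluster(self):
        """Recency seeds sit in one tight cluster; with three well-separated
        clusters the first grown member must come from the farthest one."""
        _, base = make_morse_cluster(4)
        near = [perturb_configuration(base, 0.01, i) for i in range(3)]
        mid = base.with_positions(base.positions + [3.0, 0.0, 0.0])
        far = base.with_positions(base.positions + [30.0, 0.0, 0.0])
        configs = [far, mid] + near  # recency seeds = indices 3, 4 (near cluster)
        s = fps_select(configs, 3)
        assert s == [0, 3, 4]

    def test_greedy_choice_matches_exhaustive_maxmin(self):
        configs = _cluster_history(9, spread=0.6)
        s = fps_select(configs, 3, energy_filter_kappa=None)
        seeds = [7, 8]
        grown = [i for i in s if i not in seeds]
        assert len(grown) == 1
        dist = {
            i: min(intensive_emd(configs[i], configs[j]) for j in seeds)
            for i in range(7)
        }
        best = max(dist.values())
        assert dist[grown[0]] == pytest.approx(best)

    def test_tie_break_lowest_index(self):
        _, base = make_morse_cluster(4)
        mirror = base.with_positions(base.positions + [2.0, 0.0, 0.0])
        # two identical far candidates: index 0 must win the tie
        configs = [mirror.copy(), mirror.copy(), base.copy(), base.copy()]
        s = fps_select(configs, 3, energy_filter_kappa=None)
        assert s == [0, 2, 3]

    def test_energy_filter_defers_outliers(self):
        configs = _cluster_history(10, spread=0.3)
        energies = np.zeros(10)
        energies[0] = 1e6  # absurdly strained outlier, also geometrically far
        configs[0] = configs[0].with_positions(configs[0].positions * 5.0)
        s_filtered = fps_select(configs, 4, energies=energies, energy_filter_kappa=3.0)
        assert 0 not in s_filtered
        s_free = fps_select(configs, 4, energy_filter_kappa=None)
        assert 0 in s_free


class TestStudentTPrior:
    def test_dof_floor(self):
        prior = PriorConfig()
        assert prior.dof(1) == 28
        assert prior.dof(20) == 28
        assert prior.dof(40) == 40

    def test_symmetric_about_location(self):
        prior = PriorConfig()
        up = KernelParams(1.0, np.exp(0.8), np.ones(1))
        down = KernelParams(1.0, np.exp(-0.8), np.ones(1))
        assert student_t_log_prior(up, prior, 1) == pytest.approx(
            student_t_log_prior(down, prior, 1), rel=1e-12
        )

    def test_gaussian_limit_at_large_dof(self):
        prior = PriorConfig(dof_floor=28, dof_per_interaction_type=1.0)
        params = KernelParams(1.0, np.exp(0.5), np.exp([-0.3]))
        w = params.to_log_vector()
        lp = student_t_log_prior(params, prior, int(1e4))
        gauss = norm.logpdf(w, loc=0.0, scale=1.0).sum()
        assert lp == pytest.approx(gauss, abs=1e-3)


class TestBarrier:
    def test_strength_schedule(self):
        cfg = BarrierConfig()
        assert barrier_strength(0, cfg) == pytest.approx(1e-4)
        assert barrier_strength(100, cfg) == pytest.approx(0.1001)
        assert barrier_strength(10**6, cfg) == pytest.approx(0.5)

    def test_diverges_at_bound(self):
        cfg = BarrierConfig()
        vals = [barrier_term(cfg.lambda_max - 10.0**-k, 0.3, cfg) for k in range(1, 10)]
        assert all(b > a for a, b in zip(vals, vals[1:])) is False  # decreasing
        assert vals[-1] < -5.0
        with pytest.raises(BarrierDomainError):
            barrier_term(cfg.lambda_max, 0.3, cfg)

    def test_gradient_matches_finite_differences(self):
        cfg = BarrierConfig()
        mu = 0.37
        for w0 in (-1.0, 0.0, 0.5, cfg.lambda_max - 1e-3):
            h = 1e-8
            fd = (barrier_term(w0 + h, mu, cfg) - barrier_term(w0 - h, mu, cfg)) / (2 * h)
            assert barrier_gradient_w0(w0, mu, cfg) == pytest.approx(fd, rel=1e-6)

    def test_zero_strength_recovers_plain_objective(self):
        model = _fitted_model()
        cfg = HyperoptConfig(barrier=BarrierConfig(mu0=0.0, alpha=0.0))
        subset = list(range(model.n_data))
        obj = effective_objective(model.params, model, subset, cfg, n_data=model.n_data)
        plain = model.log_marginal_likelihood(model.params, subset) + student_t_log_prior(
            model.params, cfg.prior, model.pairmap.n_types
        )
        assert obj == pytest.approx(plain, rel=1e-12)

    def test_barrier_additivity(self):
        model = _fitted_model()
        subset = list(range(model.n_data))
        on = HyperoptConfig(barrier=BarrierConfig(mu0=0.2, alpha=0.0))
        off = HyperoptConfig(barrier=BarrierConfig(mu0=0.0, alpha=0.0))
        w0 = float(np.log(model.params.sigma_f2))
        delta = effective_objective(model.params, model, subset, on, 5) - effective_objective(
            model.params, model, subset, off, 5
        )
        assert delta == pytest.approx(barrier_term(w0, 0.2, on.barrier), rel=1e-10)


def _fitted_model(n=5):
    pes, base = make_morse_cluster(4)
    pm = PairTypeMap.from_elements(base.elements)
    model = SurrogateModel(KernelParams(1.0, 1.0, np.full(pm.n_types, 0.7)), pm)
    for i in range(n):
        xi = perturb_configuration(base, 0.3, i)
        e, g = pes.evaluate(xi)
        model.add_observation(Observation(xi, e, g))
    return model


class TestOscillationFraction:
    def test_constant_history(self):
        trace = np.zeros((8, 3))
        assert oscillation_fraction(trace, 6) == 0.0

    def test_strict_alternation(self):
        t = np.arange(8)
        trace = np.column_stack([(-1.0) ** t, 2.0 * (-1.0) ** t])
        assert oscillation_fraction(trace, 6) == 1.0

    def test_monotone_history(self):
        trace = np.cumsum(np.ones((7, 2)), axis=0)
        assert oscillation_fraction(trace, 6) == 0.0

    def test_short_window_convention(self):
        assert oscillation_fraction(np.ones((2, 3)), 6) == 0.0

    def test_partial_alternation(self):
        # one oscillating component out of two: half the cells fire
        t = np.arange(8)
        trace = np.column_stack([(-1.0) ** t, t.astype(float)])
        assert oscillation_fraction(trace, 6) == pytest.approx(0.5)


class TestOptimizeHyperparameters:
    def test_subset_never_exceeds_cap(self):
        model = _fitted_model(n=12)
        cfg = HyperoptConfig(msub_init=3, msub_cap=6)
        params, trace, msub = optimize_hyperparameters(model, cfg)
        assert all(s <= 12 for s in trace.subset_sizes)
        assert msub <= 6
        assert len(model.subset) <= 12

    def test_barrier_bound_respected(self):
        model = _fitted_model(n=8)
        params, _, _ = optimize_hyperparameters(model, HyperoptConfig())
        assert np.log(params.sigma_f2) < np.log(2.0)

    def test_requires_two_observations(self):
        model = _fitted_model(n=1)
        with pytest.raises(ValueError):
            optimize_hyperparameters(model, HyperoptConfig())

    def test_forced_oscillation_limited_to_three_retries(self, monkeypatch):
        """An adversarial optimizer stub that always reports alternating
        iterates must trigger subset growth at most three times."""
        model = _fitted_model(n=12)
        calls = {"count": 0}

        class FakeResult:
            def __init__(self, w):
                self.x = w
                self.fun = 0.0

        def fake_minimize(fun, w0, callback=None, **kwargs):
            calls["count"] += 1
            for t in range(8):
                w = np.array(w0) + 0.1 * (-1.0) ** t
                if callback is not None:
                    callback(w)
            return FakeResult(np.array(w0))

        monkeypatch.setattr(ho, "minimize", fake_minimize)
        cfg = HyperoptConfig(msub_init=4, msub_cap=30, n_random_starts=0)
        params, trace, msub = optimize_hyperparameters(model, cfg)
        assert trace.retries == 3
        assert trace.unstable
        assert all(f == 1.0 for f in trace.oscillation_fractions)
        # growth: 4 -> 9 -> 14 -> 19, capped far below 30
        assert trace.subset_sizes == [4, 9, 12, 12]

    def test_legacy_mode_uses_full_history_once(self):
        model = _fitted_model(n=9)
        params, trace, _ = optimize_hyperparameters(
            model, HyperoptConfig(), legacy_full_history=True
        )
        assert trace.subset_sizes == [9]
        assert trace.retries == 0

    def test_recovers_known_hyperparameters(self):
        """Data drawn from a GP with known (sigma_f^2, l) on a triatomic:
        the fitted log-parameters land within 0.5 of the truth."""
        seed, n = 12, 30
        rng = np.random.default_rng(seed)
        base = AtomicConfiguration(
            ("A", "A", "A"), [[0, 0, 0], [1.4, 0, 0], [0.6, 1.2, 0]]
        )
        pm = PairTypeMap.from_elements(base.elements)
        true = KernelParams(1.0, 1.0, np.array([0.5]))
        configs = [perturb_configuration(base, 0.3, seed * 100 + i) for i in range(n)]
        kff, kfg, kgf, kgg = kernel_blocks(configs, configs, true, pm)
        cov = np.block([[kff, kfg], [kgf, kgg]]) + 1e-8 * np.eye(n * 10)
        y = np.linalg.cholesky(cov) @ rng.normal(size=n * 10)
        model = SurrogateModel(KernelParams(1.0, 0.5, np.array([1.5])), pm, 1e-8, 1e-8)
        for i, c in enumerate(configs):
            g = np.zeros(c.n_dof)
            g[c.dof_mask] = y[n + i * 9 : n + (i + 1) * 9]
            model.add_observation(Observation(c, float(y[i]), g))
        params, _, _ = optimize_hyperparameters(model, HyperoptConfig(msub_init=n))
        err = np.abs(params.to_log_vector() - true.to_log_vector())
        assert err.max() < 0.5
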