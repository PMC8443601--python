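"""Binning, global dwell fits, bootstrap, EM, titration, event counting."""

import numpy as np
import pytest

from kinlock.dwell_models import BindingRates, ThermoContext, TwoStateRates
from kinlock.experiments import simulate_open_dwells
from kinlock.inference import (
    FitResult,
    bootstrap_errors,
    em_two_exp_mixture,
    fit_global_double_exp,
    fit_titration_line,
    geometric_bins,
    kon_from_long_event_rate,
)
from kinlock.state_detection import extract_dwells
from kinlock.synthetic_data import build_recq_legf_scheme, gillespie_path, path_phase_dwells
from kinlock.state_detection import DwellRecord, DwellSet


class TestGeometricBins:
    def test_density_integrates_to_one(self):
        rng = np.random.default_rng(0)
        bd = geometric_bins(rng.exponential(0.01, 5000), a=1.4)
        assert np.sum(bd.densities * bd.widths) == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(bd.edges[1:] / bd.edges[:-1], 1.4)

    def test_density_tracks_exponential_law(self):
        """Bin densities agree with 100*exp(-100 t) within 3*sqrt(n) counting
        errors."""
        rng = np.random.default_rng(1)
        times = rng.exponential(0.01, 1000)
        bd = geometric_bins(times, a=1.5)
        expected = 100.0 * np.exp(-100.0 * bd.centers)
        nz = bd.counts >= 5
        sigma = bd.densities[nz] / np.sqrt(bd.counts[nz])
        assert np.all(np.abs(bd.densities[nz] - expected[nz]) < 3.5 * sigma)

    def test_single_time_single_bin(self):
        bd = geometric_bins(np.array([0.01]), a=1.4)
        assert (bd.counts > 0).sum() == 1
        assert np.sum(bd.densities * bd.widths) == pytest.approx(1.0)

    def test_duplication_leaves_densities_unchanged(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(0.01, 400)
        b1 = geometric_bins(t, a=1.3, t_min=1e-4, t_max=0.1)
        b2 = geometric_bins(np.repeat(t, 2), a=1.3, t_min=1e-4, t_max=0.1)
        assert np.allclose(b1.densities, b2.densities)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            geometric_bins(np.array([]), a=1.4)
        with pytest.raises(ValueError):
            geometric_bins(np.array([1.0]), a=1.1)
        with pytest.raises(ValueError):
            geometric_bins(np.array([1.0]), a=1.4, t_min=2.0, t_max=3.0)


RATES = TwoStateRates(100.0, 100.0)
NF_BINDING = BindingRates(1e-2, 10.9)


@pytest.fixture(scope="module")
def nf_dwellsets():
    """Open dwells at three concentrations at the no-fork operating point."""
    children = np.random.SeedSequence(301).spawn(3)
    return {
        c: simulate_open_dwells(RATES, NF_BINDING, c, 8000, s)
        for c, s in zip((0.0, 200.0, 800.0), children)
    }


class TestGlobalDoubleExpFit:
    def test_parameter_recovery(self, nf_dwellsets):
        fit = fit_global_double_exp(nf_dwellsets)
        assert fit.parameters["k_escape"] == pytest.approx(100.0, rel=0.05)
        assert fit.parameters["k_off"] == pytest.approx(10.9, rel=0.15)
        assert fit.parameters["k_on"] == pytest.approx(1e-2, rel=0.20)

    def test_binned_and_mle_agree(self, nf_dwellsets):
        fb = fit_global_double_exp(nf_dwellsets, method="binned")
        fm = fit_global_double_exp(nf_dwellsets, method="mle")
        for p in ("k_escape", "k_on", "k_off"):
            assert fm.parameters[p] == pytest.approx(fb.parameters[p], rel=0.10)

    def test_zero_concentration_only_reduces_to_single_exp(self):
        rng = np.random.default_rng(5)
        fit = fit_global_double_exp({0.0: rng.exponential(0.01, 5000)})
        assert fit.parameters["k_escape"] == pytest.approx(100.0, rel=0.05)
        assert np.isnan(fit.parameters["k_on"])
        assert "k_on" in fit.diagnostics["unidentifiable"]

    def test_fit_invariant_under_series_permutation(self, nf_dwellsets):
        forward = fit_global_double_exp(nf_dwellsets)
        shuffled = dict(reversed(list(nf_dwellsets.items())))
        backward = fit_global_double_exp(shuffled)
        for p in forward.parameters:
            assert forward.parameters[p] == pytest.approx(backward.parameters[p], rel=1e-9)

    def test_thin_series_dropped(self, nf_dwellsets):
        augmented = dict(nf_dwellsets)
        augmented[50.0] = augmented[200.0][:10]  # below min_events
        fit = fit_global_double_exp(augmented)
        assert fit.diagnostics["dropped_concentrations"] == [50.0]


class TestBootstrap:
    def test_same_seed_reproduces_errors(self, nf_dwellsets):
        small = {c: t[:2000] for c, t in nf_dwellsets.items()}
        b1 = bootstrap_errors(fit_global_double_exp, small, n_boot=10, seed=7)
        b2 = bootstrap_errors(fit_global_double_exp, small, n_boot=10, seed=7)
        assert b1.errors == b2.errors

    def test_degenerate_data_zero_spread(self):
        def mean_fit(ds):
            return FitResult(parameters={"mean": float(np.mean(ds[0.0]))})

        ds = {0.0: np.full(500, 0.01)}
        boot = bootstrap_errors(mean_fit, ds, n_boot=20, seed=0)
        assert boot.errors["mean"] == pytest.approx(0.0, abs=1e-12)
        assert boot.parameters["mean"] == pytest.approx(0.01)

    def test_excess_failures_raise(self):
        calls = {"n": 0}

        def flaky(ds):
            calls["n"] += 1
            if calls["n"] > 1:
                raise RuntimeError("no convergence")
            return FitResult(parameters={"p": 1.0})

        with pytest.raises(RuntimeError, match="bootstrap"):
            bootstrap_errors(flaky, {0.0: np.ones(100)}, n_boot=10, seed=0)


class TestEMTwoExpMixture:
    def test_pure_exponential_flagged_degenerate(self):
        rng = np.random.default_rng(8)
        res = em_two_exp_mixture(rng.exponential(0.01, 5000))
        assert res.degenerate

    def test_mixture_weight_recovered(self):
        rng = np.random.default_rng(9)
        n = 10_000
        slow = rng.exponential(1 / 4.0, int(0.2 * n))
        fast = rng.exponential(1 / 100.0, n - len(slow))
        res = em_two_exp_mixture(np.concatenate([slow, fast]))
        assert not res.degenerate
        assert res.weight_long == pytest.approx(0.2, abs=0.02)
        assert res.rate_slow == pytest.approx(4.0, rel=0.15)
        assert res.rate_fast == pytest.approx(100.0, rel=0.05)

    def test_log_likelihood_non_decreasing(self):
        rng = np.random.default_rng(10)
        t = np.concatenate([rng.exponential(0.25, 500), rng.exponential(0.01, 2000)])
        lls = [em_two_exp_mixture(t, max_iter=k).log_likelihood for k in (3, 6, 12, 50)]
        assert all(b >= a - 1e-9 for a, b in zip(lls, lls[1:]))

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            em_two_exp_mixture(np.ones(50))


class TestTitrationLine:
    CTX = ThermoContext()

    def _synthetic(self, ka=1.5e-3, t0=0.01, concs=(0.0, 100.0, 200.0, 400.0)):
        c = np.array(concs)
        means = t0 * (1 + ka * c)
        errors = np.full_like(means, t0 * 1e-3)
        return c, means, errors

    def test_exact_line_recovers_Ka_and_dG(self):
        c, m, e = self._synthetic()
        fit = fit_titration_line(c, m, e, conc_rel_err=0.0, ctx=self.CTX)
        assert fit.parameters["Ka_nM"] == pytest.approx(1.5e-3, rel=1e-6)
        expected_dg = -self.CTX.kT * np.log(1.5e-3 * 1e9)
        assert fit.parameters["dG0_kcal_mol"] == pytest.approx(expected_dg, abs=1e-6)
        assert fit.errors["dG0_kcal_mol"] > 0

    def test_flat_or_negative_slope_raises(self):
        c = np.array([0.0, 100.0, 200.0])
        means = np.array([0.01, 0.01, 0.01])
        with pytest.raises(ValueError, match="slope"):
            fit_titration_line(c, means, np.full(3, 1e-5))

    def test_concentration_rescaling_shifts_dG_by_kT_log(self):
        """Scaling every concentration by lambda scales Ka by 1/lambda and
        shifts dG by +kT*ln(lambda)."""
        lam = 10.0
        c, m, e = self._synthetic()
        f1 = fit_titration_line(c, m, e, ctx=self.CTX)
        f2 = fit_titration_line(c * lam, m, e, ctx=self.CTX)
        assert f2.parameters["Ka_nM"] == pytest.approx(f1.parameters["Ka_nM"] / lam, rel=1e-9)
        shift = f2.parameters["dG0_kcal_mol"] - f1.parameters["dG0_kcal_mol"]
        assert shift == pytest.approx(self.CTX.kT * np.log(lam), rel=1e-9)

    def test_missing_reference_raises(self):
        with pytest.raises(ValueError, match="reference"):
            fit_titration_line(np.array([10.0, 20.0, 30.0]), np.ones(3), np.full(3, 0.01))


class TestKonFromLongEvents:
    def test_no_long_events_returns_zero_with_bound(self):
        records = []
        t = 0.0
        state = "open"
        for _ in range(200):
            records.append(DwellRecord(state, t, 0.01))
            t += 0.01
            state = "closed" if state == "open" else "open"
        ds = DwellSet(records=records, total_time=t + 1)
        res = kon_from_long_event_rate(ds, long_threshold=0.5, c=10.0, mode="gap")
        assert res.k_on == 0.0
        assert res.upper_95 is not None and res.upper_95 > 0

    def test_legf_recovery_within_poisson_error(self):
        """Long-event counting at the gapped-fork operating point recovers
        k_on = 6.2e-2 /(nM s) within ~3 sqrt(N) counting errors."""
        k_on, k_off, c = 6.2e-2, 0.9, 2.0
        scheme = build_recq_legf_scheme(100.0, 100.0, k_on, k_off, c)
        path = gillespie_path(scheme, 2000.0, seed=31)
        states, starts, durs = path_phase_dwells(path, scheme.phases())
        records = [
            DwellRecord(s, float(t0), float(du))
            for s, t0, du in zip(states, starts, durs)
        ]
        ds = DwellSet(records=records, total_time=2000.0)
        res = kon_from_long_event_rate(ds, long_threshold=0.1, c=c, mode="gap")
        assert res.n_long > 50
        assert abs(res.k_on - k_on) < 3.5 * res.sd + 0.1 * k_on

    def test_pooling_halves_is_consistent(self):
        rng = np.random.default_rng(13)
        records = []
        t = 0.0
        state = "open"
        for _ in range(2000):
            dur = float(rng.exponential(0.5)) + 1e-4 if rng.random() < 0.05 else float(
                rng.exponential(0.01)) + 1e-6
            records.append(DwellRecord(state, t, dur))
            t += dur
            state = "closed" if state == "open" else "open"
        ds = DwellSet(records=records, total_time=t + 1e-3)
        full = kon_from_long_event_rate(ds, long_threshold=0.1, c=5.0, mode="fluctuating")
        half1 = DwellSet(records=[r for r in records if r.start < t / 2], total_time=t / 2)
        half2 = DwellSet(records=[r for r in records if r.start >= t / 2], total_time=t / 2)
        r1 = kon_from_long_event_rate(half1, 0.1, 5.0, mode="fluctuating")
        r2 = kon_from_long_event_rate(half2, 0.1, 5.0, mode="fluctuating")
        pooled = (r1.n_long + r2.n_long) / ((r1.t_unbound + r2.t_unbound) * 5.0)
        assert pooled == pytest.approx(full.k_on, rel=1e-9)

    def test_invalid_args(self):
        ds = DwellSet(records=[DwellRecord("open", 0.0, 1.0)], total_time=2.0)
        with pytest.raises(ValueError):
            kon_from_long_event_rate(ds, 0.1, c=0.0)
        with pytest.raises(ValueError):
            kon_from_long_event_rate(ds, 0.1, c=1.0, mode="bogus")
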