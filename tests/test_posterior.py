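"""Posterior sampling, ROC-AUC discrimination, flux conversion."""

import numpy as np
import pandas as pd
import pytest

from postflux import (
    ParameterPopulation,
    credible_interval,
    flux_from_rate,
    fluxes_from_samples,
    roc_auc_per_parameter,
    sample_posterior,
)
from postflux.fitting import FIT_RATE_NAMES, N_SHARED, N_THETA
from postflux.model import STATE_SPECIES


def make_population(glc_values: dict, wp_values: dict, n: int) -> ParameterPopulation:
    """Population with prescribed per-rate samples for both interventions."""
    theta = np.zeros((n, N_THETA))
    for j, name in enumerate(FIT_RATE_NAMES):
        g = np.asarray(glc_values.get(name, np.full(n, 0.01)), dtype=float)
        w = np.asarray(wp_values.get(name, g), dtype=float)
        theta[:, j] = np.log10(g)
        theta[:, N_SHARED + j] = np.log10(w / g)
    theta[:, 2 * N_SHARED] = 0.0  # k_Pro(WP) = k_GLY(WP)
    return ParameterPopulation(
        theta=theta, window=(0.0, 90.0), seed=None, acceptance_rate=0.25
    )


def constant_model_ds(values: dict) -> pd.DataFrame:
    rows = []
    for iv in ("GLC", "WP"):
        for t in (15.0, 30.0, 60.0, 90.0):
            for sp in STATE_SPECIES + ("glucose_M6", "protein"):
                rows.append((iv, t, sp, values.get(sp, 1.0), 0.1))
    return pd.DataFrame(
        rows, columns=["intervention", "time_min", "species", "mean_uM", "sd_uM"]
    )


class TestSampler:
    def _gaussian_target(self):
        rng = np.random.default_rng(0)
        d = 4
        mu = np.array([0.5, -0.2, 0.1, 0.8])
        L = rng.normal(0, 1, (d, d))
        S = L @ L.T / d + np.eye(d) * 0.05
        Sinv = np.linalg.inv(S)
        return mu, S, lambda x: float((x - mu) @ Sinv @ (x - mu))

    def test_gaussian_oracle_moments(self):
        # cost = (x-mu)' Sinv (x-mu) makes exp(-cost/2) exactly N(mu, S)
        mu, S, cost_fn = self._gaussian_target()
        pop = sample_posterior(
            None, mu + 0.3, n=12000, seed=42, cost_fn=cost_fn,
            bounds=np.array([[-10.0, 10.0]] * 4), n_chains=16, thin=1,
        )
        sd = np.sqrt(np.diag(S))
        assert np.all(np.abs(pop.theta.mean(axis=0) - mu) < 0.15 * sd)
        emp = np.cov(pop.theta.T)
        assert np.max(np.abs(emp - S)) < 0.1 * np.max(np.abs(S))

    def test_deterministic_and_exact_n(self):
        mu, _, cost_fn = self._gaussian_target()
        kw = dict(cost_fn=cost_fn, bounds=np.array([[-10.0, 10.0]] * 4),
                  n_chains=8, min_burn_gens=50, thin=1)
        a = sample_posterior(None, mu, n=500, seed=7, **kw)
        b = sample_posterior(None, mu, n=500, seed=7, **kw)
        assert np.array_equal(a.theta, b.theta)
        assert len(a) == 500

    def test_all_samples_within_bounds(self):
        mu, _, cost_fn = self._gaussian_target()
        bounds = np.array([[-1.0, 1.0]] * 4)
        pop = sample_posterior(None, np.zeros(4), n=400, seed=3, cost_fn=cost_fn,
                               bounds=bounds, n_chains=8, min_burn_gens=50, thin=1)
        assert np.all(pop.theta >= -1.0) and np.all(pop.theta <= 1.0)


class TestRocAuc:
    def test_identical_populations_give_half(self):
        rng = np.random.default_rng(1)
        g = {n: rng.lognormal(-2, 0.3, 200) for n in FIT_RATE_NAMES}
        pop = make_population(g, g, 200)
        auc = roc_auc_per_parameter(pop)
        assert np.allclose(auc["auc"], 0.5)
        assert not auc["strongly_regulated"].any()

    def test_fully_separated_populations_give_one(self):
        rng = np.random.default_rng(2)
        g = {n: rng.uniform(0.001, 0.009, 150) for n in FIT_RATE_NAMES}
        w = {n: 9 * v for n, v in g.items()}  # disjoint ranges
        auc = roc_auc_per_parameter(make_population(g, w, 150))
        assert np.allclose(auc["auc"], 1.0)
        assert auc["strongly_regulated"].all()

    def test_matches_brute_force_mann_whitney_small(self):
        # a univariate monotone classifier ranks by the value itself, so
        # its ROC-AUC equals pair counting with half credit for ties
        glc = np.array([0.010, 0.013, 0.009, 0.013])
        wp = np.array([0.012, 0.015, 0.013, 0.020])
        pop = make_population({"k_GLY": glc}, {"k_GLY": wp}, 4)
        reported = roc_auc_per_parameter(pop).set_index("parameter")["auc"]["k_GLY"]
        # count pairs on the exact sample values the scorer sees (the
        # log-parameterization round-trip perturbs ties at float precision)
        rates = pop.rate_samples()
        g_seen = rates["GLC"]["k_GLY"].to_numpy()
        w_seen = rates["WP"]["k_GLY"].to_numpy()
        pairs = [
            1.0 if w > g else 0.5 if w == g else 0.0 for g in g_seen for w in w_seen
        ]
        brute = np.mean(pairs)
        assert reported == pytest.approx(max(brute, 1 - brute))

    def test_label_swap_invariance(self):
        rng = np.random.default_rng(3)
        g = {"k_GLY": rng.lognormal(-2, 0.2, 100)}
        w = {"k_GLY": rng.lognormal(-1.7, 0.2, 100)}
        a = roc_auc_per_parameter(make_population(g, w, 100))
        b = roc_auc_per_parameter(make_population(w, g, 100))
        assert a.set_index("parameter")["auc"]["k_GLY"] == pytest.approx(
            b.set_index("parameter")["auc"]["k_GLY"]
        )

    def test_constant_marginal_degenerates_to_half(self):
        g = {n: np.full(50, 0.01) for n in FIT_RATE_NAMES}
        auc = roc_auc_per_parameter(make_population(g, g, 50))
        assert (auc["note"] == "degenerate").all()
        assert np.allclose(auc["auc"], 0.5)


class TestCredibleInterval:
    def test_constant_samples_zero_width(self):
        lo, hi = credible_interval(np.full(10, 3.2))
        assert lo == hi == 3.2

    def test_uniform_large_sample(self):
        rng = np.random.default_rng(4)
        lo, hi = credible_interval(rng.uniform(0, 1, 200_000), level=0.90)
        assert lo == pytest.approx(0.05, abs=0.005)
        assert hi == pytest.approx(0.95, abs=0.005)

    def test_contains_median(self):
        rng = np.random.default_rng(5)
        s = rng.lognormal(0, 1, 5000)
        lo, hi = credible_interval(s)
        assert lo <= np.median(s) <= hi

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            credible_interval([1.0])


class TestFluxes:
    def test_hand_arithmetic(self):
        # k = 0.01/min, median C = 2 uM, s = 1, 2% tracer -> 1 uM/min
        assert flux_from_rate(0.01, 2.0, 1.0, 0.02) == pytest.approx(1.0)

    def test_linearity_in_rate(self):
        k = np.array([0.01, 0.02, 0.04])
        v = flux_from_rate(k, 2.0, 1.0, 0.02)
        assert np.allclose(flux_from_rate(3 * k, 2.0, 1.0, 0.02), 3 * v)

    def test_net_and_exchange_definitions(self):
        n = 50
        g = {"k_LDHf": np.full(n, 0.03), "k_LDHb": np.full(n, 0.05)}
        pop = make_population(g, g, n)
        ds = constant_model_ds({"pyruvate_M3": 2.0, "lactate_M3": 2.0})
        fx = fluxes_from_samples(pop, ds, (0.0, 90.0), "early")
        glc = fx.table[fx.table.intervention == "GLC"].set_index("flux")
        # v_f = 0.03*2*50 = 3, v_b = 0.05*2*50 = 5
        assert glc.loc["v_LDHf", "median"] == pytest.approx(3.0)
        assert glc.loc["v_LDHb", "median"] == pytest.approx(5.0)
        assert glc.loc["LDH_net", "median"] == pytest.approx(-2.0)
        assert glc.loc["LDH_ex", "median"] == pytest.approx(3.0)
        # per-sample identities, not just medians
        s = fx.samples
        assert np.allclose(
            s[("GLC", "LDH_net")], s[("GLC", "v_LDHf")] - s[("GLC", "v_LDHb")]
        )
        assert np.allclose(
            s[("GLC", "LDH_ex")],
            np.minimum(s[("GLC", "v_LDHf")], s[("GLC", "v_LDHb")]),
        )

    def test_zero_rate_zero_flux_and_net_antisymmetry(self):
        n = 20
        a = {"k_ALTf": np.full(n, 0.03), "k_ALTb": np.full(n, 0.01),
             "k_TCA": np.full(n, 0.0) + 1e-300}
        pop_fwd = make_population(a, a, n)
        swapped = {"k_ALTf": a["k_ALTb"], "k_ALTb": a["k_ALTf"]}
        pop_swp = make_population(swapped, swapped, n)
        ds = constant_model_ds({})
        f1 = fluxes_from_samples(pop_fwd, ds, (0.0, 90.0), "early").table
        f2 = fluxes_from_samples(pop_swp, ds, (0.0, 90.0), "early").table
        g1 = f1[f1.intervention == "GLC"].set_index("flux")["median"]
        g2 = f2[f2.intervention == "GLC"].set_index("flux")["median"]
        assert g1["v_TCA"] == pytest.approx(0.0, abs=1e-250)
        assert g1["ALT_net"] == pytest.approx(-g2["ALT_net"])
        assert g1["ALT_ex"] == pytest.approx(g2["ALT_ex"])

    def test_window_scaling_factor_selection(self):
        from postflux import ScalingSchedule

        n = 10
        g = {"k_GLY": np.full(n, 0.01)}
        pop = make_population(g, g, n)
        ds = constant_model_ds({"glucose_M6": 2.0})
        sched = ScalingSchedule(s_pa=1.0, s_a=2.0)
        early = fluxes_from_samples(pop, ds, (0.0, 90.0), "early", sched).table
        late = fluxes_from_samples(pop, ds, (0.0, 90.0), "late", sched).table
        literal = fluxes_from_samples(
            pop, ds, (0.0, 90.0), "late", sched, late_uses_s_pa=False
        ).table
        v = lambda t: t[t.intervention == "GLC"].set_index("flux")["median"]["v_GLY"]
        assert v(early) == pytest.approx(0.5)  # divided by s_a = 2
        assert v(late) == pytest.approx(1.0)  # divided by s_pa = 1
        assert v(literal) == pytest.approx(0.5)

    def test_missing_substrate_series_named(self):
        pop = make_population({}, {}, 5)
        ds = constant_model_ds({})
        broken = ds[ds.species != "citrate_M2"]
        with pytest.raises(ValueError, match="citrate_M2"):
            fluxes_from_samples(pop, broken, (0.0, 90.0), "early")
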