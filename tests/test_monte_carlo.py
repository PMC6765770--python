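"""Monte Carlo propagation: degenerate chains, closed forms, conventions."""

import math

import numpy as np
import pytest
from scipy import stats

import vegrisk as vr
from vegrisk.core import ConfigurationError, InvalidInputError
from vegrisk.distributions import DistributionSpec
from vegrisk.monte_carlo import (
    MCConfig,
    conc_var,
    empirical_cdf,
    run_simulation,
    summarize_percentiles,
    thq_percentile_table,
)


def P(value):
    return DistributionSpec("point", {"value": value})


def LN(mu, sigma):
    return DistributionSpec("lognormal", {"mu": mu, "sigma": sigma})


def point_dists(group, conc, ir=100.0, bw=30.0, ef=365.0, ed=10.0):
    d = {(group, conc_var(m)): P(c) for m, c in conc.items()}
    d.update({
        (group, "IR"): P(ir), (group, "BW"): P(bw),
        (group, "EF"): P(ef), (group, "ED"): P(ed),
    })
    return d


@pytest.fixture(scope="module")
def tox():
    return vr.default_tox()


class TestDegenerateChain:
    def test_point_inputs_collapse_to_deterministic_thq(self, tox):
        cfg = MCConfig(seed=0, n_iter=200, populations=("adults",), metals=("As",))
        dists = point_dists("adults", {"As": 0.3})
        res = run_simulation(dists, tox, cfg)
        draws = res.thq_draws[("adults", "As")]
        assert np.all(draws == draws[0])
        assert draws[0] == pytest.approx(0.3 * 100 / 30 / 0.3, rel=1e-12)  # 3.333
        assert np.ptp(res.hi_draws["adults"]) == 0.0

    def test_two_point_metals_sum_exactly(self, tox):
        cfg = MCConfig(seed=0, n_iter=50, populations=("adults",), metals=("As", "Cd"))
        # with IR = BW the intake equals the concentration, so THQ = C/RfD
        dists = point_dists("adults", {"As": 0.3, "Cd": 2.0}, ir=100, bw=100)
        res = run_simulation(dists, tox, cfg)
        assert np.all(res.thq_draws[("adults", "As")] == pytest.approx(1.0))
        assert np.all(res.thq_draws[("adults", "Cd")] == pytest.approx(2.0))
        assert np.all(res.hi_draws["adults"] == pytest.approx(3.0))


@pytest.fixture(scope="module")
def lognormal_run(tox):
    cfg = MCConfig(seed=17, n_iter=30_000, populations=("adults",))
    dists = {
        (("adults"), conc_var(m)): LN(mu, 0.6)
        for m, mu in zip(vr.METALS, (-0.8, -1.1, 0.1, -0.5, 1.45))
    }
    dists.update({
        ("adults", "IR"): LN(math.log(250), 0.5),
        ("adults", "BW"): LN(math.log(60), 0.15),
        ("adults", "EF"): P(350.0),
        ("adults", "ED"): P(30.0),
    })
    return dists, run_simulation(dists, tox, cfg)


class TestStochasticRuns:
    def test_per_draw_hi_conservation(self, lognormal_run):
        """HI equals the sum of the per-metal THQs exactly, draw by draw."""
        _, res = lognormal_run
        total = np.zeros_like(res.hi_draws["adults"])
        for m in res.config.metals:
            total = total + res.thq_draws[("adults", m)]
        assert np.array_equal(total, res.hi_draws["adults"])

    def test_percentiles_monotone(self, lognormal_run):
        _, res = lognormal_run
        for m in res.config.metals:
            values = [res.thq_percentiles[("adults", m, p)] for p in res.config.percentiles]
            assert values == sorted(values)

    def test_thq_median_matches_lognormal_closed_form(self, lognormal_run, tox):
        """THQ of one metal is a product/quotient of lognormals and a point
        factor, hence lognormal with known log-parameters."""
        dists, res = lognormal_run
        for m in vr.METALS:
            mu = (
                dists[("adults", conc_var(m))].params["mu"]
                + dists[("adults", "IR")].params["mu"]
                - dists[("adults", "BW")].params["mu"]
                + math.log(350.0 / 365.0)
                - math.log(tox.rfd[m])
            )
            sim_median = res.thq_percentiles[("adults", m, 50.0)]
            assert sim_median == pytest.approx(math.exp(mu), rel=0.02)

    def test_rerun_bit_identical(self, lognormal_run, tox):
        dists, res = lognormal_run
        res2 = run_simulation(dists, tox, res.config)
        for key in res.thq_draws:
            assert np.array_equal(res.thq_draws[key], res2.thq_draws[key])

    def test_concentration_scaling_scales_thq_percentiles(self, tox):
        """Multiplying one metal's concentration distribution by k multiplies
        every THQ percentile of that metal by exactly k (same seed)."""
        k = 3.0
        cfg = MCConfig(seed=5, n_iter=5000, populations=("adults",), metals=("Cd",))
        base = {
            ("adults", "C_Cd"): LN(-1.0, 0.7),
            ("adults", "IR"): LN(math.log(200), 0.5),
            ("adults", "BW"): P(60.0), ("adults", "EF"): P(365.0), ("adults", "ED"): P(10.0),
        }
        scaled = dict(base)
        scaled[("adults", "C_Cd")] = LN(-1.0 + math.log(k), 0.7)
        r1 = run_simulation(base, tox, cfg)
        r2 = run_simulation(scaled, tox, cfg)
        for p in cfg.percentiles:
            assert r2.thq_percentiles[("adults", "Cd", p)] == pytest.approx(
                k * r1.thq_percentiles[("adults", "Cd", p)], rel=1e-12
            )


class TestValidation:
    def test_missing_spec_detected_before_sampling(self, tox):
        cfg = MCConfig(seed=0, n_iter=10, populations=("adults",), metals=("As",))
        dists = point_dists("adults", {"As": 0.3})
        del dists[("adults", "IR")]
        with pytest.raises(ConfigurationError, match="IR"):
            run_simulation(dists, tox, cfg)

    def test_missing_rfd_detected(self):
        cfg = MCConfig(seed=0, n_iter=10, populations=("adults",), metals=("Ni",))
        dists = point_dists("adults", {"Ni": 0.3})
        with pytest.raises(ConfigurationError, match="Ni"):
            run_simulation(dists, vr.default_tox(), cfg)

    @pytest.mark.parametrize("percentiles", [(5, 5, 95), (95, 5), (0, 50), (50, 100)])
    def test_bad_percentiles_rejected(self, percentiles):
        with pytest.raises(ConfigurationError):
            MCConfig(percentiles=percentiles)


class TestSummaries:
    def test_percentile_interpolation_convention(self):
        assert summarize_percentiles(range(1, 101), [50])[50.0] == 50.5

    def test_constant_draws(self):
        out = summarize_percentiles([2.0] * 10, [5, 50, 95])
        assert set(out.values()) == {2.0}

    def test_normal_tail_quantile(self):
        rng = np.random.default_rng(8)
        draws = rng.standard_normal(30_000)
        assert summarize_percentiles(draws, [95])[95.0] == pytest.approx(1.645, abs=0.03)

    def test_empty_draws_error(self):
        with pytest.raises(InvalidInputError):
            summarize_percentiles([], [50])

    def test_cdf_by_construction(self):
        pairs = empirical_cdf([2.0, 1.0, 3.0])
        assert pairs.tolist() == [[1.0, 1 / 3], [2.0, 2 / 3], [3.0, 1.0]]

    def test_cdf_constant_single_step(self):
        pairs = empirical_cdf([4.0, 4.0])
        assert np.all(pairs[:, 0] == 4.0)
        assert pairs[-1, 1] == 1.0

    def test_cdf_uniform_dkw_bound(self):
        rng = np.random.default_rng(21)
        pairs = empirical_cdf(rng.uniform(0, 1, 10_000))
        assert np.max(np.abs(pairs[:, 1] - pairs[:, 0])) < 0.02

    def test_percentile_table_layout(self, tox):
        cfg = MCConfig(seed=1, n_iter=100, populations=("adults",), metals=("As", "Cd"))
        res = run_simulation(point_dists("adults", {"As": 0.3, "Cd": 0.2}), tox, cfg)
        table = thq_percentile_table(res)
        assert list(table.columns) == ["population", "percentile", "As", "Cd"]
        assert len(table) == len(cfg.percentiles)
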