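"""Likelihood, priors and the MCMC engine."""

import itertools
import math

import numpy as np
import pytest
from scipy import integrate, stats

from errorshift import (
    Alignment,
    Calibration,
    DatingModel,
    McmcSettings,
    PosteriorSample,
    Timetree,
    calibration_log_density,
    jc69,
    hky85,
    log_likelihood,
    log_prior,
    run_mcmc,
    summarize,
)
from errorshift._mcmc import gamma_logpdf
from errorshift.dating import TIME_UNIT_MA


def three_taxon_tree():
    parent = np.array([3, 3, 4, 4, -1])
    ages = np.array([0.0, 0.0, 0.0, 10.0, 25.0])
    return Timetree(parent, ages, ["a", "b", "c", "x", None])


def enumeration_loglik(aln, tree, rates, model):
    """Independent oracle: sum over every assignment of internal-node states."""
    b = rates * tree.branch_durations
    P = {v: model.transition_matrix(b[v]) for v in range(tree.n_nodes) if tree.parent[v] >= 0}
    internals = [v for v in range(tree.n_nodes) if not tree.is_tip[v]]
    row = {name: i for i, name in enumerate(aln.names)}
    total = 0.0
    for site in range(aln.n_sites):
        obs = {v: aln.matrix[row[tree.labels[v]], site] for v in tree.tip_indices}
        site_lik = 0.0
        for states in itertools.product(range(4), repeat=len(internals)):
            assign = dict(zip(internals, states))
            assign.update(obs)
            lik = model.freqs[assign[tree.root]]
            for v in range(tree.n_nodes):
                if tree.parent[v] >= 0:
                    lik *= P[v][assign[tree.parent[v]], assign[v]]
            site_lik += lik
        total += math.log(site_lik)
    return total


class TestLogLikelihood:
    def test_equilibrium_only_single_site(self):
        """Two identical tips joined by zero-length branches: the single-site
        likelihood is just the equilibrium frequency 1/4 under JC."""
        tree = Timetree(np.array([2, 2, -1]), np.array([0.0, 0.0, 10.0]), ["a", "b", None])
        aln = Alignment.from_strings({"a": "A", "b": "A"})
        rates = np.array([0.0, 0.0, np.nan])
        assert log_likelihood(aln, tree, rates) == pytest.approx(math.log(0.25), abs=1e-12)

    @pytest.mark.parametrize("model", [jc69(), hky85(3.0, (0.35, 0.15, 0.2, 0.3))])
    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_exhaustive_enumeration(self, model, seed):
        tree = three_taxon_tree()
        rng = np.random.default_rng(seed)
        rates = np.append(rng.uniform(0.001, 0.02, 4), np.nan)
        aln = Alignment.from_strings(
            {"a": "ACGTG", "b": "AAGTC", "c": "ACGCC"}
        )
        got = log_likelihood(aln, tree, rates, model)
        want = enumeration_loglik(aln, tree, rates, model)
        assert got == pytest.approx(want, abs=1e-10)

    def test_depends_only_on_rate_times_duration(self, sim_tree, small_mixed_alignment):
        aln, rates = small_mixed_alignment
        base = log_likelihood(aln, sim_tree, rates)
        c = 3.7
        scaled_ages = sim_tree.ages * c
        rescaled = log_likelihood(aln, sim_tree, rates / c, ages=scaled_ages)
        assert rescaled == pytest.approx(base, abs=1e-8)

    def test_negative_branch_rejected(self, sim_tree, small_mixed_alignment):
        aln, rates = small_mixed_alignment
        bad = sim_tree.ages.copy()
        bad[sim_tree.node("I")] = 70.0  # older than its parent V at 66
        with pytest.raises(ValueError):
            log_likelihood(aln, sim_tree, rates, ages=bad)


class TestCalibrationDensity:
    CAL = Calibration("root", 180.0, 220.0, 0.025)

    def _pdf(self, t):
        return np.exp(calibration_log_density(t, self.CAL))

    def test_core_mass_095(self):
        mass, _ = integrate.quad(self._pdf, 180, 220)
        assert mass == pytest.approx(0.95, abs=1e-9)

    def test_tail_masses_0025_each(self):
        left, _ = integrate.quad(self._pdf, 0, 180)
        right, _ = integrate.quad(self._pdf, 220, np.inf)
        assert left == pytest.approx(0.025, abs=1e-6)
        assert right == pytest.approx(0.025, abs=1e-6)

    def test_normalizes_to_one(self):
        total = (
            integrate.quad(self._pdf, 0, 180)[0]
            + integrate.quad(self._pdf, 180, 220)[0]
            + integrate.quad(self._pdf, 220, np.inf)[0]
        )
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_continuous_at_bounds(self):
        eps = 1e-9
        assert self._pdf(180 - eps) == pytest.approx(self._pdf(180 + eps), rel=1e-5)
        assert self._pdf(220 + eps) == pytest.approx(self._pdf(220 - eps), rel=1e-5)


class TestLogPrior:
    def model(self, sim_tree, cals):
        return DatingModel(calibrations=cals, rate_prior=(1.0, 6.81), sigma2_prior=(1.0, 2.0))

    def test_gamma_hyperprior_at_its_mean(self):
        """gamma(1, b) is exponential(b): density at the prior mean 1/b is
        b * exp(-1)."""
        assert gamma_logpdf(1 / 6.81, 1.0, 6.81) == pytest.approx(math.log(6.81 * math.exp(-1)), abs=1e-12)

    def test_ordering_violation_is_minus_inf(self, sim_tree, full_calibrations):
        model = self.model(sim_tree, full_calibrations)
        rates = np.full(sim_tree.n_nodes, 0.0015)
        bad = sim_tree.ages.copy()
        bad[sim_tree.node("crown")] = 60.0  # younger than its children at 66
        assert log_prior(sim_tree, rates, 0.1469, 0.075, model, ages=bad) == -np.inf

    def test_malformed_input_raises_not_minus_inf(self, sim_tree, full_calibrations):
        model = self.model(sim_tree, full_calibrations)
        with pytest.raises(ValueError):
            log_prior(sim_tree, np.full(5, 0.0015), 0.1469, 0.075, model)
        with pytest.raises(ValueError):
            log_prior(sim_tree, np.full(sim_tree.n_nodes, 0.0015), -1.0, 0.075, model)

    def test_decomposes_into_known_terms(self, sim_tree):
        """With a single root calibration, the prior is the calibration
        density + iid lognormal rate terms + the two gamma hyperpriors."""
        cals = {"root": Calibration("root", 180, 220)}
        model = self.model(sim_tree, cals)
        mu, s2 = 0.1469, 0.075
        rate = 0.0015
        rates = np.full(sim_tree.n_nodes, rate)
        got = log_prior(sim_tree, rates, mu, s2, model)
        n_br = sim_tree.n_nodes - 1
        want = (
            calibration_log_density(200.0, cals["root"]) + math.log(TIME_UNIT_MA)
            + n_br * stats.lognorm.logpdf(rate * 100, np.sqrt(s2), scale=mu * math.exp(-s2 / 2))
            + stats.gamma.logpdf(mu, 1.0, scale=1 / 6.81)
            + stats.gamma.logpdf(s2, 1.0, scale=1 / 2.0)
        )
        assert got == pytest.approx(want, abs=1e-9)


class TestMcmcSettings:
    def test_retained_count_formula(self):
        s = McmcSettings(generations=200_000, sample_every=50, burnin=10_000)
        assert s.retained_per_chain == 3_800

    def test_invalid_settings(self):
        with pytest.raises(ValueError):
            McmcSettings(generations=100, burnin=100)
        with pytest.raises(ValueError):
            McmcSettings(sample_every=0)


class TestRunMcmc:
    def test_prior_only_root_centered_at_200(self, sim_tree, full_calibrations):
        """Without data the chain targets the joint prior; the symmetric
        root calibration keeps the root's marginal near 200 Ma.  The mean
        sits a few Ma above the midpoint because uncalibrated descendants
        contribute ordering volume — the documented joint-prior tilt of
        soft-bound dating (the same reason joint marginal priors are
        reported alongside specified calibrations)."""
        model = DatingModel(calibrations=full_calibrations, rate_prior=(1.0, 6.81), sigma2_prior=(1.0, 2.0))
        sample = run_mcmc(None, sim_tree, model, McmcSettings(20_000, 5, 2_000, seed=3, chains=2))
        s = summarize(sample)
        assert s.loc["root", "mean"] == pytest.approx(200.0, abs=5.0)
        # calibrated 33-Ma nodes sit at their bound midpoints
        assert s.loc["I", "mean"] == pytest.approx(33.0, abs=1.0)

    def test_prior_only_matches_direct_sampling(self, sim_tree, full_calibrations):
        """Prior-only marginals of the calibrated 33-Ma nodes reproduce the
        soft-bound law exactly (they have no attached free-node volume):
        2.5% mass below the minimum, median at the midpoint, 95% inside."""
        model = DatingModel(calibrations=full_calibrations, rate_prior=(1.0, 6.81), sigma2_prior=(1.0, 2.0))
        sample = run_mcmc(None, sim_tree, model, McmcSettings(30_000, 5, 3_000, seed=4, chains=1))
        draws = sample.stacked_ages()[:, sample.node_tags.index("II")]
        assert np.quantile(draws, 0.5) == pytest.approx(33.0, abs=0.3)
        assert ((draws >= 29.7) & (draws <= 36.3)).mean() == pytest.approx(0.95, abs=0.02)
        assert (draws < 29.7).mean() == pytest.approx(0.025, abs=0.012)

    def test_requires_root_calibration(self, sim_tree, small_mixed_alignment):
        aln, _ = small_mixed_alignment
        model = DatingModel(calibrations={"I": Calibration("I", 29.7, 36.3)})
        with pytest.raises(ValueError, match="root"):
            run_mcmc(aln, sim_tree, model, McmcSettings(100, 1, 10, seed=0, chains=1))

    def test_logposterior_trace_is_consistent(self, sim_tree, full_calibrations, small_mixed_alignment):
        """The kernel's recorded log-posterior at a retained draw equals the
        Python-side prior + pruning likelihood recomputed for that draw
        (cross-check of the compressed-pattern kernel against the plain
        pruning implementation)."""
        aln, _ = small_mixed_alignment
        model = DatingModel(calibrations=full_calibrations, rate_prior=(1.0, 7.51), sigma2_prior=(1.0, 2.0))
        sample = run_mcmc(aln, sim_tree, model, McmcSettings(300, 10, 100, seed=5, chains=1))
        ages = sim_tree.ages.copy()
        for tag, v in zip(sample.node_tags, sample.internal_nodes):
            ages[v] = sample.ages[0, -1, sample.node_tags.index(tag)]
        rates = sample.rates[0, -1]
        lp = log_prior(sim_tree, rates, float(sample.mu[0, -1]), float(sample.sigma2[0, -1]), model, ages=ages)
        ll = log_likelihood(aln, sim_tree, rates, ages=ages)
        assert sample.log_posterior[0, -1] == pytest.approx(lp + ll, abs=1e-5)

    def test_reproducible_and_acceptance_in_band(self, sim_tree, full_calibrations, small_mixed_alignment):
        aln, _ = small_mixed_alignment
        model = DatingModel(calibrations=full_calibrations, rate_prior=(1.0, 7.51), sigma2_prior=(1.0, 2.0))
        settings = McmcSettings(1_500, 5, 500, seed=6, chains=1)
        a = run_mcmc(aln, sim_tree, model, settings)
        b = run_mcmc(aln, sim_tree, model, settings)
        assert np.array_equal(a.ages, b.ages)
        assert np.array_equal(a.rates, b.rates)
        # tuned acceptance for age and rate moves lands in a sane band
        assert 0.15 < a.acceptance[0, 0] < 0.6
        assert 0.15 < a.acceptance[0, 1] < 0.6

    def test_superorder_label_symmetry(self, sim_tree, full_calibrations):
        """Swapping the two superorder subtrees leaves marginals unchanged:
        V and VI have exchangeable priors, so their prior-only marginals
        agree within MC error."""
        model = DatingModel(calibrations=full_calibrations, rate_prior=(1.0, 6.81), sigma2_prior=(1.0, 2.0))
        sample = run_mcmc(None, sim_tree, model, McmcSettings(20_000, 5, 2_000, seed=7, chains=1))
        s = summarize(sample)
        assert s.loc["V", "mean"] == pytest.approx(s.loc["VI", "mean"], abs=1.0)


class TestSummarize:
    def _sample(self, sim_tree, ages):
        n_int = 11
        internals = np.array([v for v in sim_tree.postorder if not sim_tree.is_tip[v]])
        tags = [sim_tree.labels[v] or f"node{v}" for v in internals]
        return PosteriorSample(
            node_tags=tags,
            internal_nodes=internals,
            ages=ages,
            rates=np.zeros((ages.shape[0], ages.shape[1], sim_tree.n_nodes)),
            mu=np.zeros(ages.shape[:2]),
            sigma2=np.zeros(ages.shape[:2]),
            log_posterior=np.zeros(ages.shape[:2]),
            acceptance=np.zeros((ages.shape[0], 6)),
            tree=sim_tree,
        )

    def test_constant_trace(self, sim_tree):
        ages = np.full((1, 50, 11), 42.0)
        s = summarize(self._sample(sim_tree, ages))
        assert (s["mean"] == 42.0).all()
        assert (s["ci_lower"] == 42.0).all() and (s["ci_upper"] == 42.0).all()

    def test_normal_trace_quantiles(self, sim_tree):
        rng = np.random.default_rng(0)
        ages = rng.standard_normal((1, 100_000, 11))
        s = summarize(self._sample(sim_tree, ages))
        assert np.allclose(s["ci_lower"], -1.96, atol=0.03)
        assert np.allclose(s["ci_upper"], 1.96, atol=0.03)

    def test_ess_of_iid_trace_near_length(self, sim_tree):
        rng = np.random.default_rng(1)
        ages = rng.standard_normal((1, 5_000, 11))
        s = summarize(self._sample(sim_tree, ages))
        assert s["ess"].mean() == pytest.approx(5_000, rel=0.10)
        assert np.all(np.abs(s["ess"] - 5_000) < 1_000)

    def test_empty_sample_rejected(self, sim_tree):
        with pytest.raises(ValueError, match="empty"):
            summarize(self._sample(sim_tree, np.zeros((1, 0, 11))))
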