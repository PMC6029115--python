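"""Bayesian relaxed-clock node dating on a fixed topology.

The model follows the standard independent-rates construction: given node
ages t and per-branch rates r, the sequence likelihood is the pruning
(Felsenstein) likelihood with branch lengths r x duration; branch rates are
iid lognormal with arithmetic mean mu and log-scale variance sigma2; mu and
sigma2 carry gamma hyperpriors parameterized as (shape, inverse scale), so
the prior mean of mu is shape/invscale.  Calibrated nodes carry soft uniform
bounds with 2.5% tails by default; uncalibrated node ages take a flat
order-statistic prior between their bounding nodes.  Time is handled in
units of 100 Ma internally; the public interface speaks Ma.

Absolute ages are identifiable only through the calibrations: the data
constrain rate x time, so jointly rescaling rates and times leaves the
likelihood unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import arviz as az
import numpy as np
import pandas as pd

from . import _mcmc
from .simulate import Alignment
from .submodels import SubstitutionModel, jc69
from .timetree import Calibration, Timetree

__all__ = [
    "DatingModel",
    "McmcSettings",
    "PosteriorSample",
    "log_likelihood",
    "calibration_log_density",
    "log_prior",
    "run_mcmc",
    "summarize",
]

#: times are sampled in units of 100 Ma (so a rate of 0.1469 means
#: 0.1469 substitutions/site per 100 Ma)
TIME_UNIT_MA = 100.0


@dataclass(frozen=True)
class DatingModel:
    """Priors and substitution model for one dating analysis.

    ``rate_prior`` and ``sigma2_prior`` are (shape, inverse scale) of the
    gamma hyperpriors on the mean rate mu (per 100 Ma) and the log-rate
    variance sigma2.  The defaults are the empirical-analysis settings
    (mean rate 1/5.41, sigma2 mean 1/4.207); the simulation experiments use
    (1, 6.81) / (1, 7.51) and (1, 2.0).
    """

    calibrations: dict[str, Calibration] = field(default_factory=dict)
    subst_model: SubstitutionModel = field(default_factory=jc69)
    rate_prior: tuple[float, float] = (1.0, 5.41)
    sigma2_prior: tuple[float, float] = (1.0, 4.207)

    def __post_init__(self) -> None:
        for pair, name in ((self.rate_prior, "rate_prior"), (self.sigma2_prior, "sigma2_prior")):
            if not (pair[0] > 0 and pair[1] > 0):
                raise ValueError(f"{name} parameters must be positive")

    def with_calibrations(self, cals: dict[str, Calibration]) -> "DatingModel":
        return replace(self, calibrations=dict(cals))


@dataclass(frozen=True)
class McmcSettings:
    """Chain-length settings; defaults match the study's MCMC protocol
    (200,000 generations, sampling every 50th, 10,000 burn-in)."""

    generations: int = 200_000
    sample_every: int = 50
    burnin: int = 10_000
    seed: int | None = None
    chains: int = 2
    ess_threshold: float = 200.0

    def __post_init__(self) -> None:
        if not (0 <= self.burnin < self.generations):
            raise ValueError("burn-in must be shorter than the chain")
        if self.sample_every < 1 or self.chains < 1:
            raise ValueError("sampling interval and chain count must be >= 1")

    @property
    def retained_per_chain(self) -> int:
        return (self.generations - self.burnin) // self.sample_every


@dataclass
class PosteriorSample:
    """Retained draws from :func:`run_mcmc`.

    ``ages`` has shape (chains, draws, internal nodes) in Ma; ``rates``
    (chains, draws, nodes) in subs/site/Ma indexed by child node; ``mu`` is
    on the 100-Ma scale as sampled.  ``node_tags`` names the internal-node
    columns of ``ages``.
    """

    node_tags: list[str]
    internal_nodes: np.ndarray
    ages: np.ndarray
    rates: np.ndarray
    mu: np.ndarray
    sigma2: np.ndarray
    log_posterior: np.ndarray
    acceptance: np.ndarray
    tree: Timetree
    converged: bool = True
    warnings: list[str] = field(default_factory=list)

    @property
    def n_draws(self) -> int:
        return self.ages.shape[0] * self.ages.shape[1]

    def stacked_ages(self) -> np.ndarray:
        return self.ages.reshape(-1, self.ages.shape[-1])


# ---------------------------------------------------------------------------
# densities
# ---------------------------------------------------------------------------


def calibration_log_density(age, cal: Calibration):
    """Log density (1/Ma) of the soft-bound calibration prior at ``age`` Ma.

    The density is uniform on [min, max] carrying mass 1 - 2 tail, with a
    power-decay left tail and an exponential right tail each carrying the
    tail mass and continuous at the bounds; it integrates to one over
    (0, inf).
    """
    ages = np.asarray(age, dtype=float)
    out = np.array(
        [_mcmc.soft_bound_logpdf(t, cal.min_age, cal.max_age, cal.tail) for t in np.atleast_1d(ages)]
    )
    return out.reshape(ages.shape) if ages.ndim else float(out[0])


def _branch_lengths(tree: Timetree, ages: np.ndarray, rates: np.ndarray) -> np.ndarray:
    nonroot = tree.parent >= 0
    dur = np.zeros(tree.n_nodes)
    dur[nonroot] = ages[tree.parent[nonroot]] - ages[nonroot]
    if np.any(dur[nonroot] < 0):
        raise ValueError("ages violate the tree ordering")
    b = np.where(nonroot, rates * dur, 0.0)
    if np.any(~np.isfinite(b[nonroot])) or np.any(b[nonroot] < 0):
        raise ValueError("branch lengths must be finite and non-negative")
    return b


def log_likelihood(
    alignment: Alignment,
    tree: Timetree,
    rates: np.ndarray,
    model: SubstitutionModel | None = None,
    ages: np.ndarray | None = None,
) -> float:
    """Pruning log-likelihood of ``alignment`` on ``tree``.

    Branch lengths are rate x duration per branch (rates in subs/site/Ma
    indexed by child node; durations from ``ages``, defaulting to the tree's
    own ages).  Site patterns are compressed before pruning.
    """
    model = model or jc69()
    ages = tree.ages if ages is None else np.asarray(ages, dtype=float)
    b = _branch_lengths(tree, ages, np.asarray(rates, dtype=float))
    pats = alignment.patterns
    counts = alignment.pattern_counts
    row = {name: i for i, name in enumerate(alignment.names)}
    try:
        tip_rows = {v: row[tree.labels[v]] for v in tree.tip_indices}
    except KeyError as e:
        raise ValueError(f"alignment has no sequence for tip {e.args[0]!r}") from None

    npat = pats.shape[1]
    partial = {}
    for v in tree.postorder:
        if tree.is_tip[v]:
            L = np.zeros((npat, 4))
            L[np.arange(npat), pats[tip_rows[v]]] = 1.0
        else:
            L = np.ones((npat, 4))
            for child in tree.children[v]:
                p = model.transition_matrix(b[child])
                L = L * (partial.pop(child) @ p.T)
        partial[v] = L
    site = partial[tree.root] @ model.freqs
    return float(np.dot(counts, np.log(site)))


def log_prior(
    tree: Timetree,
    rates: np.ndarray,
    mu: float,
    sigma2: float,
    model: DatingModel,
    ages: np.ndarray | None = None,
) -> float:
    """Joint log prior of (ages, rates, mu, sigma2) under ``model``.

    Rates are in subs/site/Ma and converted to the engine's 100-Ma scale to
    match mu's hyperprior.  An age configuration violating the tree ordering
    returns -inf (a rejected state); malformed inputs raise.
    """
    ages = tree.ages if ages is None else np.asarray(ages, dtype=float)
    rates = np.asarray(rates, dtype=float)
    if rates.shape != (tree.n_nodes,):
        raise ValueError("need one rate per node")
    if mu <= 0 or sigma2 <= 0:
        raise ValueError("mu and sigma2 must be positive")
    nonroot = tree.parent >= 0
    if np.any(ages[tree.parent[nonroot]] - ages[nonroot] <= 0):
        return -math.inf
    cal_node, cal_lo, cal_hi, cal_tail = _calibration_arrays(tree, model.calibrations)
    return _mcmc.full_log_prior(
        ages / TIME_UNIT_MA,
        np.where(nonroot, rates * TIME_UNIT_MA, 1.0),
        mu,
        max(sigma2, _mcmc.SIGMA2_FLOOR),
        tree.root,
        tree.n_nodes,
        cal_node, cal_lo / TIME_UNIT_MA, cal_hi / TIME_UNIT_MA, cal_tail,
        model.rate_prior[0], model.rate_prior[1],
        model.sigma2_prior[0], model.sigma2_prior[1],
    )


# ---------------------------------------------------------------------------
# MCMC
# ---------------------------------------------------------------------------


def _calibration_arrays(tree: Timetree, cals: dict[str, Calibration]):
    node = np.array([tree.node(c.tag) for c in cals.values()], dtype=np.int64)
    lo = np.array([c.min_age for c in cals.values()])
    hi = np.array([c.max_age for c in cals.values()])
    tail = np.array([c.tail for c in cals.values()])
    return node, lo, hi, tail


def _pattern_structure(tree: Timetree, alignment: Alignment):
    """Per-subtree pattern compression: index maps from each internal node's
    pattern table into its children's tables (tip entries are states)."""
    pats = alignment.patterns
    counts = alignment.pattern_counts.astype(float)
    row = {name: i for i, name in enumerate(alignment.names)}
    internals = [v for v in tree.postorder if not tree.is_tip[v]]
    int_of_node = np.full(tree.n_nodes, -1, dtype=np.int64)
    for iv, v in enumerate(internals):
        int_of_node[v] = iv
    pat_id: dict[int, np.ndarray] = {}
    lidx_parts, ridx_parts = [], []
    npat = np.zeros(len(internals), dtype=np.int64)
    for iv, v in enumerate(internals):
        l, r = tree.children[v]
        lid = pats[row[tree.labels[l]]].astype(np.int64) if tree.is_tip[l] else pat_id[l]
        rid = pats[row[tree.labels[r]]].astype(np.int64) if tree.is_tip[r] else pat_id[r]
        pairs = np.stack([lid, rid], axis=1)
        uniq, inv = np.unique(pairs, axis=0, return_inverse=True)
        lidx_parts.append(uniq[:, 0].astype(np.int32))
        ridx_parts.append(uniq[:, 1].astype(np.int32))
        npat[iv] = len(uniq)
        pat_id[v] = inv
    pat_off = np.zeros(len(internals), dtype=np.int64)
    pat_off[1:] = np.cumsum(npat)[:-1]
    part_off = pat_off.copy()
    lidx = np.concatenate(lidx_parts)
    ridx = np.concatenate(ridx_parts)
    root_counts = np.bincount(pat_id[tree.root], weights=counts, minlength=npat[-1])
    node_of_int = np.array(internals, dtype=np.int64)
    left = np.array([tree.children[v][0] for v in internals], dtype=np.int64)
    right = np.array([tree.children[v][1] for v in internals], dtype=np.int64)
    return node_of_int, int_of_node, left, right, npat, pat_off, part_off, lidx, ridx, root_counts


def _internal_tags(tree: Timetree) -> tuple[list[str], np.ndarray]:
    internals = [v for v in tree.postorder if not tree.is_tip[v]]
    tags = [tree.labels[v] if tree.labels[v] is not None else f"node{v}" for v in internals]
    return tags, np.array(internals, dtype=np.int64)


def _initial_ages(tree: Timetree, cals: dict[str, Calibration]) -> np.ndarray:
    """Deterministic starting ages: calibrated nodes at their bound
    midpoints, uncalibrated nodes interpolated between their bounding
    constraints.  Starting from the prior's centre (rather than any
    particular age configuration) removes a directional burn-in bias on
    weakly identified deep nodes."""
    mid = {tree.node(c.tag): 0.5 * (c.min_age + c.max_age) for c in cals.values()}
    maxcal = np.zeros(tree.n_nodes)  # highest calibrated midpoint in each subtree
    for v in tree.postorder:
        own = mid.get(v, 0.0)
        below = max((maxcal[c] for c in tree.children[v]), default=0.0)
        maxcal[v] = max(own, below)
    ages = np.zeros(tree.n_nodes)
    for v in tree.preorder:
        if tree.is_tip[v]:
            continue
        upper = ages[tree.parent[v]] if tree.parent[v] >= 0 else np.inf
        lower = max((maxcal[c] for c in tree.children[v]), default=0.0)
        if v in mid:
            ages[v] = mid[v]
        else:
            ages[v] = 0.5 * (lower + upper) if np.isfinite(upper) else lower * 1.5 + 1.0
        if not (lower <= ages[v] and ages[v] < upper):
            raise ValueError(
                "calibration midpoints are incompatible with the tree ordering "
                f"around node {tree.labels[v] or v}"
            )
    return ages


def run_mcmc(
    alignment: Alignment | None,
    tree: Timetree,
    model: DatingModel,
    settings: McmcSettings | None = None,
) -> PosteriorSample:
    """Sample node ages, branch rates and hyperparameters by MCMC.

    ``tree`` supplies the fixed topology and the starting ages.  If
    ``alignment`` is None or has zero sites the chain targets the joint
    prior (prior-only mode), which is also how joint marginal calibration
    priors are obtained.  Calibrations come from ``model.calibrations``
    merged over any attached to the tree; the root must be calibrated.
    Reproducible for a given ``settings.seed``.
    """
    settings = settings or McmcSettings()
    cals = {**tree.calibrations, **model.calibrations}
    root_tag = tree.labels[tree.root]
    if not any(tree.node(c.tag) == tree.root for c in cals.values()):
        raise ValueError(f"the root node ({root_tag!r}) must carry a calibration")
    cal_node, cal_lo, cal_hi, cal_tail = _calibration_arrays(tree, cals)

    prior_only = alignment is None or alignment.n_sites == 0
    if prior_only:
        dummy = Alignment(
            [tree.labels[i] for i in tree.tip_indices],
            np.zeros((tree.n_tips, 1), dtype=np.uint8),
        )
        struct = _pattern_structure(tree, dummy)
    else:
        missing = set(n for n in (tree.labels[i] for i in tree.tip_indices)) - set(alignment.names)
        if missing:
            raise ValueError(f"alignment lacks sequences for tips: {sorted(missing)}")
        struct = _pattern_structure(tree, alignment)
    (node_of_int, int_of_node, left, right, npat, pat_off, part_off, lidx, ridx, counts) = struct

    w, u, uinv = model.subst_model.eigensystem
    pi = model.subst_model.freqs
    a_mu, b_mu = model.rate_prior
    a_s2, b_s2 = model.sigma2_prior

    age0 = _initial_ages(tree, cals) / TIME_UNIT_MA
    mu0 = a_mu / b_mu
    s20 = a_s2 / b_s2
    rate0 = np.full(tree.n_nodes, mu0)

    n_int = len(node_of_int)
    rng = np.random.SeedSequence(settings.seed)
    chain_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in rng.spawn(settings.chains)]

    ages_all, rates_all, mu_all, s2_all, lp_all, acc_all = [], [], [], [], [], []
    for seed in chain_seeds:
        tr_age, tr_rate, tr_mu, tr_s2, tr_lp, acc = _mcmc.run_chain(
            tree.parent, tree.root, age0, rate0, mu0, s20,
            node_of_int, int_of_node, left, right,
            npat, pat_off, part_off, lidx, ridx, counts, pi,
            w, u, uinv,
            cal_node, cal_lo / TIME_UNIT_MA, cal_hi / TIME_UNIT_MA, cal_tail,
            a_mu, b_mu, a_s2, b_s2,
            settings.generations, settings.burnin, settings.sample_every,
            seed, prior_only,
        )
        ages_all.append(tr_age * TIME_UNIT_MA)
        rates_all.append(tr_rate / TIME_UNIT_MA)
        mu_all.append(tr_mu)
        s2_all.append(tr_s2)
        lp_all.append(tr_lp)
        acc_all.append(acc)

    tags, internal_nodes = _internal_tags(tree)
    sample = PosteriorSample(
        node_tags=tags,
        internal_nodes=internal_nodes,
        ages=np.stack(ages_all),
        rates=np.stack(rates_all),
        mu=np.stack(mu_all),
        sigma2=np.stack(s2_all),
        log_posterior=np.stack(lp_all),
        acceptance=np.stack(acc_all),
        tree=tree,
    )
    _flag_convergence(sample, settings)
    return sample


def _flag_convergence(sample: PosteriorSample, settings: McmcSettings) -> None:
    """Record (never hide) convergence problems: low ESS on any node age, or
    a between-chain disagreement in mean age beyond 1 Ma."""
    warnings = []
    ess = _ess_per_node(sample)
    low = [t for t, e in zip(sample.node_tags, ess) if e < settings.ess_threshold]
    if low:
        warnings.append(f"ESS below {settings.ess_threshold:g} for nodes: {', '.join(low)}")
    if sample.ages.shape[0] > 1:
        chain_means = sample.ages.mean(axis=1)
        gap = np.abs(chain_means - chain_means.mean(axis=0)).max()
        if gap > 1.0:
            warnings.append(f"between-chain mean age gap {gap:.2f} Ma exceeds 1 Ma")
    sample.warnings = warnings
    sample.converged = not warnings


def _ess_per_node(sample: PosteriorSample) -> np.ndarray:
    return np.array(
        [float(az.ess(az.convert_to_dataset(sample.ages[:, :, j]))["x"]) for j in range(sample.ages.shape[2])]
    )


def summarize(sample: PosteriorSample) -> pd.DataFrame:
    """Posterior mean, 95% equal-tail credible interval and ESS per internal
    node age (Ma), indexed by node tag."""
    if sample.n_draws == 0:
        raise ValueError("posterior sample is empty")
    flat = sample.stacked_ages()
    mean = flat.mean(axis=0)
    lo, hi = np.quantile(flat, [0.025, 0.975], axis=0)
    ess = _ess_per_node(sample)
    df = pd.DataFrame(
        {"mean": mean, "ci_lower": lo, "ci_upper": hi, "ess": ess},
        index=pd.Index(sample.node_tags, name="node"),
    )
    df["true_age"] = [sample.tree.ages[v] for v in sample.internal_nodes]
    return df
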