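"""Branch-rate schemes for the simulation experiments.

Rates are iid lognormal per branch; the "mixed rates" scheme additionally
divides the drawn rate by 5 on a designated set of branches (the daughter
lineages of the two low-rate 33-Ma clades), mimicking the parallel rate
decelerations of large, long-lived mammals such as whales and seacows.

The lognormal location/scale defaults (ln mean -6.523, s.d. 0.274, in log
substitutions/site/Ma) are modelled on inferred rates for small-to-mid-sized
mammals; exp(-6.523) = 0.001469 subs/site/Ma, i.e. 0.1469 per 100 Ma.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .timetree import Timetree

__all__ = ["RateScheme", "draw_branch_rates", "expected_substitutions"]

#: lognormal location of the ancestral-rates distribution, log(subs/site/Ma)
LOG_RATE_LOCATION = -6.523
#: lognormal scale (s.d. on the log scale)
LOG_RATE_SD = 0.274


@dataclass(frozen=True)
class RateScheme:
    """Lognormal branch-rate law with an optional decelerated branch set.

    ``decelerated`` holds branch ids — the tag/name of the branch's child
    node; an empty set is the "ancestral rates" scheme.
    """

    log_location: float = LOG_RATE_LOCATION
    log_sd: float = LOG_RATE_SD
    decelerated: frozenset[str] = frozenset()
    factor: float = 0.2

    def __post_init__(self) -> None:
        if self.log_sd < 0:
            raise ValueError("log-scale s.d. must be non-negative")
        if not (0 < self.factor <= 1):
            raise ValueError("deceleration factor must lie in (0, 1]")
        object.__setattr__(self, "decelerated", frozenset(self.decelerated))

    @property
    def name(self) -> str:
        return "ancestral" if not self.decelerated else "mixed"

    @property
    def median_rate(self) -> float:
        """Median branch rate, substitutions/site/Ma."""
        return float(np.exp(self.log_location))

    @classmethod
    def ancestral(cls, **kw) -> "RateScheme":
        return cls(**kw)

    @classmethod
    def mixed(cls, tree: Timetree, low_rate_nodes: tuple[str, ...] = ("I", "III"), **kw) -> "RateScheme":
        """Decelerate the daughter branches of the named nodes (their two
        immediate child branches each)."""
        branches = []
        for tag in low_rate_nodes:
            for child in tree.children[tree.node(tag)]:
                label = tree.labels[child]
                if label is None:
                    raise ValueError(f"daughter branch of {tag!r} has no label to identify it")
                branches.append(label)
        return cls(decelerated=frozenset(branches), **kw)


def draw_branch_rates(
    tree: Timetree, scheme: RateScheme, seed: int | np.random.Generator | None = None
) -> np.ndarray:
    """Draw one substitution rate (subs/site/Ma) per branch.

    Returns an array indexed by child node (NaN at the root).  Rates are iid
    lognormal(``log_location``, ``log_sd``); branches named in
    ``scheme.decelerated`` have their drawn rate multiplied by
    ``scheme.factor``.  Reproducible for a given seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    for tag in sorted(scheme.decelerated):
        i = tree.node(tag)  # raises KeyError for unknown branch ids
        if i == tree.root:
            raise KeyError(f"{tag!r} is the root and has no branch")
    rates = np.exp(rng.normal(scheme.log_location, scheme.log_sd, size=tree.n_nodes))
    for tag in scheme.decelerated:
        rates[tree.node(tag)] *= scheme.factor
    rates[tree.root] = np.nan
    return rates


def expected_substitutions(tree: Timetree, rates: np.ndarray) -> np.ndarray:
    """Expected substitutions/site per branch: rate x duration (indexed by
    child node, 0 at the root)."""
    rates = np.asarray(rates, dtype=float)
    if rates.shape != (tree.n_nodes,):
        raise ValueError("need one rate per node (NaN allowed only at the root)")
    nonroot = tree.parent >= 0
    if np.any(~np.isfinite(rates[nonroot])) or np.any(rates[nonroot] < 0):
        raise ValueError("every branch needs a finite non-negative rate")
    out = rates * tree.branch_durations
    out[tree.root] = 0.0
    return out
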