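"""Test for non-random between-group DNA exchange.

Under the null model every inter-group strain pairing of a segment's panel is
equally likely to host a conversion, so the expected number of conversions
between groups g1 and g2 is proportional to n_g1 * n_g2.  Expected counts are
conditional on each segment's observed event total T_s and summed across
segments:

    E_c = sum_s T_s * w_s(c),   w_s(c) = pairings of c in s's panel
                                         / total inter-group pairings

A Pearson chi-square score X^2 = sum_c (O_c - E_c)^2 / E_c over group pairs
measures departure; its p-value comes from multinomial simulation (many cells
are empty, so the asymptotic chi-square distribution is unreliable): each
replicate reassigns every segment's T_s events to categories by a multinomial
draw with probabilities w_s, sums across segments, and recomputes X^2.  The
global p-value is the proportion of replicates whose score reaches the
observed score; per-category one-sided tails give over/under-representation
p-values for individual group pairs.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping

import numpy as np

from .conversion_detect import category_groups, is_inter
from .tier_enum import OpportunityTable, TierEventSet


@dataclasses.dataclass(frozen=True)
class ExpectedCounts:
    """Expected event counts per category under proportional opportunity."""

    expected: Mapping[str, float]
    rounded: bool

    def as_array(self, categories: list[str]) -> np.ndarray:
        return np.array([self.expected[c] for c in categories], dtype=float)


@dataclasses.dataclass(frozen=True)
class ExchangeTestResult:
    categories: tuple[str, ...]
    observed: tuple[int, ...]
    expected: tuple[float, ...]
    pearson: float
    n_sims: int
    p_global: float
    p_over: tuple[float, ...]
    p_under: tuple[float, ...]
    seed: int
    flagged: tuple[str, ...] = ()  # categories with E=0 but O>0

    def to_dict(self) -> dict:
        return {
            "pearson": self.pearson,
            "p_global": self.p_global,
            "n_sims": self.n_sims,
            "seed": self.seed,
            "flagged": list(self.flagged),
            "categories": {
                c: {
                    "observed": o,
                    "expected": e,
                    "p_over": po,
                    "p_under": pu,
                }
                for c, o, e, po, pu in zip(
                    self.categories,
                    self.observed,
                    self.expected,
                    self.p_over,
                    self.p_under,
                )
            },
        }


def _segment_weights(
    opp: OpportunityTable,
    segment_id: str,
    categories: list[str],
    exclude_groups: frozenset[str],
) -> np.ndarray:
    """w_s(c) for one segment: category pairings over total inter pairings,
    after dropping categories touching excluded groups."""
    panel = opp.panel_for(segment_id)
    counts = opp.pair_counts[panel]
    raw = np.array(
        [
            0.0
            if set(category_groups(c)) & exclude_groups
            else float(counts.get(c, 0))
            for c in categories
        ]
    )
    total = raw.sum()
    if total <= 0:
        raise ValueError(
            f"segment {segment_id}: panel {panel!r} has zero total pairing weight"
        )
    return raw / total


def expected_counts(
    tier_events: TierEventSet,
    opp: OpportunityTable,
    rounding: str = "none",
    exclude_groups: Iterable[str] = (),
) -> ExpectedCounts:
    """Expected inter-group event counts E_c = sum_s T_s * w_s(c).

    rounding = "paper-compat" rounds each E_c to the nearest integer (half
    away from zero) after summation over segments, matching the integer
    expected counts the original analysis reports; "none" leaves them exact.
    """
    if rounding not in {"none", "paper-compat"}:
        raise ValueError(f"unknown rounding mode {rounding!r}")
    excl = frozenset(exclude_groups)
    categories = [
        c
        for c in opp.categories(inter_only=True)
        if not set(category_groups(c)) & excl
    ]
    totals = tier_events.segment_totals(inter_only=True)
    e = np.zeros(len(categories))
    for seg, t in totals.items():
        if t == 0:
            continue
        e += t * _segment_weights(opp, seg, categories, excl)
    if rounding == "paper-compat":
        e = np.floor(e + 0.5)  # half away from zero; counts are >= 0
    return ExpectedCounts(
        expected=dict(zip(categories, e.tolist())), rounded=rounding == "paper-compat"
    )


def pearson_score(observed: np.ndarray, expected: np.ndarray) -> float:
    """X^2 = sum (O - E)^2 / E over categories with E > 0.

    Categories with E = 0 and O = 0 are skipped; E = 0 with O > 0 cannot
    enter the statistic (the caller flags them and relies on the simulated
    per-category tails instead).
    """
    o = np.asarray(observed, dtype=float)
    e = np.asarray(expected, dtype=float)
    if o.shape != e.shape:
        raise ValueError("observed/expected shape mismatch")
    mask = e > 0
    return float(((o[mask] - e[mask]) ** 2 / e[mask]).sum())


def simulate_null(
    tier_events: TierEventSet,
    opp: OpportunityTable,
    n_sims: int = 1_000_000,
    seed: int = 0,
    exclude_groups: Iterable[str] = (),
) -> ExchangeTestResult:
    """Multinomial-simulation p-values for the observed exchange pattern.

    Per replicate and segment s, T_s events are reassigned to categories with
    probabilities w_s(.); replicate counts are summed over segments and the
    Pearson score recomputed against the (unrounded) expected counts.
    p_global is the plain proportion of replicates with simulated X^2 >= the
    observed X^2 (minimum reportable value 1/n_sims); p_over / p_under are
    per-category one-sided tails of the simulated count distribution.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    excl = frozenset(exclude_groups)
    exp = expected_counts(tier_events, opp, rounding="none", exclude_groups=excl)
    categories = sorted(exp.expected)
    e = exp.as_array(categories)
    obs_map = tier_events.by_category(inter_only=True)
    dropped = {
        c
        for c in obs_map
        if set(category_groups(c)) & excl and obs_map[c] > 0
    }
    o = np.array([obs_map.get(c, 0) for c in categories], dtype=np.int64)
    flagged = tuple(
        c for c, oc, ec in zip(categories, o, e) if ec == 0 and oc > 0
    )
    observed_score = pearson_score(o, e)

    rng = np.random.default_rng(seed)
    sim_counts = np.zeros((n_sims, len(categories)), dtype=np.int64)
    for seg, t in sorted(tier_events.segment_totals(inter_only=True).items()):
        if t == 0:
            continue
        w = _segment_weights(opp, seg, categories, excl)
        sim_counts += rng.multinomial(t, w, size=n_sims)
    mask = e > 0
    with np.errstate(invalid="ignore"):
        scores = ((sim_counts[:, mask] - e[mask]) ** 2 / e[mask]).sum(axis=1)
    p_global = float((scores >= observed_score).mean())
    p_over = (sim_counts >= o).mean(axis=0)
    p_under = (sim_counts <= o).mean(axis=0)
    if dropped:
        import logging

        logging.getLogger(__name__).warning(
            "events in excluded-group categories ignored: %s", sorted(dropped)
        )
    return ExchangeTestResult(
        categories=tuple(categories),
        observed=tuple(int(x) for x in o),
        expected=tuple(float(x) for x in e),
        pearson=observed_score,
        n_sims=n_sims,
        p_global=p_global,
        p_over=tuple(float(x) for x in p_over),
        p_under=tuple(float(x) for x in p_under),
        seed=seed,
        flagged=flagged,
    )
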