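"""Rho-statistic coalescence dating, Saillard standard errors, ancient-tip
rate calibration and the star-like expansion index.

For a node v of a mutation-annotated tree with n descendant tips, the Rho
statistic is the mean number of mutations separating v from its tips,

    rho(v) = (1/n) * sum_tips (mutations on the v -> tip path),

an unbiased estimate of the expected mutation count accumulated since the
node's coalescence; multiplied by the years-per-mutation constant
1 / (mu * L) it estimates the node age in years.  Its standard deviation is
the Saillard branch-sum estimator

    SD(rho)^2 = sum over branches b below v of l_b * (n_b / n)^2,

where l_b is the branch's mutation count and n_b the tips below it.  The
star-like index S = rho / (n * SD^2) ranges from 1/n to 1; it equals 1
exactly for a pure multifurcation (every tip hanging directly off the node)
and values >= 0.5 conventionally indicate a star-like topology, the
phylogenetic footprint of a rapid demographic expansion.

Rho deliberately averages over *all* descendant tips, ancient ones
included and uncorrected for their age - the convention under which the
published per-node chronology (root rho computed on a tree containing four
ancient genomes) is reproduced.

The mutation rate is calibrated on radiocarbon-dated ancient tips with a
moment estimator: an ancient tip of age a is expected to lack mu*L*a
mutations relative to its modern relatives, so summing those deficits over
calibration tips and dividing by L * sum(ages) estimates mu.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .phylogeny import CladeTree, Node

__all__ = [
    "DEFAULT_YEARS_PER_MUTATION",
    "DEFAULT_MU",
    "DEFAULT_L_EFF",
    "STARLIKE_HIGH_THRESHOLD",
    "NodeChronology",
    "RateCalibration",
    "StarlikeResult",
    "rho",
    "rho_sd",
    "calibrate_rate",
    "to_years",
    "starlike_index",
    "date_split_node",
    "compare_chronologies",
    "chronology_table",
]

DEFAULT_MU = 0.735e-9  # mutations / site / year
DEFAULT_L_EFF = 3_335_000  # bp; together with mu gives 408 years/mutation
DEFAULT_YEARS_PER_MUTATION = 408.0
STARLIKE_HIGH_THRESHOLD = 0.5


@dataclass
class RateCalibration:
    """Mutation rate and callable length, and the derived waiting time."""

    mu: float
    L_eff: float
    mu_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.mu <= 0 or self.L_eff <= 0:
            raise ValueError("mu and L_eff must be positive")

    @property
    def years_per_mutation(self) -> float:
        return 1.0 / (self.mu * self.L_eff)


@dataclass
class NodeChronology:
    """Per-node rho, its SD, tip count, calendar age and star-like index."""

    node_id: int
    rho: float
    sd_rho: float
    n_tips: int
    time_years: float | None = None
    sd_time_years: float | None = None
    starlike: float | None = None
    starlike_high: bool | None = None


class StarlikeResult(NamedTuple):
    value: float
    high: bool


# ---------------------------------------------------------------------------
# Rho and its standard deviation
# ---------------------------------------------------------------------------


def _tip_path_counts(node: Node) -> dict[str, float]:
    """Mutation count on the path from ``node`` down to each descendant tip."""
    out: dict[str, float] = {}
    stack: list[tuple[Node, float]] = [(node, 0.0)]
    while stack:
        cur, depth = stack.pop()
        if cur.is_tip:
            out[cur.name] = depth
        for child in cur.children:
            stack.append((child, depth + child.length))
    return out


def rho(tree: CladeTree, node: Node | int) -> float:
    """Mean mutation count from a node to its descendant tips (all tips,
    ancient included).  A tip's own rho is 0."""
    if isinstance(node, int):
        node = tree.node(node)
    counts = _tip_path_counts(node)
    if not counts:
        raise ValueError("node has no descendant tips")
    return float(np.mean(list(counts.values())))


def _subtree_branch_stats(node: Node) -> list[tuple[float, int]]:
    """(branch length, tips below) for every branch in the node's subtree."""
    stats_: list[tuple[float, int]] = []
    counts: dict[int, int] = {}

    def rec(cur: Node) -> int:
        n = 1 if cur.is_tip else sum(rec(c) for c in cur.children)
        counts[id(cur)] = n
        return n

    rec(node)
    stack = list(node.children)
    while stack:
        cur = stack.pop()
        stats_.append((cur.length, counts[id(cur)]))
        stack.extend(cur.children)
    return stats_


def rho_sd(tree: CladeTree, node: Node | int) -> float:
    """Saillard standard deviation of rho: sqrt(sum_b l_b * (n_b/n)^2)."""
    if isinstance(node, int):
        node = tree.node(node)
    branches = _subtree_branch_stats(node)
    n_tips = len(_tip_path_counts(node))
    if n_tips == 0:
        raise ValueError("node has no descendant tips")
    var = sum(l * (nb / n_tips) ** 2 for l, nb in branches)
    return math.sqrt(var)


def _rho_restricted(node: Node, include: set[str]) -> float | None:
    counts = {t: c for t, c in _tip_path_counts(node).items() if t in include}
    if not counts:
        return None
    return float(np.mean(list(counts.values())))


# ---------------------------------------------------------------------------
# Rate calibration on ancient tips
# ---------------------------------------------------------------------------


def _mu_from_deltas(
    deltas: Sequence[float], ages: Sequence[float], L_eff: float
) -> float:
    """Moment estimator mu = sum(delta_c) / (L * sum(a_c)); negative deltas
    (sampling noise) are permitted and simply pull the estimate down."""
    total_age = float(np.sum(ages))
    if total_age <= 0:
        raise ValueError("calibration requires a positive total tip age")
    return float(np.sum(deltas)) / (L_eff * total_age)


def calibrate_rate(
    tree: CladeTree,
    calibration_tips: Sequence[tuple[str, float]],
    L_eff: float,
) -> RateCalibration:
    """Calibrate the per-site per-year mutation rate on dated ancient tips.

    For each calibration tip c of age a_c (years BP), the mutation deficit
    delta_c = rho_modern(parent(c)) - m_c is computed, where m_c counts the
    mutations on c's terminal branch and rho_modern averages over the modern
    (non-calibration) descendant tips of c's parent.  E[delta_c] = mu*L*a_c,
    so mu_hat = sum(delta_c) / (L_eff * sum(a_c)).  The SD comes from the
    delta method treating each path count as Poisson.

    Tips of age 0 are excluded (they carry no signal); a calibration tip
    whose parent has no modern descendants, or an all-zero age sum, raises
    ``ValueError``.
    """
    dated = [(name, age) for name, age in calibration_tips if age > 0]
    if not dated:
        raise ValueError("no calibration tip with positive age")
    calib_names = {name for name, _ in calibration_tips}
    modern = {t.name for t in tree.tips()} - calib_names

    deltas: list[float] = []
    ages: list[float] = []
    variances: list[float] = []
    for name, age in dated:
        tip = tree.tip(name)
        parent = tip.parent
        if parent is None:
            raise ValueError(f"calibration tip {name} is the root")
        rho_mod = _rho_restricted(parent, modern)
        if rho_mod is None:
            raise ValueError(
                f"calibration tip {name} has no modern relatives under its parent"
            )
        m_c = tip.length
        deltas.append(rho_mod - m_c)
        ages.append(age)
        # Poisson counts: Var(rho_modern) ~ Saillard sum restricted to moderns,
        # approximated by rho_mod / n_modern_tips; Var(m_c) ~ m_c.
        n_mod = len(
            [t for t in _tip_path_counts(parent) if t in modern]
        )
        variances.append(rho_mod / max(n_mod, 1) + m_c)

    mu_hat = _mu_from_deltas(deltas, ages, L_eff)
    denom = L_eff * float(np.sum(ages))
    mu_sd = math.sqrt(float(np.sum(variances))) / denom
    if mu_hat <= 0:
        raise ValueError(
            "calibration produced a non-positive rate; the ancient tips carry "
            "no resolvable mutation deficit at this sequence length"
        )
    return RateCalibration(mu=mu_hat, L_eff=L_eff, mu_sd=mu_sd)


# ---------------------------------------------------------------------------
# Conversion to calendar time and star-likeness
# ---------------------------------------------------------------------------


def to_years(
    entry: NodeChronology,
    calibration: RateCalibration | float,
) -> NodeChronology:
    """Complete a chronology entry with calendar times.

    ``time = rho * years_per_mutation`` and ``sd_time = SD(rho) *
    years_per_mutation``; the rate's own uncertainty is *not* propagated
    (the published per-node SD column equals SD(rho) x 408), it is reported
    separately on the :class:`RateCalibration`.
    """
    ypm = (
        calibration.years_per_mutation
        if isinstance(calibration, RateCalibration)
        else float(calibration)
    )
    if ypm <= 0:
        raise ValueError("years-per-mutation must be positive")
    entry.time_years = entry.rho * ypm
    entry.sd_time_years = entry.sd_rho * ypm
    return entry


def starlike_index(rho_value: float, sd_rho: float, n_tips: int) -> StarlikeResult:
    """Star-like index S = rho / (n * SD^2), with the conventional high flag
    at S >= 0.5.  Undefined (raises) for SD = 0 or fewer than two tips."""
    if n_tips < 2:
        raise ValueError("star-like index requires >= 2 tips")
    if sd_rho <= 0:
        raise ValueError("star-like index undefined for SD(rho) = 0")
    value = rho_value / (n_tips * sd_rho**2)
    return StarlikeResult(value=value, high=value >= STARLIKE_HIGH_THRESHOLD)


def date_split_node(
    parent_time: float, child_time: float, m_above: int, m_below: int
) -> float:
    """Interpolate the age of a genotyped split between two dated nodes.

    A marker splitting a branch with ``m_above`` mutations above the split
    and ``m_below`` below is placed linearly in mutation count:
    ``t = parent - (parent - child) * m_above / (m_above + m_below)``.
    """
    if m_above < 0 or m_below < 0:
        raise ValueError("mutation counts must be non-negative")
    if m_above + m_below < 1:
        raise ValueError("at least one mutation is needed to place the split")
    if parent_time < child_time:
        raise ValueError("parent_time must be >= child_time")
    frac = m_above / (m_above + m_below)
    return parent_time - (parent_time - child_time) * frac


def compare_chronologies(
    times_a: Sequence[float], times_b: Sequence[float]
) -> float:
    """Squared Pearson correlation between two dating vectors (concordance
    of two dating methods on the same nodes).  Symmetric; requires >= 3
    paired values and non-degenerate variance."""
    a = np.asarray(times_a, dtype=float)
    b = np.asarray(times_b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need paired vectors of length >= 3")
    if np.var(a) == 0 or np.var(b) == 0:
        raise ValueError("zero variance in a dating vector")
    r = stats.pearsonr(a, b).statistic
    return float(r**2)


# ---------------------------------------------------------------------------
# Whole-tree chronology table
# ---------------------------------------------------------------------------


def chronology_table(
    tree: CladeTree,
    calibration: RateCalibration | float = DEFAULT_YEARS_PER_MUTATION,
) -> pd.DataFrame:
    """Per-internal-node chronology: rho, SD, n, time (kya) and star-like
    index, in deterministic node-id order."""
    counts = tree.tip_counts()
    rows = []
    for node in tree.internal_nodes():
        entry = NodeChronology(
            node_id=node.id,
            rho=rho(tree, node),
            sd_rho=rho_sd(tree, node),
            n_tips=counts[node.id],
        )
        to_years(entry, calibration)
        if entry.sd_rho > 0 and entry.n_tips >= 2:
            s = starlike_index(entry.rho, entry.sd_rho, entry.n_tips)
            entry.starlike, entry.starlike_high = s.value, s.high
        rows.append(
            {
                "node_id": entry.node_id,
                "rho": round(entry.rho, 2),
                "sd_rho": round(entry.sd_rho, 2),
                "n_tips": entry.n_tips,
                "time_kya": round(entry.time_years / 1000.0, 2),
                "sd_time_kya": round(entry.sd_time_years / 1000.0, 2),
                "starlike": (
                    round(entry.starlike, 2) if entry.starlike is not None else np.nan
                ),
                "starlike_high": entry.starlike_high,
            }
        )
    return pd.DataFrame(rows)
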