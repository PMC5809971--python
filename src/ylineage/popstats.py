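"""Haplogroup assignment, frequency tables and the trans-Saharan
population-level statistics.

The population analysis asks whether the sub-Saharan component of the
northern African paternal gene pool looks like the product of recent forced
migration (the Arab slave trade) or of older gene flow across a once-fertile
Sahara.  American admixed populations, shaped by the comparably recent
Atlantic slave trade, serve as a positive control: if the northern African
component were recent, its E-M2 sub-lineage profile should correlate with
the sub-Saharan source profile the way the American one does.

This module provides:

* most-derived haplogroup assignment from a diagnostic-marker hierarchy,
  with detection of hierarchy-inconsistent genotypes;
* population x haplogroup count tables annotated with macro-region,
  linguistic family and nomadic status;
* the macro-region collapsing procedure (drop nomads, drop singleton
  lineages, merge NE+NW Africa and the sub-Saharan regions, keep the
  American admixed group) yielding within-region relative proportions of
  E-M2 sub-lineages;
* tie-corrected Spearman correlation and Mann-Whitney tests (exact by
  enumeration for small samples), and the linguistic-association test.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MarkerHierarchy",
    "Assignment",
    "FrequencyTable",
    "TestResult",
    "assign_haplogroup",
    "frequency_table",
    "collapse_fig5",
    "spearman",
    "mann_whitney",
    "linguistic_association",
    "NORTHERN_AFRICA_REGIONS",
    "SUB_SAHARAN_REGIONS",
]

#: Macro-regions merged into "Northern Africa" for the collapsed matrix.
NORTHERN_AFRICA_REGIONS = frozenset(
    {"Northeastern Africa", "Northwestern Africa"}
)
#: Macro-regions (incl. the Bantu groups within them) merged into
#: "Sub-Saharan Africa".
SUB_SAHARAN_REGIONS = frozenset(
    {
        "Central Sahel",
        "Western Africa",
        "Central Africa",
        "Great Lakes region",
        "Horn of Africa",
        "Southern Africa",
    }
)
ADMIXED_REGION = "American admixed"


@dataclass
class MarkerHierarchy:
    """Diagnostic markers arranged as a rooted haplogroup tree.

    ``parent[marker]`` names the marker's parent; exactly one marker (the
    root) maps to ``None``.  Cycles and multiple roots are rejected.
    """

    parent: Mapping[str, str | None]

    def __post_init__(self) -> None:
        roots = [m for m, p in self.parent.items() if p is None]
        if len(roots) != 1:
            raise ValueError(f"hierarchy must have exactly one root, got {roots}")
        for marker in self.parent:
            seen = set()
            cur = marker
            while cur is not None:
                if cur in seen:
                    raise ValueError(f"cycle in hierarchy at {cur}")
                seen.add(cur)
                cur = self.parent.get(cur)
                if cur is not None and cur not in self.parent:
                    raise ValueError(f"unknown parent marker {cur}")

    @property
    def root(self) -> str:
        return next(m for m, p in self.parent.items() if p is None)

    def ancestors(self, marker: str) -> list[str]:
        out = []
        cur = self.parent[marker]
        while cur is not None:
            out.append(cur)
            cur = self.parent[cur]
        return out

    def depth(self, marker: str) -> int:
        return len(self.ancestors(marker))


@dataclass
class Assignment:
    haplogroup: str  # marker name, or "unassigned"
    consistent: bool


def assign_haplogroup(
    sample_calls: Mapping[str, int | None], hierarchy: MarkerHierarchy
) -> Assignment:
    """Most-derived haplogroup of a sample from its diagnostic-marker calls.

    ``sample_calls`` maps marker -> 1 (derived), 0 (ancestral) or None /
    absent (untyped).  The assignment is the deepest derived marker whose
    typed ancestors are all derived; a sample derived at a marker but
    ancestral at one of its ancestors is impossible under the hierarchy and
    is flagged inconsistent.  No derived marker yields "unassigned".
    """
    derived = [m for m in hierarchy.parent if sample_calls.get(m) == 1]
    consistent = True
    candidates = []
    for marker in derived:
        anc_states = [sample_calls.get(a) for a in hierarchy.ancestors(marker)]
        if any(s == 0 for s in anc_states):
            consistent = False
        else:
            candidates.append(marker)
    if not candidates:
        return Assignment("unassigned", consistent)
    best = max(candidates, key=lambda m: (hierarchy.depth(m), m))
    return Assignment(best, consistent)


# ---------------------------------------------------------------------------
# Frequency tables
# ---------------------------------------------------------------------------


@dataclass
class FrequencyTable:
    """Population x haplogroup counts with per-population annotations.

    ``counts`` is indexed by population with one column per haplogroup (a
    stable schema: empty haplogroups keep a zero column); ``meta`` carries
    macroregion, linguistic_family, nomadic and sample size n per
    population.  Row counts never exceed n (the remainder is unassigned).
    """

    counts: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.meta.index):
            raise ValueError("counts and meta must share the population index")
        over = self.counts.sum(axis=1) > self.meta["n"]
        if over.any():
            bad = list(self.counts.index[over])
            raise ValueError(f"assigned counts exceed sample size for {bad}")

    def relative(self) -> pd.DataFrame:
        """Per-population relative frequencies (fractions of n)."""
        return self.counts.div(self.meta["n"], axis=0)

    def by_macroregion(self) -> pd.DataFrame:
        """Counts aggregated over populations within each macro-region."""
        return self.counts.groupby(self.meta["macroregion"]).sum()


def frequency_table(
    assignments: Mapping[str, str] | pd.Series,
    metadata: pd.DataFrame,
    haplogroups: Sequence[str] | None = None,
) -> FrequencyTable:
    """Tabulate per-population haplogroup counts.

    ``assignments`` maps sample id -> haplogroup; ``metadata`` must carry
    sample_id, population, macroregion, linguistic_family and nomadic
    columns.  A sample whose population is unknown raises ``ValueError``
    naming it.  Column order is deterministic (sorted, or the explicit
    ``haplogroups`` list, which also pins zero columns).
    """
    assignments = pd.Series(dict(assignments))
    meta_by_sample = metadata.set_index("sample_id")
    missing = [s for s in assignments.index if s not in meta_by_sample.index]
    if missing:
        raise ValueError(f"samples without population metadata: {sorted(missing)}")

    df = pd.DataFrame(
        {
            "haplogroup": assignments,
            "population": meta_by_sample.loc[assignments.index, "population"],
        }
    )
    cols = sorted(set(assignments) - {"unassigned"})
    if haplogroups is not None:
        cols = list(haplogroups)
    counts = (
        df[df["haplogroup"] != "unassigned"]
        .groupby(["population", "haplogroup"])
        .size()
        .unstack(fill_value=0)
        .reindex(columns=cols, fill_value=0)
    )
    pops = sorted(meta_by_sample.loc[assignments.index, "population"].unique())
    counts = counts.reindex(index=pops, fill_value=0)

    meta_rows = (
        meta_by_sample.loc[assignments.index]
        .groupby("population")
        .agg(
            macroregion=("macroregion", "first"),
            linguistic_family=("linguistic_family", "first"),
            nomadic=("nomadic", "first"),
            n=("population", "size"),
        )
        .reindex(index=pops)
    )
    return FrequencyTable(counts=counts.astype(int), meta=meta_rows)


def collapse_fig5(
    table: FrequencyTable,
    lineages: Sequence[str] | None = None,
    min_total: int = 2,
    nomadic_populations: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Collapse the frequency table into the 3 x k proportion matrix used to
    contrast American admixed, sub-Saharan and northern African profiles.

    Nomadic populations (their recent range decouples location from origin)
    are dropped, lineages with a total absolute count below ``min_total``
    (default: singletons) are dropped, the two northern macro-regions merge
    into "Northern Africa", the listed sub-Saharan regions (Bantu groups
    included) into "Sub-Saharan Africa", and "American admixed" stays.
    Cells are within-region relative proportions (each row sums to 1).
    """
    if "macroregion" not in table.meta.columns:
        raise ValueError("table lacks macroregion annotation")
    meta = table.meta
    keep_rows = ~meta["nomadic"].astype(bool)
    if nomadic_populations is not None:
        keep_rows &= ~meta.index.isin(list(nomadic_populations))
    counts = table.counts.loc[keep_rows]
    meta = meta.loc[keep_rows]

    def region_of(macro: str) -> str | None:
        if macro in NORTHERN_AFRICA_REGIONS:
            return "Northern Africa"
        if macro in SUB_SAHARAN_REGIONS or "Bantu" in macro:
            return "Sub-Saharan Africa"
        if macro == ADMIXED_REGION:
            return ADMIXED_REGION
        return None

    region = meta["macroregion"].map(region_of)
    counts = counts.loc[region.notna()]
    grouped = counts.groupby(region.dropna()).sum()
    if lineages is not None:
        grouped = grouped.reindex(columns=list(lineages), fill_value=0)
    grouped = grouped.loc[:, grouped.sum(axis=0) >= min_total]
    row_sums = grouped.sum(axis=1)
    if (row_sums == 0).any():
        empty = list(grouped.index[row_sums == 0])
        raise ValueError(f"regions with no carriers cannot be normalised: {empty}")
    order = [ADMIXED_REGION, "Sub-Saharan Africa", "Northern Africa"]
    grouped = grouped.reindex(index=[r for r in order if r in grouped.index])
    return grouped.div(grouped.sum(axis=1), axis=0)


# ---------------------------------------------------------------------------
# Rank statistics
# ---------------------------------------------------------------------------


@dataclass
class TestResult:
    statistic: float
    p_value: float
    n: int
    method: str


def spearman(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Tie-corrected Spearman rank correlation with the two-sided p-value
    from the t approximation on n-2 degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 4:
        raise ValueError("need paired vectors of length >= 4")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant vector: rank correlation undefined")
    res = stats.spearmanr(x, y)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n=int(x.size),
        method="spearman",
    )


_EXACT_LIMIT = 12


def _mann_whitney_u(a: np.ndarray, b: np.ndarray) -> float:
    """U statistic of group a with average ranks (tie-aware)."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    r_a = float(ranks[: a.size].sum())
    return r_a - a.size * (a.size + 1) / 2.0


def mann_whitney(
    group_a: Sequence[float], group_b: Sequence[float]
) -> TestResult:
    """Mann-Whitney U test, exact by enumeration for small samples.

    With n_a + n_b <= 12 the two-sided p-value is computed by enumerating
    every partition of the pooled values (handles ties exactly): the
    proportion of partitions whose U deviates from n_a*n_b/2 at least as
    much as the observed one.  Larger samples use the normal approximation
    with continuity and tie correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    u_obs = _mann_whitney_u(a, b)
    n_a, n_b = a.size, b.size
    mu = n_a * n_b / 2.0
    if n_a + n_b <= _EXACT_LIMIT:
        pooled = np.concatenate([a, b])
        dev = abs(u_obs - mu)
        hits = 0
        total = 0
        for idx in itertools.combinations(range(pooled.size), n_a):
            mask = np.zeros(pooled.size, dtype=bool)
            mask[list(idx)] = True
            u = _mann_whitney_u(pooled[mask], pooled[~mask])
            hits += abs(u - mu) >= dev - 1e-12
            total += 1
        return TestResult(
            statistic=u_obs,
            p_value=hits / total,
            n=n_a + n_b,
            method="mann-whitney-exact",
        )
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n=n_a + n_b,
        method="mann-whitney-normal",
    )


def linguistic_association(
    clade: str, table: FrequencyTable, family: str
) -> TestResult:
    """Is a clade's per-population frequency elevated in one linguistic
    family?  Mann-Whitney on relative frequencies, target family vs all
    other populations."""
    if "linguistic_family" not in table.meta.columns:
        raise ValueError("table lacks linguistic annotation")
    families = table.meta["linguistic_family"]
    if family not in set(families):
        raise ValueError(f"linguistic family {family!r} absent from table")
    freqs = table.counts[clade] / table.meta["n"]
    in_family = freqs[families == family].to_numpy()
    others = freqs[families != family].to_numpy()
    return mann_whitney(in_family, others)
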