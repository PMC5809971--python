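"""Variant ingestion, callable-mask construction and the SNP filter tiers.

Three tiers separate true Y-SNPs from calling artifacts:

1. *direct* filtering on the evidence embedded in the VCF record (QUAL,
   per-site missingness) plus a callable mask built from per-base depth
   (bases are unreliable where any sample is under-covered, or over-covered
   relative to its own mean, a proxy for collapsed duplications);
2. *cluster* filtering, which flags groups of two or more SNPs in close
   physical proximity on the same branch of the phylogeny - the signature of
   a local misalignment rather than of independent mutations;
3. in place of the original manual alignment review, a machine-readable
   report of every verdict.

Coordinates are 1-based in VCF and mask I/O; mask intervals are 0-based
half-open internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .phylogeny import MISSING

__all__ = [
    "VariantSite",
    "VcfData",
    "CallableMask",
    "FilterReport",
    "Cluster",
    "read_vcf",
    "build_callable_mask",
    "direct_filter",
    "cluster_filter",
]


@dataclass
class VariantSite:
    """One biallelic or triallelic chrY site with per-sample haploid calls.

    ``calls[i]`` is 0 for the reference allele, 1 or 2 for the first or
    second ALT, -1 for a missing call, aligned to the sample roster of the
    source VCF.
    """

    position: int
    ref: str
    alts: tuple[str, ...]
    calls: np.ndarray
    qual: float | None = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("positions are 1-based")
        if not 1 <= len(self.alts) <= 2:
            raise ValueError("sites must carry one or two ALT alleles")
        self.calls = np.asarray(self.calls, dtype=np.int8)

    @property
    def triallelic(self) -> bool:
        """Two ALT alleles: a candidate for independent per-allele placement."""
        return len(self.alts) == 2

    @property
    def missingness(self) -> float:
        return float(np.mean(self.calls == MISSING))


@dataclass
class VcfData:
    sites: list[VariantSite]
    samples: list[str]
    n_multiallelic_rejected: int = 0


def read_vcf(path: str | Path) -> VcfData:
    """Read haploid chrY calls from a VCF (v4.2, plain text or bgzipped).

    Positions must be strictly increasing; records with more than two ALT
    alleles are rejected (counted, not raised); a ``.`` genotype becomes a
    missing call.  A diploid GT violates the chrY contract and raises
    ``ValueError``, as does a malformed record (with its position).
    """
    import pysam

    path = str(path)
    try:
        vf = pysam.VariantFile(path)
    except (OSError, ValueError) as exc:
        raise ValueError(f"cannot parse VCF {path}: {exc}") from exc
    samples = list(vf.header.samples)
    sites: list[VariantSite] = []
    rejected = 0
    last_pos = 0
    for rec in vf:
        if rec.alts is None or len(rec.alts) == 0:
            continue
        if len(rec.alts) > 2:
            rejected += 1
            continue
        if rec.pos <= last_pos:
            raise ValueError(
                f"positions not strictly increasing at {rec.pos} (after {last_pos})"
            )
        last_pos = rec.pos
        calls = np.empty(len(samples), dtype=np.int8)
        for i, s in enumerate(samples):
            gt = rec.samples[s]["GT"]
            if len(gt) != 1:
                raise ValueError(
                    f"diploid GT for sample {s} at position {rec.pos}: "
                    "chrY calls must be haploid"
                )
            calls[i] = MISSING if gt[0] is None else int(gt[0])
        sites.append(
            VariantSite(
                position=rec.pos,
                ref=rec.ref,
                alts=tuple(rec.alts),
                calls=calls,
                qual=rec.qual,
            )
        )
    return VcfData(sites=sites, samples=samples, n_multiallelic_rejected=rejected)


# ---------------------------------------------------------------------------
# Callable mask
# ---------------------------------------------------------------------------


@dataclass
class CallableMask:
    """Sorted, non-overlapping 0-based half-open intervals of reliable bases."""

    intervals: list[tuple[int, int]]

    def __post_init__(self) -> None:
        merged: list[tuple[int, int]] = []
        for start, end in sorted(self.intervals):
            if end <= start:
                raise ValueError(f"empty or inverted interval ({start}, {end})")
            if merged and start <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], end))
            else:
                merged.append((start, end))
        self.intervals = merged

    @property
    def total_bp(self) -> int:
        return sum(end - start for start, end in self.intervals)

    def contains(self, position_1based: int) -> bool:
        p = position_1based - 1
        starts = [s for s, _ in self.intervals]
        i = int(np.searchsorted(starts, p, side="right")) - 1
        return i >= 0 and self.intervals[i][0] <= p < self.intervals[i][1]

    def to_bed(self, path: str | Path, name: str = "callable") -> None:
        with open(path, "w") as fh:
            for start, end in self.intervals:
                fh.write(f"chrY\t{start}\t{end}\t{name}\n")

    @classmethod
    def from_bed(cls, path: str | Path) -> "CallableMask":
        intervals = []
        for line in Path(path).read_text().splitlines():
            if not line or line.startswith(("#", "track")):
                continue
            _, start, end, *_ = line.split("\t")
            intervals.append((int(start), int(end)))
        return cls(intervals)


def build_callable_mask(
    depth_table: pd.DataFrame | str | Path,
    min_depth: int = 8,
    max_depth_factor: float = 2.0,
) -> CallableMask:
    """Build the callable mask from a per-base depth table.

    ``depth_table`` holds columns ``pos`` (1-based), ``sample`` and
    ``depth``; a base is callable iff *every* sample's depth lies in
    ``[min_depth, max_depth_factor * that sample's mean depth]`` (the upper
    bound proxies collapsed duplications).  Positions absent for a sample
    count as depth 0.  Adjacent callable bases are merged into intervals.
    """
    if isinstance(depth_table, (str, Path)):
        depth_table = pd.read_csv(depth_table, sep="\t")
    if depth_table.empty:
        raise ValueError("depth table is empty")
    wide = depth_table.pivot_table(
        index="pos", columns="sample", values="depth", fill_value=0
    ).sort_index()
    means = wide.mean(axis=0)
    ok = (wide >= min_depth) & (wide.le(max_depth_factor * means, axis=1))
    callable_pos = wide.index[ok.all(axis=1)].to_numpy()
    intervals: list[tuple[int, int]] = []
    for p in callable_pos:
        start = int(p) - 1
        if intervals and intervals[-1][1] == start:
            intervals[-1] = (intervals[-1][0], start + 1)
        else:
            intervals.append((start, start + 1))
    return CallableMask(intervals=intervals)


# ---------------------------------------------------------------------------
# Filter report
# ---------------------------------------------------------------------------


@dataclass
class Cluster:
    id: int
    branch_id: int
    positions: list[int]

    @property
    def span_bp(self) -> int:
        return self.positions[-1] - self.positions[0] + 1


@dataclass
class FilterReport:
    """One verdict per input site: ``pass``, ``fail_direct:<reason>``,
    ``off_mask`` or ``flagged_cluster:<id>``."""

    verdicts: dict[int, str] = field(default_factory=dict)
    clusters: list[Cluster] = field(default_factory=list)

    def pass_positions(self) -> list[int]:
        return [p for p, v in self.verdicts.items() if v == "pass"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"position": p, "verdict": v} for p, v in sorted(self.verdicts.items())]
        )


def direct_filter(
    sites: Sequence[VariantSite],
    min_qual: float = 20.0,
    max_missingness: float = 0.1,
    mask: CallableMask | None = None,
) -> FilterReport:
    """Tier-1 filtering on the evidence carried by the VCF itself.

    Order-preserving and report-only: every site receives exactly one
    verdict (``off_mask`` takes precedence, then QUAL, then missingness).
    """
    report = FilterReport()
    for site in sites:
        if mask is not None and not mask.contains(site.position):
            report.verdicts[site.position] = "off_mask"
        elif site.qual is not None and site.qual < min_qual:
            report.verdicts[site.position] = "fail_direct:qual"
        elif site.missingness > max_missingness:
            report.verdicts[site.position] = "fail_direct:missingness"
        else:
            report.verdicts[site.position] = "pass"
    return report


def cluster_filter(
    positions: Iterable[int],
    branch_assignment: Mapping[int, int],
    window_bp: int = 10,
    report: FilterReport | None = None,
) -> FilterReport:
    """Tier-3 filtering: flag same-branch SNPs in close physical proximity.

    Maximal chains of >= 2 passing sites on the same phylogeny branch whose
    consecutive gaps are all <= ``window_bp`` are flagged as clusters
    (report-only; the decision to drop is downstream's).  Raises ``KeyError``
    for a passing site with no branch assignment.
    """
    report = report or FilterReport()
    positions = sorted(positions)
    for pos in positions:
        if pos not in branch_assignment:
            raise KeyError(f"site {pos} has no branch assignment")
        report.verdicts.setdefault(pos, "pass")
    by_branch: dict[int, list[int]] = {}
    for pos in positions:
        if report.verdicts.get(pos) == "pass":
            by_branch.setdefault(branch_assignment[pos], []).append(pos)
    cid = len(report.clusters)
    for branch_id in sorted(by_branch):
        chain: list[int] = []
        for pos in by_branch[branch_id] + [None]:
            if chain and (pos is None or pos - chain[-1] > window_bp):
                if len(chain) >= 2:
                    cluster = Cluster(id=cid, branch_id=branch_id, positions=chain)
                    report.clusters.append(cluster)
                    for p in chain:
                        report.verdicts[p] = f"flagged_cluster:{cid}"
                    cid += 1
                chain = []
            if pos is not None:
                chain.append(pos)
    return report
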