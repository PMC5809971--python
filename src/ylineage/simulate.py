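"""Coalescent simulation of Y-chromosome genealogies with ancient tips.

Generates the ground truth the rest of the pipeline is validated against: a
serially-sampled Kingman coalescent (haploid, time in years, optional
exponential growth), Poisson mutations under the infinite-sites model at a
configurable per-site per-year rate, optional recurrent sites and clustered
artifact SNPs mimicking alignment errors, and text exports (haploid VCF,
metadata TSV, newick, truth tables) that round-trip exactly.

Scale defaults emulate the study design this package addresses: ~3.3 Mb of
callable non-recombining sequence, a mutation rate of 0.735e-9 per site per
year, ~150 modern deep-sequenced chromosomes and four radiocarbon-dated
ancient genomes (Loschbour 8,055, Kotias 9,712, Bichon 13,665 and Ust'-Ishim
44,890 years BP) used as calibration points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .phylogeny import MISSING, CladeTree, GenotypeMatrix, Node

__all__ = [
    "ANCIENT_CALIBRATION_AGES",
    "DEFAULT_MU",
    "DEFAULT_L",
    "SimConfig",
    "TruthSet",
    "simulate_genealogy",
    "sprinkle_mutations",
    "inject_artifacts",
    "default_metadata",
    "export_simulation",
    "import_vcf_matrix",
]

#: Published calibrated radiocarbon ages (years BP) of the four ancient
#: genomes used as tip calibration points.
ANCIENT_CALIBRATION_AGES: dict[str, int] = {
    "Loschbour": 8055,
    "Kotias": 9712,
    "Bichon": 13665,
    "Ust_Ishim": 44890,
}

DEFAULT_MU = 0.735e-9  # mutations / site / year
DEFAULT_L = 3_300_000  # callable bp of the X-degenerate target


@dataclass
class SimConfig:
    """Parameters of one simulated dataset.

    ``effective_size_years`` is the haploid coalescent timescale expressed
    directly in years (pairwise coalescence rate 1/Ne per year), so no
    generation time ever enters; ``growth_rate`` is an exponential growth
    rate per year (population size shrinking backward in time).  The same
    config + seed always reproduces byte-identical outputs.
    """

    seed: int
    n_modern: int = 146
    ancient_tips: tuple[tuple[float, int], ...] = tuple(
        (age, 1) for age in sorted(ANCIENT_CALIBRATION_AGES.values())
    )
    effective_size_years: float = 130_000.0
    growth_rate: float = 0.0
    mu: float = DEFAULT_MU
    L: int = DEFAULT_L
    recurrent_site_fraction: float = 0.0
    cluster_artifact_rate: float = 0.0
    cluster_window_bp: int = 10
    population_scheme: Mapping[str, tuple[str, str, str, bool]] | None = None

    def __post_init__(self) -> None:
        if self.n_modern < 2:
            raise ValueError("n_modern must be >= 2")
        if self.mu <= 0:
            raise ValueError("mu must be > 0")
        if self.L <= 0:
            raise ValueError("L must be > 0")
        if not 0 <= self.recurrent_site_fraction < 1:
            raise ValueError("recurrent_site_fraction must lie in [0, 1)")
        if self.cluster_artifact_rate < 0:
            raise ValueError("cluster_artifact_rate must be >= 0")
        if any(age < 0 for age, _ in self.ancient_tips):
            raise ValueError("ancient tip ages must be >= 0")
        if self.effective_size_years <= 0:
            raise ValueError("effective_size_years must be > 0")

    def tip_ages(self) -> dict[str, float]:
        """Deterministic tip naming: M### for moderns, A#_<age> for ancients."""
        ages = {f"M{i:03d}": 0.0 for i in range(self.n_modern)}
        k = 0
        for age, count in self.ancient_tips:
            for _ in range(count):
                ages[f"A{k}_{int(age)}"] = float(age)
                k += 1
        return ages


@dataclass
class TruthSet:
    """Ground truth of one replicate: genealogy, rate and branch counts."""

    tree: CladeTree
    mu: float
    L: int
    tip_ages: dict[str, float]
    branch_mutation_counts: dict[int, int] = field(default_factory=dict)

    @property
    def tmrca(self) -> float:
        return self.tree.root.time_years


# ---------------------------------------------------------------------------
# Genealogy
# ---------------------------------------------------------------------------


def _coalescence_waiting_time(
    k: int, t: float, n0: float, growth: float, rng: np.random.Generator
) -> float:
    """Waiting time to the next coalescence among ``k`` lineages at time ``t``
    (years before present), under N(t) = n0 * exp(-growth * t)."""
    pairs = k * (k - 1) / 2.0
    e = rng.exponential()
    if growth == 0.0:
        return e * n0 / pairs
    # integrate pairs * exp(growth * s) / n0 over [t, t + w] = e
    arg = math.exp(growth * t) + e * n0 * growth / pairs
    return math.log(arg) / growth - t


def simulate_genealogy(config: SimConfig) -> TruthSet:
    """Simulate a serially-sampled Kingman genealogy over modern and ancient
    tips.

    Ancient tips enter the coalescent process at their age (years BP); node
    times strictly increase from tips to root, and the root necessarily
    predates the oldest tip.  Deterministic for a fixed config.
    """
    rng = np.random.default_rng(config.seed)
    ages = config.tip_ages()
    pending = sorted(ages.items(), key=lambda kv: (kv[1], kv[0]))
    active: list[Node] = []
    t = 0.0
    i = 0
    while i < len(pending) or len(active) > 1:
        # activate every tip whose age has been reached
        while i < len(pending) and pending[i][1] <= t:
            name, age = pending[i]
            active.append(Node(name=name, time_years=float(age)))
            i += 1
        next_activation = pending[i][1] if i < len(pending) else math.inf
        if len(active) >= 2:
            w = _coalescence_waiting_time(
                len(active), t, config.effective_size_years, config.growth_rate, rng
            )
            if t + w <= next_activation:
                t += w
                a, b = rng.choice(len(active), size=2, replace=False)
                a, b = sorted((int(a), int(b)))
                parent = Node(time_years=t)
                parent.add(active[a])
                parent.add(active[b])
                active = [n for j, n in enumerate(active) if j not in (a, b)]
                active.append(parent)
                continue
        if math.isinf(next_activation):  # pragma: no cover - defensive
            raise RuntimeError("coalescent failed to absorb all lineages")
        t = next_activation
    tree = CladeTree(active[0])
    for node in tree.preorder():
        for child in node.children:
            if child.time_years >= node.time_years:
                raise RuntimeError(
                    "node times must strictly decrease from root to tips"
                )
    return TruthSet(tree=tree, mu=config.mu, L=config.L, tip_ages=ages)


# ---------------------------------------------------------------------------
# Mutations
# ---------------------------------------------------------------------------


def sprinkle_mutations(
    truth: TruthSet,
    mu: float | None = None,
    L: int | None = None,
    seed: int | None = None,
    recurrent_site_fraction: float = 0.0,
) -> tuple[GenotypeMatrix, dict[int, int]]:
    """Drop Poisson mutations on the genealogy under (near-)infinite sites.

    Per-branch counts are Poisson(mu * L * branch duration); each mutation
    takes a fresh uniform position in 1..L except that, with probability
    ``recurrent_site_fraction``, it re-uses an already occupied position
    (modelling recurrent mutation).  The derived allele is assigned to every
    tip below the branch; a re-used position unions the carrier sets of its
    events.  Updates ``truth.branch_mutation_counts`` and returns the matrix
    together with the position -> branch(node id) assignment of the
    *first* event at each position.

    Raises ``ValueError`` if the total mutation count exceeds ``L``.
    """
    mu = truth.mu if mu is None else mu
    L = truth.L if L is None else L
    rng = np.random.default_rng(seed)
    tree = truth.tree
    clades = tree.clades()
    sample_index = {name: i for i, name in enumerate(sorted(truth.tip_ages))}
    samples = sorted(sample_index)

    branch_counts: dict[int, int] = {}
    events: list[tuple[int, frozenset[str]]] = []  # (branch node id, carriers)
    total = 0
    for node in tree.preorder():
        if node.parent is None:
            continue
        duration = node.parent.time_years - node.time_years
        count = int(rng.poisson(mu * L * duration))
        branch_counts[node.id] = count
        total += count
        for _ in range(count):
            events.append((node.id, clades[node.id]))
    if total > L:
        raise ValueError(
            f"{total} mutations exceed {L} sites: infinite-sites violated"
        )
    truth.branch_mutation_counts = branch_counts

    used: list[int] = []
    used_set: set[int] = set()
    calls_by_pos: dict[int, np.ndarray] = {}
    assignment: dict[int, int] = {}
    for branch_id, carriers in events:
        reuse = (
            recurrent_site_fraction > 0
            and used
            and rng.random() < recurrent_site_fraction
        )
        if reuse:
            pos = int(used[rng.integers(len(used))])
        else:
            while True:
                pos = int(rng.integers(1, L + 1))
                if pos not in used_set:
                    break
            used.append(pos)
            used_set.add(pos)
            calls_by_pos[pos] = np.zeros(len(samples), dtype=np.int8)
            assignment[pos] = branch_id
        for name in carriers:
            calls_by_pos[pos][sample_index[name]] = 1

    positions = np.array(sorted(calls_by_pos), dtype=np.int64)
    calls = (
        np.stack([calls_by_pos[int(p)] for p in positions], axis=1)
        if len(positions)
        else np.zeros((len(samples), 0), dtype=np.int8)
    )
    matrix = GenotypeMatrix(samples, positions, calls)
    return matrix, assignment


# ---------------------------------------------------------------------------
# Artifact injection
# ---------------------------------------------------------------------------


def inject_artifacts(
    matrix: GenotypeMatrix,
    config: SimConfig,
    seed: int | None = None,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Add clustered private SNPs mimicking mapping artifacts.

    Draws Poisson(cluster_artifact_rate * n_tips) clusters; each cluster puts
    2-4 novel private SNPs within ``cluster_window_bp`` on one randomly
    chosen modern tip's terminal branch.  The returned ledger lists every
    injected site (cluster id, tip, position) so downstream filter recall can
    be scored exactly.
    """
    if config.cluster_window_bp > config.L:
        raise ValueError("cluster window exceeds callable length")
    rng = np.random.default_rng(seed if seed is not None else config.seed + 1)
    n_clusters = int(rng.poisson(config.cluster_artifact_rate * len(matrix.samples)))
    records: list[dict] = []
    if n_clusters == 0:
        return matrix, pd.DataFrame(columns=["cluster", "tip", "position"])

    used = set(int(p) for p in matrix.positions)
    moderns = [s for s in matrix.samples if s.startswith("M")] or list(matrix.samples)
    new_cols: dict[int, np.ndarray] = {}
    for cid in range(n_clusters):
        tip = moderns[int(rng.integers(len(moderns)))]
        size = 2 + int(rng.integers(0, 3))
        for _ in range(200):
            anchor = int(rng.integers(1, config.L - config.cluster_window_bp))
            span = range(anchor, anchor + config.cluster_window_bp + 1)
            free = [p for p in span if p not in used]
            if len(free) >= size:
                break
        else:  # pragma: no cover - astronomically unlikely at default density
            raise RuntimeError("could not place artifact cluster")
        chosen = sorted(
            int(p) for p in rng.choice(free, size=size, replace=False)
        )
        row = matrix.samples.index(tip)
        for pos in chosen:
            col = np.zeros(matrix.n_samples, dtype=np.int8)
            col[row] = 1
            new_cols[pos] = col
            used.add(pos)
            records.append({"cluster": cid, "tip": tip, "position": pos})

    all_pos = np.array(
        sorted(list(map(int, matrix.positions)) + list(new_cols)), dtype=np.int64
    )
    calls = np.zeros((matrix.n_samples, len(all_pos)), dtype=np.int8)
    for j, pos in enumerate(all_pos):
        pos = int(pos)
        if pos in new_cols:
            calls[:, j] = new_cols[pos]
        else:
            calls[:, j] = matrix.column(pos)
    out = GenotypeMatrix(list(matrix.samples), all_pos, calls)
    ledger = pd.DataFrame.from_records(records, columns=["cluster", "tip", "position"])
    return out, ledger


# ---------------------------------------------------------------------------
# Metadata and export
# ---------------------------------------------------------------------------

#: Default population scheme: plausible labelled groups spanning the
#: macro-regions the frequency analyses distinguish.
DEFAULT_POPULATIONS: tuple[tuple[str, str, str, bool], ...] = (
    ("Moroccans", "Northwestern Africa", "Afro-asiatic", False),
    ("Egyptians", "Northeastern Africa", "Afro-asiatic", False),
    ("Tuareg", "Central Sahel", "Afro-asiatic", True),
    ("Daza", "Central Sahel", "Nilo-Saharan", False),
    ("Yoruba", "Western Africa", "Niger-Congo", False),
    ("Amhara", "Horn of Africa", "Afro-asiatic", False),
    ("Luo", "Great Lakes region", "Nilo-Saharan", False),
    ("ASW", "American admixed", "Niger-Congo", False),
)


def default_metadata(config: SimConfig) -> pd.DataFrame:
    """Sample metadata table: population, macro-region, linguistic family,
    nomadic flag and age (years BP; 0 for moderns)."""
    rows = []
    ages = config.tip_ages()
    moderns = sorted(n for n, a in ages.items() if a == 0)
    ancients = sorted((n for n, a in ages.items() if a > 0), key=lambda n: ages[n])
    for i, name in enumerate(moderns):
        if config.population_scheme and name in config.population_scheme:
            pop, macro, ling, nomadic = config.population_scheme[name]
        else:
            pop, macro, ling, nomadic = DEFAULT_POPULATIONS[
                i % len(DEFAULT_POPULATIONS)
            ]
        rows.append(
            dict(
                sample_id=name,
                population=pop,
                macroregion=macro,
                linguistic_family=ling,
                nomadic=nomadic,
                age_years_bp=0,
            )
        )
    for name in ancients:
        rows.append(
            dict(
                sample_id=name,
                population="ancient",
                macroregion="Eurasia",
                linguistic_family="unknown",
                nomadic=False,
                age_years_bp=int(ages[name]),
            )
        )
    return pd.DataFrame(rows)


_BASES = "ACGT"


def _alleles_for(pos: int, n_alts: int = 1) -> tuple[str, list[str]]:
    ref = _BASES[pos % 4]
    alts = [_BASES[(pos + k) % 4] for k in range(1, n_alts + 1)]
    return ref, alts


def write_vcf(path: str | Path, matrix: GenotypeMatrix, contig_length: int) -> None:
    """Write the matrix as an uncompressed haploid VCF v4.2 on chrY."""
    lines = [
        "##fileformat=VCFv4.2",
        "##source=ylineage-simulate",
        f"##contig=<ID=chrY,length={contig_length}>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Haploid genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(matrix.samples),
    ]
    for j, pos in enumerate(matrix.positions):
        pos = int(pos)
        col = matrix.calls[:, j]
        n_alts = max(1, int(col.max()))
        ref, alts = _alleles_for(pos, n_alts)
        gts = [("." if c == MISSING else str(int(c))) for c in col]
        lines.append(
            f"chrY\t{pos}\t.\t{ref}\t{','.join(alts)}\t99\tPASS\t.\tGT\t"
            + "\t".join(gts)
        )
    Path(path).write_text("\n".join(lines) + "\n")


def import_vcf_matrix(path: str | Path) -> GenotypeMatrix:
    """Read a haploid VCF back into a ref/alt-coded genotype matrix."""
    from .filtering import read_vcf

    data = read_vcf(path)
    positions = np.array([s.position for s in data.sites], dtype=np.int64)
    calls = (
        np.stack([s.calls for s in data.sites], axis=1)
        if data.sites
        else np.zeros((len(data.samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(list(data.samples), positions, calls)


def export_simulation(
    outdir: str | Path,
    matrix: GenotypeMatrix,
    truth: TruthSet,
    metadata: pd.DataFrame,
    branch_assignment: dict[int, int] | None = None,
) -> dict[str, Path]:
    """Write the simulated dataset as plain-text files.

    Emits ``sim.vcf`` (haploid GT, chrY, 1-based positions, strictly
    increasing), ``metadata.tsv``, ``true_tree.nwk`` (branch lengths in
    years, internal labels = node ids), ``node_times.tsv`` and
    ``branch_mutations.tsv``.  Raises ``ValueError`` naming offending ids if
    matrix samples and metadata disagree.
    """
    from .phylogeny import to_newick

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta_ids = set(metadata["sample_id"])
    matrix_ids = set(matrix.samples)
    if meta_ids != matrix_ids:
        missing = sorted(matrix_ids - meta_ids)
        extra = sorted(meta_ids - matrix_ids)
        raise ValueError(
            f"sample id mismatch: missing from metadata {missing}, "
            f"absent from matrix {extra}"
        )

    paths = {
        "vcf": outdir / "sim.vcf",
        "metadata": outdir / "metadata.tsv",
        "tree": outdir / "true_tree.nwk",
        "node_times": outdir / "node_times.tsv",
        "branch_mutations": outdir / "branch_mutations.tsv",
    }
    write_vcf(paths["vcf"], matrix, truth.L)
    metadata.to_csv(paths["metadata"], sep="\t", index=False)
    paths["tree"].write_text(to_newick(truth.tree, lengths="years") + "\n")
    times = pd.DataFrame(
        [
            {"node_id": n.id, "time_years": n.time_years, "tip": n.name or ""}
            for n in truth.tree.preorder()
        ]
    )
    times.to_csv(paths["node_times"], sep="\t", index=False)
    assign = branch_assignment or {}
    pd.DataFrame(
        [{"position": p, "node_id": b} for p, b in sorted(assign.items())]
    ).to_csv(paths["branch_mutations"], sep="\t", index=False)
    return paths
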