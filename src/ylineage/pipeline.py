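"""End-to-end pipeline runner, reproducibility manifest and packaged fixtures.

Chains the stages simulate -> filter -> tree -> date -> popstats under a
single serialisable configuration.  Every random stage derives its stream
from the single configured seed, so re-running an identical configuration
reproduces identical numeric outputs; each stage writes its artifacts before
the next starts, and a failure leaves the earlier outputs intact with the
failing stage recorded in the manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import chronology, filtering, phylogeny, popstats, simulate

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "make_star_tree",
    "make_table1_fixture",
]

logger = logging.getLogger("ylineage")

STAGES = ("simulate", "filter", "tree", "date", "popstats")


@dataclass
class PipelineConfig:
    """Fully serialisable pipeline configuration.

    Each stage key is either ``None`` (disabled) or a parameter mapping;
    the manifest written next to the outputs records every effective
    parameter and the checksum of every input file.
    """

    seed: int
    outdir: str
    simulate: dict[str, Any] | None = None
    filter: dict[str, Any] | None = None
    tree: dict[str, Any] | None = None
    date: dict[str, Any] | None = None
    popstats: dict[str, Any] | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(**raw)

    def to_dict(self) -> dict[str, Any]:
        return {
            "seed": self.seed,
            "outdir": self.outdir,
            **{s: getattr(self, s) for s in STAGES},
        }

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("an explicit seed is required (no wall-clock default)")
        if self.filter is not None and self.simulate is None:
            if "vcf" not in self.filter:
                raise ValueError("filter stage needs a vcf input or the simulate stage")
        if self.tree is not None and self.filter is None and self.simulate is None:
            if "vcf" not in (self.tree or {}):
                raise ValueError("tree stage needs upstream variants")
        if self.date is not None and self.tree is None:
            if "tree" not in (self.date or {}):
                raise ValueError(
                    "date stage needs the tree stage or an explicit tree input"
                )
        if self.popstats is not None and "frequency_table" not in self.popstats:
            raise ValueError("popstats stage needs a frequency_table input")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run the enabled stages in order; return (and write) the manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "config": config.to_dict(),
        "stages": {},
        "inputs": {},
    }
    state: dict[str, Any] = {}

    def finish(stage: str, status: str, **info: Any) -> None:
        manifest["stages"][stage] = {"status": status, **info}
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    for stage in STAGES:
        params = getattr(config, stage)
        if params is None:
            continue
        logger.info("stage %s: starting", stage)
        try:
            runner = globals()[f"_stage_{stage}"]
            info = runner(config, dict(params), outdir, state, manifest)
            finish(stage, "ok", **(info or {}))
        except Exception as exc:
            finish(stage, "failed", error=str(exc))
            raise
        logger.info("stage %s: done", stage)
    return manifest


# ---------------------------------------------------------------------------
# Stage implementations
# ---------------------------------------------------------------------------


def _stage_simulate(config, params, outdir, state, manifest):
    simdir = outdir / "simulate"
    sim_config = simulate.SimConfig(seed=config.seed, **params)
    truth = simulate.simulate_genealogy(sim_config)
    matrix, assignment = simulate.sprinkle_mutations(
        truth,
        seed=config.seed + 1,
        recurrent_site_fraction=sim_config.recurrent_site_fraction,
    )
    ledger = None
    if sim_config.cluster_artifact_rate > 0:
        matrix, ledger = simulate.inject_artifacts(
            matrix, sim_config, seed=config.seed + 2
        )
    metadata = simulate.default_metadata(sim_config)
    paths = simulate.export_simulation(simdir, matrix, truth, metadata, assignment)
    if ledger is not None:
        ledger.to_csv(simdir / "artifact_ledger.tsv", sep="\t", index=False)
    state.update(
        truth=truth,
        matrix=matrix,
        metadata=metadata,
        true_assignment=assignment,
        vcf=paths["vcf"],
        sim_config=sim_config,
    )
    return {"n_sites": matrix.n_sites, "n_samples": matrix.n_samples}


def _stage_filter(config, params, outdir, state, manifest):
    vcf = Path(params.get("vcf", state.get("vcf")))
    manifest["inputs"][str(vcf)] = _sha256(vcf)
    data = filtering.read_vcf(vcf)
    mask = None
    if "depth" in params:
        depth = Path(params["depth"])
        manifest["inputs"][str(depth)] = _sha256(depth)
        mask = filtering.build_callable_mask(
            depth,
            min_depth=params.get("min_depth", 8),
            max_depth_factor=params.get("max_depth_factor", 2.0),
        )
        mask.to_bed(outdir / "callable_mask.bed")
    report = filtering.direct_filter(
        data.sites,
        min_qual=params.get("min_qual", 20.0),
        max_missingness=params.get("max_missingness", 0.1),
        mask=mask,
    )
    report.to_frame().to_csv(outdir / "filter_report.tsv", sep="\t", index=False)
    state.update(vcf_data=data, filter_report=report)
    return {
        "n_sites": len(data.sites),
        "n_pass": len(report.pass_positions()),
        "n_multiallelic_rejected": data.n_multiallelic_rejected,
    }


def _stage_tree(config, params, outdir, state, manifest):
    if "vcf_data" not in state:
        data = filtering.read_vcf(params["vcf"])
        state["vcf_data"] = data
        state["filter_report"] = filtering.direct_filter(data.sites)
    data = state["vcf_data"]
    report = state["filter_report"]
    passing = set(report.pass_positions())
    biallelic = [s for s in data.sites if s.position in passing and not s.triallelic]
    tri = [s for s in data.sites if s.position in passing and s.triallelic]

    positions = np.array([s.position for s in biallelic], dtype=np.int64)
    calls = np.stack([s.calls for s in biallelic], axis=1)
    matrix = phylogeny.GenotypeMatrix(list(data.samples), positions, calls)
    matrix, anchored, dropped = phylogeny.polarize(
        matrix, outgroup=params.get("outgroup")
    )
    tree, deferred = phylogeny.build_perfect_phylogeny(matrix)

    leftovers = matrix.subset_sites(deferred) if deferred else None
    classification = phylogeny.SiteClassification()
    if leftovers is not None:
        classification = phylogeny.map_incompatible_sites(
            tree, leftovers, polarity_anchored=anchored
        )
    if tri:
        tri_matrix = phylogeny.GenotypeMatrix(
            list(data.samples),
            np.array([s.position for s in tri], dtype=np.int64),
            np.stack([s.calls for s in tri], axis=1),
        )
        tri_class = phylogeny.map_incompatible_sites(
            tree, tri_matrix, polarity_anchored=anchored
        )
        classification.verdicts.update(tri_class.verdicts)
        classification.changes.update(tri_class.changes)

    assignment = tree.branch_assignment()
    cluster_report = filtering.cluster_filter(
        [p for p in assignment if p in passing],
        assignment,
        window_bp=params.get("window_bp", 10),
    )
    (outdir / "tree.nwk").write_text(phylogeny.to_newick(tree) + "\n")
    pd.DataFrame(
        [{"position": p, "node_id": b} for p, b in sorted(assignment.items())]
    ).to_csv(outdir / "branch_assignment.tsv", sep="\t", index=False)
    cluster_report.to_frame().to_csv(
        outdir / "cluster_report.tsv", sep="\t", index=False
    )
    state.update(tree=tree, classification=classification, cluster_report=cluster_report)
    return {
        "n_tips": len(tree.tips()),
        "n_deferred": len(deferred),
        "n_dropped_invariant": len(dropped),
        "n_clusters_flagged": len(cluster_report.clusters),
        "classification": classification.counts(),
    }


def _stage_date(config, params, outdir, state, manifest):
    tree = state.get("tree")
    if tree is None:
        tree = phylogeny.from_newick(Path(params["tree"]).read_text())
    calibration: chronology.RateCalibration | float
    if "calibration_tips" in params:
        calibration = chronology.calibrate_rate(
            tree,
            [(n, float(a)) for n, a in params["calibration_tips"]],
            L_eff=params.get("L_eff", chronology.DEFAULT_L_EFF),
        )
    else:
        calibration = float(
            params.get("years_per_mutation", chronology.DEFAULT_YEARS_PER_MUTATION)
        )
    table = chronology.chronology_table(tree, calibration)
    table.to_csv(outdir / "chronology.tsv", sep="\t", index=False)
    state["chronology"] = table
    info = {"n_nodes": len(table)}
    if isinstance(calibration, chronology.RateCalibration):
        info["mu_hat"] = calibration.mu
        info["years_per_mutation"] = calibration.years_per_mutation
    return info


def _stage_popstats(config, params, outdir, state, manifest):
    path = Path(params["frequency_table"])
    manifest["inputs"][str(path)] = _sha256(path)
    raw = pd.read_csv(path, sep="\t")
    meta_cols = ["population", "macroregion", "linguistic_family", "nomadic", "n"]
    lineage_cols = [c for c in raw.columns if c not in meta_cols]
    table = popstats.FrequencyTable(
        counts=raw.set_index("population")[lineage_cols],
        meta=raw.set_index("population")[meta_cols[1:]],
    )
    collapsed = popstats.collapse_fig5(table, min_total=params.get("min_total", 2))
    collapsed.to_csv(outdir / "collapsed_proportions.tsv", sep="\t")
    results = []
    for a, b in params.get(
        "correlations",
        [
            ("American admixed", "Sub-Saharan Africa"),
            ("Northern Africa", "Sub-Saharan Africa"),
            ("Northern Africa", "American admixed"),
        ],
    ):
        if a in collapsed.index and b in collapsed.index:
            res = popstats.spearman(collapsed.loc[a], collapsed.loc[b])
            results.append(
                {"pair": f"{a} vs {b}", "rho_s": res.statistic, "p": res.p_value}
            )
    pd.DataFrame(results).to_csv(outdir / "correlations.tsv", sep="\t", index=False)
    state["collapsed"] = collapsed
    return {"n_lineages": collapsed.shape[1], "tests": results}


# ---------------------------------------------------------------------------
# Packaged fixtures
# ---------------------------------------------------------------------------


def make_star_tree(branch_mutation_counts: list[int]) -> phylogeny.CladeTree:
    """A single multifurcation: tip i hangs off the root with the given
    number of mutations (positions assigned sequentially)."""
    root = phylogeny.Node(mutations=[])
    pos = 1
    for i, count in enumerate(branch_mutation_counts):
        muts = list(range(pos, pos + count))
        pos += count
        root.add(phylogeny.Node(name=f"T{i:02d}", mutations=muts))
    return phylogeny.CladeTree(root)


def make_table1_fixture(outdir: str | Path | None = None) -> dict[str, Any]:
    """Small trees and rho values reproducing verifiable published rows.

    * ``node34``: 2 tips x 3 mutations -> rho 3.00, SD 1.22, 1.22 kya, SD 0.50
    * ``node253``: 3 tips x 2 mutations -> rho 2.00, SD 0.82, 0.82 kya
    * ``star18``: an 18-tip pure multifurcation (star-like index exactly 1)
    * ``root_rho``: 628.78, converting to 256.54 kya at 408 years/mutation
    """
    fixtures: dict[str, Any] = {
        "node34": make_star_tree([3, 3]),
        "node253": make_star_tree([2, 2, 2]),
        "star18": make_star_tree(list(range(1, 19))),
        "root_rho": 628.78,
        "years_per_mutation": chronology.DEFAULT_YEARS_PER_MUTATION,
    }
    expected = pd.DataFrame(
        [
            {"fixture": "node34", "rho": 3.00, "sd_rho": 1.22, "time_kya": 1.22,
             "sd_time_kya": 0.50},
            {"fixture": "node253", "rho": 2.00, "sd_rho": 0.82, "time_kya": 0.82,
             "sd_time_kya": 0.33},
            {"fixture": "star18", "starlike": 1.0},
            {"fixture": "root_rho", "time_kya": 256.54},
        ]
    )
    fixtures["expected"] = expected
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in ("node34", "node253", "star18"):
            (outdir / f"{name}.nwk").write_text(
                phylogeny.to_newick(fixtures[name]) + "\n"
            )
        expected.to_csv(outdir / "expected.tsv", sep="\t", index=False)
    return fixtures
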