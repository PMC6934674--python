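"""End-to-end analysis pipeline: six association networks, their metrics,
validation, regression, context comparisons and class summaries.

Stages (in order): validate → exclusions → sighting tallies → HWI per
(context × data type) → comprehensive networks + metrics → estimated forest
networks via monthly-matched subsampling → Spearman validation of estimated
vs comprehensive → permutation regression of road presence on forest
proximity covariates → randomization comparisons of road vs estimated
forest metrics → walktrap clustering → age-sex-class summaries.  The run is
a pure function of (inputs, config, seed); a manifest records everything
needed to reproduce it.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .association import (
    DEFAULT_AFFILIATIVE_STATES,
    AssociationMatrix,
    hwi,
    joint_counts,
    road_proportion,
)
from .group_stats import class_metric_differences, neighbour_counts, neighbour_summary, risk_perception_tests
from .metrics import MetricTable, SocialNetwork, build_network, node_metrics
from .regression import PermutationOLS, PermutationOLSResults, build_design
from .resampling import (
    ComparisonResult,
    comparison_table,
    estimated_network,
    metric_differences,
    monthly_matched_subsamples,
    plan_from_road,
    randomization_test,
    spearman_validate,
)
from .scan_data import Roster, apply_exclusions, tally_sightings, validation_report

logger = logging.getLogger("socioscan")

COMPARED_METRICS = ("weighted_degree", "betweenness", "closeness", "eigenvector")


@dataclass
class RunConfig:
    """Tunable pipeline parameters (defaults are the study conditions)."""

    n_subsamples: int = 100
    n_resamples: int = 10_000
    max_iter: int = 5000
    randomization_mode: str = "sign_flip"
    affiliative_states: frozenset = DEFAULT_AFFILIATIVE_STATES
    build_estimated: bool = True
    compare_against: str = "estimated"  # or "comprehensive"
    seed: int = 0

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items()}
        d["affiliative_states"] = sorted(self.affiliative_states)
        return d


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


@dataclass
class ResultBundle:
    """Everything a default run produces."""

    networks: dict[str, SocialNetwork]
    metric_tables: dict[str, MetricTable]
    validation: pd.DataFrame
    regression: PermutationOLSResults
    comparisons: list[ComparisonResult]
    class_differences: pd.DataFrame
    risk_perception: pd.DataFrame
    neighbour_table: pd.DataFrame
    matrices: dict[str, AssociationMatrix]
    manifest: dict

    def bundle_hash(self) -> str:
        """Digest of the bundle's numeric tables (reproducibility check)."""
        h = hashlib.sha256()
        for tag in sorted(self.metric_tables):
            mt = self.metric_tables[tag]
            h.update(mt.table.round(12).to_csv().encode())
            h.update(f"{mt.density:.12f}|{mt.modularity:.12f}".encode())
        h.update(self.regression.to_frame().round(12).to_csv().encode())
        h.update(comparison_table(self.comparisons).round(12).to_csv().encode())
        return h.hexdigest()

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for tag, net in self.networks.items():
            net.write_edgelist(outdir / f"network_{tag}.csv")
            net.write_graphml(outdir / f"network_{tag}.graphml")
        for tag, mt in self.metric_tables.items():
            mt.write_csv(outdir / f"metrics_{tag}.csv")
        for tag, m in self.matrices.items():
            m.write_csv(outdir / f"hwi_{tag}.csv")
        self.validation.to_csv(outdir / "spearman_validation.csv", index=False)
        self.regression.write_csv(outdir / "regression.csv")
        comparison_table(self.comparisons).to_csv(outdir / "comparisons.csv", index=False)
        self.class_differences.to_csv(outdir / "class_differences.csv", index=False)
        self.risk_perception.to_csv(outdir / "risk_perception.csv", index=False)
        self.neighbour_table.to_csv(outdir / "neighbour_counts.csv", index=False)
        manifest = dict(self.manifest)
        manifest["bundle_hash"] = self.bundle_hash()
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as e:  # noqa: BLE001 - stage name is the contract
                raise PipelineError(name, e) from e
            logger.info("stage %s: %.2fs", name, time.perf_counter() - t0)
            return out
        return wrapper
    return deco


def run_pipeline(
    scans: pd.DataFrame,
    interactions: pd.DataFrame,
    roster: Roster,
    config: RunConfig | None = None,
) -> ResultBundle:
    """Run the full analysis on validated records; see module docstring."""
    config = config or RunConfig()

    scans, interactions, analysis = _stage("exclusions")(apply_exclusions)(scans, interactions, roster)
    report = validation_report(scans, interactions, analysis)

    @_stage("association")
    def _associations():
        sightings = {c: tally_sightings(scans, c, analysis) for c in ("road", "forest")}
        mats: dict[str, AssociationMatrix] = {}
        for ctx in ("road", "forest"):
            prox = joint_counts(scans, ctx, "proximity", analysis)
            mats[f"{ctx}_proximity"] = hwi(prox, sightings[ctx])
            aff = joint_counts(
                interactions, ctx, "affiliative", analysis,
                scans=scans, affiliative_states=config.affiliative_states,
            )
            mats[f"{ctx}_affiliative"] = hwi(aff, sightings[ctx])
        return mats

    matrices = _associations()

    if config.build_estimated:
        @_stage("estimated_network")
        def _estimated():
            plan = plan_from_road(scans, n_samples=config.n_subsamples, seed=config.seed)
            samples = monthly_matched_subsamples(scans, plan)
            est = {}
            est["estimated_forest_proximity"] = estimated_network(samples, scans, analysis, "proximity")
            est["estimated_forest_affiliative"] = estimated_network(
                samples, scans, analysis, "affiliative",
                interactions=interactions, affiliative_states=config.affiliative_states,
            )
            return est

        matrices.update(_estimated())
    else:
        logger.warning("estimated networks disabled; context comparisons will be skipped")

    @_stage("networks")
    def _networks():
        nets = {tag: build_network(m) for tag, m in matrices.items()}
        tables = {tag: node_metrics(net) for tag, net in nets.items()}
        return nets, tables

    networks, metric_tables = _networks()

    @_stage("spearman_validation")
    def _validate():
        rows = []
        if config.build_estimated:
            for dt in ("proximity", "affiliative"):
                comp = metric_tables[f"forest_{dt}"]
                est = metric_tables[f"estimated_forest_{dt}"]
                for metric in COMPARED_METRICS:
                    rho, p = spearman_validate(comp, est, metric)
                    rows.append({"data_type": dt, "metric": metric, "rho": rho, "p_value": p})
        return pd.DataFrame(rows)

    validation = _validate()

    @_stage("regression")
    def _regression():
        props = road_proportion(scans, analysis, percent=True)
        design = build_design(analysis, metric_tables["forest_proximity"], matrices["forest_proximity"], props)
        model = PermutationOLS.from_dataframe(design)
        return design, model.fit(max_iter=config.max_iter, seed=config.seed)

    design, regression = _regression()

    @_stage("comparisons")
    def _comparisons():
        results = []
        if not config.build_estimated and config.compare_against == "estimated":
            return results
        for dt in ("proximity", "affiliative"):
            road_mt = metric_tables[f"road_{dt}"]
            forest_tag = f"estimated_forest_{dt}" if config.compare_against == "estimated" else f"forest_{dt}"
            forest_mt = metric_tables[forest_tag]
            for metric in COMPARED_METRICS:
                diffs = metric_differences(road_mt, forest_mt, metric)
                results.append(
                    randomization_test(
                        diffs,
                        n_resamples=config.n_resamples,
                        mode=config.randomization_mode,
                        seed=config.seed,
                        metric=metric,
                        data_type=dt,
                    )
                )
        return results

    comparisons = _comparisons()

    @_stage("class_summaries")
    def _class_summaries():
        samples = neighbour_counts(scans, analysis)
        risk = risk_perception_tests(samples)
        ntable = neighbour_summary(samples)
        if config.build_estimated:
            cdiff = class_metric_differences(
                metric_tables["road_proximity"], metric_tables["estimated_forest_proximity"], analysis
            )
            cdiff.insert(0, "data_type", "proximity")
            cdiff_a = class_metric_differences(
                metric_tables["road_affiliative"], metric_tables["estimated_forest_affiliative"], analysis
            )
            cdiff_a.insert(0, "data_type", "affiliative")
            cdiff = pd.concat([cdiff, cdiff_a], ignore_index=True)
        else:
            cdiff = pd.DataFrame()
        return risk, ntable, cdiff

    risk, ntable, cdiff = _class_summaries()

    manifest = {
        "socioscan_version": __version__,
        "config": config.to_dict(),
        "seed": config.seed,
        "data": report,
        "n_analysis_individuals": len(analysis),
        "n_networks": len(networks),
    }
    return ResultBundle(
        networks=networks,
        metric_tables=metric_tables,
        validation=validation,
        regression=regression,
        comparisons=comparisons,
        class_differences=cdiff,
        risk_perception=risk,
        neighbour_table=ntable,
        matrices=matrices,
        manifest=manifest,
    )
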