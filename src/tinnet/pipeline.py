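"""End-to-end orchestration: score -> correlate -> estimate -> centrality ->
predictability -> stability -> flow -> export.

`run_pipeline` executes every stage in order on one response table, writes
each module's exports into the output directory, and finishes with a
machine-readable run manifest (seed, config hash, stage status and timings).
A stage failure is recorded with a FAILED marker while earlier stages'
outputs stay intact, and the first hard error is re-raised at the end.
All randomness flows from the single seed in the config, so a rerun with an
identical config produces byte-identical numerical outputs (the manifest's
timings are the only nondeterministic bytes).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import __version__
from .association import (
    nearest_positive_semidefinite,
    spearman_matrix,
    write_correlation_csv,
)
from .centrality import centrality_profile, flow_network
from .instruments import (
    GAD7,
    PHQ9,
    Instrument,
    ItemResponseMatrix,
    cronbach_alpha,
    severity_band,
    severity_tally,
    total_score,
    validate_responses,
)
from .network import estimate_network
from .predictability import node_predictability
from .stability import (
    DEFAULT_DROP_PROPORTIONS,
    BootConfig,
    bootstrap_edges,
    cs_coefficient,
    difference_tests,
    metric_replicates,
    metric_replicates_bridge,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineStageError", "run_pipeline", "layout_network"]


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


@dataclass
class RunConfig:
    """Settings of one pipeline run; defaults follow the standard workflow
    (EBIC gamma 0.5, 2000 bootstraps, alpha 0.05, 80th-percentile bridges)."""

    gamma: float = 0.5
    n_lambdas: int = 100
    lambda_min_ratio: float = 0.01
    bridge_percentile: float = 80.0
    focal: str | None = "D9"
    nboots: int = 2000
    alpha: float = 0.05
    drop_proportions: tuple[float, ...] = DEFAULT_DROP_PROPORTIONS
    cs_threshold: float = 0.7
    cs_confidence: float = 0.95
    seed: int = 0
    run_stability: bool = True
    n_jobs: int = 1
    subject_id_column: str | None = "subject"

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()

    def boot_config(self) -> BootConfig:
        return BootConfig(
            nboots=self.nboots,
            seed=self.seed,
            gamma=self.gamma,
            n_lambdas=self.n_lambdas,
            lambda_min_ratio=self.lambda_min_ratio,
            alpha=self.alpha,
            drop_proportions=tuple(self.drop_proportions),
            cs_threshold=self.cs_threshold,
            cs_confidence=self.cs_confidence,
            n_jobs=self.n_jobs,
        )


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=float) + "\n")


def layout_network(net, seed: int = 0) -> pd.DataFrame:
    """Force-directed (Fruchterman-Reingold) 2-D coordinates.

    Attraction uses |weight|, so strongly correlated symptoms sit close
    together; coordinates are deterministic under the seed and purely
    presentational.  A single node lands at the origin.
    """
    G = net.to_graph()
    if G.number_of_nodes() == 1:
        return pd.DataFrame({"x": [0.0], "y": [0.0]}, index=list(G.nodes))
    pos = nx.spring_layout(G, weight="absweight", seed=seed)
    return pd.DataFrame(
        {"x": [pos[n][0] for n in net.labels], "y": [pos[n][1] for n in net.labels]},
        index=net.labels,
    )


def run_pipeline(
    raw_table: pd.DataFrame,
    out_dir: str | Path,
    config: RunConfig | None = None,
    instruments: tuple[Instrument, ...] = (PHQ9, GAD7),
) -> dict:
    """Run every analysis stage on one raw response table.

    Returns a bundle dict with the in-memory results and writes all exports
    under ``out_dir``.  Raises :class:`PipelineStageError` for the first
    stage that failed (after writing the manifest and a FAILED marker).
    """
    config = config or RunConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"config": config}
    stages: list[dict] = []
    first_error: PipelineStageError | None = None

    def run_stage(name: str, fn, *deps_ok: bool) -> bool:
        nonlocal first_error
        if not all(deps_ok):
            stages.append({"stage": name, "status": "SKIPPED", "seconds": 0.0})
            return False
        t0 = time.perf_counter()
        try:
            fn()
        except Exception as exc:  # noqa: BLE001 - reported per stage
            stages.append(
                {
                    "stage": name,
                    "status": "FAILED",
                    "seconds": round(time.perf_counter() - t0, 3),
                    "error": str(exc),
                }
            )
            (out / f"{name}.FAILED").write_text(str(exc) + "\n")
            if first_error is None:
                first_error = PipelineStageError(name, exc)
            logger.error("stage %s failed: %s", name, exc)
            return False
        stages.append(
            {
                "stage": name,
                "status": "OK",
                "seconds": round(time.perf_counter() - t0, 3),
            }
        )
        return True

    # --- score ---------------------------------------------------------
    def stage_score() -> None:
        responses, report = validate_responses(
            raw_table, instruments, subject_id_column=config.subject_id_column
        )
        bundle["responses"] = responses
        bundle["validation"] = report
        scored = pd.DataFrame(index=responses.subjects)
        alphas = {}
        tallies = {}
        for ins in instruments:
            totals = total_score(responses, ins)
            scored[f"{ins.name}_total"] = totals
            scored[f"{ins.name}_band"] = [
                severity_band(int(s), ins) for s in totals
            ]
            alphas[ins.name] = cronbach_alpha(responses, ins)
            tallies[ins.name] = severity_tally(responses, ins)
        bundle["scored"] = scored
        bundle["cronbach_alpha"] = alphas
        bundle["severity_tallies"] = tallies
        scored.to_csv(out / "scored.csv", index_label="subject")
        with (out / "validation.jsonl").open("w") as fh:
            fh.write(
                json.dumps(
                    {"n_input": report.n_input, "n_kept": report.n_kept,
                     "n_rejected": report.n_rejected}, sort_keys=True
                ) + "\n"
            )
            for rec in report.to_records():
                fh.write(json.dumps(rec, sort_keys=True) + "\n")
        pd.concat(
            [t.to_frame().assign(instrument=k) for k, t in tallies.items()]
        ).to_csv(out / "severity_tally.csv", index=False)

    ok_score = run_stage("score", stage_score)

    # --- correlate ------------------------------------------------------
    def stage_correlate() -> None:
        corr = nearest_positive_semidefinite(spearman_matrix(bundle["responses"]))
        bundle["correlations"] = corr
        write_correlation_csv(corr, out / "correlations.csv")

    ok_corr = run_stage("correlate", stage_correlate, ok_score)

    # --- estimate -------------------------------------------------------
    def stage_estimate() -> None:
        net, path = estimate_network(
            bundle["correlations"],
            communities=bundle["responses"].communities,
            gamma=config.gamma,
            n_lambdas=config.n_lambdas,
            lambda_min_ratio=config.lambda_min_ratio,
        )
        bundle["network"] = net
        bundle["penalty_path"] = path
        net.edge_list().to_csv(out / "edges.csv", index=False)
        nx.write_graphml(net.to_graph(), out / "network.graphml")
        _write_json(
            out / "network.json",
            {
                "labels": net.labels,
                "lambda_selected": net.lambda_selected,
                "ebic_gamma": net.ebic_gamma,
                "n": net.n,
                "n_possible_edges": net.n_possible_edges,
                "n_edges": net.n_edges,
                "density": net.density,
                "path": json.loads(path.to_json()),
            },
        )
        layout_network(net, seed=config.seed).to_csv(
            out / "layout.csv", index_label="node"
        )

    ok_net = run_stage("estimate", stage_estimate, ok_corr)

    # --- centrality + predictability -----------------------------------
    def stage_centrality() -> None:
        profile = centrality_profile(
            bundle["network"], percentile=config.bridge_percentile
        )
        pred = node_predictability(bundle["responses"], bundle["network"])
        table = profile.table.copy()
        table["predictability"] = pred.r2
        bundle["centrality"] = profile
        bundle["predictability"] = pred
        table.to_csv(out / "centrality.csv", index_label="node")

    ok_cent = run_stage("centrality", stage_centrality, ok_net)

    # --- stability ------------------------------------------------------
    def stage_stability() -> None:
        bc = config.boot_config()
        responses = bundle["responses"]
        net = bundle["network"]
        edge_report = bootstrap_edges(responses, bc, net=net)
        bundle["edge_cis"] = edge_report
        edge_report.to_frame().to_csv(out / "edge_cis.csv", index=False)

        edge_diff = difference_tests(
            edge_report.replicates,
            edge_report.point,
            [f"{a}--{b}" for a, b in edge_report.pairs],
            alpha=config.alpha,
        )
        ei_reps = metric_replicates(edge_report, net.labels, "expected_influence")
        ei_diff = difference_tests(
            ei_reps, net.W.sum(axis=1), net.labels, alpha=config.alpha
        )
        bei_reps = metric_replicates_bridge(
            edge_report, net.labels, net.communities
        )
        bei_point = bei_reps.mean(axis=0)
        bei_diff = difference_tests(
            bei_reps, bei_point, net.labels, alpha=config.alpha
        )
        bundle["difference_tests"] = {
            "edges": edge_diff, "expected_influence": ei_diff,
            "bridge_expected_influence": bei_diff,
        }
        ei_diff.to_frame().to_csv(out / "diff_expected_influence.csv")
        bei_diff.to_frame().to_csv(out / "diff_bridge_expected_influence.csv")

        cs_ei = cs_coefficient(responses, "expected_influence", bc, net=net)
        cs_bei = cs_coefficient(
            responses, "bridge_expected_influence", bc, net=net
        )
        bundle["cs"] = {"expected_influence": cs_ei,
                        "bridge_expected_influence": cs_bei}
        cs_ei.to_frame().to_csv(out / "cs_expected_influence.csv", index=False)
        cs_bei.to_frame().to_csv(
            out / "cs_bridge_expected_influence.csv", index=False
        )
        _write_json(
            out / "stability_summary.json",
            {
                "nboots": bc.nboots,
                "edge_boot_failures": edge_report.n_failed,
                "cs_expected_influence": cs_ei.cs,
                "cs_bridge_expected_influence": cs_bei.cs,
                "edge_diff_significant_pairs": edge_diff.n_significant_pairs,
                "ei_diff_significant_pairs": ei_diff.n_significant_pairs,
                "bei_diff_significant_pairs": bei_diff.n_significant_pairs,
            },
        )

    ok_stab = True
    if config.run_stability:
        ok_stab = run_stage("stability", stage_stability, ok_cent)

    # --- flow -----------------------------------------------------------
    def stage_flow() -> None:
        flow = flow_network(bundle["network"], config.focal)
        bundle["flow"] = flow
        _write_json(out / "flow.json", flow.to_dict())

    if config.focal is not None:
        run_stage("flow", stage_flow, ok_net)

    # --- manifest -------------------------------------------------------
    manifest = {
        "tinnet_version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "stages": stages,
    }
    _write_json(out / "manifest.json", manifest)
    bundle["manifest"] = manifest

    if first_error is not None:
        raise first_error
    return bundle
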