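"""End-to-end stratified network analysis.

``run_analysis`` drives the full procedure — load or simulate a cohort,
split it into MHO/MUO strata by HOMA-IR, estimate each stratum's
partial-correlation network, compute all node-level and global graph
statistics, and write every artifact (matrices, edge lists, metric
tables, GEXF/GraphML graphs) plus a run manifest into an output
directory.  The manifest records the resolved configuration and seeds,
so a run can be reproduced bit-identically from it.

``compare_strata`` reads a manifest back and produces the side-by-side
stratum comparison (global metrics, centrality ranks, communities and
the per-stratum bridge node).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .community import WEIGHTS_MODES, louvain_communities
from .errors import ConfigurationError, EstimationError, MetabonetError
from .export import write_gexf, write_graphml
from .graph import global_metrics, metrics_table, rank_centrality
from .io import read_cohort_csv, validate_cohort, write_cohort_csv
from .network import SELECTION_MODES, PartialCorrelationNetwork
from .schema import DIMENSIONS
from .simulate import SyntheticCohortParams, generate_cohort
from .stratify import MHO, MUO, stratify_cohort

logger = logging.getLogger(__name__)

#: Centrality metrics summarised in the manifest and comparison report.
RANKED_METRICS = ("eigenvector", "betweenness", "closeness")

#: Minimum stratum size for estimation (13 nodes + 2).
MIN_STRATUM_N = 15


@dataclass
class SyntheticInput:
    seed: int = 1
    n_mho: int = 132
    n_muo: int = 56
    scenario_mho: str = "mho_like"
    scenario_muo: str = "muo_like"


@dataclass
class RunConfig:
    """Fully serialisable configuration of one analysis run."""

    input_csv: str | None = None
    synthetic: SyntheticInput | None = None
    glucose_units: str = "mg/dL"
    use_precomputed_homa: bool = False
    selection_mode: str = "pvalue"
    threshold: float = 0.25
    ridge_lambda: float = 0.0
    louvain_seed: int = 0
    louvain_weights_mode: str = "absolute"
    output_dir: str = "metabonet-run"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.input_csv is None) == (self.synthetic is None):
            raise ConfigurationError(
                "input: provide exactly one of input.csv or input.synthetic"
            )
        if self.selection_mode not in SELECTION_MODES:
            raise ConfigurationError(
                f"selection.mode: {self.selection_mode!r} not in {SELECTION_MODES}"
            )
        if not 0.0 < self.threshold < 1.0:
            raise ConfigurationError(
                f"selection.threshold: must be in (0, 1), got {self.threshold}"
            )
        if self.ridge_lambda < 0:
            raise ConfigurationError(
                f"estimation.ridge_lambda: must be >= 0, got {self.ridge_lambda}"
            )
        if self.louvain_weights_mode not in WEIGHTS_MODES:
            raise ConfigurationError(
                f"louvain.weights_mode: {self.louvain_weights_mode!r} not in {WEIGHTS_MODES}"
            )
        if self.log_level.upper() not in ("DEBUG", "INFO", "WARNING", "ERROR"):
            raise ConfigurationError(f"log_level: unknown level {self.log_level!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        try:
            inp = raw.get("input", {}) or {}
            synthetic = None
            if "synthetic" in inp and inp["synthetic"] is not None:
                synthetic = SyntheticInput(**inp["synthetic"])
            selection = raw.get("selection", {}) or {}
            estimation = raw.get("estimation", {}) or {}
            louvain = raw.get("louvain", {}) or {}
            return cls(
                input_csv=inp.get("csv"),
                synthetic=synthetic,
                glucose_units=raw.get("glucose_units", "mg/dL"),
                use_precomputed_homa=bool(raw.get("use_precomputed_homa", False)),
                selection_mode=selection.get("mode", "pvalue"),
                threshold=float(selection.get("threshold", 0.25)),
                ridge_lambda=float(estimation.get("ridge_lambda", 0.0)),
                louvain_seed=int(louvain.get("seed", 0)),
                louvain_weights_mode=louvain.get("weights_mode", "absolute"),
                output_dir=raw.get("output_dir", "metabonet-run"),
                log_level=raw.get("log_level", "INFO"),
            )
        except (TypeError, ValueError) as exc:
            raise ConfigurationError(f"invalid run configuration: {exc}") from exc

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text(encoding="utf-8")
        raw = yaml.safe_load(text)  # YAML superset also parses JSON
        if not isinstance(raw, dict):
            raise ConfigurationError(f"{path}: config must be a mapping")
        return cls.from_dict(raw)


def _now() -> str:
    return datetime.now(timezone.utc).isoformat()


def _resolve_cohort(config: RunConfig, run_dir: Path):
    if config.input_csv is not None:
        table = read_cohort_csv(config.input_csv, glucose_units=config.glucose_units)
        return table, None
    syn = config.synthetic
    params = SyntheticCohortParams(
        n_mho=syn.n_mho, n_muo=syn.n_muo, seed=syn.seed,
        scenario={MHO: syn.scenario_mho, MUO: syn.scenario_muo},
        glucose_units=config.glucose_units,
    )
    table, truth = generate_cohort(params)
    write_cohort_csv(table, run_dir / "cohort.csv")
    truth.write(run_dir / "ground_truth.json")
    return table, truth


def _analyze_stratum(table, config: RunConfig, stratum_dir: Path) -> dict:
    est = PartialCorrelationNetwork(
        selection_mode=config.selection_mode,
        threshold=config.threshold,
        ridge_lambda=config.ridge_lambda,
    )
    est.fit(table)
    logger.debug("full Rp matrix:\n%s", est.partial_corr_)
    graph = est.graph_
    nodes = est.nodes_

    pd.DataFrame(est.partial_corr_, index=nodes, columns=nodes).to_csv(
        stratum_dir / "rp_matrix.csv")
    est.edges_.to_csv(stratum_dir / "edges.csv", index=False)

    if graph.m == 0:
        logger.warning("no edges selected in %s; graph metrics skipped", stratum_dir.name)
        return {
            "n": est.n_samples_, "edge_count": 0, "note": "no edges selected",
            "files": {"rp_matrix": "rp_matrix.csv", "edges": "edges.csv"},
        }

    partition = louvain_communities(
        graph, weights_mode=config.louvain_weights_mode, seed=config.louvain_seed)
    table_df = metrics_table(graph, partition)
    table_df.to_csv(stratum_dir / "metrics.csv", index=False)
    gm = global_metrics(graph)
    with open(stratum_dir / "global_metrics.json", "w", encoding="utf-8") as fh:
        json.dump(gm.to_dict(), fh, indent=2)

    ranks = pd.DataFrame({
        metric: rank_centrality(table_df, metric) for metric in RANKED_METRICS
    })
    ranks.index.name = "rank"
    ranks.to_csv(stratum_dir / "centrality_ranks.csv")

    node_attrs = {}
    for row in table_df.itertuples():
        node_attrs[row.node] = {
            "dimension": DIMENSIONS.get(row.node, "unknown"),
            "community": int(row.modularity_class),
            "closeness": float(row.closeness),
            "harmonic_closeness": float(row.harmonic_closeness),
            "betweenness": float(row.betweenness),
            "authority": float(row.authority),
            "hub": float(row.hub),
            "clustering_coefficient": float(row.clustering_coefficient),
            "triangles": int(row.triangles),
            "eigenvector": float(row.eigenvector),
        }
    write_gexf(graph, stratum_dir / "network.gexf", node_attrs)
    write_graphml(graph, stratum_dir / "network.graphml", node_attrs)

    return {
        "n": est.n_samples_,
        "edge_count": graph.m,
        "global_metrics": gm.to_dict(),
        "modularity_q": partition.modularity_q,
        "n_communities": partition.n_communities,
        "top3": {m: rank_centrality(table_df, m)[:3] for m in RANKED_METRICS},
        "files": {
            "rp_matrix": "rp_matrix.csv", "edges": "edges.csv",
            "metrics": "metrics.csv", "global_metrics": "global_metrics.json",
            "centrality_ranks": "centrality_ranks.csv",
            "gexf": "network.gexf", "graphml": "network.graphml",
        },
    }


def run_analysis(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the manifest (also written last
    to ``<output_dir>/manifest.json``)."""
    logging.getLogger("metabonet").setLevel(config.log_level.upper())
    started = _now()
    run_dir = Path(config.output_dir)
    run_dir.mkdir(parents=True, exist_ok=True)

    cohort, _ = _resolve_cohort(config, run_dir)
    report = validate_cohort(cohort)
    if not report.ok:
        logger.warning("cohort validation: %s", report.summary())
    strat = stratify_cohort(cohort, use_precomputed=config.use_precomputed_homa)
    with open(run_dir / "stratification.json", "w", encoding="utf-8") as fh:
        json.dump({
            "source_n": strat.source_n, "n_mho": len(strat.mho), "n_muo": len(strat.muo),
            "n_boundary": strat.n_boundary, "n_homa_discrepant": strat.n_discrepant,
        }, fh, indent=2)

    manifest: dict = {
        "tool": "metabonet",
        "version": __version__,
        "config": config.to_dict(),
        "validation_findings": len(report.findings),
        "stratification": {
            "source_n": strat.source_n, "n_mho": len(strat.mho), "n_muo": len(strat.muo),
            "n_boundary": strat.n_boundary, "n_homa_discrepant": strat.n_discrepant,
        },
        "strata": {},
    }
    for name, table in ((MHO, strat.mho), (MUO, strat.muo)):
        if len(table) < MIN_STRATUM_N:
            manifest["strata"][name] = {
                "n": len(table),
                "note": f"skipped: stratum too small for estimation (n < {MIN_STRATUM_N})",
            }
            logger.warning("stratum %s skipped (n=%d)", name, len(table))
            continue
        stratum_dir = run_dir / name.lower()
        stratum_dir.mkdir(exist_ok=True)
        try:
            manifest["strata"][name] = _analyze_stratum(table, config, stratum_dir)
        except MetabonetError as exc:
            raise EstimationError(f"estimation failed in stratum {name}: {exc}") from exc
    manifest["timestamps"] = {"started": started, "finished": _now()}
    with open(run_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def compare_strata(manifest_path) -> dict:
    """Side-by-side MHO/MUO comparison from a finished run.

    Reports global-metric differences (MUO minus MHO), per-node
    centrality ranks and community labels, and each stratum's bridge
    node (highest betweenness).
    """
    manifest_path = Path(manifest_path)
    if manifest_path.is_dir():
        manifest_path = manifest_path / "manifest.json"
    with open(manifest_path, encoding="utf-8") as fh:
        manifest = json.load(fh)
    run_dir = manifest_path.parent
    strata = manifest.get("strata", {})
    analyzed = {s: v for s, v in strata.items() if "global_metrics" in v}
    if len(analyzed) < 2:
        raise MetabonetError(
            "comparison unavailable: need two analyzed strata, got "
            f"{sorted(analyzed) or 'none'}"
        )

    report: dict = {"run": str(run_dir), "global_metrics": {}, "bridge_nodes": {},
                    "ranks": {}, "communities": {}}
    for key in ("edge_count", "density", "diameter", "average_path_length",
                "average_clustering"):
        mho_v = analyzed[MHO]["global_metrics"][key]
        muo_v = analyzed[MUO]["global_metrics"][key]
        report["global_metrics"][key] = {
            MHO: mho_v, MUO: muo_v, "difference_muo_minus_mho": muo_v - mho_v,
        }
    for stratum in (MHO, MUO):
        metrics = pd.read_csv(run_dir / stratum.lower() / strata[stratum]["files"]["metrics"])
        report["bridge_nodes"][stratum] = rank_centrality(metrics, "betweenness")[0]
        report["ranks"][stratum] = {
            m: rank_centrality(metrics, m) for m in RANKED_METRICS
        }
        report["communities"][stratum] = dict(
            zip(metrics["node"], metrics["modularity_class"].astype(int).tolist())
        )
    report["bridge_nodes"]["differ"] = (
        report["bridge_nodes"][MHO] != report["bridge_nodes"][MUO]
    )
    return report
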