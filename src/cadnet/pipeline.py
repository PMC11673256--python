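"""End-to-end orchestration: cohort → normalization → statistics → networks
→ metrics → sensitivity, with a hashed artifact manifest for auditability.

Every artifact is written deterministically (no timestamps) so that two
runs with the same config and seed produce hash-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import netmetrics, network, records, sensitivity, simulate, stats
from .records import Category, Cohort
from .network import CooccurrenceNetwork

__all__ = ["PipelineConfig", "run_pipeline", "degree_tables", "cooccurrence_pairs"]

logger = logging.getLogger("cadnet.pipeline")


@dataclass(frozen=True)
class PipelineConfig:
    output_dir: str
    input_path: str | None = None  # existing cohort file; else simulate
    input_format: str | None = None
    cohort_config: simulate.CohortConfig | None = None
    term_map_path: str | None = None
    strict_map: bool = False
    ci_level: float = 0.95
    top_k: int = 20
    pair_cutoff: int = 10  # co-occurrence pair-table weight cutoff
    min_partners: int = 10  # degree-table partner cutoff
    thresholds: tuple[int, ...] = sensitivity.DEFAULT_THRESHOLDS
    modes: tuple[str, ...] = ("diagnosis", "comorbidity", "bipartite")
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must lie in (0,1)")
        if self.input_path is None and self.cohort_config is None:
            raise ValueError("either input_path or cohort_config is required")

    def snapshot(self) -> dict:
        d = {
            "input_path": self.input_path,
            "term_map_path": self.term_map_path,
            "strict_map": self.strict_map,
            "ci_level": self.ci_level,
            "top_k": self.top_k,
            "pair_cutoff": self.pair_cutoff,
            "min_partners": self.min_partners,
            "thresholds": list(self.thresholds),
            "modes": list(self.modes),
            "seed": self.seed,
        }
        if self.cohort_config is not None:
            d["cohort_config"] = self.cohort_config.to_dict()
        return d


def cooccurrence_pairs(bipartite: CooccurrenceNetwork, cutoff: int = 10) -> pd.DataFrame:
    """Diagnosis–comorbidity pairs with weight >= cutoff, descending.

    The analogue of the published high-frequency pair table; ties order
    alphabetically by (diagnosis, comorbidity).
    """
    if bipartite.mode != "bipartite":
        raise ValueError("pair table requires a bipartite network")
    g = bipartite.graph
    rows = []
    for u, v, d in g.edges(data=True):
        if d["weight"] < cutoff:
            continue
        dia, com = (u, v) if g.nodes[u]["category"] == "diagnosis" else (v, u)
        rows.append({
            "diagnosis": bipartite.term_of(dia),
            "comorbidity": bipartite.term_of(com),
            "weight": d["weight"],
        })
    rows.sort(key=lambda r: (-r["weight"], r["diagnosis"], r["comorbidity"]))
    return pd.DataFrame(rows, columns=["diagnosis", "comorbidity", "weight"])


def degree_tables(
    bipartite: CooccurrenceNetwork, min_partners: int = 10
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Distinct cross-category partner counts per node, filtered and ranked.

    Returns (diagnosis table, comorbidity table): for each diagnosis the
    number of distinct comorbidities it co-occurs with (its unweighted
    bipartite degree), kept when >= min_partners, descending; and the
    symmetric comorbidity table.
    """
    if bipartite.mode != "bipartite":
        raise ValueError("degree tables require a bipartite network")
    g = bipartite.graph
    out = {}
    for cat in ("diagnosis", "comorbidity"):
        rows = [
            {"term": bipartite.term_of(n), "n_partners": g.degree(n)}
            for n, d in g.nodes(data=True)
            if d["category"] == cat and g.degree(n) >= min_partners
        ]
        rows.sort(key=lambda r: (-r["n_partners"], r["term"]))
        out[cat] = pd.DataFrame(rows, columns=["term", "n_partners"])
    return out["diagnosis"], out["comorbidity"]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the artifact manifest (also written to
    ``manifest.json``). Any stage failure aborts with the stage name."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []
    stage = "load"

    def emit_df(df: pd.DataFrame, name: str) -> None:
        p = out / name
        df.to_csv(p, index=False)
        artifacts.append(p)

    try:
        if config.input_path is not None:
            cohort = records.load_cohort(config.input_path, config.input_format)
        else:
            stage = "simulate"
            cohort = simulate.generate_cohort(config.cohort_config)
        logger.info("%s: %d records", stage, len(cohort))

        stage = "normalize"
        raw_cohort = cohort
        if config.term_map_path is not None:
            term_map = records.load_term_map(config.term_map_path)
            cohort = records.apply_term_map(cohort, term_map, strict=config.strict_map)
        records.write_cohort(cohort, out / "cohort.jsonl")
        artifacts.append(out / "cohort.jsonl")
        summary = records.vocab_summary(raw_cohort, cohort)
        (out / "vocab_summary.json").write_text(json.dumps(summary, indent=2))
        artifacts.append(out / "vocab_summary.json")

        stage = "statistics"
        for cat in (Category.DIAGNOSIS, Category.COMORBIDITY):
            emit_df(
                stats.sex_association_table(cohort, cat, top_k=config.top_k),
                f"table_top_{cat.value}.csv",
            )
            for strat in ("age_bin", "sex", "admission_year"):
                table = stats.stratified_top_k(cohort, strat, cat, k=5)
                emit_df(table.to_frame(), f"table_top5_{cat.value}_by_{strat}.csv")

        stage = "networks"
        nets: dict[str, CooccurrenceNetwork] = {}
        for mode in config.modes:
            net = (
                network.build_bipartite(cohort)
                if mode == "bipartite"
                else network.build_monopartite(cohort, mode)
            )
            nets[mode] = net
            network.write_edge_list(net, out / f"network_{mode}_edges.csv")
            network.write_node_list(net, out / f"network_{mode}_nodes.csv")
            network.write_graphml(net, out / f"network_{mode}.graphml")
            artifacts += [
                out / f"network_{mode}_edges.csv",
                out / f"network_{mode}_nodes.csv",
                out / f"network_{mode}.graphml",
            ]
            logger.info("network %s: %d nodes, %d edges", mode, net.n_nodes, net.n_edges)

        if "bipartite" in nets:
            emit_df(
                cooccurrence_pairs(nets["bipartite"], config.pair_cutoff),
                "table_pairs.csv",
            )
            dia_t, com_t = degree_tables(nets["bipartite"], config.min_partners)
            emit_df(dia_t, "table_diagnosis_partners.csv")
            emit_df(com_t, "table_comorbidity_partners.csv")

        stage = "metrics"
        reports = {}
        for mode, net in nets.items():
            report = netmetrics.network_report(net, seed=config.seed)
            reports[mode] = report.to_dict()
        (out / "network_metrics.json").write_text(json.dumps(reports, indent=2))
        artifacts.append(out / "network_metrics.json")

        stage = "sensitivity"
        hub_stability = {}
        for mode, net in nets.items():
            sweep = sensitivity.threshold_sweep(net, config.thresholds, seed=config.seed)
            emit_df(sensitivity.sweep_to_table(sweep), f"sensitivity_{mode}.csv")
            hub_stability[mode] = sweep.hub_stable
        (out / "hub_stability.json").write_text(json.dumps(hub_stability, indent=2))
        artifacts.append(out / "hub_stability.json")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    manifest = {
        "config": config.snapshot(),
        "seed": config.seed,
        "n_records": len(cohort),
        "artifacts": {p.name: _sha256(p) for p in sorted(artifacts)},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
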