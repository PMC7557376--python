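"""One-command orchestration: build -> LCC -> cluster -> layout -> centralities
-> power-law fits -> labels -> hints, with a machine-readable run report.
"""

from __future__ import annotations

import configparser
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx

from ddsn import build, centrality, community, io, layout, powerlaw, prioritize

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    interactions: str
    annotations: str | None = None
    outdir: str = "ddsn_out"
    method: str = "recursive_bisection"
    betweenness_mode: str = "pairs"
    t: int = 5
    layout_a: float = 1.0
    layout_r: float = 0.0
    layout_iterations: int = 1000
    seed: int = 42
    keep_full_graph: bool = False  # skip the LCC restriction

    @classmethod
    def from_ini(cls, path: str | Path, **overrides) -> "RunConfig":
        parser = configparser.ConfigParser()
        read = parser.read(path)
        if not read:
            raise FileNotFoundError(path)
        section = parser["ddsn"] if parser.has_section("ddsn") else parser["DEFAULT"]
        kwargs: dict = {}
        for f, caster in [
            ("interactions", str), ("annotations", str), ("outdir", str),
            ("method", str), ("betweenness_mode", str), ("t", int),
            ("layout_a", float), ("layout_r", float),
            ("layout_iterations", int), ("seed", int),
        ]:
            if f in section:
                kwargs[f] = caster(section[f])
        if "keep_full_graph" in section:
            kwargs["keep_full_graph"] = section.getboolean("keep_full_graph")
        kwargs.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**kwargs)


def _stage(name: str):
    logger.info("stage: %s", name)
    return time.perf_counter()


def run_pipeline(config: RunConfig) -> dict:
    """Run the full method and write all artifacts under ``config.outdir``.

    Writes ddsn.gexf, partition.csv, coords.csv, centrality.csv, fit.json,
    hints.json, and report.json; returns the report dict.  Idempotent for a
    fixed config and seed.
    """
    if not Path(config.interactions).exists():
        raise FileNotFoundError(f"interactions table not found: {config.interactions}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    t0 = _stage("build")
    table = io.read_interaction_table(config.interactions)
    g_full = build.project_ddsn(table)
    g = g_full if config.keep_full_graph else build.largest_connected_component(g_full)

    _stage("cluster")
    partition = community.detect_communities(g, method=config.method, seed=config.seed)

    _stage("layout")
    params = layout.LayoutParams(
        a=config.layout_a, r=config.layout_r,
        iterations=config.layout_iterations, seed=config.seed,
    )
    coords = layout.force_layout(g, params)
    nmi = layout.layout_modularity_agreement(coords, partition, seed=config.seed)

    _stage("centrality")
    cent = centrality.centrality_table(g, mode=config.betweenness_mode)

    _stage("powerlaw")
    fits = {}
    for column in ("degree", "weighted_degree", "betweenness", "bd"):
        values = cent[column][cent[column] > 0]
        try:
            fit = powerlaw.fit_power_law(values)
            fits[column] = {
                "alpha": fit.alpha, "xmin": fit.xmin,
                "ks": fit.ks, "n_tail": fit.n_tail,
            }
        except ValueError as exc:
            fits[column] = {"error": str(exc)}

    _stage("hints")
    ann = io.read_annotations(config.annotations) if config.annotations else io.AnnotationTable()
    labels = community.label_communities(partition, ann)
    tops = prioritize.top_bd(partition, cent, t=config.t)
    report_hints = prioritize.select_hints(tops, labels, ann, t=config.t)
    summary, overall_rate = prioritize.confirmation_summary(partition, labels, ann)

    _stage("write")
    for node, (x, y) in coords.items():
        g.nodes[node]["x"], g.nodes[node]["y"] = x, y
        g.nodes[node]["community"] = partition.membership[node]
        g.nodes[node]["bd"] = float(cent.loc[str(node), "bd"])
    io.write_graph(g, outdir / "ddsn.gexf", "gexf")

    with open(outdir / "partition.csv", "w", encoding="utf-8") as fh:
        fh.write("drug_id,community,is_dominant_compliant\n")
        by_index = {lab.community: lab for lab in labels}
        for node in sorted(partition.membership, key=str):
            c = partition.membership[node]
            compliant = node not in by_index[c].non_compliant and by_index[c].resolved
            fh.write(f"{node},{c},{str(compliant).lower()}\n")
    with open(outdir / "coords.csv", "w", encoding="utf-8") as fh:
        fh.write("drug_id,x,y\n")
        for node in sorted(coords, key=str):
            fh.write(f"{node},{coords[node][0]:.10g},{coords[node][1]:.10g}\n")
    cent.to_csv(outdir / "centrality.csv", float_format="%.12g")
    with open(outdir / "fit.json", "w", encoding="utf-8") as fh:
        json.dump(fits, fh, indent=2, sort_keys=True)
    hints_payload = [
        {
            "community": c.community,
            "label": sorted(c.label_tags),
            "dominance": max(c.label_tags.values(), default=0.0),
            "unresolved": c.unresolved,
            "top": [asdict(e) for e in c.top],
        }
        for c in report_hints.communities
    ]
    with open(outdir / "hints.json", "w", encoding="utf-8") as fh:
        json.dump(hints_payload, fh, indent=2, sort_keys=True)

    report = {
        "seed": config.seed,
        "method": config.method,
        "t": config.t,
        "n_drugs_input": len(table.drugs),
        "n_nodes": g.number_of_nodes(),
        "n_edges": g.number_of_edges(),
        "n_communities": partition.m,
        "modularity": partition.modularity,
        "layout_partition_nmi": nmi,
        "overall_confirmation_rate_pct": overall_rate,
        "n_hints": len(report_hints.all_hints),
        "hints": sorted(e.drug for e in report_hints.all_hints),
        "powerlaw": fits,
        "confirmation_by_community": summary.reset_index().to_dict(orient="records"),
    }
    logger.info("pipeline finished in %.2fs", time.perf_counter() - t0)
    with open(outdir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
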