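"""Comorbidity network assembly, visual attributes, export, and the pipeline.

A network has one node per retained disease (size proportional to prevalence)
and an undirected edge for every pair whose association passed the bootstrap
percentile rule with positive mean phi; edge width is proportional to the
*square* of mean phi.  Density (mean phi over all candidate pairs) and node
connectivity annotate the object.

``run_pipeline`` chains the whole analysis: read -> validate -> stratify by
both phenotype traits -> joint 3.5% prevalence filter -> per-stratum bootstrap
(resample size 800 for CB strata, 400 for Ex strata) -> edge significance ->
density -> connectivity -> network export and a cross-stratum comparison
report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .association import filter_diseases
from .bootstrap import (
    BootstrapConfig,
    BootstrapResult,
    bootstrap_pairs,
    connectivity_overlap,
    network_density,
    node_connectivity,
    significant_edges,
)
from .cohort import (
    CohortTable,
    load_column_config,
    read_cohort,
    split_by_phenotype,
    validate_cohort,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ComorbidityNetwork",
    "build_network",
    "visual_attributes",
    "export_network",
    "validate_network_json",
    "run_pipeline",
    "PipelineSettings",
]


@dataclass
class ComorbidityNetwork:
    """Nodes, gated edges and summary annotations for one phenotype stratum."""

    nodes: list[dict]  # {"disease", "prevalence", "connectivity"}
    edges: list[dict]  # {"i", "j", "mean_phi", "significant"}
    density: float
    stratum_label: str
    provenance: dict = field(default_factory=dict)

    @property
    def node_names(self) -> list[str]:
        return [n["disease"] for n in self.nodes]

    @property
    def max_edges(self) -> int:
        k = len(self.nodes)
        return k * (k - 1) // 2


def build_network(
    result: BootstrapResult,
    edges: set[tuple[str, str]],
    prevalences: Mapping[str, float],
    label: str,
) -> ComorbidityNetwork:
    """Assemble the network: all retained nodes, only significant positive edges."""
    names = set(result.disease_names)
    for i, j in edges:
        if i not in names or j not in names:
            raise ValueError(f"edge ({i!r}, {j!r}) references an unknown node")
    conn = node_connectivity(result)
    nodes = [
        {
            "disease": d,
            "prevalence": float(prevalences.get(d, float("nan"))),
            "connectivity": conn[d],
        }
        for d in result.disease_names
    ]
    edge_rows = []
    for k, (i, j) in enumerate(result.pairs):
        if ((i, j) in edges or (j, i) in edges) and result.mean_phi[k] > 0:
            edge_rows.append(
                {"i": i, "j": j, "mean_phi": float(result.mean_phi[k]), "significant": True}
            )
    return ComorbidityNetwork(
        nodes=nodes,
        edges=edge_rows,
        density=network_density(result),
        stratum_label=label,
        provenance={
            "n_resamples": result.config.n_resamples,
            "resample_size": result.config.resample_size,
            "percentile": result.config.percentile,
            "seed": result.config.seed,
        },
    )


def visual_attributes(
    net: ComorbidityNetwork, size_scale: float = 1.0, width_scale: float = 1.0
) -> dict[str, pd.DataFrame]:
    """Rendering attributes: node size ~ prevalence, edge width ~ mean phi squared."""
    if size_scale <= 0 or width_scale <= 0:
        raise ValueError("size_scale and width_scale must be positive")
    nodes = pd.DataFrame(
        {
            "disease": [n["disease"] for n in net.nodes],
            "node_size": [size_scale * n["prevalence"] for n in net.nodes],
        }
    )
    edges = pd.DataFrame(
        {
            "i": [e["i"] for e in net.edges],
            "j": [e["j"] for e in net.edges],
            "edge_width": [width_scale * e["mean_phi"] ** 2 for e in net.edges],
        }
    )
    return {"nodes": nodes, "edges": edges}


def _network_jsonable(net: ComorbidityNetwork) -> dict:
    return {
        "stratum": net.stratum_label,
        "density": net.density,
        "nodes": net.nodes,
        "edges": net.edges,
        "provenance": net.provenance,
    }


def validate_network_json(obj: dict) -> None:
    """Structural check of an exported network JSON document.

    Mirrors docs/network.schema.json; raises ValueError on the first
    violation.
    """
    for key in ("stratum", "density", "nodes", "edges"):
        if key not in obj:
            raise ValueError(f"network JSON missing key {key!r}")
    if not isinstance(obj["density"], (int, float)):
        raise ValueError("density must be numeric")
    names = set()
    for node in obj["nodes"]:
        if {"disease", "prevalence", "connectivity"} - set(node):
            raise ValueError(f"malformed node entry: {node!r}")
        names.add(node["disease"])
    for edge in obj["edges"]:
        if {"i", "j", "mean_phi", "significant"} - set(edge):
            raise ValueError(f"malformed edge entry: {edge!r}")
        if edge["i"] not in names or edge["j"] not in names:
            raise ValueError(f"edge references unknown node: {edge!r}")
        if not edge["significant"] or not edge["mean_phi"] > 0:
            raise ValueError(f"edge violates significance gating: {edge!r}")


def to_networkx(net: ComorbidityNetwork) -> nx.Graph:
    g = nx.Graph()
    g.graph["stratum"] = net.stratum_label
    g.graph["density"] = net.density
    for node in net.nodes:
        g.add_node(
            node["disease"],
            prevalence=node["prevalence"],
            connectivity=node["connectivity"],
        )
    for e in net.edges:
        g.add_edge(e["i"], e["j"], mean_phi=e["mean_phi"], width=e["mean_phi"] ** 2)
    return g


def export_network(net: ComorbidityNetwork, path, fmt: str = "graphml") -> Path:
    """Write the network as GraphML, edge-list CSV, or JSON."""
    path = Path(path)
    fmt = fmt.lower()
    if fmt == "graphml":
        nx.write_graphml(to_networkx(net), path)
    elif fmt in ("csv", "edgelist"):
        pd.DataFrame(net.edges).to_csv(path, index=False)
    elif fmt == "json":
        doc = _network_jsonable(net)
        validate_network_json(doc)
        path.write_text(json.dumps(doc, sort_keys=True, indent=1))
    else:
        raise ValueError(f"unknown export format {fmt!r}")
    return path


# ---------------------------------------------------------------------------
# pipeline


@dataclass(frozen=True)
class PipelineSettings:
    """End-to-end analysis knobs with the study defaults."""

    n_resamples: int = 10_000
    resample_size_cb: int = 800
    resample_size_ex: int = 400
    percentile: float = 0.025
    prevalence_threshold: float = 0.035
    seed: int = 0
    compute_pair_tests: bool = True
    connectivity_mode: str = "mean"


#: stratum label -> (trait, positive?) in pipeline order
_PIPELINE_STRATA = (
    ("cb-", "cb", False),
    ("cb+", "cb", True),
    ("ex-", "ex", False),
    ("ex+", "ex", True),
)


def run_pipeline_from_cohort(
    cohort: CohortTable, settings: PipelineSettings | None = None
) -> dict:
    """Full stratified network analysis of an in-memory cohort.

    Returns a JSON-serialisable report: validation summary, jointly retained
    diseases, per-stratum bootstrap summaries, networks, densities,
    connectivities, and per-trait overlap comparisons.  Deterministic for a
    fixed (cohort, settings) pair.
    """
    settings = settings or PipelineSettings()
    report_val = validate_cohort(cohort)
    logger.info("pipeline: %d subjects, %d candidate diseases",
                cohort.n_subjects, len(cohort.disease_names))

    cb_pos, cb_neg = split_by_phenotype(cohort, "cb")
    ex_pos, ex_neg = split_by_phenotype(cohort, "ex")
    strata_tables = {"cb-": cb_neg, "cb+": cb_pos, "ex-": ex_neg, "ex+": ex_pos}
    missing = [lbl for lbl, t in strata_tables.items() if t is None]
    if missing:
        raise ValueError(f"empty phenotype strata: {missing}")

    # the filter pools all four subgroups so every network shares one node set
    retained = filter_diseases(
        [strata_tables[lbl] for lbl, *_ in _PIPELINE_STRATA],
        threshold=settings.prevalence_threshold,
    )
    logger.info("pipeline: retained %d/%d diseases (>= %.1f%% in any subgroup)",
                len(retained), len(cohort.disease_names),
                100 * settings.prevalence_threshold)

    results: dict[str, BootstrapResult] = {}
    networks: dict[str, ComorbidityNetwork] = {}
    for label, trait, _pos in _PIPELINE_STRATA:
        table = strata_tables[label]
        size = settings.resample_size_cb if trait == "cb" else settings.resample_size_ex
        config = BootstrapConfig(
            n_resamples=settings.n_resamples,
            resample_size=size,
            percentile=settings.percentile,
            seed=settings.seed,
            compute_pair_tests=settings.compute_pair_tests,
        )
        res = bootstrap_pairs(table, retained, config, stratum_label=label)
        results[label] = res
        prev = {
            d: float(v)
            for d, v in zip(res.disease_names, res.mean_prevalence)
        }
        networks[label] = build_network(res, significant_edges(res), prev, label)
        logger.info("pipeline: stratum %s n=%d density=%.4f edges=%d",
                    label, table.n_subjects, networks[label].density,
                    len(networks[label].edges))

    comparisons = {}
    for trait, (a, b) in {"cb": ("cb-", "cb+"), "ex": ("ex-", "ex+")}.items():
        per_node = {}
        for d in retained:
            rep = connectivity_overlap(results[a], results[b], d)
            per_node[d] = {
                f"interval_{a}": list(rep.interval_a),
                f"interval_{b}": list(rep.interval_b),
                "overlap": rep.overlap,
            }
        comparisons[trait] = {
            "densities": {a: networks[a].density, b: networks[b].density},
            "per_node_connectivity_overlap": per_node,
        }

    return {
        "settings": {
            "n_resamples": settings.n_resamples,
            "resample_size_cb": settings.resample_size_cb,
            "resample_size_ex": settings.resample_size_ex,
            "percentile": settings.percentile,
            "prevalence_threshold": settings.prevalence_threshold,
            "seed": settings.seed,
        },
        "validation": json.loads(report_val.to_json()),
        "retained_diseases": retained,
        "n_candidate_pairs": len(retained) * (len(retained) - 1) // 2,
        "strata": {
            label: {
                "n_subjects": strata_tables[label].n_subjects,
                "density": networks[label].density,
                "n_edges": len(networks[label].edges),
                "connectivity": node_connectivity(
                    results[label], settings.connectivity_mode
                ),
                "bootstrap": results[label].to_jsonable(),
            }
            for label, *_ in _PIPELINE_STRATA
        },
        "comparisons": comparisons,
    }


def run_pipeline(
    cohort_path,
    config_path,
    settings: PipelineSettings | None = None,
    out_dir=None,
) -> dict:
    """File-level entry point: read the cohort, analyse, optionally export.

    When ``out_dir`` is given, writes ``report.json`` plus GraphML and
    edge-list CSV per stratum; the JSON is byte-stable for a fixed input and
    seed.
    """
    cohort = read_cohort(cohort_path, load_column_config(config_path))
    report = run_pipeline_from_cohort(cohort, settings)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, sort_keys=True, indent=1))
        # rebuild the per-stratum networks for export from the report content
        for label in ("cb-", "cb+", "ex-", "ex+"):
            stratum = report["strata"][label]
            net = ComorbidityNetwork(
                nodes=[
                    {
                        "disease": d,
                        "prevalence": stratum["bootstrap"]["mean_prevalence"][k],
                        "connectivity": stratum["connectivity"][d],
                    }
                    for k, d in enumerate(report["retained_diseases"])
                ],
                edges=[
                    {"i": p["i"], "j": p["j"], "mean_phi": p["mean_phi"], "significant": True}
                    for p in stratum["bootstrap"]["pairs"]
                    if p["phi_p025"] is not None and p["phi_p025"] > 0 and p["mean_phi"] > 0
                ],
                density=stratum["density"],
                stratum_label=label,
                provenance=report["settings"],
            )
            safe = label.replace("+", "pos").replace("-", "neg")
            export_network(net, out / f"network_{safe}.graphml", "graphml")
            export_network(net, out / f"network_{safe}_edges.csv", "csv")
    return report
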