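"""End-to-end study orchestration.

Stage order (the study's own order: membrane network first, confidence
filtering second):

1. build the sperm and egg networks from their evidence files;
2. overlap the two compartments (shared nodes, edge union);
3. restrict the overlap to membrane candidates;
4. filter the membrane network's merged evidence through the functional
   (combined-score) and physical (MI/publication) routes;
5. build the two high-confidence networks over the full membrane node set
   and merge them into the union network;
6. topology metrics on the union network; hub/bottleneck classification;
   drug mapping; reports.

Every stage logs its input/output counts; the run summary records the
counts, thresholds and versions machine-readably.  A stage failure aborts
the run with the stage name, and a ``RUN.partial`` marker is left in the
output directory so partial artifacts are recognizable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from . import __version__
from .assembly import membrane_subnetwork, overlap_network, union_networks
from .filtering import FilterConfig, filter_functional, filter_physical
from .model import (
    EvidenceRecord,
    GameteNetError,
    Network,
    build_network,
    new_network,
    read_annotations,
    read_evidence,
    write_network,
)
from .targets import (
    bundled_drug_associations,
    classify_targets,
    map_drugs,
    read_drug_associations,
    target_report,
)
from .topology import centrality_table, fit_power_law, path_stats

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("gametenet")


class PipelineError(GameteNetError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Inputs, thresholds and switches for one pipeline run."""

    sperm_evidence: Path
    egg_evidence: Path
    annotations: Path
    outdir: Path
    drug_associations: Path | None = None  # None -> bundled table
    filters: FilterConfig = field(default_factory=FilterConfig)
    #: networks to run topology on, any of {"union", "overlap", "membrane"};
    #: targets are always called on the union network
    analyze: tuple[str, ...] = ("union",)
    #: apply confidence filters to raw compartment evidence before the
    #: overlap instead of after membrane extraction
    filter_first: bool = False
    seed: int | None = None  # recorded in the summary when inputs are synthetic

    def __post_init__(self) -> None:
        for p in ("sperm_evidence", "egg_evidence", "annotations", "outdir"):
            setattr(self, p, Path(getattr(self, p)))
        if self.drug_associations is not None:
            self.drug_associations = Path(self.drug_associations)
        bad = set(self.analyze) - {"union", "overlap", "membrane"}
        if bad:
            raise GameteNetError(f"unknown analyze targets {sorted(bad)}")

    @classmethod
    def from_mapping(cls, mapping: dict) -> "PipelineConfig":
        kwargs = dict(mapping)
        if "filters" in kwargs and isinstance(kwargs["filters"], dict):
            kwargs["filters"] = FilterConfig.from_mapping(kwargs["filters"])
        if "analyze" in kwargs:
            kwargs["analyze"] = tuple(kwargs["analyze"])
        return cls(**kwargs)


def _restrict_evidence(
    records: Sequence[EvidenceRecord], net: Network
) -> list[EvidenceRecord]:
    """Evidence records whose pair is an edge of *net*."""
    edges = {frozenset(e) for e in net.edges}
    return [r for r in records if frozenset(r.pair) in edges]


def _merge_evidence(
    a: Sequence[EvidenceRecord], b: Sequence[EvidenceRecord]
) -> list[EvidenceRecord]:
    """Merge two evidence lists pairwise (max scores, OR of flags)."""
    merged: dict[tuple[str, str], EvidenceRecord] = {}
    for r in [*a, *b]:
        prev = merged.get(r.pair)
        if prev is None:
            merged[r.pair] = r
        else:
            n = max(len(prev.channel_scores), len(r.channel_scores))
            ch = tuple(
                max(
                    prev.channel_scores[i] if i < len(prev.channel_scores) else 0.0,
                    r.channel_scores[i] if i < len(r.channel_scores) else 0.0,
                )
                for i in range(n)
            )
            merged[r.pair] = EvidenceRecord(
                protein_a=r.protein_a,
                protein_b=r.protein_b,
                channel_scores=ch,
                mi_score=max(prev.mi_score, r.mi_score),
                n_publications=max(prev.n_publications, r.n_publications),
                is_physical=prev.is_physical or r.is_physical,
                n_conserved_species=max(
                    prev.n_conserved_species, r.n_conserved_species
                ),
            )
    return [merged[k] for k in sorted(merged)]


def _net_counts(net: Network) -> dict:
    return {"nodes": net.number_of_nodes(), "edges": net.number_of_edges()}


def _write_path_stats(stats, path: Path) -> None:
    with path.open("w") as fh:
        fh.write("path_length\tn_pairs\n")
        for d, c in sorted(stats.histogram.items()):
            fh.write(f"{d}\t{c}\n")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the full study and return the machine-readable summary dict.

    Artifacts written to ``cfg.outdir``: per-stage networks (SIF), the
    centrality table, path-length histogram, power-law fit summary, target
    report and ``run_summary.json``.
    """
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    partial_marker = cfg.outdir / "RUN.partial"
    partial_marker.write_text("run in progress / aborted\n")
    summary: dict = {
        "versions": {
            "gametenet": __version__,
            "networkx": nx.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "filters": cfg.filters.to_mapping(),
        "filter_first": cfg.filter_first,
        "stages": {},
    }
    if cfg.seed is not None:
        summary["seed"] = cfg.seed

    stage = "read-inputs"
    try:
        for p in (cfg.sperm_evidence, cfg.egg_evidence, cfg.annotations):
            if not Path(p).exists():
                raise GameteNetError(f"input file not found: {p}")
        sperm_ev = read_evidence(cfg.sperm_evidence)
        egg_ev = read_evidence(cfg.egg_evidence)
        annotations = read_annotations(cfg.annotations)
        summary["stages"][stage] = {
            "sperm_records": len(sperm_ev),
            "egg_records": len(egg_ev),
            "annotations": len(annotations),
        }
        log.info(
            "read inputs: %d sperm records, %d egg records, %d annotations",
            len(sperm_ev), len(egg_ev), len(annotations),
        )

        if cfg.filter_first:
            stage = "pre-filter"
            sperm_ev = _merge_evidence(
                filter_functional(sperm_ev, cfg.filters),
                filter_physical(sperm_ev, cfg.filters),
            )
            egg_ev = _merge_evidence(
                filter_functional(egg_ev, cfg.filters),
                filter_physical(egg_ev, cfg.filters),
            )
            summary["stages"][stage] = {
                "sperm_records": len(sperm_ev),
                "egg_records": len(egg_ev),
            }

        stage = "build-networks"
        sperm_net = build_network(sperm_ev)
        egg_net = build_network(egg_ev)
        summary["stages"][stage] = {
            "sperm": _net_counts(sperm_net),
            "egg": _net_counts(egg_net),
        }
        log.info("sperm network %s; egg network %s",
                 _net_counts(sperm_net), _net_counts(egg_net))

        stage = "overlap"
        overlap = overlap_network(sperm_net, egg_net)
        summary["stages"][stage] = _net_counts(overlap)
        write_network(overlap, cfg.outdir / "overlap_network.sif")
        log.info("overlap network %s", _net_counts(overlap))

        stage = "membrane"
        membrane = membrane_subnetwork(overlap, annotations)
        summary["stages"][stage] = _net_counts(membrane)
        write_network(membrane, cfg.outdir / "membrane_network.sif")
        log.info("membrane network %s", _net_counts(membrane))

        stage = "confidence-filter"
        membrane_ev = _restrict_evidence(_merge_evidence(sperm_ev, egg_ev), membrane)
        functional = filter_functional(membrane_ev, cfg.filters)
        physical = filter_physical(membrane_ev, cfg.filters)
        # high-confidence networks keep the full membrane node set so that
        # the union never silently drops proteins that lost all their edges
        membrane_nodes = list(membrane.nodes)
        func_net = new_network(membrane_nodes, (r.pair for r in functional))
        phys_net = new_network(membrane_nodes, (r.pair for r in physical))
        summary["stages"][stage] = {
            "membrane_evidence": len(membrane_ev),
            "functional": _net_counts(func_net),
            "physical": _net_counts(phys_net),
        }
        write_network(func_net, cfg.outdir / "high_confidence_functional.sif")
        write_network(phys_net, cfg.outdir / "high_confidence_physical.sif")
        log.info(
            "confidence filter: %d membrane records -> functional %s, physical %s",
            len(membrane_ev), _net_counts(func_net), _net_counts(phys_net),
        )

        stage = "union"
        union = union_networks(func_net, phys_net)
        summary["stages"][stage] = _net_counts(union)
        write_network(union, cfg.outdir / "union_network.sif")
        log.info("union network %s", _net_counts(union))

        stage = "topology"
        nets = {"union": union, "overlap": overlap, "membrane": membrane}
        topo_summary: dict = {}
        for name in cfg.analyze:
            net = nets[name]
            tbl = centrality_table(net, annotations)
            tbl.to_csv(cfg.outdir / f"centrality_{name}.tsv", sep="\t", index=False)
            stats = path_stats(net)
            _write_path_stats(stats, cfg.outdir / f"path_histogram_{name}.tsv")
            entry: dict = {
                "characteristic_path_length": stats.characteristic_path_length,
                "n_connected_pairs": stats.n_pairs,
            }
            try:
                fit = fit_power_law(dict(zip(tbl["accession"], tbl["degree"])))
                entry["power_law"] = dataclasses.asdict(fit)
                (cfg.outdir / f"power_law_{name}.json").write_text(
                    json.dumps(dataclasses.asdict(fit), indent=2) + "\n"
                )
            except GameteNetError as exc:
                entry["power_law"] = None
                log.warning("power-law fit skipped for %s: %s", name, exc)
            topo_summary[name] = entry
        summary["stages"][stage] = topo_summary

        stage = "targets"
        union_tbl = centrality_table(union, annotations)
        if len(union_tbl) == 0:
            calls = []
        else:
            calls = classify_targets(union_tbl)
        assoc = (
            read_drug_associations(cfg.drug_associations)
            if cfg.drug_associations is not None
            else bundled_drug_associations()
        )
        calls = map_drugs(calls, assoc)
        target_report(calls, cfg.outdir / "target_report.tsv")
        hubs = [c for c in calls if c.is_hub]
        summary["stages"][stage] = {
            "n_nodes": len(calls),
            "n_hubs": len(hubs),
            "n_bottlenecks": sum(c.is_bottleneck for c in calls),
            "hub_symbols": [c.gene_symbol for c in hubs],
            "hubs_with_drugs": sum(bool(c.drugs) for c in hubs),
        }
        log.info("targets: %d hubs of %d nodes", len(hubs), len(calls))
    except GameteNetError as exc:
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, str(exc)) from exc

    (cfg.outdir / "run_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    partial_marker.unlink(missing_ok=True)
    return summary
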