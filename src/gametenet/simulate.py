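"""Synthetic two-compartment interaction studies with known ground truth.

The original sperm/egg interaction inputs were snapshots of interaction
databases that cannot be reconstructed, so every pipeline stage is
exercised instead on synthetic studies that reproduce the statistical
structure the analysis assumes:

* two overlapping scale-free compartment networks built by preferential
  attachment around a shared core (defaults follow the study's scale:
  a 2076-node sperm network, a 409-node egg network, 167 shared proteins,
  roughly 63% of shared proteins membrane-annotated);
* a set of *planted hubs* — shared, always membrane-annotated proteins
  wired to high degree in the shared core — which serve as the known
  essential proteins that end-to-end target recovery is measured against;
* per-edge evidence: channel scores drawn from a "true" beta distribution
  (mean near 0.8) for genuine edges and a "noise" beta (mean near 0.2) for
  spurious edges added on top, plus MI scores, publication counts and
  physical/conservation fields separated the same way.

All randomness flows from a single integer seed, so the same spec always
produces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .model import (
    EvidenceRecord,
    Network,
    ProteinRecord,
    ValidationError,
    write_annotations,
    write_evidence,
)

__all__ = ["StudySpec", "generate_study", "generate_powerlaw_network", "write_study"]


@dataclass(frozen=True)
class StudySpec:
    """Parameters of one synthetic two-compartment interaction study.

    Network shape: ``n_sperm``/``n_egg`` total proteins per compartment,
    ``n_shared`` proteins present in both, ``attachment_edges_per_node``
    (the preferential-attachment ``m``).  ``membrane_fraction`` is the
    probability a non-planted protein carries a signal-peptide and/or
    transmembrane annotation.  ``n_planted_hubs`` shared membrane proteins
    are wired to high degree in the shared core and recorded as ground
    truth.

    Evidence model: channel scores are Beta draws with ``(alpha, beta)``
    parameters per edge label; publication counts are Poisson; MI scores
    are Beta; ``physical_prob`` is the chance any edge is flagged physical.
    ``noise_edge_fraction`` spurious edges (relative to the number of true
    edges) are added per compartment and labelled noise in ground truth.
    """

    n_sperm: int = 2076
    n_egg: int = 409
    n_shared: int = 167
    attachment_edges_per_node: int = 4
    membrane_fraction: float = 0.63
    n_planted_hubs: int = 8
    n_channels: int = 3
    true_edge_channel_dist: tuple[float, float] = (8.0, 2.0)
    noise_edge_channel_dist: tuple[float, float] = (2.0, 8.0)
    physical_prob: float = 0.7
    publication_mean_true: float = 4.0
    publication_mean_noise: float = 0.8
    mi_given_physical_dist: tuple[float, float] = (6.0, 3.0)
    mi_noise_dist: tuple[float, float] = (2.0, 8.0)
    conserved_mean_true: float = 2.5
    conserved_mean_noise: float = 0.3
    noise_edge_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_shared > min(self.n_sperm, self.n_egg):
            raise ValidationError("n_shared must not exceed min(n_sperm, n_egg)")
        if self.n_planted_hubs > self.n_shared:
            raise ValidationError("n_planted_hubs must not exceed n_shared")
        if not 1 <= self.attachment_edges_per_node < self.n_shared:
            raise ValidationError("attachment_edges_per_node must be in [1, n_shared)")
        for name in ("membrane_fraction", "physical_prob", "noise_edge_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1]")
        for name in (
            "true_edge_channel_dist",
            "noise_edge_channel_dist",
            "mi_given_physical_dist",
            "mi_noise_dist",
        ):
            a, b = getattr(self, name)
            if a <= 0 or b <= 0:
                raise ValidationError(f"{name} beta parameters must be positive")

    def to_mapping(self) -> dict:
        d = dataclasses.asdict(self)
        return {k: list(v) if isinstance(v, tuple) else v for k, v in d.items()}

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "StudySpec":
        fields = {f.name for f in dataclasses.fields(cls)}
        kwargs = {}
        for k, v in mapping.items():
            if k not in fields:
                raise ValidationError(f"unknown StudySpec field {k!r}")
            kwargs[k] = tuple(v) if isinstance(v, list) else v
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# Preferential attachment
# ---------------------------------------------------------------------------


def _ba_edges(n: int, m: int, rng: np.random.Generator) -> list[tuple[int, int]]:
    """Barabasi-Albert edges over integer nodes 0..n-1.

    Seeded with a complete graph on the first m nodes; every later node
    attaches m edges to distinct existing nodes chosen proportionally to
    degree.  Edge count is therefore C(m, 2) + m * (n - m) and the graph is
    connected and simple.
    """
    edges = [(i, j) for i in range(m) for j in range(i + 1, m)]
    # one entry per unit of degree; seed clique nodes get one baseline entry
    # each so that m=1 (single seed node, no clique edges) stays attachable
    repeated: list[int] = [v for e in edges for v in e] or list(range(m))
    for new in range(m, n):
        targets: set[int] = set()
        while len(targets) < m:
            targets.add(repeated[int(rng.integers(len(repeated)))])
        for t in sorted(targets):
            edges.append((t, new))
            repeated.extend((t, new))
    return edges


def generate_powerlaw_network(n: int, m: int, seed: int) -> Network:
    """Seeded preferential-attachment (scale-free) network on n nodes.

    Nodes are labelled ``N0000`` .. ``N{n-1}``.  The graph is simple and
    connected, with ``m * (n - m) + C(m, 2)`` edges (the seed is a complete
    graph on the first ``m`` nodes).
    """
    if not 1 <= m < n:
        raise ValidationError(f"need 1 <= m < n, got m={m}, n={n}")
    rng = np.random.default_rng(seed)
    g = nx.Graph()
    labels = [f"N{i:04d}" for i in range(n)]
    g.add_nodes_from(labels)
    g.add_edges_from((labels[a], labels[b]) for a, b in _ba_edges(n, m, rng))
    return g


def _extend_preferential(
    g: nx.Graph, new_nodes: Sequence[str], m: int, rng: np.random.Generator
) -> None:
    """Attach new nodes to an existing graph by degree-proportional choice."""
    repeated: list[str] = []
    for v in sorted(g.nodes):
        repeated.extend([v] * max(g.degree(v), 1))
    for node in new_nodes:
        k = min(m, g.number_of_nodes())
        targets: set[str] = set()
        while len(targets) < k:
            targets.add(repeated[int(rng.integers(len(repeated)))])
        g.add_node(node)
        for t in sorted(targets):
            g.add_edge(t, node)
            repeated.extend((t, node))


def _sample_noise_edges(
    g: nx.Graph, n_noise: int, rng: np.random.Generator
) -> list[tuple[str, str]]:
    """Random node pairs not already edges (rejection sampling)."""
    nodes = sorted(g.nodes)
    out: list[tuple[str, str]] = []
    seen: set[frozenset] = set()
    attempts = 0
    while len(out) < n_noise and attempts < 50 * max(n_noise, 1):
        attempts += 1
        i, j = rng.integers(len(nodes), size=2)
        if i == j:
            continue
        a, b = sorted((nodes[int(i)], nodes[int(j)]))
        key = frozenset((a, b))
        if key in seen or g.has_edge(a, b):
            continue
        seen.add(key)
        out.append((a, b))
    return out


# ---------------------------------------------------------------------------
# Study generation
# ---------------------------------------------------------------------------


def _emit_record(
    pair: tuple[str, str], is_true: bool, spec: StudySpec, rng: np.random.Generator
) -> EvidenceRecord:
    ch_a, ch_b = (
        spec.true_edge_channel_dist if is_true else spec.noise_edge_channel_dist
    )
    mi_a, mi_b = spec.mi_given_physical_dist if is_true else spec.mi_noise_dist
    pub_mean = spec.publication_mean_true if is_true else spec.publication_mean_noise
    cons_mean = spec.conserved_mean_true if is_true else spec.conserved_mean_noise
    return EvidenceRecord(
        protein_a=pair[0],
        protein_b=pair[1],
        channel_scores=tuple(
            float(x) for x in rng.beta(ch_a, ch_b, size=spec.n_channels)
        ),
        mi_score=float(rng.beta(mi_a, mi_b)),
        n_publications=int(rng.poisson(pub_mean)),
        is_physical=bool(rng.random() < spec.physical_prob),
        n_conserved_species=int(rng.poisson(cons_mean)),
    )


def generate_study(
    spec: StudySpec,
) -> tuple[list[EvidenceRecord], list[EvidenceRecord], list[ProteinRecord], dict]:
    """Generate one synthetic study: (sperm evidence, egg evidence, annotations, ground truth).

    Construction order: a shared scale-free core on ``n_shared`` proteins;
    planted hubs rewired to high degree within the core; compartment-only
    proteins preferentially attached to give the sperm and egg networks
    their full sizes; noise edges added per compartment; evidence fields
    drawn per edge according to its true/noise label.  Ground truth records
    the planted hub accessions/symbols and the true and noise edge lists.
    """
    rng = np.random.default_rng(spec.seed)
    m = spec.attachment_edges_per_node

    shared = [f"SH{i:04d}" for i in range(spec.n_shared)]
    core = nx.Graph()
    core.add_nodes_from(shared)
    core.add_edges_from(
        (shared[a], shared[b]) for a, b in _ba_edges(spec.n_shared, m, rng)
    )

    # plant hubs: wire selected shared proteins up to a degree well above
    # anything preferential attachment produces naturally, so they dominate
    # the half-of-maximum criterion downstream
    hub_ids = sorted(
        shared[int(i)]
        for i in rng.choice(spec.n_shared, size=spec.n_planted_hubs, replace=False)
    )
    lo = max(int(0.55 * spec.n_shared), m + 1)
    hi = max(int(0.70 * spec.n_shared), lo + 1)
    others = np.array(shared)
    for h in hub_ids:
        target_deg = int(rng.integers(lo, hi))
        candidates = [v for v in others if v != h and not core.has_edge(h, v)]
        need = max(target_deg - core.degree(h), 0)
        if need > 0 and candidates:
            picks = rng.choice(len(candidates), size=min(need, len(candidates)), replace=False)
            for p in sorted(int(i) for i in picks):
                core.add_edge(h, candidates[p])

    sperm_net = core.copy()
    _extend_preferential(
        sperm_net,
        [f"SP{i:04d}" for i in range(spec.n_sperm - spec.n_shared)],
        m,
        rng,
    )
    egg_net = core.copy()
    _extend_preferential(
        egg_net,
        [f"EG{i:04d}" for i in range(spec.n_egg - spec.n_shared)],
        m,
        rng,
    )

    ground_truth: dict = {
        "planted_hubs": hub_ids,
        "planted_hub_symbols": [f"g{h}" for h in hub_ids],
        "true_edges": {},
        "noise_edges": {},
    }
    evidence: dict[str, list[EvidenceRecord]] = {}
    for name, net in (("sperm", sperm_net), ("egg", egg_net)):
        true_edges = sorted(tuple(sorted(e)) for e in net.edges)
        n_noise = int(round(spec.noise_edge_fraction * len(true_edges)))
        noise_edges = sorted(_sample_noise_edges(net, n_noise, rng))
        ground_truth["true_edges"][name] = [list(e) for e in true_edges]
        ground_truth["noise_edges"][name] = [list(e) for e in noise_edges]
        recs = [_emit_record(e, True, spec, rng) for e in true_edges]
        recs += [_emit_record(e, False, spec, rng) for e in noise_edges]
        recs.sort(key=lambda r: r.pair)
        evidence[name] = recs

    annotations: list[ProteinRecord] = []
    all_nodes = sorted(set(sperm_net.nodes) | set(egg_net.nodes))
    for acc in all_nodes:
        comps = set()
        if acc in sperm_net:
            comps.add("sperm")
        if acc in egg_net:
            comps.add("egg")
        if acc in hub_ids:
            sig, tm = True, True
        elif rng.random() < spec.membrane_fraction:
            sig = bool(rng.random() < 0.7)
            tm = bool(rng.random() < 0.7)
            if not (sig or tm):
                tm = True
        else:
            sig = tm = False
        annotations.append(
            ProteinRecord(
                accession=acc,
                gene_symbol=f"g{acc}",
                has_signal_peptide=sig,
                has_transmembrane=tm,
                compartments=frozenset(comps),
            )
        )
    return evidence["sperm"], evidence["egg"], annotations, ground_truth


def write_study(spec: StudySpec, outdir: str | Path) -> dict[str, Path]:
    """Generate a study and write its files under *outdir*.

    Emits ``sperm_evidence.tsv``, ``egg_evidence.tsv``, ``annotations.tsv``,
    ``ground_truth.json`` and a ``study_spec.json`` sidecar recording the
    generating parameters.  Returns the path map.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sperm, egg, annotations, truth = generate_study(spec)
    paths = {
        "sperm_evidence": outdir / "sperm_evidence.tsv",
        "egg_evidence": outdir / "egg_evidence.tsv",
        "annotations": outdir / "annotations.tsv",
        "ground_truth": outdir / "ground_truth.json",
        "study_spec": outdir / "study_spec.json",
    }
    write_evidence(sperm, paths["sperm_evidence"], n_channels=spec.n_channels)
    write_evidence(egg, paths["egg_evidence"], n_channels=spec.n_channels)
    write_annotations(annotations, paths["annotations"])
    paths["ground_truth"].write_text(json.dumps(truth, indent=2) + "\n")
    paths["study_spec"].write_text(json.dumps(spec.to_mapping(), indent=2) + "\n")
    return paths
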