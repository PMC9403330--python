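"""Readers and writers for the flat-file formats, plus the pipeline driver.

Formats (all UTF-8, tab-separated, header row):

* edge list — ``source_kind source_id target_kind target_id weight origin``;
  one file per network plus one for cross-network links.
* fingerprints — a ``#bits=<L>`` header line, then
  ``compound_id<TAB>comma-separated indices of 1-bits`` (sparse) or a dense
  0/1 string of length L.
* centralities — ``gene bc cc`` with an optional ``protein_id`` column.
* bipartite profiles — ``plant_id gene protein_id protein_weight edge_weight``.

Malformed rows are rejected with ``path:line`` prefixed errors.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import yaml

from .network_model import (
    Edge,
    NodeRef,
    TripartiteNetwork,
    ValidationError,
    link_protein_identity,
    merge_networks,
    prune_untraceable,
)
from .optimizer import SearchConfig, SearchResult, branch_and_bound
from .protein_weighting import ProteinWeightTable, normalize_weights
from .scoring import FormulaCandidate
from .similarity import (
    DEFAULT_THRESHOLD,
    Fingerprint,
    best_match_links,
    threshold_links,
)
from .synthetic_data import SyntheticSpec, generate_networks
from .traversal import PlantProteinProfile, annotate_compounds, backtrack_to_plants

logger = logging.getLogger("herbnet")

REPORT_SCHEMA_VERSION = 1

EDGE_COLUMNS = ["source_kind", "source_id", "target_kind", "target_id", "weight", "origin"]


def _fail(path, lineno: int, msg: str):
    raise ValidationError(f"{path}:{lineno}: {msg}")


# --------------------------------------------------------------------------
# edges


def write_edges(path, edges: Iterable[Edge]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(EDGE_COLUMNS) + "\n")
        for e in edges:
            fh.write(
                f"{e.source.kind}\t{e.source.id}\t{e.target.kind}\t{e.target.id}"
                f"\t{e.weight!r}\t{e.origin}\n"
            )


def read_edges(
    path, source_network: str, target_network: str | None = None
) -> list[Edge]:
    """Parse an edge-list TSV; node networks are supplied by the caller.

    For a within-network file pass one network label; for a cross-link file
    pass both (source then target).
    """
    target_network = target_network or source_network
    edges = []
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != EDGE_COLUMNS:
            _fail(path, 1, f"expected header {EDGE_COLUMNS}, got {header}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(EDGE_COLUMNS):
                _fail(path, lineno, f"expected {len(EDGE_COLUMNS)} columns, got {len(parts)}")
            sk, sid, tk, tid, w, origin = parts
            try:
                weight = float(w)
            except ValueError:
                _fail(path, lineno, f"non-numeric weight {w!r}")
            try:
                edges.append(
                    Edge(
                        NodeRef(sk, sid, source_network),
                        NodeRef(tk, tid, target_network),
                        weight,
                        origin,
                    )
                )
            except ValidationError as exc:
                _fail(path, lineno, str(exc))
    return edges


# --------------------------------------------------------------------------
# fingerprints


def write_fingerprints(path, fps: Sequence[Fingerprint]) -> None:
    length = len(fps[0]) if fps else 0
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"#bits={length}\n")
        for fp in fps:
            idx = ",".join(str(i) for i in fp.on_indices)
            fh.write(f"{fp.compound_id}\t{idx}\n")


def read_fingerprints(path) -> list[Fingerprint]:
    fps = []
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().strip()
        if not header.startswith("#bits="):
            _fail(path, 1, "expected '#bits=<length>' header line")
        try:
            length = int(header.split("=", 1)[1])
        except ValueError:
            _fail(path, 1, f"bad bit length in header {header!r}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                _fail(path, lineno, "expected 'compound_id<TAB>bits'")
            cid, bits = parts
            try:
                if set(bits) <= {"0", "1"} and len(bits) == length:
                    fps.append(Fingerprint.from_dense(cid, bits))
                elif bits == "":
                    fps.append(Fingerprint.from_indices(cid, (), length))
                else:
                    fps.append(
                        Fingerprint.from_indices(
                            cid, (int(i) for i in bits.split(",")), length
                        )
                    )
            except (ValueError, ValidationError) as exc:
                _fail(path, lineno, f"bad fingerprint: {exc}")
    return fps


# --------------------------------------------------------------------------
# centralities and bipartite profiles


def write_centralities(path, rows: Iterable[Sequence]) -> None:
    rows = list(rows)
    has_pid = rows and len(rows[0]) == 4
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene\tbc\tcc" + ("\tprotein_id" if has_pid else "") + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_centralities(path) -> list[tuple]:
    rows = []
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["gene", "bc", "cc"]:
            _fail(path, 1, f"expected columns gene/bc/cc, got {header}")
        width = len(header)
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != width:
                _fail(path, lineno, f"expected {width} columns, got {len(parts)}")
            try:
                bc, cc = float(parts[1]), float(parts[2])
            except ValueError:
                _fail(path, lineno, "non-numeric centrality")
            rows.append((parts[0], bc, cc, *parts[3:4]))
    return rows


BIPARTITE_COLUMNS = ["plant_id", "gene", "protein_id", "protein_weight", "edge_weight"]


def write_bipartite(path, profiles: Iterable[PlantProteinProfile]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(BIPARTITE_COLUMNS) + "\n")
        for prof in profiles:
            for pid, (gene, pw, ew) in sorted(prof.proteins.items()):
                fh.write(f"{prof.plant_id}\t{gene}\t{pid}\t{pw!r}\t{ew!r}\n")


def read_bipartite(path) -> list[PlantProteinProfile]:
    profiles: dict[str, PlantProteinProfile] = {}
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != BIPARTITE_COLUMNS:
            _fail(path, 1, f"expected header {BIPARTITE_COLUMNS}, got {header}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 5:
                _fail(path, lineno, f"expected 5 columns, got {len(parts)}")
            plant, gene, pid, pw_s, ew_s = parts
            try:
                pw, ew = float(pw_s), float(ew_s)
            except ValueError:
                _fail(path, lineno, "non-numeric weight")
            if not (0.0 <= ew <= 1.0):
                _fail(path, lineno, f"edge weight {ew} outside [0, 1]")
            profiles.setdefault(plant, PlantProteinProfile(plant)).record(pid, gene, pw, ew)
    return [profiles[p] for p in sorted(profiles)]


# --------------------------------------------------------------------------
# candidate report


def candidates_report(result: SearchResult, cfg: SearchConfig) -> dict:
    return {
        "schema_version": REPORT_SCHEMA_VERSION,
        "config": {
            "k": cfg.k,
            "top_f": cfg.top_f,
            "strategy": cfg.strategy,
            "branching": cfg.branching,
            "dominance_filter": cfg.dominance_filter,
        },
        "candidates": [c.as_dict() for c in result.candidates],
        "telemetry": {
            "nodes_generated": result.nodes_generated,
            "nodes_pruned": result.nodes_pruned,
        },
    }


def write_candidates(path, result: SearchResult, cfg: SearchConfig) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(candidates_report(result, cfg), fh, indent=2)
        fh.write("\n")


def format_candidate_table(candidates: Sequence[FormulaCandidate]) -> str:
    """Human-readable table: composition size, plant names, formula score."""
    lines = [f"{'k':>3}  {'formula score':>14}  plants"]
    for c in candidates:
        lines.append(f"{len(c.plants):>3}  {c.score:>14.5f}  {', '.join(c.plants)}")
    return "\n".join(lines)


# --------------------------------------------------------------------------
# run configuration and pipeline


@dataclass
class RunConfig:
    """End-to-end pipeline configuration.

    Either ``synthetic`` is set (inputs are generated) or the file paths
    are: edge lists for networks A/B/C, fingerprint files for the three
    compound sets, and a centrality table.
    """

    search: SearchConfig
    synthetic: SyntheticSpec | None = None
    edges_a: str | None = None
    edges_b: str | None = None
    edges_c: str | None = None
    fingerprints_a: str | None = None
    fingerprints_b: str | None = None
    fingerprints_c: str | None = None
    centralities: str | None = None
    threshold: float = DEFAULT_THRESHOLD
    outdir: str = "herbnet_out"
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = {
            "search": vars(self.search).copy(),
            "threshold": self.threshold,
            "outdir": self.outdir,
            "log_level": self.log_level,
        }
        if self.synthetic is not None:
            d["synthetic"] = vars(self.synthetic).copy()
            d["synthetic"]["compounds_per_plant"] = list(self.synthetic.compounds_per_plant)
            d["synthetic"]["proteins_per_compound"] = list(self.synthetic.proteins_per_compound)
        for name in (
            "edges_a", "edges_b", "edges_c",
            "fingerprints_a", "fingerprints_b", "fingerprints_c", "centralities",
        ):
            if getattr(self, name) is not None:
                d[name] = getattr(self, name)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        search = SearchConfig(**d.pop("search"))
        syn = d.pop("synthetic", None)
        if syn is not None:
            syn = dict(syn)
            for key in ("compounds_per_plant", "proteins_per_compound"):
                if key in syn:
                    syn[key] = tuple(syn[key])
            syn = SyntheticSpec(**syn)
        return cls(search=search, synthetic=syn, **d)


def load_config(path) -> RunConfig:
    text = Path(path).read_text(encoding="utf-8")
    data = yaml.safe_load(text)  # YAML is a superset of JSON
    if not isinstance(data, dict):
        raise ValidationError(f"{path}: config must be a mapping")
    return RunConfig.from_dict(data)


def save_config(path, cfg: RunConfig) -> None:
    Path(path).write_text(
        yaml.safe_dump(cfg.to_dict(), sort_keys=False), encoding="utf-8"
    )


def _load_inputs(cfg: RunConfig):
    if cfg.synthetic is not None:
        data = generate_networks(cfg.synthetic)
        return (
            data.net_a,
            data.net_b,
            data.net_c,
            data.fingerprints_a,
            data.fingerprints_b,
            data.fingerprints_c,
            data.centralities,
        )
    required = {
        "edges_a": cfg.edges_a,
        "edges_c": cfg.edges_c,
        "fingerprints_a": cfg.fingerprints_a,
        "centralities": cfg.centralities,
    }
    missing = [k for k, v in required.items() if v is None]
    if missing:
        raise ValidationError(f"run config missing inputs: {', '.join(missing)}")
    net_a = TripartiteNetwork(read_edges(cfg.edges_a, "A"))
    net_b = TripartiteNetwork(read_edges(cfg.edges_b, "B")) if cfg.edges_b else TripartiteNetwork()
    net_c = TripartiteNetwork(read_edges(cfg.edges_c, "C"))
    fps_a = read_fingerprints(cfg.fingerprints_a)
    fps_b = read_fingerprints(cfg.fingerprints_b) if cfg.fingerprints_b else []
    fps_c = read_fingerprints(cfg.fingerprints_c) if cfg.fingerprints_c else []
    cents = read_centralities(cfg.centralities)
    return net_a, net_b, net_c, fps_a, fps_b, fps_c, cents


def run_pipeline(cfg: RunConfig) -> dict:
    """link -> prune -> traverse -> weight -> search, writing a JSON report.

    Returns the report dict; stage-level node/edge counts are logged so a
    run's bookkeeping can be audited afterwards.
    """
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    stage = "load"
    try:
        net_a, net_b, net_c, fps_a, fps_b, fps_c, cents = _load_inputs(cfg)
        table = normalize_weights(cents)
        logger.info(
            "load: |A|=%d |B|=%d |C|=%d nodes; %d proteins weighted",
            len(net_a), len(net_b), len(net_c), len(table),
        )

        stage = "link"
        links: list[Edge] = []
        if fps_a and fps_b:
            links += threshold_links(fps_a, fps_b, cfg.threshold)
        if fps_c and fps_a:
            links += best_match_links(fps_c, fps_a)
        links += link_protein_identity(net_a, net_c)
        links += link_protein_identity(net_b, net_c)
        net = merge_networks(net_a, net_b, net_c, links=links)
        logger.info("link: %d cross-links; merged network has %d nodes", len(links), len(net))

        stage = "prune"
        seeds = {
            NodeRef("protein", pid, "C")
            for pid, _, _ in table.items()
            if NodeRef("protein", pid, "C") in net
        }
        net = prune_untraceable(net, seeds)
        logger.info("prune: %d nodes reachable from %d seed proteins", len(net), len(seeds))

        stage = "traverse"
        annotations = annotate_compounds(net, table)
        profiles = backtrack_to_plants(annotations, net)
        logger.info(
            "traverse: %d annotated compounds -> %d plant profiles",
            len(annotations), len(profiles),
        )
        if len(profiles) < cfg.search.k:
            raise ValidationError(
                f"only {len(profiles)} traceable plants; cannot compose k={cfg.search.k}"
            )

        stage = "search"
        result = branch_and_bound(profiles, cfg.search)
        logger.info(
            "search: %d candidates, %d nodes generated, %d pruned",
            len(result.candidates), result.nodes_generated, result.nodes_pruned,
        )
    except ValidationError as exc:
        raise ValidationError(f"pipeline stage {stage!r}: {exc}") from exc

    report = candidates_report(result, cfg.search)
    report["stages"] = {
        "network_nodes": len(net),
        "annotated_compounds": len(annotations),
        "plant_profiles": len(profiles),
        "max_attainable_score": table.total_weight,
    }
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "candidates.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2)
        fh.write("\n")
    (outdir / "candidates.txt").write_text(
        format_candidate_table(result.candidates) + "\n", encoding="utf-8"
    )
    write_bipartite(outdir / "bipartite.tsv", profiles)
    return report
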