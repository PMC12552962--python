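"""End-to-end run: similarity -> clustering -> summarisation -> render.

A :class:`RunConfig` captures every knob of one analysis and is fully
serialisable to YAML; each run logs the resolved config verbatim so any
result can be reproduced from its log.  All tabular outputs are written
atomically (temp file + rename) under a common output prefix.
"""

from __future__ import annotations

import logging
import os
import tempfile
import time
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml
from scipy.cluster.hierarchy import leaves_list, linkage as scipy_linkage
from scipy.spatial.distance import squareform

from . import clustering, similarity as sim, summarize as summ
from .clustering import BinaryCutParams, ClusterAssignment
from .errors import InputError
from .genesets import read_gmt
from .ontology import OntologyGraph, parse_obo

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one pipeline run depends on."""

    enrichment: str = ""
    obo: str = ""
    gmt: str | None = None          # optional annotation corpus for IC
    namespace: str | None = None    # OBO namespace filter
    score_type: str = "nes"
    measure: str = "rel"
    method: str = "combined"        # binary | hclust | combined
    cutoff: float = 0.85
    partitioner: str = "pam2"
    min_split: int = 2
    refine_threshold: float = 0.5
    max_cluster_size: int = 50
    linkage: str = "average"
    min_cover: int = 2
    min_level: int = 3
    max_reps: int = 5
    broad_level: int = 2
    top_k: int = 8
    out_prefix: str = "gosum_run"
    seed: int = 1
    image_format: str = "png"       # png | svg | pdf
    max_display: int = 2000

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        raw = yaml.safe_load(text) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _atomic_write(path: Path, text: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=path.name + ".")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _display_order(S: sim.SimilarityMatrix, assignment: ClusterAssignment,
                   ranks: list[summ.ClusterRank],
                   linkage_method: str) -> list[int]:
    """Row order for the heatmap: clusters in rank order, members of
    each cluster in average-linkage dendrogram leaf order."""
    pos = {t: i for i, t in enumerate(S.term_ids)}
    order: list[int] = []
    for r in ranks:
        members = [t for t in S.term_ids if assignment.labels[t] == r.cluster]
        idx = [pos[t] for t in members]
        if len(idx) > 2:
            sub = S.values[np.ix_(idx, idx)]
            D = 1.0 - sub
            np.fill_diagonal(D, 0.0)
            Z = scipy_linkage(squareform(np.clip((D + D.T) / 2, 0, None),
                                         checks=False),
                              method=linkage_method)
            idx = [idx[i] for i in leaves_list(Z)]
        order.extend(idx)
    return order


def cluster_with(S, cfg: RunConfig) -> ClusterAssignment:
    params = BinaryCutParams(cutoff=cfg.cutoff, partitioner=cfg.partitioner,
                             min_split=cfg.min_split, seed=cfg.seed)
    if cfg.method == "binary":
        return clustering.binary_cut(S, params)
    if cfg.method == "hclust":
        return clustering.hierarchical_cluster(S, linkage=cfg.linkage)
    if cfg.method == "combined":
        return clustering.combined_cluster(
            S, params, refine_threshold=cfg.refine_threshold,
            max_cluster_size=cfg.max_cluster_size, linkage=cfg.linkage)
    raise InputError(f"unknown clustering method {cfg.method!r}")


def run_pipeline(cfg: RunConfig) -> dict[str, Path]:
    """Execute the full analysis; returns the written output paths.

    Outputs under ``cfg.out_prefix``: ``.clusters.tsv`` (term, cluster,
    rank, display row order), ``.representatives.tsv``, ``.panel.tsv``,
    ``.heatmap.<fmt>``, ``.config.yaml`` and ``.log``.
    """
    t0 = time.perf_counter()
    log_lines: list[str] = ["# resolved config", *cfg.to_yaml().rstrip().splitlines()]

    def stage(msg: str) -> None:
        line = f"[{time.perf_counter() - t0:8.2f}s] {msg}"
        logger.info(msg)
        log_lines.append(line)

    obo_text = Path(cfg.obo).read_text()
    g = parse_obo(obo_text, namespace_filter=cfg.namespace)
    stage(f"ontology: {len(g.active_terms)} terms, root {g.root_id}")

    table = summ.EnrichmentTable.read_tsv(Path(cfg.enrichment).read_text(),
                                          score_type=cfg.score_type)
    stage(f"enrichment: {len(table)} terms, score_type={cfg.score_type}")

    annotations = None
    if cfg.gmt:
        coll = read_gmt(Path(cfg.gmt).read_text())
        annotations = {name: set(genes) for name, genes in coll.sets.items()
                       if name in g.terms}
        stage(f"annotations: {len(annotations)} terms with gene sets")
    ic = sim.information_content(g, annotations)

    S = sim.similarity_matrix(g, table, measure=cfg.measure, ic=ic)
    n_dropped = len(getattr(S, "dropped", []))
    stage(f"similarity: {len(S)} x {len(S)} matrix ({cfg.measure}), "
          f"{n_dropped} input terms dropped (absent from ontology)")

    assignment = cluster_with(S, cfg)
    stage(f"clustering: method={cfg.method}, {assignment.n_clusters} clusters")

    ranks = summ.rank_clusters(table, assignment)
    rep_sets = [
        summ.representative_terms(
            g, assignment.members(r.cluster), min_cover=cfg.min_cover,
            min_level=cfg.min_level, max_reps=cfg.max_reps, cluster=r.cluster)
        for r in ranks
    ]
    panel = summ.broad_term_panel(g, S.term_ids, broad_level=cfg.broad_level,
                                  top_k=cfg.top_k)
    stage(f"summarise: {sum(len(rs.representatives) for rs in rep_sets)} "
          f"representatives, {len(panel.entries)} broad panel entries")

    order = _display_order(S, assignment, ranks, cfg.linkage)
    rank_of = {r.cluster: i + 1 for i, r in enumerate(ranks)}
    mean_of = {r.cluster: r.mean_score for r in ranks}
    cluster_lines = ["term_id\tcluster\tcluster_rank\tcluster_mean_score\t"
                     "row_order\tmethod"]
    row_pos = {S.term_ids[i]: pos for pos, i in enumerate(order)}
    for t in S.term_ids:
        c = assignment.labels[t]
        cluster_lines.append(
            f"{t}\t{c}\t{rank_of[c]}\t{mean_of[c]:.6g}\t{row_pos[t]}\t"
            f"{assignment.method}")
    prefix = Path(cfg.out_prefix)
    outputs = {
        "clusters": prefix.with_name(prefix.name + ".clusters.tsv"),
        "representatives": prefix.with_name(prefix.name + ".representatives.tsv"),
        "panel": prefix.with_name(prefix.name + ".panel.tsv"),
        "heatmap": prefix.with_name(prefix.name + f".heatmap.{cfg.image_format}"),
        "config": prefix.with_name(prefix.name + ".config.yaml"),
        "log": prefix.with_name(prefix.name + ".log"),
    }
    _atomic_write(outputs["clusters"], "\n".join(cluster_lines) + "\n")
    _atomic_write(outputs["representatives"], summ.representatives_tsv(g, rep_sets))
    _atomic_write(outputs["panel"], summ.panel_tsv(g, panel))
    _atomic_write(outputs["config"], cfg.to_yaml())

    from .viz import render_heatmap  # deferred: matplotlib import is slow
    render_heatmap(S, assignment, ranks, rep_sets, panel, g,
                   order=order, path=outputs["heatmap"],
                   image_format=cfg.image_format, max_display=cfg.max_display)
    stage(f"render: {outputs['heatmap'].name}")
    _atomic_write(outputs["log"], "\n".join(log_lines) + "\n")
    return outputs
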