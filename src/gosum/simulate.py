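"""Synthetic inputs with known ground truth.

Everything the pipeline consumes can be generated here so the whole
tool is exercisable offline: random rooted DAG ontologies (with a
round-trippable OBO serialisation), planted-block similarity matrices
(the standard ground-truthed substrate for judging cluster recovery),
and synthetic enrichment tables.  All generators are deterministic
given their seed; seeds are mandatory, there is no global randomness.

The planted-block generator enforces its separation constraint
(within-block low end strictly above between-block high end) by
default so that recovery tests are well-posed; it can be disabled for
fuzzing, where no recovery guarantee holds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError
from .genesets import GeneSetCollection, write_gmt
from .ontology import OntologyGraph, build_ontology, parse_obo, TermRecord
from .similarity import SimilarityMatrix
from .summarize import EnrichmentTable


@dataclass
class DagSpec:
    """Shape of a random rooted DAG ontology."""

    n_terms: int = 50
    max_parents: int = 3
    depth_target: int = 5
    seed: int = 1
    part_of_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.n_terms < 2:
            raise InputError(f"n_terms must be >= 2, got {self.n_terms}")
        if self.max_parents < 1:
            raise InputError("max_parents must be >= 1")
        if self.depth_target < 2:
            raise InputError("depth_target must be >= 2")


def synth_dag(spec: DagSpec) -> tuple[OntologyGraph, str]:
    """Random single-rooted DAG plus its OBO serialisation.

    Terms are added in level order: each non-root term draws a target
    level in 2..depth_target, takes one parent uniformly from the level
    above it and up to ``max_parents - 1`` extra parents uniformly from
    all earlier terms.  Acyclicity and single-rootedness hold by
    construction; ``parse_obo`` of the emitted text reproduces the
    graph exactly.
    """
    rng = np.random.default_rng(spec.seed)
    ids = [f"T{i:04d}" for i in range(1, spec.n_terms + 1)]
    root = ids[0]
    levels = {root: 1}
    edges: set[tuple[str, str, str]] = set()
    by_level: dict[int, list[str]] = {1: [root]}

    for i, tid in enumerate(ids[1:], start=1):
        max_level = max(by_level) + 1
        desired = int(rng.integers(2, min(spec.depth_target, max_level) + 1))
        primary = by_level[desired - 1][int(rng.integers(len(by_level[desired - 1])))]
        parents = {primary}
        n_extra = int(rng.integers(0, spec.max_parents))
        pool = [t for t in ids[:i] if t != primary]
        if pool and n_extra:
            extra = rng.choice(len(pool), size=min(n_extra, len(pool)),
                               replace=False)
            parents |= {pool[int(j)] for j in extra}
        level = 1 + min(levels[p] for p in parents)
        levels[tid] = level
        by_level.setdefault(level, []).append(tid)
        for p in parents:
            rel = "part_of" if rng.random() < spec.part_of_fraction else "is_a"
            edges.add((tid, p, rel))

    terms = {
        tid: TermRecord(term_id=tid, name=f"synthetic term {tid[1:]}",
                        namespace="synthetic")
        for tid in ids
    }
    graph = build_ontology(terms, edges)
    return graph, serialize_obo(graph)


def serialize_obo(g: OntologyGraph) -> str:
    """OBO text that parse_obo maps back to the same structure."""
    parents: dict[str, list[tuple[str, str]]] = {}
    for child, parent, rel in sorted(g.edges):
        parents.setdefault(child, []).append((parent, rel))
    chunks = ["format-version: 1.2", ""]
    for tid in sorted(g.terms):
        rec = g.terms[tid]
        lines = [f"[Term]", f"id: {tid}", f"name: {rec.name}",
                 f"namespace: {rec.namespace}"]
        if rec.is_obsolete:
            lines.append("is_obsolete: true")
        else:
            for parent, rel in parents.get(tid, []):
                pname = g.terms[parent].name
                if rel == "is_a":
                    lines.append(f"is_a: {parent} ! {pname}")
                else:
                    lines.append(f"relationship: {rel} {parent} ! {pname}")
        chunks.append("\n".join(lines))
        chunks.append("")
    return "\n".join(chunks)


@dataclass
class BlockSpec:
    """Planted-block similarity matrix: sizes and similarity ranges.

    Defaults match the conditions under which cluster recovery is
    well-posed for the default binary-cut cutoff of 0.85: block mean
    similarity (0.89) sits above the cutoff with margin even for small
    blocks, and the separation constraint within.lo > between.hi is
    enforced.
    """

    block_sizes: list[int] = field(default_factory=lambda: [10, 10, 10])
    within_range: tuple[float, float] = (0.80, 0.98)
    between_range: tuple[float, float] = (0.0, 0.20)
    seed: int = 1
    enforce_separation: bool = True

    def __post_init__(self) -> None:
        if not self.block_sizes:
            raise InputError("block_sizes must be non-empty")
        if any(s < 1 for s in self.block_sizes):
            raise InputError("block sizes must be positive")
        for lo, hi in (self.within_range, self.between_range):
            if not (0.0 <= lo <= hi <= 1.0):
                raise InputError("ranges must satisfy 0 <= lo <= hi <= 1")
        if self.enforce_separation and not (
            self.within_range[0] > self.between_range[1]
        ):
            raise InputError(
                "within_range.lo must exceed between_range.hi "
                "(set enforce_separation=False to fuzz without a "
                "recovery guarantee)"
            )


def synth_similarity(spec: BlockSpec) -> tuple[SimilarityMatrix, np.ndarray]:
    """Planted-block matrix and its true 0-based labels."""
    rng = np.random.default_rng(spec.seed)
    n = sum(spec.block_sizes)
    labels = np.repeat(np.arange(len(spec.block_sizes)), spec.block_sizes)
    vals = np.ones((n, n))
    wlo, whi = spec.within_range
    blo, bhi = spec.between_range
    for i in range(n):
        for j in range(i + 1, n):
            if labels[i] == labels[j]:
                v = rng.uniform(wlo, whi)
            else:
                v = rng.uniform(blo, bhi)
            vals[i, j] = vals[j, i] = v
    ids = [f"B{labels[i]}_{i:03d}" for i in range(n)]
    return SimilarityMatrix(term_ids=ids, values=vals), labels


def synth_enrichment(
    g: OntologyGraph,
    n_terms: int,
    score_type: str = "nes",
    seed: int = 1,
    sign: int = 1,
) -> EnrichmentTable:
    """Random enrichment table over terms of ``g``.

    NES scores are drawn uniformly from 1..3 (times ``sign``, a single
    sign per table as the sign rule requires); overlap proportions from
    (0, 1].  Adjusted p-values are drawn uniformly below 0.05, mimicking
    a pre-filtered significant set.
    """
    rng = np.random.default_rng(seed)
    pool = sorted(g.active_terms)
    if n_terms > len(pool):
        raise InputError(
            f"cannot sample {n_terms} terms from a {len(pool)}-term ontology"
        )
    if sign not in (1, -1):
        raise InputError("sign must be +1 or -1")
    chosen = sorted(rng.choice(len(pool), size=n_terms, replace=False))
    terms = [pool[i] for i in chosen]
    if score_type == "nes":
        scores = sign * rng.uniform(1.0, 3.0, size=n_terms)
    elif score_type == "overlap":
        scores = 1.0 - rng.uniform(0.0, 1.0, size=n_terms)  # (0, 1]
    else:
        raise InputError(f"unknown score_type {score_type!r}")
    df = pd.DataFrame({
        "term_id": terms,
        "score": scores,
        "padj": rng.uniform(0.0, 0.05, size=n_terms),
    })
    return EnrichmentTable(data=df, score_type=score_type)


def synth_annotations(g: OntologyGraph, genes_per_term: tuple[int, int] = (1, 10),
                      seed: int = 1) -> GeneSetCollection:
    """Random direct gene annotations per leaf-ish term, as a GMT-able
    collection (set names are term ids)."""
    rng = np.random.default_rng(seed)
    lo, hi = genes_per_term
    sets = {}
    for tid in sorted(g.active_terms):
        k = int(rng.integers(lo, hi + 1))
        genes = {f"GENE{int(x):05d}" for x in rng.integers(0, 5000, size=k)}
        sets[tid] = frozenset(genes)
    return GeneSetCollection(sets=sets, source_label="synthetic annotations")


def write_fixture_dir(
    out_dir: str | Path,
    dag_spec: DagSpec,
    n_enrich: int,
    score_type: str = "nes",
) -> dict[str, Path]:
    """Write a complete synthetic input bundle (OBO, enrichment TSV,
    annotation GMT) under ``out_dir``; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    g, obo_text = synth_dag(dag_spec)
    table = synth_enrichment(g, n_enrich, score_type=score_type,
                             seed=dag_spec.seed)
    ann = synth_annotations(g, seed=dag_spec.seed)
    paths = {
        "obo": out / "ontology.obo",
        "enrichment": out / "enrichment.tsv",
        "annotations": out / "annotations.gmt",
    }
    paths["obo"].write_text(obo_text)
    paths["enrichment"].write_text(table.to_tsv())
    paths["annotations"].write_text(write_gmt(ann))
    return paths
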