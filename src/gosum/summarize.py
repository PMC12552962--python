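"""Cluster summarisation: representative terms, broad-term panel, ranking.

After clustering, each cluster is labelled by *representative terms*:
repeatedly pick the deepest-level common ancestor that covers enough of
the still-uncovered members ("highest-level" meaning most specific —
the point is to escape overly general labels), remove the covered
members, and repeat.  A shallow *broad-term panel* gives the complement:
for each term at a small ontology level, the percentage of input terms
that descend from it.  Clusters are ranked by the magnitude of their
mean enrichment score (NES from GSEA or gene-overlap proportion from
ORA), which drives heatmap display order.

NES tables must be single-signed: up- and down-regulated terms belong
to separate analyses, so mixed-sign input is rejected outright.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .clustering import ClusterAssignment
from .errors import InputError, StructuralError
from .ontology import OntologyGraph

SCORE_TYPES = ("nes", "overlap")

SIGN_RULE_MESSAGE = (
    "mixed-sign NES scores: terms with positive and negative NES must be "
    "summarised in separate analyses (one run per sign)"
)


@dataclass
class EnrichmentTable:
    """Significant terms with their quantitative score.

    ``data`` columns: term_id, score, optionally padj and genes (a list
    per row).  ``score_type`` is "nes" (signed, single sign per table)
    or "overlap" (proportion in [0, 1]).
    """

    data: pd.DataFrame
    score_type: str = "nes"

    def __post_init__(self) -> None:
        df = self.data
        for colname in ("term_id", "score"):
            if colname not in df.columns:
                raise InputError(f"enrichment table lacks column {colname!r}")
        if df["term_id"].duplicated().any():
            dupes = sorted(df.loc[df["term_id"].duplicated(), "term_id"])
            raise InputError(f"duplicated term ids in enrichment table: {dupes[:5]}")
        if self.score_type not in SCORE_TYPES:
            raise InputError(
                f"score_type must be one of {SCORE_TYPES}, got {self.score_type!r}"
            )
        scores = df["score"].to_numpy(dtype=float)
        if np.isnan(scores).any():
            raise InputError("enrichment scores contain NaN")
        if self.score_type == "overlap":
            if scores.min() < 0 or scores.max() > 1:
                raise InputError("overlap proportions must lie in [0, 1]")
        else:
            if (scores > 0).any() and (scores < 0).any():
                raise InputError(SIGN_RULE_MESSAGE)
        if "padj" in df.columns:
            padj = df["padj"].dropna().to_numpy(dtype=float)
            if len(padj) and (padj.min() < 0 or padj.max() > 1):
                raise InputError("adjusted p-values must lie in [0, 1]")

    @property
    def term_ids(self) -> list[str]:
        return list(self.data["term_id"])

    def score_of(self, term_id: str) -> float:
        row = self.data.loc[self.data["term_id"] == term_id, "score"]
        if row.empty:
            raise InputError(f"term {term_id!r} not in enrichment table")
        return float(row.iloc[0])

    def __len__(self) -> int:
        return len(self.data)

    @classmethod
    def read_tsv(cls, text: str, score_type: str = "nes") -> "EnrichmentTable":
        """Read a TSV with columns term_id, score[, padj][, genes]
        (genes comma-separated)."""
        df = pd.read_csv(io.StringIO(text), sep="\t", dtype={"term_id": str})
        if "genes" in df.columns:
            df["genes"] = df["genes"].map(
                lambda v: [] if pd.isna(v) else str(v).split(",")
            )
        return cls(data=df, score_type=score_type)

    def to_tsv(self) -> str:
        df = self.data.copy()
        if "genes" in df.columns:
            df["genes"] = df["genes"].map(
                lambda v: ",".join(v) if isinstance(v, (list, tuple)) else v
            )
        return df.to_csv(sep="\t", index=False)


# -- representative terms -----------------------------------------------------

@dataclass(frozen=True)
class Representative:
    term_id: str
    level: int
    covered: frozenset[str]
    is_member: bool  # False when the representative is a pure ancestor


@dataclass
class RepresentativeSet:
    cluster: int | None
    representatives: list[Representative] = field(default_factory=list)

    @property
    def covered_union(self) -> set[str]:
        out: set[str] = set()
        for rep in self.representatives:
            out |= rep.covered
        return out


def representative_terms(
    g: OntologyGraph,
    cluster_members: Iterable[str],
    min_cover: int = 2,
    min_level: int = 3,
    max_reps: int = 5,
    cluster: int | None = None,
) -> RepresentativeSet:
    """Greedy deepest-common-ancestor cover of one cluster.

    Each round scans every ancestor-or-self of the uncovered members,
    keeps candidates at level >= ``min_level`` covering at least
    ``min_cover`` uncovered members, and selects the one maximising
    (level, coverage, lexicographically smallest id) in that priority.
    Covered members are removed and the loop repeats until the cluster
    is covered, no candidate qualifies, or ``max_reps`` representatives
    were selected; leftover members then represent themselves.  The
    covered sets partition the cluster (first cover wins).
    """
    members = sorted(set(cluster_members))
    if not members:
        raise InputError("cluster is empty")
    if min_cover < 1:
        raise InputError(f"min_cover must be >= 1, got {min_cover}")
    for t in members:
        if t not in g.active_terms:
            raise InputError(f"cluster member {t!r} not in ontology")
    member_set = set(members)

    uncovered = set(members)
    reps: list[Representative] = []
    while uncovered and len(reps) < max_reps:
        cover: dict[str, set[str]] = {}
        for t in uncovered:
            for a in g.ancestors(t) | {t}:
                if g.levels[a] >= min_level:
                    cover.setdefault(a, set()).add(t)
        qualified = [(a, c) for a, c in cover.items() if len(c) >= min_cover]
        if not qualified:
            break
        qualified.sort(key=lambda ac: (-g.levels[ac[0]], -len(ac[1]), ac[0]))
        best, best_cover = qualified[0]
        reps.append(Representative(
            term_id=best, level=g.levels[best],
            covered=frozenset(best_cover),
            is_member=best in member_set,
        ))
        uncovered -= best_cover
    for t in sorted(uncovered):
        reps.append(Representative(term_id=t, level=g.levels[t],
                                   covered=frozenset({t}), is_member=True))
    return RepresentativeSet(cluster=cluster, representatives=reps)


def representatives_tsv(g: OntologyGraph,
                        rep_sets: Sequence[RepresentativeSet]) -> str:
    lines = ["cluster\trank\tterm_id\tname\tlevel\tis_member\tn_covered\tcovered_ids"]
    for rs in rep_sets:
        for rank, rep in enumerate(rs.representatives, 1):
            name = g.terms[rep.term_id].name if rep.term_id in g.terms else ""
            lines.append("\t".join([
                str(rs.cluster), str(rank), rep.term_id, name,
                str(rep.level), str(rep.is_member).lower(),
                str(len(rep.covered)), ",".join(sorted(rep.covered)),
            ]))
    return "\n".join(lines) + "\n"


# -- broad-term panel ---------------------------------------------------------

@dataclass
class BroadPanel:
    """Shallow terms annotated with the percentage of input terms that
    are descendant-or-self of each; entries need not sum to 100 because
    DAG terms may descend from several broad terms."""

    entries: list[tuple[str, float]]  # (broad_term_id, percentage in [0, 100])


def broad_term_panel(
    g: OntologyGraph,
    input_terms: Iterable[str],
    broad_level: int = 2,
    top_k: int = 8,
) -> BroadPanel:
    """Percentage of input terms under each term at ``broad_level``.

    Returns the ``top_k`` entries by percentage (ties broken by term
    id); zero-percentage broad terms are dropped.
    """
    terms = sorted(set(input_terms))
    if not terms:
        raise InputError("input term set is empty")
    if broad_level < 2:
        raise InputError(f"broad_level must be >= 2, got {broad_level}")
    for t in terms:
        if t not in g.active_terms:
            raise InputError(f"input term {t!r} not in ontology")
    broad = g.terms_at_level(broad_level)
    if not broad:
        raise StructuralError(f"ontology has no term at level {broad_level}")
    closures = {t: g.ancestors(t) | {t} for t in terms}
    n = len(terms)
    entries = []
    for b in broad:
        count = sum(1 for t in terms if b in closures[t])
        if count:
            entries.append((b, 100.0 * count / n))
    entries.sort(key=lambda e: (-e[1], e[0]))
    return BroadPanel(entries=entries[:top_k])


def panel_tsv(g: OntologyGraph, panel: BroadPanel) -> str:
    lines = ["broad_term_id\tname\tpercentage"]
    for tid, pct in panel.entries:
        lines.append(f"{tid}\t{g.terms[tid].name}\t{pct:.4f}")
    return "\n".join(lines) + "\n"


# -- cluster ranking ----------------------------------------------------------

@dataclass(frozen=True)
class ClusterRank:
    cluster: int
    mean_score: float
    size: int


def rank_clusters(table: EnrichmentTable,
                  assignment: ClusterAssignment) -> list[ClusterRank]:
    """Order clusters by descending |mean score|.

    Magnitude ordering keeps negative-NES analyses ranked by strength
    of enrichment; ties prefer the larger cluster, then the smaller
    cluster index.  Every clustered term must carry a score.
    """
    scores: Mapping[str, float] = dict(
        zip(table.data["term_id"], table.data["score"].astype(float))
    )
    by_cluster: dict[int, list[float]] = {}
    for term, c in assignment.labels.items():
        if term not in scores:
            raise InputError(
                f"clustered term {term!r} is missing from the enrichment table"
            )
        by_cluster.setdefault(c, []).append(scores[term])
    ranks = [
        ClusterRank(cluster=c, mean_score=float(np.mean(vals)), size=len(vals))
        for c, vals in by_cluster.items()
    ]
    ranks.sort(key=lambda r: (-abs(r.mean_score), -r.size, r.cluster))
    return ranks
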