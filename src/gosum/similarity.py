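"""Semantic-similarity matrices over ontology terms.

The clustering substrate is a symmetric term-by-term matrix of pairwise
semantic similarity in [0, 1].  Similarity is computed from the
information content (IC) of the most informative common ancestor
(MICA): with p(t) the probability mass of a term, ic(t) = -ln p(t),
the supported measures are

* ``lin``          2 ic(MICA) / (ic(t1) + ic(t2))
* ``rel``          lin * (1 - exp(-ic(MICA)))      (Schlicker relevance)
* ``resnik_norm``  ic(MICA) / max ic over the ontology
* ``jaccard_anc``  |A1 & A2| / |A1 | A2| on ancestor-or-self closures

IC comes either from an annotation corpus (p(t) = genes annotated to t
or any descendant, over all annotated genes) or, by default, from a
structural fallback based on descendant counts so the tool runs with no
corpus at all: p(t) = (|descendants(t)| + 1) / N.  Both give ic(root)=0
and are monotone non-decreasing down the DAG.

The default measure is ``rel`` with structural IC; both are
configurable because different choices trade specificity differently
and no single convention dominates in practice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import InputError
from .ontology import OntologyGraph

logger = logging.getLogger(__name__)

MEASURES = ("rel", "lin", "resnik_norm", "jaccard_anc")
DEFAULT_MEASURE = "rel"

_ATOL = 1e-12


@dataclass
class InformationContent:
    """Per-term information content in nats; ic(root) = 0."""

    ic: dict[str, float]

    @property
    def max_ic(self) -> float:
        return max(self.ic.values()) if self.ic else 0.0

    def __getitem__(self, term_id: str) -> float:
        return self.ic[term_id]


def information_content(
    g: OntologyGraph,
    annotations: Mapping[str, Iterable[str]] | None = None,
) -> InformationContent:
    """Information content for every non-obsolete term of ``g``.

    With ``annotations`` (term -> gene set), annotations propagate to
    all ancestors and p(t) is the propagated gene count over the corpus
    size; terms left with zero propagated count get a pseudo-count of 1
    (logged).  Without annotations, the structural fallback
    ic(t) = -ln((|descendants(t)| + 1) / N) is used.
    """
    active = g.active_terms
    if annotations is None:
        n = len(active)
        ic = {
            t: -np.log((len(g.descendants(t)) + 1) / n) for t in active
        }
        return InformationContent(ic=ic)

    unknown = [t for t in annotations if t not in g.terms]
    if unknown:
        raise InputError(
            f"annotated terms not present in the ontology: {sorted(unknown)[:5]}"
        )
    propagated: dict[str, set[str]] = {t: set() for t in active}
    corpus: set[str] = set()
    for term, genes in annotations.items():
        genes = set(genes)
        corpus |= genes
        if term not in active:
            continue  # obsolete: contributes to the corpus only
        propagated[term] |= genes
        for anc in g.ancestors(term):
            propagated[anc] |= genes
    if not corpus:
        raise InputError("annotation corpus is empty")
    n_corpus = len(corpus)
    ic: dict[str, float] = {}
    n_zero = 0
    for t in active:
        count = len(propagated[t])
        if count == 0:
            count = 1  # pseudo-count keeps ic finite
            n_zero += 1
        ic[t] = -np.log(count / n_corpus)
    if n_zero:
        logger.warning(
            "%d terms had no propagated annotations; assigned pseudo-count 1",
            n_zero,
        )
    return InformationContent(ic=ic)


def _closure(g: OntologyGraph, t: str) -> frozenset[str]:
    return frozenset(g.ancestors(t) | {t})


def term_similarity(
    g: OntologyGraph,
    ic: InformationContent | None,
    t1: str,
    t2: str,
    measure: str = DEFAULT_MEASURE,
) -> float:
    """Pairwise semantic similarity in [0, 1]; symmetric in (t1, t2)."""
    if measure not in MEASURES:
        raise InputError(
            f"unknown similarity measure {measure!r}; choose from {MEASURES}"
        )
    a1, a2 = _closure(g, t1), _closure(g, t2)
    if measure == "jaccard_anc":
        union = a1 | a2
        return len(a1 & a2) / len(union) if union else 0.0
    if ic is None:
        raise InputError(f"measure {measure!r} requires information content")
    common = a1 & a2
    mica_ic = max(ic.ic[t] for t in common) if common else 0.0
    if measure == "resnik_norm":
        m = ic.max_ic
        return float(mica_ic / m) if m > 0 else 0.0
    denom = ic.ic[t1] + ic.ic[t2]
    lin = 2.0 * mica_ic / denom if denom > 0 else 0.0
    if measure == "lin":
        return float(lin)
    return float(lin * (1.0 - np.exp(-mica_ic)))  # rel


@dataclass
class SimilarityMatrix:
    """Symmetric term-by-term similarity in [0, 1] with unit diagonal."""

    term_ids: list[str]
    values: np.ndarray
    measure: str = DEFAULT_MEASURE

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.validate()

    def validate(self) -> None:
        n = len(self.term_ids)
        if len(set(self.term_ids)) != n:
            raise InputError("duplicate term ids in similarity matrix")
        v = self.values
        if v.shape != (n, n):
            raise InputError(
                f"matrix shape {v.shape} does not match {n} term ids"
            )
        if not np.allclose(v, v.T, atol=_ATOL):
            raise InputError("similarity matrix is not symmetric")
        if v.min() < -_ATOL or v.max() > 1 + _ATOL:
            raise InputError("similarity values outside [0, 1]")
        if not np.allclose(np.diag(v), 1.0, atol=_ATOL):
            raise InputError("similarity matrix diagonal must be 1")

    def __len__(self) -> int:
        return len(self.term_ids)

    def to_tsv(self) -> str:
        header = "term_id\t" + "\t".join(self.term_ids)
        rows = [header]
        for tid, row in zip(self.term_ids, self.values):
            rows.append(tid + "\t" + "\t".join(f"{x:.10g}" for x in row))
        return "\n".join(rows) + "\n"

    @classmethod
    def from_tsv(cls, text: str, measure: str = DEFAULT_MEASURE) -> "SimilarityMatrix":
        lines = [ln for ln in text.splitlines() if ln.strip()]
        ids = lines[0].split("\t")[1:]
        vals = np.array(
            [[float(x) for x in ln.split("\t")[1:]] for ln in lines[1:]]
        )
        return cls(term_ids=ids, values=vals, measure=measure)


def similarity_matrix(
    g: OntologyGraph,
    terms: Sequence[str],
    measure: str = DEFAULT_MEASURE,
    ic: InformationContent | None = None,
) -> SimilarityMatrix:
    """Similarity matrix over an enrichment result's term set.

    ``terms`` may be an explicit id sequence or any object exposing
    ``term_ids`` (an enrichment table).  Terms absent from the ontology
    are dropped with a warning (recorded on the result as ``dropped``);
    duplicated ids are an error, and fewer than 2 retained terms is an
    error because clustering is undefined.
    """
    ids = list(getattr(terms, "term_ids", terms))
    if len(set(ids)) != len(ids):
        dupes = sorted({t for t in ids if ids.count(t) > 1})
        raise InputError(f"duplicated term ids in input: {dupes[:5]}")
    retained = [t for t in ids if t in g.active_terms]
    dropped = [t for t in ids if t not in g.active_terms]
    if dropped:
        logger.warning(
            "%d input terms absent from the ontology were dropped: %s%s",
            len(dropped), dropped[:5], "..." if len(dropped) > 5 else "",
        )
    if len(retained) < 2:
        raise InputError(
            f"need at least 2 ontology terms to build a matrix, got {len(retained)}"
        )
    if measure not in MEASURES:
        raise InputError(
            f"unknown similarity measure {measure!r}; choose from {MEASURES}"
        )
    if measure != "jaccard_anc" and ic is None:
        ic = information_content(g)

    # vectorise over a boolean ancestor-or-self incidence matrix
    universe = sorted(g.active_terms)
    col = {t: j for j, t in enumerate(universe)}
    m, n_all = len(retained), len(universe)
    anc = np.zeros((m, n_all), dtype=bool)
    for i, t in enumerate(retained):
        for a in g.ancestors(t) | {t}:
            anc[i, col[a]] = True

    if measure == "jaccard_anc":
        sizes = anc.sum(axis=1).astype(float)
        inter = (anc.astype(np.float64) @ anc.T.astype(np.float64))
        union = sizes[:, None] + sizes[None, :] - inter
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = np.where(union > 0, inter / union, 0.0)
    else:
        ic_vec = np.array([ic.ic[t] for t in universe])
        ic_self = np.array([ic.ic[t] for t in retained])
        mica = np.empty((m, m))
        for i in range(m):
            masked = np.where(anc[i][None, :] & anc, ic_vec[None, :], -np.inf)
            row = masked.max(axis=1)
            mica[i] = np.where(np.isfinite(row), row, 0.0)
        mica = np.maximum(mica, 0.0)
        if measure == "resnik_norm":
            mx = ic.max_ic
            vals = mica / mx if mx > 0 else np.zeros_like(mica)
        else:
            denom = ic_self[:, None] + ic_self[None, :]
            with np.errstate(invalid="ignore", divide="ignore"):
                lin = np.where(denom > 0, 2.0 * mica / denom, 0.0)
            vals = lin if measure == "lin" else lin * (1.0 - np.exp(-mica))

    vals = np.clip((vals + vals.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(vals, 1.0)
    result = SimilarityMatrix(term_ids=retained, values=vals, measure=measure)
    result.dropped = dropped
    return result
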