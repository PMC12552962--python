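"""Gene-set collections (GMT) and cross-collection overlap analysis.

The overlap between two collections (e.g. GO Biological Process gene
sets against the MSigDB Hallmark collection) is summarised as a matrix
of proportions |A_i & B_j| / |A_i| — *row-relative*, i.e. the fraction
of the row set's genes found in the column set, so a value of 1 means
the row set is entirely contained in the column set.  A row set is
called "included" in the other collection when its best column reaches
a containment threshold (default 0.8).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError, ParseError


@dataclass
class GeneSetCollection:
    """Named gene sets; names unique, every set non-empty."""

    sets: dict[str, frozenset[str]]
    source_label: str = ""

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise InputError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    @property
    def names(self) -> list[str]:
        return list(self.sets)


def read_gmt(gmt_text: str, source_label: str = "",
             fold_case: bool = False) -> GeneSetCollection:
    """Parse GMT (one set per line: name, description, genes...).

    Duplicate genes within a line are deduplicated; empty gene tokens
    are dropped; case is preserved unless ``fold_case``.  Lines with
    fewer than 3 fields and duplicate set names are errors naming the
    line.
    """
    sets: dict[str, frozenset[str]] = {}
    for lineno, raw in enumerate(gmt_text.splitlines(), 1):
        if not raw.strip():
            continue
        fields = raw.split("\t")
        if len(fields) < 3:
            raise ParseError(
                f"line {lineno}: GMT line needs >= 3 tab-separated fields, "
                f"got {len(fields)}"
            )
        name = fields[0].strip()
        if name in sets:
            raise ParseError(f"line {lineno}: duplicate set name {name!r}")
        genes = {g.strip() for g in fields[2:] if g.strip()}
        if fold_case:
            genes = {g.upper() for g in genes}
        if not genes:
            raise ParseError(f"line {lineno}: gene set {name!r} is empty")
        sets[name] = frozenset(genes)
    if not sets:
        raise ParseError("GMT document contains no gene set")
    return GeneSetCollection(sets=sets, source_label=source_label)


def write_gmt(collection: GeneSetCollection, description: str = "na") -> str:
    lines = []
    for name, genes in collection.sets.items():
        lines.append("\t".join([name, description, *sorted(genes)]))
    return "\n".join(lines) + "\n"


@dataclass
class OverlapMatrix:
    """Row-relative overlap proportions between two collections.

    ``values.loc[a, b] = |A_a & B_b| / |A_a|``; not symmetric in
    general.  ``orientation`` records the denominator convention.
    """

    values: pd.DataFrame
    orientation: str = "row"

    @property
    def row_names(self) -> list[str]:
        return list(self.values.index)

    @property
    def col_names(self) -> list[str]:
        return list(self.values.columns)

    def to_tsv(self) -> str:
        header = f"# orientation: proportions relative to the ROW set size\n"
        return header + self.values.to_csv(sep="\t", index_label="row_set")


def overlap_matrix(a: GeneSetCollection, b: GeneSetCollection) -> OverlapMatrix:
    """Proportion of each row set's genes contained in each column set."""
    if not len(a) or not len(b):
        raise InputError("both collections must be non-empty")
    genes = sorted(set().union(*a.sets.values(), *b.sets.values()))
    col = {g: j for j, g in enumerate(genes)}
    ma = np.zeros((len(a), len(genes)), dtype=np.float64)
    for i, name in enumerate(a.names):
        for g in a.sets[name]:
            ma[i, col[g]] = 1.0
    mb = np.zeros((len(b), len(genes)), dtype=np.float64)
    for j, name in enumerate(b.names):
        for g in b.sets[name]:
            mb[j, col[g]] = 1.0
    inter = ma @ mb.T
    sizes = ma.sum(axis=1)
    props = inter / sizes[:, None]
    df = pd.DataFrame(props, index=a.names, columns=b.names)
    return OverlapMatrix(values=df)


def inclusion_calls(m: OverlapMatrix,
                    threshold: float = 0.8) -> list[tuple[str, str, float]]:
    """Rows whose best column overlap reaches the threshold (>=).

    Returns ``(row set, argmax column, proportion)`` per included row;
    argmax ties break lexicographically by column name.
    """
    if not 0.0 < threshold <= 1.0:
        raise InputError(f"threshold must be in (0, 1], got {threshold}")
    calls = []
    vals = m.values
    for row in vals.index:
        series = vals.loc[row]
        best = float(series.max())
        if best >= threshold:
            best_col = min(c for c in vals.columns if series[c] == best)
            calls.append((row, best_col, best))
    return calls


def inclusion_tsv(calls: list[tuple[str, str, float]]) -> str:
    lines = ["row_set\tbest_col_set\tproportion"]
    for row, colname, prop in calls:
        lines.append(f"{row}\t{colname}\t{prop:.6g}")
    return "\n".join(lines) + "\n"
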