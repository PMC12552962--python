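"""Annotated similarity heatmap.

One figure: the clustered similarity matrix with white cluster
boundaries, the broad-term percentages as a bar panel above, and each
cluster's representative terms listed on the right at the cluster's
vertical midpoint (falling back to the cluster index when a cluster has
no representatives).  Rows and columns follow cluster rank order, with
within-cluster dendrogram leaf ordering supplied by the caller.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .clustering import ClusterAssignment
from .errors import InputError
from .ontology import OntologyGraph
from .similarity import SimilarityMatrix
from .summarize import BroadPanel, ClusterRank, RepresentativeSet

IMAGE_FORMATS = ("png", "svg", "pdf")


def render_heatmap(
    S: SimilarityMatrix,
    assignment: ClusterAssignment,
    ranks: Sequence[ClusterRank],
    rep_sets: Sequence[RepresentativeSet],
    panel: BroadPanel,
    g: OntologyGraph | None,
    order: Sequence[int],
    path: str | Path,
    image_format: str = "png",
    max_display: int = 2000,
) -> Path:
    if image_format not in IMAGE_FORMATS:
        raise InputError(f"image format must be one of {IMAGE_FORMATS}")
    n = len(S)
    if n > max_display:
        raise InputError(
            f"{n} terms exceed the display limit of {max_display}; "
            "pre-filter the enrichment table before plotting"
        )
    if len(order) != n:
        raise InputError("display order does not cover the term set")

    V = S.values[order][:, order]
    labels_in_order = [assignment.labels[S.term_ids[i]] for i in order]

    fig = plt.figure(figsize=(10, 8))
    gs = fig.add_gridspec(2, 2, width_ratios=[4, 2], height_ratios=[1, 5],
                          hspace=0.08, wspace=0.04)
    ax_panel = fig.add_subplot(gs[0, 0])
    ax_heat = fig.add_subplot(gs[1, 0])
    ax_reps = fig.add_subplot(gs[1, 1])

    ax_heat.imshow(V, cmap="Reds", vmin=0.0, vmax=1.0, aspect="auto",
                   interpolation="nearest")
    # cluster block boundaries
    bounds = [i for i in range(1, n) if labels_in_order[i] != labels_in_order[i - 1]]
    for b in bounds:
        ax_heat.axhline(b - 0.5, color="white", lw=1.2)
        ax_heat.axvline(b - 0.5, color="white", lw=1.2)
    ax_heat.set_xticks([])
    ax_heat.set_yticks([])
    ax_heat.set_xlabel(f"{n} terms, {assignment.n_clusters} clusters "
                       f"({assignment.method})")

    # broad-term bar panel
    if panel.entries:
        names = []
        for tid, _ in panel.entries:
            label = g.terms[tid].name if g and tid in g.terms else tid
            names.append(label if len(label) <= 28 else label[:25] + "...")
        pcts = [pct for _, pct in panel.entries]
        ax_panel.bar(range(len(pcts)), pcts, color="#4878a8")
        for x, pct in enumerate(pcts):
            ax_panel.text(x, pct, f"{pct:.0f}%", ha="center", va="bottom",
                          fontsize=7)
        ax_panel.set_xticks(range(len(names)))
        ax_panel.set_xticklabels(names, rotation=30, ha="right", fontsize=6)
        ax_panel.set_ylabel("% of terms", fontsize=7)
        ax_panel.set_ylim(0, max(pcts) * 1.3)
    else:
        ax_panel.axis("off")

    # right panel: representative terms per cluster, at block midpoints
    ax_reps.set_ylim(n - 0.5, -0.5)
    ax_reps.set_xlim(0, 1)
    ax_reps.axis("off")
    block_start = 0
    reps_by_cluster = {rs.cluster: rs for rs in rep_sets}
    for end in bounds + [n]:
        cluster = labels_in_order[block_start]
        mid = (block_start + end - 1) / 2.0
        rs = reps_by_cluster.get(cluster)
        if rs and rs.representatives:
            lines = []
            for rep in rs.representatives[:3]:
                name = (g.terms[rep.term_id].name
                        if g and rep.term_id in g.terms else rep.term_id)
                lines.append(name if len(name) <= 40 else name[:37] + "...")
            text = "\n".join(lines)
        else:
            text = f"cluster {cluster}"
        ax_reps.text(0.02, mid, f"[{cluster}] {text}", va="center",
                     fontsize=6, family="sans-serif")
        block_start = end

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, format=image_format, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path


def render_overlap_heatmap(values, path: str | Path,
                           image_format: str = "png") -> Path:
    """Simple annotated heatmap for a cross-collection overlap matrix."""
    if image_format not in IMAGE_FORMATS:
        raise InputError(f"image format must be one of {IMAGE_FORMATS}")
    fig, ax = plt.subplots(figsize=(8, max(3, 0.15 * values.shape[0])))
    im = ax.imshow(values.to_numpy(), cmap="Reds", vmin=0, vmax=1,
                   aspect="auto", interpolation="nearest")
    ax.set_yticks(range(values.shape[0]))
    ax.set_yticklabels(values.index, fontsize=5)
    ax.set_xticks(range(values.shape[1]))
    ax.set_xticklabels(values.columns, rotation=90, fontsize=5)
    fig.colorbar(im, ax=ax, label="overlap proportion (row-relative)")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, format=image_format, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path
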