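"""Independent brute-force oracles.

Deliberately naive re-implementations (plain dicts, explicit loops, no
graph library) used to cross-check the package: breadth-first levels,
transitive-closure ancestry, exhaustive-MICA similarity, pair-enumeration
difference score, round-by-round greedy representative selection and
set-intersection overlap.  Nothing here imports the implementation
paths it checks.
"""

from __future__ import annotations

import math
from collections import deque


def parent_map(edges):
    """child -> set of parents from (child, parent, relation) triples."""
    out: dict[str, set[str]] = {}
    for child, parent, _rel in edges:
        out.setdefault(child, set()).add(parent)
    return out


def bfs_levels(edges, root):
    """Levels by breadth-first search from the root along parent->child."""
    children: dict[str, set[str]] = {}
    nodes = {root}
    for child, parent, _rel in edges:
        children.setdefault(parent, set()).add(child)
        nodes.update((child, parent))
    levels = {root: 1}
    queue = deque([root])
    while queue:
        node = queue.popleft()
        for ch in children.get(node, ()):
            if ch not in levels:
                levels[ch] = levels[node] + 1
                queue.append(ch)
    return levels


def closure_ancestors(edges, term):
    """Transitive closure of the parent relation, excluding the term."""
    parents = parent_map(edges)
    seen: set[str] = set()
    stack = list(parents.get(term, ()))
    while stack:
        p = stack.pop()
        if p not in seen:
            seen.add(p)
            stack.extend(parents.get(p, ()))
    return seen


def closure_descendants(edges, term, all_terms):
    return {t for t in all_terms
            if t != term and term in closure_ancestors(edges, t)}


def structural_ic(edges, all_terms):
    """ic(t) = -ln((|descendants| + 1) / N) from brute-force closures."""
    n = len(all_terms)
    return {
        t: -math.log((len(closure_descendants(edges, t, all_terms)) + 1) / n)
        for t in all_terms
    }


def mica_similarity(edges, ic, t1, t2, measure):
    """Scan every common ancestor for the maximum-IC pivot."""
    a1 = closure_ancestors(edges, t1) | {t1}
    a2 = closure_ancestors(edges, t2) | {t2}
    common = a1 & a2
    if measure == "jaccard_anc":
        union = a1 | a2
        return len(common) / len(union) if union else 0.0
    mica = max((ic[t] for t in common), default=0.0)
    if measure == "resnik_norm":
        mx = max(ic.values())
        return mica / mx if mx > 0 else 0.0
    denom = ic[t1] + ic[t2]
    lin = 2.0 * mica / denom if denom > 0 else 0.0
    if measure == "lin":
        return lin
    return lin * (1.0 - math.exp(-mica))


def pairwise_difference_score(values, labels):
    """Double loop over all unordered pairs."""
    n = len(labels)
    within, between = [], []
    for i in range(n):
        for j in range(i + 1, n):
            (within if labels[i] == labels[j] else between).append(values[i][j])
    w = sum(within) / len(within) if within else 0.0
    b = sum(between) / len(between)
    return w - b


def greedy_representatives(edges, levels, members, min_cover, min_level,
                           max_reps):
    """Round-by-round greedy cover with full candidate re-enumeration.

    Returns a list of (term_id, covered frozenset) in selection order,
    residual members appended as self-representatives.
    """
    uncovered = set(members)
    chosen = []
    while uncovered and len(chosen) < max_reps:
        candidates = {}
        for t in uncovered:
            for a in closure_ancestors(edges, t) | {t}:
                if levels[a] >= min_level:
                    candidates.setdefault(a, set()).add(t)
        qualified = {a: c for a, c in candidates.items()
                     if len(c) >= min_cover}
        if not qualified:
            break
        best = None
        for a, cov in qualified.items():
            key = (levels[a], len(cov))
            if best is None:
                best = (a, cov)
                continue
            bkey = (levels[best[0]], len(best[1]))
            if key > bkey or (key == bkey and a < best[0]):
                best = (a, cov)
        chosen.append((best[0], frozenset(best[1])))
        uncovered -= best[1]
    for t in sorted(uncovered):
        chosen.append((t, frozenset({t})))
    return chosen


def overlap_proportions(sets_a, sets_b):
    """Row-relative overlap by explicit set intersection."""
    return {
        (na, nb): len(ga & gb) / len(ga)
        for na, ga in sets_a.items()
        for nb, gb in sets_b.items()
    }
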