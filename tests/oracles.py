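"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (explicit Python loops, no shared code
with the package beyond constant tables) so that agreement with the package
is meaningful.
"""

from __future__ import annotations

import numpy as np

from protraits.codons import REDUNDANCY_CLASSES, CLASS_WEIGHTS, SYNONYMOUS_FAMILIES


def enc_prime_bruteforce(counts: dict[str, int], background: dict[str, float]) -> float:
    """Naive ENC' following the definition amino acid by amino acid."""
    per_class: dict[int, list[float]] = {c: [] for c in REDUNDANCY_CLASSES}
    for aa, codons in SYNONYMOUS_FAMILIES.items():
        k = len(codons)
        if k < 2:
            continue
        n = sum(counts.get(c, 0) for c in codons)
        if n < 2:
            continue
        e = [background[c] for c in codons]
        if any((not np.isfinite(v)) or v <= 0 for v in e):
            continue
        chi2 = 0.0
        for c, ec in zip(codons, e):
            p = counts.get(c, 0) / n
            chi2 += (p - ec) ** 2 / ec
        chi2 *= n
        f_hat = (chi2 + n - k) / (k * (n - 1))
        if f_hat <= 0:
            continue
        per_class[k].append(f_hat)
    means = {c: sum(v) / len(v) for c, v in per_class.items() if v}
    if 2 not in means or 4 not in means:
        return float("nan")
    if 3 not in means:
        means[3] = (means[2] + means[4]) / 2
    if 6 not in means:
        means[6] = means[4]
    enc = 2.0
    for c in REDUNDANCY_CLASSES:
        enc += CLASS_WEIGHTS[c] / means[c]
    return min(61.0, max(20.0, enc))


def rank_average(values: np.ndarray) -> np.ndarray:
    """Average ranks with explicit tie handling."""
    order = np.argsort(values, kind="stable")
    ranks = np.empty(len(values), dtype=float)
    i = 0
    sorted_vals = values[order]
    while i < len(values):
        j = i
        while j + 1 < len(values) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def spearman_bruteforce(x: np.ndarray, y: np.ndarray) -> float:
    """Rank both vectors, then plain Pearson correlation."""
    rx, ry = rank_average(np.asarray(x, float)), rank_average(np.asarray(y, float))
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry)))


def mantel_class_r_bruteforce(
    D_phylo: np.ndarray, D_trait: np.ndarray, lo: float, hi: float
) -> float | None:
    """Mantel statistic of one distance class by explicit double loop.

    Returns the correlation between the class indicator and trait distance,
    negated so that positive values mean within-class trait distances are
    smaller than average.  None when the class is empty or saturated.
    """
    n = D_phylo.shape[0]
    ind, td = [], []
    for i in range(n):
        for j in range(i + 1, n):
            ind.append(1.0 if lo < D_phylo[i, j] <= hi else 0.0)
            td.append(D_trait[i, j])
    ind, td = np.array(ind), np.array(td)
    s = ind.sum()
    if s == 0 or s == len(ind):
        return None
    ic = ind - ind.mean()
    tc = td - td.mean()
    return float(-(ic @ tc) / np.sqrt((ic @ ic) * (tc @ tc)))


def vcv_bruteforce(tree) -> tuple[np.ndarray, list[str]]:
    """Phylogenetic covariance by explicit root-path enumeration (dendropy)."""
    leaves = list(tree.leaf_node_iter())
    labels = [l.taxon.label for l in leaves]

    def root_path(node):
        path = []
        while node is not None:
            path.append(node)
            node = node.parent_node
        return path[::-1]

    paths = [root_path(l) for l in leaves]
    n = len(leaves)
    V = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            shared = 0.0
            for a, b in zip(paths[i], paths[j]):
                if a is not b:
                    break
                shared += a.edge.length or 0.0
            V[i, j] = shared
    return V, labels


def connected_components_bruteforce(ids, edges):
    """Naive repeated-BFS connected components."""
    adj = {i: set() for i in ids}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    seen, comps = set(), []
    for start in ids:
        if start in seen:
            continue
        comp, stack = set(), [start]
        while stack:
            node = stack.pop()
            if node in comp:
                continue
            comp.add(node)
            stack.extend(adj[node] - comp)
        seen |= comp
        comps.append(frozenset(comp))
    return set(comps)
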