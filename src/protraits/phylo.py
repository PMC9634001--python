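"""Phylogenetic signal statistics and Brownian-motion trait prediction.

Implements Blomberg's K (with a tip-randomization permutation test),
Pagel's lambda (profile maximum likelihood with a boundary likelihood-ratio
test), Mantel correlograms over equal-width phylogenetic distance classes,
and generalized-least-squares hidden-state prediction of tip traits — the
machinery needed to judge whether a genomic trait tracks the phylogeny
closely enough to be extrapolated from marker genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy import optimize, stats


@dataclass
class Phylogeny:
    """Rooted tree with branch lengths; source of the covariance matrix V
    (shared root-path lengths) and patristic distance matrix D."""

    tree: dendropy.Tree
    _cache: dict = field(default_factory=dict, repr=False)

    @classmethod
    def from_newick(cls, path_or_string: str, *, is_path: bool = True) -> "Phylogeny":
        if is_path:
            tree = dendropy.Tree.get(path=path_or_string, schema="newick")
        else:
            tree = dendropy.Tree.get(data=path_or_string, schema="newick")
        return cls(tree)

    def to_newick(self) -> str:
        return self.tree.as_string(schema="newick").strip()

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def vcv(self) -> tuple[np.ndarray, np.ndarray, list[str]]:
        """(V, D, tip labels): see :func:`phylo_vcv`."""
        if "vcv" not in self._cache:
            self._cache["vcv"] = phylo_vcv(self)
        return self._cache["vcv"]


@dataclass
class PhyloSignalResult:
    statistic: str  # "K" | "lambda"
    estimate: float
    p: float
    n_tips: int
    detail: dict = field(default_factory=dict)

    def summary(self) -> str:
        return (
            f"{self.statistic} = {self.estimate:.4g} (n = {self.n_tips}, "
            f"p = {self.p:.4g})"
        )


@dataclass
class MantelCorrelogramResult:
    classes: pd.DataFrame  # lower, upper, n_pairs, r, p_raw, p_adj, significant
    max_pd: float
    alpha: float

    def summary(self) -> str:
        return (
            self.classes.round(4).to_string(index=False)
            + f"\nmax continuous significant distance: {self.max_pd}"
        )


def phylo_vcv(phylo: Phylogeny) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Phylogenetic covariance V and patristic distances D.

    V(i, j) is the root-path length shared by tips i and j (the depth of
    their most recent common ancestor); diag(V) holds root-to-tip distances;
    D(i, j) = V(i, i) + V(j, j) - 2 V(i, j).
    """
    tree = phylo.tree
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    V = np.zeros((n, n))

    # depth of every node; tips under every node, merging children pairwise
    depth: dict[int, float] = {}
    tips_below: dict[int, list[int]] = {}
    for node in tree.preorder_node_iter():
        el = node.edge.length
        if el is not None and el < 0:
            raise ValueError("negative branch length")
        parent_depth = depth.get(id(node.parent_node), 0.0)
        depth[id(node)] = parent_depth + (el or 0.0)
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            i = index[node.taxon.label]
            tips_below[id(node)] = [i]
            V[i, i] = depth[id(node)]
            continue
        children = [tips_below.pop(id(c)) for c in node.child_nodes()]
        d = depth[id(node)]
        for a in range(len(children)):
            for b in range(a + 1, len(children)):
                for i in children[a]:
                    V[i, children[b]] = d
                    V[children[b], i] = d
        tips_below[id(node)] = [i for ch in children for i in ch]
    diag = np.diag(V)
    D = diag[:, None] + diag[None, :] - 2.0 * V
    return V, D, labels


def _align(phylo: Phylogeny, values: pd.Series) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    V, D, labels = phylo.vcv()
    missing = [t for t in labels if t not in values.index]
    if missing:
        raise ValueError(f"trait values missing for tips: {missing[:5]}")
    x = values.loc[labels].to_numpy(dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("non-finite trait values")
    return V, D, x


def _k_mse(Vinv: np.ndarray, x: np.ndarray) -> tuple[float, float]:
    n = len(x)
    ones = np.ones(n)
    denom = ones @ Vinv @ ones
    a_hat = (ones @ Vinv @ x) / denom
    resid = x - a_hat
    mse0 = float(resid @ resid) / (n - 1)
    mse = float(resid @ Vinv @ resid) / (n - 1)
    return mse0, mse


def blomberg_K(
    phylo: Phylogeny,
    values: pd.Series,
    n_perm: int = 999,
    seed: int | None = None,
) -> PhyloSignalResult:
    """Blomberg's K with a tip-randomization permutation test.

    K is the ratio of observed to Brownian-expected (MSE0/MSE); K = 1 under
    Brownian motion, K < 1 for less and K > 1 for more phylogenetic signal
    than Brownian expectation.  The permutation test shuffles trait values
    across tips and counts how often the phylogenetically corrected MSE is
    as small as observed.
    """
    V, _, x = _align(phylo, values)
    if np.ptp(x) == 0:
        raise ValueError("trait is constant across tips")
    n = len(x)
    Vinv = np.linalg.inv(V)
    ones = np.ones(n)
    denom = float(ones @ Vinv @ ones)
    mse0, mse = _k_mse(Vinv, x)
    expected_ratio = (np.trace(V) - n / denom) / (n - 1)
    k = (mse0 / mse) / expected_ratio

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        xp = rng.permutation(x)
        _, mse_p = _k_mse(Vinv, xp)
        if mse_p <= mse:
            hits += 1
    p = (1.0 + hits) / (1.0 + n_perm)
    return PhyloSignalResult("K", float(k), p, n, {"n_perm": n_perm, "mse": mse})


def _lambda_negloglik(lam: float, V: np.ndarray, x: np.ndarray) -> float:
    n = len(x)
    W = lam * V + (1.0 - lam) * np.diag(np.diag(V))
    try:
        L = np.linalg.cholesky(W)
    except np.linalg.LinAlgError:
        return np.inf
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    ones = np.ones(n)
    sol_x = np.linalg.solve(L, x)
    sol_1 = np.linalg.solve(L, ones)
    a_hat = float(sol_1 @ sol_x) / float(sol_1 @ sol_1)
    r = sol_x - a_hat * sol_1
    sigma2 = float(r @ r) / n
    if sigma2 <= 0:
        return np.inf
    return 0.5 * (n * np.log(2.0 * np.pi * sigma2) + logdet + n)


def pagel_lambda(
    phylo: Phylogeny,
    values: pd.Series,
    lambda_max: float = 1.0,
    tol: float = 1e-8,
) -> PhyloSignalResult:
    """Pagel's lambda by profile maximum likelihood.

    V(lambda) scales the off-diagonal of the phylogenetic covariance by
    lambda; lambda = 0 erases the tree structure, lambda = 1 is plain
    Brownian motion.  The p-value is a likelihood-ratio test of
    lambda-hat vs lambda = 0 using the boundary-corrected
    0.5*chi2(0) + 0.5*chi2(1) mixture.
    """
    V, _, x = _align(phylo, values)
    if np.ptp(x) == 0:
        raise ValueError("trait is constant across tips")
    res = optimize.minimize_scalar(
        _lambda_negloglik,
        bounds=(0.0, lambda_max),
        args=(V, x),
        method="bounded",
        options={"xatol": tol},
    )
    candidates = {0.0: _lambda_negloglik(0.0, V, x),
                  lambda_max: _lambda_negloglik(lambda_max, V, x),
                  float(res.x): float(res.fun)}
    lam_hat = min(candidates, key=candidates.get)
    nll_hat, nll0 = candidates[lam_hat], candidates[0.0]
    lr = max(0.0, 2.0 * (nll0 - nll_hat))
    p = 1.0 if lr == 0 else 0.5 * float(stats.chi2.sf(lr, df=1))
    return PhyloSignalResult(
        "lambda", float(lam_hat), p, len(x),
        {"loglik": -nll_hat, "loglik_lambda0": -nll0, "lrt": lr},
    )


def mantel_correlogram(
    D_phylo: np.ndarray,
    D_trait: np.ndarray | None = None,
    trait: np.ndarray | None = None,
    class_width: float = 0.5,
    max_pd: float = 3.0,
    n_perm: int = 200,
    alpha: float = 0.1,
    seed: int | None = None,
) -> MantelCorrelogramResult:
    """Mantel correlogram over equal-width phylogenetic distance classes.

    For each class (lower, upper] the Mantel statistic correlates the class
    membership indicator with the trait distance matrix, with the sign
    convention that positive r means within-class trait distances are
    *smaller* than average (positive phylogenetic autocorrelation).
    Significance per class is by simultaneous row/column permutation of the
    trait distances (two-sided on |r|), Bonferroni-adjusted over the
    non-empty classes; a class is flagged significant when r > 0 and
    Padj < ``alpha``.  ``max_pd`` of the result is the largest class upper
    bound up to which every class is significant.
    """
    D_phylo = np.asarray(D_phylo, dtype=float)
    if D_trait is None:
        if trait is None:
            raise ValueError("provide D_trait or trait")
        t = np.asarray(trait, dtype=float)
        D_trait = np.abs(t[:, None] - t[None, :])
    D_trait = np.asarray(D_trait, dtype=float)
    if D_phylo.shape != D_trait.shape:
        raise ValueError("distance matrices must be conformable")
    n = D_phylo.shape[0]
    iu = np.triu_indices(n, k=1)
    d = D_phylo[iu]

    edges = np.arange(0.0, max_pd + 1e-12, class_width)
    bounds = [(edges[i], edges[i] + class_width) for i in range(len(edges))
              if edges[i] + class_width <= max_pd + 1e-9]
    masks, kept = [], []
    for lo, hi in bounds:
        m = (d > lo) & (d <= hi)
        if 0 < m.sum() < len(d):
            masks.append(m.astype(float))
            kept.append((lo, hi, int(m.sum())))
    if not masks:
        raise ValueError("no usable distance classes")
    M = np.vstack(masks)  # classes x pairs
    m_mean = M.mean(axis=1)
    m_sd = M.std(axis=1)

    def class_r(t_off: np.ndarray) -> np.ndarray:
        t_c = t_off - t_off.mean()
        sd_t = t_off.std()
        cov = (M @ t_c) / len(t_off)
        return -cov / (m_sd * sd_t)

    t_obs = D_trait[iu]
    r_obs = class_r(t_obs)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(masks))
    for _ in range(n_perm):
        perm = rng.permutation(n)
        t_perm = D_trait[np.ix_(perm, perm)][iu]
        exceed += np.abs(class_r(t_perm)) >= np.abs(r_obs)
    p_raw = (1.0 + exceed) / (1.0 + n_perm)
    m_classes = len(masks)
    p_adj = np.minimum(1.0, p_raw * m_classes)
    significant = (r_obs > 0) & (p_adj < alpha)

    max_sig = 0.0
    expected_lo = kept[0][0] if kept[0][0] == 0.0 else None
    for idx, (lo, hi, _) in enumerate(kept):
        # a skipped (empty) class breaks the continuity requirement
        if expected_lo is None or lo != expected_lo or not significant[idx]:
            break
        max_sig = hi
        expected_lo = hi
    classes = pd.DataFrame(
        {
            "lower": [b[0] for b in kept],
            "upper": [b[1] for b in kept],
            "n_pairs": [b[2] for b in kept],
            "r": r_obs,
            "p_raw": p_raw,
            "p_adj": p_adj,
            "significant": significant,
        }
    )
    return MantelCorrelogramResult(classes, float(max_sig), alpha)


def hsp_predict(
    phylo: Phylogeny,
    observed: pd.Series,
    query_tips: list[str],
    max_pd: float | None = None,
) -> pd.DataFrame:
    """Hidden-state prediction of tip traits under Brownian motion.

    Generalized-least-squares interpolation on the tree:
    ``x_hat_q = mu + c' C^-1 (x - mu)`` with C the observed-tip covariance,
    c the query-observed covariances and mu the GLS mean of the observed
    values.  A prediction is flagged unreliable when the nearest observed
    tip is farther (patristic) than ``max_pd`` — typically the largest
    distance with continuous phylogenetic autocorrelation from
    :func:`mantel_correlogram`.
    """
    V, D, labels = phylo.vcv()
    index = {lab: i for i, lab in enumerate(labels)}
    obs_labels = [t for t in labels if t in observed.index]
    if len(obs_labels) < 2:
        raise ValueError("need at least 2 observed tips")
    unknown = [q for q in query_tips if q not in index]
    if unknown:
        raise ValueError(f"query tips not on the tree: {unknown[:5]}")
    oi = np.array([index[t] for t in obs_labels])
    x = observed.loc[obs_labels].to_numpy(dtype=float)
    C = V[np.ix_(oi, oi)]
    Cinv = np.linalg.inv(C)
    ones = np.ones(len(oi))
    mu = float(ones @ Cinv @ x) / float(ones @ Cinv @ ones)

    rows = []
    for q in query_tips:
        qi = index[q]
        if q in observed.index:
            rows.append((q, float(observed[q]), 0.0, True))
            continue
        c = V[qi, oi]
        pred = mu + float(c @ Cinv @ (x - mu))
        nearest = float(D[qi, oi].min())
        reliable = True if max_pd is None else nearest <= max_pd
        rows.append((q, pred, nearest, reliable))
    return pd.DataFrame(
        rows, columns=["tip", "predicted", "nearest_observed_pd", "reliable"]
    ).set_index("tip")
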