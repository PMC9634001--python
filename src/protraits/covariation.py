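"""Trait-trait covariation: transforms, PCA, Spearman matrices, loess,
and genome-size / habitat-stratified correlation reports.

All multivariate statistics operate on species-level trait tables.  PCA is
run on z-standardized columns with loadings reported as variable-component
correlations; pairwise association uses Spearman rank correlation with
Bonferroni adjustment over the pairs actually tested.  The stratified report
contrasts small (<4 Mbp) against large (>5 Mbp) genomes — the 4-5 Mbp band
is deliberately excluded — and/or habitat classes, for a fixed set of
resistance-vs-resilience trait pairs.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .io import TraitTable

#: resistance x resilience pairs reported in the stratified analysis
DEFAULT_STRATIFIED_PAIRS = (
    ("genome_size", "cub_f"),
    ("genome_size", "rrn"),
    ("gene_duplication", "cub_f"),
    ("gene_duplication", "rrn"),
    ("pct_tf", "cub_f"),
    ("pct_tf", "rrn"),
)

SIZE_STRATA = {"lt4Mbp": (None, 4e6), "gt5Mbp": (5e6, None)}


@dataclass
class PcaResult:
    """Standardized PCA with correlation-scaled loadings."""

    loadings: pd.DataFrame  # trait x component
    explained_variance: pd.Series  # % per component
    n_rows: int
    scores: pd.DataFrame | None = None
    loading_p: pd.DataFrame | None = None

    def summary(self) -> str:
        lines = [f"PCA on {self.n_rows} rows, {self.loadings.shape[0]} traits"]
        ev = self.explained_variance
        lines.append(
            "explained variance (%): "
            + ", ".join(f"{c}={v:.1f}" for c, v in ev.items())
        )
        lines.append(self.loadings.round(3).to_string())
        if self.loading_p is not None:
            lines.append("permutation p-values:")
            lines.append(self.loading_p.round(4).to_string())
        return "\n".join(lines)


@dataclass
class CorrelationMatrix:
    """Spearman rho with raw and Bonferroni-adjusted p per trait pair."""

    rho: pd.DataFrame
    p_raw: pd.DataFrame
    p_adj: pd.DataFrame
    n: pd.DataFrame
    m_tests: int

    def summary(self) -> str:
        return (
            f"Spearman matrix ({self.m_tests} pairs tested, Bonferroni)\n"
            + self.rho.round(3).to_string()
        )


@dataclass
class LoessCurve:
    """Robust locally-weighted linear fit evaluated on the data grid."""

    x: np.ndarray
    fitted: np.ndarray
    span: float
    iterations: int

    def predict(self, xs: np.ndarray) -> np.ndarray:
        return np.interp(xs, self.x, self.fitted)


@dataclass
class StratifiedReport:
    """Per-stratum Spearman statistics for named trait pairs."""

    table: pd.DataFrame  # columns: stratum, trait_a, trait_b, n, rho, p_raw, p_adj
    strata_n: dict[str, int]
    m_tests: int

    def get(self, stratum: str, trait_a: str, trait_b: str) -> pd.Series:
        t = self.table
        row = t[(t.stratum == stratum) & (t.trait_a == trait_a) & (t.trait_b == trait_b)]
        if row.empty:
            raise KeyError((stratum, trait_a, trait_b))
        return row.iloc[0]

    def summary(self) -> str:
        return (
            f"Stratified Spearman report ({self.m_tests} cells, Bonferroni)\n"
            + self.table.round(3).to_string(index=False)
        )


def transform_traits(table: TraitTable) -> TraitTable:
    """Variance-stabilizing transforms used ahead of PCA/correlation plots.

    %HGT -> ln(x + 0.001) (many exact zeros), generation time -> ln(x); rRNA
    copy number and prophage counts are left untransformed (no transform
    improves their fit to normality).
    """
    if table.transform_state != "raw":
        raise ValueError(f"table already {table.transform_state}")
    out = table.copy()
    shifted = []
    if "pct_hgt" in out.data.columns:
        out.data["pct_hgt"] = np.log(out.data["pct_hgt"] + 0.001)
        shifted.append("pct_hgt")
    if "generation_time" in out.data.columns:
        out.data["generation_time"] = np.log(out.data["generation_time"])
        shifted.append("generation_time")
    out.transform_state = "transformed"
    out.log_shifted = tuple(shifted)
    return out


def run_pca(table: TraitTable, traits: list[str]) -> PcaResult:
    """Standardized PCA of the selected traits (complete cases required).

    Loadings are scaled as correlations of each standardized trait with each
    component score (eigenvector times sqrt(eigenvalue) of the correlation
    matrix); component signs are fixed by making the largest-magnitude
    loading of each component positive.
    """
    df = table.data[traits].dropna()
    if len(df) < 3:
        raise ValueError("PCA needs at least 3 complete rows")
    stds = df.std(ddof=1)
    constant = stds[stds == 0]
    if not constant.empty:
        raise ValueError(f"constant trait column: {constant.index[0]!r}")
    z = ((df - df.mean()) / stds).values
    loadings, eigval, score_mat = _pca_core(z)
    comps = [f"PC{i + 1}" for i in range(len(traits))]
    return PcaResult(
        loadings=pd.DataFrame(loadings, index=traits, columns=comps),
        explained_variance=pd.Series(100.0 * eigval / eigval.sum(), index=comps),
        n_rows=len(df),
        scores=pd.DataFrame(score_mat, index=df.index, columns=comps),
    )


def _pca_core(z: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Eigendecomposition of the correlation matrix of standardized data,
    with the deterministic sign convention.  Returns (loadings, eigenvalues,
    scores)."""
    corr = np.corrcoef(z, rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = np.clip(eigval[order], 0, None), eigvec[:, order]
    loadings = eigvec * np.sqrt(eigval)
    for j in range(loadings.shape[1]):
        if loadings[np.argmax(np.abs(loadings[:, j])), j] < 0:
            loadings[:, j] *= -1
            eigvec[:, j] *= -1
    return loadings, eigval, z @ eigvec


def pca_loading_significance(
    table: TraitTable,
    traits: list[str],
    n_perm: int = 100,
    seed: int | None = None,
) -> pd.DataFrame:
    """Permutation p-values for the absolute PCA loadings.

    The null is built by independently permuting each trait column (breaking
    all covariation while keeping marginals), re-running the PCA, and
    recording |loading| per (trait, component);
    p = (1 + #{null >= observed}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    observed = np.abs(run_pca(table, traits).loadings.values)
    df = table.data[traits].dropna()
    z = ((df - df.mean()) / df.std(ddof=1)).values
    exceed = np.zeros_like(observed)
    zp = np.empty_like(z)
    for _ in range(n_perm):
        for j in range(z.shape[1]):
            zp[:, j] = z[rng.permutation(z.shape[0]), j]
        null = np.abs(_pca_core(zp)[0])
        exceed += null >= observed
    p = (1.0 + exceed) / (1.0 + n_perm)
    comps = [f"PC{i + 1}" for i in range(len(traits))]
    return pd.DataFrame(p, index=traits, columns=comps)


def spearman_matrix(table: TraitTable, traits: list[str]) -> CorrelationMatrix:
    """Pairwise-complete Spearman correlations with Bonferroni adjustment.

    Ties receive average ranks; p-values use the t approximation; pairs with
    fewer than 4 complete observations yield missing cells and do not count
    toward the Bonferroni factor m.
    """
    k = len(traits)
    rho = pd.DataFrame(np.eye(k), index=traits, columns=traits)
    p_raw = pd.DataFrame(np.nan, index=traits, columns=traits)
    n_mat = pd.DataFrame(0, index=traits, columns=traits, dtype=int)
    tested = 0
    for a, b in itertools.combinations(traits, 2):
        pair = table.data[[a, b]].dropna()
        n_mat.loc[a, b] = n_mat.loc[b, a] = len(pair)
        if len(pair) < 4 or pair[a].nunique() < 2 or pair[b].nunique() < 2:
            rho.loc[a, b] = rho.loc[b, a] = np.nan
            continue
        r, p = stats.spearmanr(pair[a], pair[b])
        rho.loc[a, b] = rho.loc[b, a] = r
        p_raw.loc[a, b] = p_raw.loc[b, a] = p
        tested += 1
    p_adj = (p_raw * tested).clip(upper=1.0)
    return CorrelationMatrix(rho, p_raw, p_adj, n_mat, tested)


def loess_fit(
    x: np.ndarray,
    y: np.ndarray,
    f: float = 2.0 / 3.0,
    iters: int = 3,
) -> LoessCurve:
    """Robust loess trendline (local linear, tricube kernel, bisquare
    reweighting iterated ``iters`` times over the ``f`` nearest fraction)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same shape")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("loess inputs must be finite")
    if len(x) < 10:
        raise ValueError("loess needs at least 10 points")
    fitted = lowess(y, x, frac=f, it=iters, return_sorted=True)
    grid, values = fitted[:, 0], fitted[:, 1]
    # collapse duplicated x positions to their mean fit
    ux, inverse = np.unique(grid, return_inverse=True)
    uy = np.bincount(inverse, weights=values) / np.bincount(inverse)
    return LoessCurve(ux, uy, span=f, iterations=iters)


def stratified_correlations(
    table: TraitTable,
    pairs: tuple[tuple[str, str], ...] = DEFAULT_STRATIFIED_PAIRS,
    strata: str | list[str] = "size",
) -> StratifiedReport:
    """Spearman statistics per trait pair within genome-size and/or habitat
    strata.

    Size strata are genome_size < 4 Mbp and > 5 Mbp (rows in between belong
    to no size stratum); habitat strata are the classified habitat labels.
    Bonferroni adjustment is over all (pair, stratum) cells with a computed
    p-value; cells from strata with fewer than 4 complete rows are missing.
    """
    if isinstance(strata, str):
        strata = [strata]
    masks: dict[str, pd.Series] = {}
    for spec in strata:
        if spec == "size":
            size = table.data["genome_size"]
            for name, (lo, hi) in SIZE_STRATA.items():
                mask = pd.Series(True, index=table.data.index)
                if lo is not None:
                    mask &= size > lo
                if hi is not None:
                    mask &= size < hi
                masks[name] = mask
        elif spec == "habitat":
            if "habitat" not in table.data.columns:
                raise ValueError("table has no habitat column")
            from .species import classify_habitat

            labels = table.data["habitat"].map(classify_habitat)
            for label in labels.dropna().unique():
                if label != "unclassified":
                    masks[label] = labels == label
        else:
            raise ValueError(f"unknown stratum spec {spec!r}")

    rows = []
    for name, mask in masks.items():
        sub = table.data[mask]
        for a, b in pairs:
            pair_df = sub[[a, b]].dropna()
            if len(pair_df) < 4 or pair_df[a].nunique() < 2 or pair_df[b].nunique() < 2:
                rows.append((name, a, b, len(pair_df), np.nan, np.nan))
                continue
            r, p = stats.spearmanr(pair_df[a], pair_df[b])
            rows.append((name, a, b, len(pair_df), r, p))
    report = pd.DataFrame(
        rows, columns=["stratum", "trait_a", "trait_b", "n", "rho", "p_raw"]
    )
    m = int(report["p_raw"].notna().sum())
    report["p_adj"] = (report["p_raw"] * m).clip(upper=1.0)
    strata_n = {name: int(mask.sum()) for name, mask in masks.items()}
    return StratifiedReport(report, strata_n, m)
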