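"""OTU-table community statistics.

Covers the post-clustering half of an amplicon workflow: rarefying
normalization to the shallowest sample, per-sample alpha-diversity
indices (richness, Chao1, Shannon, Pielou evenness, Gini-Simpson,
Good's coverage), Bray-Curtis dissimilarities on log(x+1) abundances,
UPGMA dendrograms, permutational multivariate ANOVA (PERMANOVA) with
permutation of residuals under a reduced model, canonical correspondence
analysis (CCA) with per-variable permutation tests, and Benjamini-
Hochberg FDR adjustment.

PERMANOVA partitions the Gower-centred distance matrix G = -1/2 J (D*D) J
(McArdle & Anderson).  For a tested term with full-model hat matrix H
and reduced-model hat matrix H0 (all other terms plus intercept),

    pseudo-F = [tr((H - H0) G) / df_term] / [tr((I - H) G) / df_res]

and significance comes from permuting residuals of the reduced model
(Freedman-Lane): G* = M G M' with M = H0 + P (I - H0) for a random
permutation matrix P.

CCA follows ter Braak: chi-square standardised abundances are projected
onto the row-weighted explanatory variables and the fitted matrix is
decomposed by SVD; constrained eigenvalues are the squared singular
values and total inertia equals that of unconstrained correspondence
analysis.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average as _average_linkage
from scipy.spatial.distance import pdist, squareform
from skbio import TreeNode
from skbio.diversity.alpha import chao1 as _chao1
from skbio.diversity.alpha import goods_coverage as _goods
from skbio.stats.distance import DistanceMatrix
from statsmodels.stats.multitest import multipletests

from .exceptions import UndefinedResultError, ValidationError

__all__ = [
    "OTUTable", "DiversityIndices", "PermanovaResult", "CCAResult",
    "normalize_to_min", "diversity", "bray_curtis", "upgma",
    "permanova", "cca", "bh_adjust",
]


@dataclass(frozen=True)
class OTUTable:
    """Count matrix (samples x OTUs) with optional sample metadata."""

    counts: pd.DataFrame
    metadata: pd.DataFrame | None = None

    def __post_init__(self):
        counts = self.counts
        if not isinstance(counts, pd.DataFrame):
            counts = pd.DataFrame(counts)
            object.__setattr__(self, "counts", counts)
        vals = counts.to_numpy()
        if vals.size == 0:
            raise ValidationError("empty OTU table")
        if np.any(vals < 0):
            raise ValidationError("OTU counts must be non-negative")
        if not np.allclose(vals, np.round(vals)):
            raise ValidationError("OTU counts must be integers")
        if self.metadata is not None:
            missing = counts.index.difference(self.metadata.index)
            if len(missing):
                raise ValidationError(
                    f"samples without metadata: {list(missing)[:5]}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def depths(self) -> pd.Series:
        return self.counts.sum(axis=1)


@dataclass(frozen=True)
class DiversityIndices:
    """Per-sample alpha-diversity table."""

    values: pd.DataFrame  # columns: richness, chao1, shannon, evenness,
    #                       simpson, goods_coverage


@dataclass(frozen=True)
class PermanovaResult:
    """Per-term PERMANOVA output."""

    table: pd.DataFrame   # index: term; columns: df, ss, pseudo_f, p_value
    n_permutations: int
    exhaustive: bool = False


@dataclass(frozen=True)
class CCAResult:
    """Constrained correspondence analysis output."""

    eigenvalues: np.ndarray        # constrained axes, non-increasing
    total_inertia: float
    constrained_inertia: float
    site_scores: pd.DataFrame      # linear-combination (LC) scores
    species_scores: pd.DataFrame
    biplot_scores: pd.DataFrame    # per explanatory variable
    pvalues: pd.Series | None = None
    n_permutations: int = 0
    rank_deficient: bool = False


# ---------------------------------------------------------------------------
# normalization & alpha diversity

def normalize_to_min(table: OTUTable, seed: int | None = None,
                     depth: int | None = None) -> OTUTable:
    """Rarefy every sample without replacement to the minimum sample depth.

    A seeded random subsample (multivariate hypergeometric draw) per
    sample; pass ``depth`` to override the automatic minimum.
    """
    totals = table.depths
    if (totals == 0).any():
        empty = totals.index[totals == 0].tolist()
        raise ValidationError(f"samples with zero reads: {empty[:5]}")
    target = int(totals.min()) if depth is None else int(depth)
    if target <= 0 or (totals < target).any():
        raise ValidationError("rarefaction depth exceeds a sample total")
    rng = np.random.default_rng(seed)
    out = np.empty_like(table.counts.to_numpy(dtype=np.int64))
    for i, row in enumerate(table.counts.to_numpy(dtype=np.int64)):
        out[i] = rng.multivariate_hypergeometric(row, target)
    counts = pd.DataFrame(out, index=table.counts.index,
                          columns=table.counts.columns)
    return OTUTable(counts, table.metadata)


def _sample_indices(counts: np.ndarray) -> dict[str, float]:
    n = counts.sum()
    if n == 0:
        raise ValidationError("cannot compute diversity of an empty sample")
    present = counts[counts > 0]
    s = present.size
    p = present / n
    h = float(-(p * np.log(p)).sum())
    return {
        "richness": float(s),
        "chao1": float(_chao1(counts)),
        "shannon": h,
        "evenness": h / math.log(s) if s > 1 else 0.0,
        "simpson": float(1.0 - (p ** 2).sum()),
        "goods_coverage": float(_goods(counts.astype(int))),
    }


def diversity(table: OTUTable) -> DiversityIndices:
    """Alpha-diversity indices per sample (natural-log Shannon, Pielou
    evenness, Gini-Simpson, bias-corrected Chao1, Good's coverage)."""
    rows = {sid: _sample_indices(np.asarray(row, dtype=np.int64))
            for sid, row in table.counts.iterrows()}
    return DiversityIndices(pd.DataFrame.from_dict(rows, orient="index"))


# ---------------------------------------------------------------------------
# beta diversity & clustering

def bray_curtis(table: OTUTable, transform: str = "log1p") -> DistanceMatrix:
    """Bray-Curtis dissimilarity matrix on (optionally log(x+1)) abundances."""
    x = table.counts.to_numpy(dtype=float)
    if transform == "log1p":
        x = np.log1p(x)
    elif transform not in (None, "none"):
        raise ValidationError(f"unknown transform {transform!r}")
    if np.any(x.sum(axis=1) == 0):
        raise UndefinedResultError(
            "Bray-Curtis undefined for an all-zero sample")
    d = pdist(x, metric="braycurtis")
    return DistanceMatrix(squareform(d), ids=table.sample_ids)


def upgma(dist: DistanceMatrix) -> str:
    """Average-linkage (UPGMA) dendrogram of a distance matrix, as newick.

    Ties between merge candidates break on the lowest pair index, which
    scipy's implementation applies deterministically.
    """
    linkage = _average_linkage(dist.condensed_form())
    tree = TreeNode.from_linkage_matrix(linkage, list(dist.ids))
    return str(tree).strip()


# ---------------------------------------------------------------------------
# PERMANOVA

def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d ** 2
    n = a.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j

def _dummy(values: pd.Series) -> np.ndarray:
    """Treatment-coded design columns for a factor (drop first level)."""
    levels = pd.unique(values)
    if len(levels) < 2:
        raise ValidationError(
            f"term {values.name!r} has a single level")
    return np.column_stack([(values == lv).to_numpy(float)
                            for lv in levels[1:]])

def _hat(x: np.ndarray) -> np.ndarray:
    q, r = np.linalg.qr(x)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(np.diag(r)).max())
    q = q[:, keep]
    return q @ q.T


def permanova(dist: DistanceMatrix, metadata: pd.DataFrame,
              terms: list[str], n_perm: int = 999,
              seed: int | None = None,
              exhaustive: bool = False) -> PermanovaResult:
    """Multi-factor PERMANOVA on a distance matrix.

    Each term in ``terms`` (metadata factor columns) is tested
    marginally: the reduced model holds every other term, significance
    by Freedman-Lane permutation of reduced-model residuals.  With
    ``exhaustive=True`` all n! sample permutations are enumerated
    instead of sampling (small n only) so the p-value is exact.
    """
    meta = metadata.loc[list(dist.ids)]
    n = len(dist.ids)
    g = _gower_center(dist.data)
    ss_total = float(np.trace(g))
    blocks = {t: _dummy(meta[t]) for t in terms}
    intercept = np.ones((n, 1))
    x_full = np.hstack([intercept] + [blocks[t] for t in terms])
    h_full = _hat(x_full)
    rank_full = int(np.linalg.matrix_rank(x_full))
    df_res = n - rank_full
    ss_res = float(np.trace((np.eye(n) - h_full) @ g))

    if exhaustive:
        perms = [np.asarray(p) for p in
                 itertools.permutations(range(n))]
    else:
        rng = np.random.default_rng(seed)
        perms = [rng.permutation(n) for _ in range(n_perm)]

    rows = {}
    for t in terms:
        others = [blocks[o] for o in terms if o != t]
        x_red = np.hstack([intercept] + others) if others else intercept
        h_red = _hat(x_red)
        df_t = rank_full - int(np.linalg.matrix_rank(x_red))
        ss_t = float(np.trace((h_full - h_red) @ g))
        f_obs = (ss_t / df_t) / (ss_res / df_res)

        resid_proj = np.eye(n) - h_red
        count = 0
        for p in perms:
            m = h_red + resid_proj[p, :]
            g_star = m @ g @ m.T
            ss_t_p = float(np.trace((h_full - h_red) @ g_star))
            ss_res_p = float(np.trace((np.eye(n) - h_full) @ g_star))
            f_p = (ss_t_p / df_t) / (ss_res_p / df_res)
            if f_p >= f_obs - 1e-12:
                count += 1
        if exhaustive:
            p_val = count / len(perms)  # identity permutation included
        else:
            p_val = (1 + count) / (1 + len(perms))
        rows[t] = {"df": df_t, "ss": ss_t, "pseudo_f": f_obs,
                   "p_value": p_val}

    tbl = pd.DataFrame.from_dict(rows, orient="index")
    tbl.attrs["ss_total"] = ss_total
    tbl.attrs["ss_residual"] = ss_res
    return PermanovaResult(tbl, len(perms), exhaustive)


# ---------------------------------------------------------------------------
# CCA

def _chi_square_standardize(y: np.ndarray):
    total = y.sum()
    if total <= 0:
        raise ValidationError("abundance table sums to zero")
    p = y / total
    r = p.sum(axis=1)
    c = p.sum(axis=0)
    if np.any(r == 0) or np.any(c == 0):
        raise ValidationError("CCA requires non-empty rows and columns")
    q = (p - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    return q, r, c


def _cca_core(y: np.ndarray, x: np.ndarray):
    """Constrained inertia decomposition; returns (eigvals, u, v, q, r, c)."""
    q, r, c = _chi_square_standardize(y)
    # centre env variables by row weights, then weight rows by sqrt(r)
    xw = x - np.average(x, axis=0, weights=r)
    z = xw * np.sqrt(r)[:, None]
    zq, zr = np.linalg.qr(z)
    keep = np.abs(np.diag(zr)) > 1e-10 * max(1.0, np.abs(np.diag(zr)).max())
    zq = zq[:, keep]
    q_fit = zq @ (zq.T @ q)
    u, s, vt = np.linalg.svd(q_fit, full_matrices=False)
    rank = min(zq.shape[1], y.shape[1] - 1)
    return s[:rank] ** 2, u[:, :rank], vt[:rank].T, q, r, c


def cca(table: OTUTable, env: pd.DataFrame, n_perm: int = 999,
        seed: int | None = None) -> CCAResult:
    """Canonical correspondence analysis with per-variable permutation tests.

    ``env`` holds numeric explanatory variables (rows = samples).  Each
    variable's significance is assessed marginally: a single-variable
    CCA pseudo-F, recomputed under ``n_perm`` permutations of that
    variable's values across samples.
    """
    y = table.counts.to_numpy(dtype=float)
    envx = env.loc[table.sample_ids].to_numpy(dtype=float)
    n, q_vars = envx.shape
    if np.any(np.std(envx, axis=0) == 0):
        bad = env.columns[np.std(envx, axis=0) == 0].tolist()
        raise ValidationError(f"constant explanatory variable(s): {bad}")
    if n < q_vars + 2:
        raise ValidationError("need at least n_variables + 2 samples")

    eig, u, v, q, r, c = _cca_core(y, envx)
    total_inertia = float((q ** 2).sum())
    constrained = float(eig.sum())
    rank_deficient = np.linalg.matrix_rank(
        envx - envx.mean(axis=0)) < q_vars

    axes = [f"CCA{i + 1}" for i in range(eig.size)]
    sqrt_eig = np.sqrt(eig)
    site = (u * sqrt_eig) / np.sqrt(r)[:, None]
    species = v / np.sqrt(c)[:, None]
    site_df = pd.DataFrame(site, index=table.sample_ids, columns=axes)
    species_df = pd.DataFrame(species, index=table.counts.columns,
                              columns=axes)
    # biplot scores: weighted correlation of each variable with the site axes
    xc = envx - np.average(envx, axis=0, weights=r)
    sc = site - np.average(site, axis=0, weights=r)
    w = r[:, None]
    cov = (w * xc).T @ sc
    sx = np.sqrt((w * xc ** 2).sum(axis=0))
    ss = np.sqrt((w * sc ** 2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        biplot = cov / np.outer(sx, ss)
    biplot_df = pd.DataFrame(biplot, index=env.columns, columns=axes)

    pvals = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        pvals = {}
        for j, name in enumerate(env.columns):
            xj = envx[:, [j]]
            f_obs = _single_var_pseudo_f(y, xj)
            count = 0
            for _ in range(n_perm):
                perm = rng.permutation(n)
                if _single_var_pseudo_f(y, xj[perm]) >= f_obs - 1e-12:
                    count += 1
            pvals[name] = (1 + count) / (1 + n_perm)
        pvals = pd.Series(pvals, name="p_value")

    return CCAResult(eigenvalues=eig, total_inertia=total_inertia,
                     constrained_inertia=constrained,
                     site_scores=site_df, species_scores=species_df,
                     biplot_scores=biplot_df, pvalues=pvals,
                     n_permutations=n_perm, rank_deficient=bool(rank_deficient))


def _single_var_pseudo_f(y: np.ndarray, xj: np.ndarray) -> float:
    eig, *_ , q, _, _ = _cca_core(y, xj)
    fitted = float(eig.sum())
    total = float((q ** 2).sum())
    resid = total - fitted
    n = y.shape[0]
    return (fitted / 1.0) / (resid / (n - 2))


# ---------------------------------------------------------------------------
# multiple testing

def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any(p < 0) or np.any(p > 1) or np.any(~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
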