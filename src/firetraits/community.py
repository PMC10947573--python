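"""Community diversity, Bray-Curtis dissimilarity and marginal-SS PERMANOVA.

Cover data arrive as a plot x species percent-cover matrix (converted from
ordinal Domin cover classes by class-interval midpoints) with a taxonomy
record per species. Diversity indices are the standard set for vegetation
surveys: species richness, Shannon-Wiener entropy (nats), Pielou evenness,
and Faith's phylogenetic diversity (total branch length of the minimal
rooted subtree spanning the community).

The PERMANOVA here decomposes a dissimilarity matrix on continuous and/or
categorical plot-level predictors using marginal (Type III) sums of squares:
each term's SS is the drop in explained (Gower-centred) sum of squares when
that term alone is removed from the full model, and p-values come from free
permutation of plot identities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .phylo import MissingTaxonError, Phylogeny

__all__ = [
    "DOMIN_MIDPOINTS",
    "CoverTable",
    "domin_to_cover",
    "diversity",
    "bray_curtis",
    "permanova_marginal",
    "PermanovaResult",
    "AliasedTermsError",
]

# Midpoints of a modified Domin cover-abundance scale. Class boundaries for
# "modified" Domin scales vary between surveys, so the mapping is explicitly
# configurable everywhere it is consumed; this default uses the common
# 10-class intervals (e.g. class 8 spans 50-75% cover -> 62.5).
DOMIN_MIDPOINTS: dict[int, float] = {
    0: 0.0,     # absent
    1: 0.05,    # a few individuals, <0.1%
    2: 0.5,     # <1%
    3: 2.0,     # 1-4%
    4: 7.0,     # 4-10%
    5: 18.0,    # 11-25%
    6: 29.5,    # 26-33%
    7: 42.0,    # 34-50%
    8: 62.5,    # 50-75%
    9: 83.0,    # 76-90%
    10: 95.5,   # 91-100%
}


class AliasedTermsError(ValueError):
    """The predictor set is rank deficient."""


@dataclass
class CoverTable:
    """Plot x species percent cover plus per-species taxonomy.

    ``matrix`` is indexed by plot with one column per species; covers are
    non-negative and plot totals may exceed 100 (the Domin design has no
    upper limit on total cover). ``taxonomy`` is indexed by species with
    columns ``genus``, ``family`` and ``functional_group``; every species in
    the matrix must have a record.
    """

    matrix: pd.DataFrame
    taxonomy: pd.DataFrame

    def __post_init__(self):
        if (np.asarray(self.matrix) < 0).any():
            raise ValueError("cover values must be non-negative")
        missing = set(self.matrix.columns) - set(self.taxonomy.index)
        if missing:
            raise ValueError(
                f"species without a taxonomy record: {sorted(missing)}"
            )

    @property
    def plots(self) -> list:
        return list(self.matrix.index)

    @property
    def species(self) -> list:
        return list(self.matrix.columns)

    def relative(self) -> pd.DataFrame:
        """Row-normalised cover (weights summing to 1 per plot)."""
        totals = self.matrix.sum(axis=1)
        return self.matrix.div(totals, axis=0)


def domin_to_cover(codes, mapping: dict | None = None):
    """Replace ordinal Domin class codes by continuous percent-cover midpoints.

    ``codes`` may be a scalar, array, Series or DataFrame; missing values
    map to 0 (absent). Codes absent from the mapping raise ``ValueError``
    naming the offending code.
    """
    table = DOMIN_MIDPOINTS if mapping is None else mapping

    def _one(code):
        if pd.isna(code):
            return 0.0
        key = int(code)
        if key != code or key not in table:
            raise ValueError(f"Domin class code not in mapping: {code!r}")
        return float(table[key])

    if isinstance(codes, pd.DataFrame):
        return codes.map(_one)
    if isinstance(codes, pd.Series):
        return codes.map(_one)
    arr = np.asarray(codes)
    if arr.ndim == 0:
        return _one(arr.item())
    return np.vectorize(_one, otypes=[float])(arr)


def diversity(cover: CoverTable, tree: Phylogeny | None = None) -> pd.DataFrame:
    """Per-plot richness, Shannon entropy, Pielou evenness and Faith's PD.

    Faith's PD needs ``tree`` containing every species with positive cover
    (a missing species raises :class:`MissingTaxonError`). Plots with zero
    total cover get NaN indices and a warning rather than silent zeros;
    Pielou evenness is NaN for single-species plots.
    """
    mat = cover.matrix
    if tree is not None:
        present = set(mat.columns[(mat > 0).any(axis=0)])
        missing = present - set(tree.tip_labels)
        if missing:
            raise MissingTaxonError(
                f"species with cover but missing from tree: {sorted(missing)}"
            )
    rows = []
    for plot, row in mat.iterrows():
        total = row.sum()
        if total <= 0:
            warnings.warn(f"plot {plot!r} has zero total cover; indices undefined")
            rows.append((plot, 0, np.nan, np.nan, np.nan))
            continue
        p = row[row > 0] / total
        richness = int((row > 0).sum())
        shannon = float(-(p * np.log(p)).sum())
        pielou = shannon / np.log(richness) if richness > 1 else np.nan
        if tree is not None:
            pd_val = tree.faith_pd(p.index)
        else:
            pd_val = np.nan
        rows.append((plot, richness, shannon, pielou, pd_val))
    out = pd.DataFrame(
        rows, columns=["plot", "richness", "shannon", "pielou", "faith_pd"]
    ).set_index("plot")
    return out


def bray_curtis(cover) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity between plots.

    d(a, b) = sum|x_a - x_b| / sum(x_a + x_b) over species. Pairs of
    all-zero plots are undefined (NaN) and flagged with a warning.
    """
    mat = cover.matrix if isinstance(cover, CoverTable) else pd.DataFrame(cover)
    if len(mat) < 2:
        raise ValueError("need at least 2 plots")
    X = np.asarray(mat, dtype=float)
    zero_rows = X.sum(axis=1) == 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        D = squareform(pdist(X, metric="braycurtis"))
    if zero_rows.any():
        warnings.warn(
            f"plots with zero total cover produce undefined dissimilarities: "
            f"{list(mat.index[zero_rows])}"
        )
    np.fill_diagonal(D, 0.0)
    return pd.DataFrame(D, index=mat.index, columns=mat.index)


@dataclass
class PermanovaResult:
    """Marginal PERMANOVA table plus bookkeeping."""

    table: pd.DataFrame  # per term: df, ss, r2, pseudo_f, p_value
    n_permutations: int
    seed: object = None
    terms: list = field(default_factory=list)

    def __repr__(self):  # pragma: no cover
        return f"PermanovaResult(n_perm={self.n_permutations})\n{self.table}"


def _gower_center(D: np.ndarray) -> np.ndarray:
    A = -0.5 * D ** 2
    n = len(A)
    J = np.eye(n) - np.ones((n, n)) / n
    return J @ A @ J


def _hat(X: np.ndarray) -> np.ndarray:
    Q, _ = np.linalg.qr(X)
    r = np.linalg.matrix_rank(X)
    Q = Q[:, :r]
    return Q @ Q.T


def permanova_marginal(
    dist,
    predictors: pd.DataFrame,
    n_perm: int = 999,
    seed=None,
    exhaustive: bool = False,
) -> PermanovaResult:
    """PERMANOVA with marginal (Type III) sums of squares.

    ``dist`` is a symmetric plot x plot dissimilarity matrix aligned with
    ``predictors`` (one numeric column per term; encode factors beforehand).
    For each term, SS = SS(full model) - SS(model without the term); the
    pseudo-F ratio uses the full-model residual. p-values permute raw plot
    rows freely, which is the default behaviour of the standard marginal
    implementation. Rank-deficient predictor sets raise
    :class:`AliasedTermsError` listing the aliased terms.

    With ``exhaustive`` all n! row permutations are enumerated (identity
    included, so p = #{F_perm >= F_obs} / n!); only sensible for small n.
    """
    if isinstance(dist, pd.DataFrame):
        if list(dist.index) != list(predictors.index):
            predictors = predictors.loc[dist.index]
        D = np.asarray(dist, dtype=float)
    else:
        D = np.asarray(dist, dtype=float)
    n = len(D)
    if not exhaustive and n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    terms = list(predictors.columns)
    Xcols = {t: np.asarray(predictors[t], dtype=float).reshape(n, 1) for t in terms}
    ones = np.ones((n, 1))
    X_full = np.hstack([ones] + [Xcols[t] for t in terms])
    rank_full = np.linalg.matrix_rank(X_full)
    if rank_full < X_full.shape[1]:
        aliased = [
            t for t in terms
            if np.linalg.matrix_rank(
                np.hstack([ones] + [Xcols[u] for u in terms if u != t])
            ) == rank_full
        ]
        raise AliasedTermsError(f"aliased terms in predictor set: {aliased}")

    G = _gower_center(D)
    ss_total = float(np.trace(G))
    H_full = _hat(X_full)
    df_resid = n - rank_full

    H_reduced = {}
    for t in terms:
        X_red = np.hstack([ones] + [Xcols[u] for u in terms if u != t])
        H_reduced[t] = _hat(X_red)

    def term_stats(Gmat):
        ss_model = float(np.sum(H_full * Gmat))
        ss_res = float(np.trace(Gmat)) - ss_model
        out = {}
        for t in terms:
            ss_t = ss_model - float(np.sum(H_reduced[t] * Gmat))
            df_t = 1
            f_t = (ss_t / df_t) / (ss_res / df_resid)
            out[t] = (ss_t, df_t, f_t)
        return out, ss_res

    obs, ss_res_obs = term_stats(G)

    exceed = {t: 0 for t in terms}
    if exhaustive:
        from itertools import permutations as _perms
        from math import factorial

        for perm in _perms(range(n)):
            Gp = G[np.ix_(perm, perm)]
            stats_p, _ = term_stats(Gp)
            for t in terms:
                if stats_p[t][2] >= obs[t][2] - 1e-12:
                    exceed[t] += 1
        n_eff = factorial(n)
        pvals = {t: exceed[t] / n_eff for t in terms}
        n_perm = n_eff
    else:
        rng = np.random.default_rng(seed)
        for _ in range(n_perm):
            perm = rng.permutation(n)
            Gp = G[np.ix_(perm, perm)]
            stats_p, _ = term_stats(Gp)
            for t in terms:
                if stats_p[t][2] >= obs[t][2]:
                    exceed[t] += 1
        pvals = {t: (1 + exceed[t]) / (1 + n_perm) for t in terms}

    rows = []
    for t in terms:
        ss_t, df_t, f_t = obs[t]
        rows.append((t, df_t, ss_t, ss_t / ss_total, f_t, pvals[t]))
    rows.append(("Residual", df_resid, ss_res_obs, ss_res_obs / ss_total,
                 np.nan, np.nan))
    rows.append(("Total", n - 1, ss_total, 1.0, np.nan, np.nan))
    table = pd.DataFrame(
        rows, columns=["term", "df", "ss", "r2", "pseudo_f", "p_value"]
    ).set_index("term")
    return PermanovaResult(table=table, n_permutations=n_perm, seed=seed,
                           terms=terms)
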