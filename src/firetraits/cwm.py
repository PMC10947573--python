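"""Trait derivation and community-weighted means at four aggregation scales.

A community-weighted mean (CWM) is the cover-weighted average trait of a
plot. Computing it at progressively coarser trait-aggregation scales
partitions the trait-environment slope into its sources:

* ``full_variability`` - each species' plot-specific mean trait, so the CWM
  carries intraspecific adjustment along the gradient as well as turnover;
* ``species_means`` - one cross-plot mean per species (intraspecific
  variation removed; species turnover and abundance shifts remain);
* ``genera_means`` - one mean per genus (only turnover among genera);
* ``functional_means`` - one mean per functional group (only turnover in
  functional composition).

Regressing each scale's CWM on fire frequency and differencing the slopes
then attributes the community trait shift to within-species change versus
replacement at each taxonomic level. When all scale slopes share a sign and
steepen monotonically from the functional scale to the full-variability
scale, the intraspecific and turnover components reinforce each other - a
"co-gradient".
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .community import CoverTable

__all__ = [
    "TRAITS",
    "SCALES",
    "derive_traits",
    "cwm",
    "cwm_profiles",
    "decompose",
    "species_trends",
    "CWMDecomposition",
    "OrphanSpeciesError",
]

logger = logging.getLogger(__name__)

#: Derived leaf-economics traits carried through the pipeline.
TRAITS = ("n_mass", "n_area", "cn_ratio", "sla")

#: Aggregation scales, ordered coarse -> fine.
SCALES = ("functional_means", "genera_means", "species_means", "full_variability")


class OrphanSpeciesError(ValueError):
    """Species with cover but no trait record anywhere."""


def derive_traits(raw: pd.DataFrame, return_rejected: bool = False):
    """Derive leaf-economics traits from raw individual measurements.

    ``raw`` needs columns ``plot``, ``species``, ``percent_n`` (%N),
    ``percent_c`` (%C) and ``sla`` (cm^2/g). Derived columns:

    * ``n_mass`` = 10 * %N  (mg N per g dry mass)
    * ``n_area`` = n_mass / sla  (mg N per cm^2 leaf area)
    * ``cn_ratio`` = %C / %N  (mass ratio, unitless)

    Records with non-positive SLA or %N are rejected with a logged reason.
    """
    required = {"plot", "species", "percent_n", "percent_c", "sla"}
    missing = required - set(raw.columns)
    if missing:
        raise ValueError(f"raw trait table missing columns: {sorted(missing)}")
    bad_sla = raw["sla"] <= 0
    bad_n = raw["percent_n"] <= 0
    bad = bad_sla | bad_n
    if bad.any():
        for idx, row in raw[bad].iterrows():
            reason = "non-positive SLA" if row["sla"] <= 0 else "non-positive %N"
            logger.warning(
                "rejecting trait record %s (%s/%s): %s",
                idx, row["plot"], row["species"], reason,
            )
    out = raw[~bad].copy()
    out["n_mass"] = 10.0 * out["percent_n"]
    out["n_area"] = out["n_mass"] / out["sla"]
    out["cn_ratio"] = out["percent_c"] / out["percent_n"]
    if return_rejected:
        return out, raw[bad].copy()
    return out


def _plot_species_means(traits: pd.DataFrame) -> pd.DataFrame:
    return traits.groupby(["plot", "species"])[list(TRAITS)].mean()


def _species_means(traits: pd.DataFrame) -> pd.DataFrame:
    # simple (unweighted) mean of the species' plot-level means, so every
    # plot where the species was sampled contributes equally
    return _plot_species_means(traits).groupby("species").mean()


def cwm(cover: CoverTable, traits: pd.DataFrame, scale: str) -> pd.DataFrame:
    """Community-weighted mean traits per plot at one aggregation scale.

    Weights are relative covers (summing to 1 within each plot) computed
    after aggregating cover to the scale's taxonomic level. At the
    ``full_variability`` scale a species with cover in a plot but no trait
    record there falls back to its cross-plot mean (logged). A species with
    cover somewhere but no trait record anywhere raises
    :class:`OrphanSpeciesError` listing the orphans.
    """
    if scale not in SCALES:
        raise ValueError(f"scale must be one of {SCALES}, got {scale!r}")
    mat = cover.matrix
    tax = cover.taxonomy

    sp_means = _species_means(traits)
    covered = set(mat.columns[(mat > 0).any(axis=0)])
    orphans = sorted(covered - set(sp_means.index))
    if orphans:
        raise OrphanSpeciesError(
            f"species with cover but no trait record: {orphans}"
        )

    if scale == "species_means":
        values = sp_means
        weights = mat
    elif scale == "genera_means":
        genus = tax["genus"]
        # genus trait = unweighted mean of constituent species means
        values = sp_means.join(genus, how="left").groupby("genus").mean()
        weights = mat.T.groupby(genus).sum().T
    elif scale == "functional_means":
        group = tax["functional_group"]
        values = sp_means.join(group, how="left").groupby("functional_group").mean()
        weights = mat.T.groupby(group).sum().T
    else:  # full_variability
        ps_means = _plot_species_means(traits)
        rows = []
        n_fallback = 0
        for plot in mat.index:
            row = mat.loc[plot]
            present = row[row > 0]
            vals = pd.DataFrame(index=present.index, columns=list(TRAITS),
                                dtype=float)
            for sp in present.index:
                if (plot, sp) in ps_means.index:
                    vals.loc[sp] = ps_means.loc[(plot, sp)]
                else:
                    vals.loc[sp] = sp_means.loc[sp]
                    n_fallback += 1
                    logger.info(
                        "plot %s species %s: no plot-specific trait record; "
                        "using cross-plot species mean", plot, sp,
                    )
            w = present / present.sum()
            rows.append(vals.mul(w, axis=0).sum(axis=0).rename(plot))
        if n_fallback:
            logger.warning(
                "full_variability CWM used species-mean fallback for %d "
                "(plot, species) pairs", n_fallback,
            )
        return pd.DataFrame(rows).rename_axis("plot")

    present = weights.columns.intersection(values.index)
    weights = weights[present]
    rel = weights.div(weights.sum(axis=1), axis=0)
    out = rel @ values.loc[present, list(TRAITS)]
    return out.rename_axis("plot")


def cwm_profiles(cover: CoverTable, traits: pd.DataFrame,
                 scales=SCALES) -> pd.DataFrame:
    """CWMs at several scales, stacked long with a ``scale`` column."""
    frames = []
    for scale in scales:
        prof = cwm(cover, traits, scale).reset_index()
        prof.insert(0, "scale", scale)
        frames.append(prof)
    return pd.concat(frames, ignore_index=True)


@dataclass
class CWMDecomposition:
    """Per-trait CWM~fire slopes across scales and their changes.

    ``slopes`` has one row per (trait, scale) with the OLS slope, its
    standard error, intercept, r^2 and p. ``pct_change`` holds
    100 * (slope_finer - slope_coarser) / |slope_coarser| for adjacent
    scales (coarse -> fine order). ``co_gradient`` flags traits whose scale
    slopes all share a sign with |slope| non-decreasing from the functional
    to the full-variability scale.
    """

    slopes: pd.DataFrame
    pct_change: pd.DataFrame
    co_gradient: dict = field(default_factory=dict)


def _ols_line(x: np.ndarray, y: np.ndarray):
    res = stats.linregress(x, y)
    return res.slope, res.stderr, res.intercept, res.rvalue ** 2, res.pvalue


def decompose(profiles: pd.DataFrame, env: pd.DataFrame) -> CWMDecomposition:
    """Regress CWM on fire frequency at every scale and compare slopes.

    ``profiles`` is the long table from :func:`cwm_profiles`; ``env`` maps
    plots to ``fire_freq`` (one row per plot). A constant fire gradient is
    degenerate and raises ``ValueError``.
    """
    env_plot = env.drop_duplicates("plot").set_index("plot")["fire_freq"]
    if env_plot.nunique() < 2:
        raise ValueError("fire frequency is constant across plots: no gradient")
    scales = [s for s in SCALES if s in set(profiles["scale"])]
    traits = [t for t in TRAITS if t in profiles.columns]

    slope_rows = []
    for scale in scales:
        sub = profiles[profiles["scale"] == scale].set_index("plot")
        fire = env_plot.loc[sub.index].astype(float)
        if len(sub) < 3:
            raise ValueError("need at least 3 plots to fit CWM~fire lines")
        for trait in traits:
            sl, se, ic, r2, p = _ols_line(fire.values, sub[trait].values.astype(float))
            slope_rows.append((trait, scale, sl, se, ic, r2, p))
    slopes = pd.DataFrame(
        slope_rows,
        columns=["trait", "scale", "slope", "stderr", "intercept", "r2", "p_value"],
    ).set_index(["trait", "scale"])

    pct_rows = []
    for trait in traits:
        for coarse, fine in itertools.pairwise(scales):
            s_c = slopes.loc[(trait, coarse), "slope"]
            s_f = slopes.loc[(trait, fine), "slope"]
            pct = 100.0 * (s_f - s_c) / abs(s_c) if s_c != 0 else np.nan
            pct_rows.append((trait, coarse, fine, pct))
    pct_change = pd.DataFrame(
        pct_rows, columns=["trait", "coarser", "finer", "pct_change"]
    )

    co_gradient = {}
    for trait in traits:
        ss = slopes.loc[trait].loc[list(scales), "slope"].values
        same_sign = np.all(np.sign(ss) == np.sign(ss[0])) and ss[0] != 0
        monotone = np.all(np.diff(np.abs(ss)) >= 0)
        co_gradient[trait] = bool(same_sign and monotone)

    return CWMDecomposition(slopes=slopes, pct_change=pct_change,
                            co_gradient=co_gradient)


def species_trends(traits: pd.DataFrame, env: pd.DataFrame,
                   alpha: float = 0.10) -> pd.DataFrame:
    """Within-species trait~fire OLS trends across the plots where it occurs.

    Species present in fewer than 3 plots cannot be fit and are marked
    (``fit = False``) rather than dropped. Returns one row per
    (species, trait) with slope, two-sided p, plot count and a significance
    flag at ``alpha``; the summary counts answering "how many species
    respond, and in which direction" are available via :func:`trend_summary`.
    """
    env_plot = env.drop_duplicates("plot").set_index("plot")["fire_freq"]
    ps = _plot_species_means(traits).reset_index()
    ps["fire"] = ps["plot"].map(env_plot)
    rows = []
    for (sp,), sub in ps.groupby(["species"]):
        for trait in TRAITS:
            vals = sub[["fire", trait]].dropna()
            n = len(vals)
            if n < 3 or vals["fire"].nunique() < 2:
                rows.append((sp, trait, np.nan, np.nan, n, False, False))
                continue
            if np.allclose(vals[trait], vals[trait].iloc[0]):
                # perfectly flat response: slope 0, never significant
                rows.append((sp, trait, 0.0, 1.0, n, True, False))
                continue
            res = stats.linregress(vals["fire"], vals[trait])
            rows.append(
                (sp, trait, res.slope, res.pvalue, n, True, res.pvalue < alpha)
            )
    return pd.DataFrame(
        rows,
        columns=["species", "trait", "slope", "p_value", "n_plots", "fit",
                 "significant"],
    )


def trend_summary(trends: pd.DataFrame) -> pd.DataFrame:
    """Per-trait counts of significant and significant-negative species."""
    rows = []
    for trait, sub in trends.groupby("trait"):
        sig = sub[sub["significant"]]
        rows.append((trait, len(sub), int(sub["fit"].sum()), len(sig),
                     int((sig["slope"] < 0).sum())))
    return pd.DataFrame(
        rows,
        columns=["trait", "n_species", "n_fit", "n_significant",
                 "n_significant_negative"],
    ).set_index("trait")
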