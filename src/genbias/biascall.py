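"""Negative-binomial differential expression between life-cycle generations
and the bias / specificity / fold-change-bin classification layer.

The test engine is a self-contained NB Wald test in the DESeq2 mould:
median-of-ratios size factors, gene-wise method-of-moments dispersions shrunk
toward a fitted mean-dispersion trend, per-group NB means fitted by Newton
iteration, and a Wald test on the log2 generation effect.  The classification
layer then applies the field-standard thresholds: a gene is generation-biased
when it shows at least a twofold difference between gametophyte (GA) and
sporophyte (SP) samples at BH FDR < 0.05, and generation-specific when, in
addition, the disfavored generation's mean TPM falls below the species
expression floor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

CLASSES = ("GA-biased", "SP-biased", "unbiased", "not-expressed")
FC_BIN_EDGES = (2.0, 6.0, 20.0)
FC_BINS = ("[2,6)", "[6,20)", ">=20")

_MIN_DISPERSION = 1e-8
_MIN_MEAN = 1e-8


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios sample size factors, rescaled to geometric mean 1.

    Ratios are taken over genes with all-positive counts; with none present
    the caller should fall back to another normalization (we raise).
    """
    mat = counts.to_numpy(dtype=float)
    allpos = (mat > 0).all(axis=1)
    if not allpos.any():
        raise ValueError(
            "no gene has positive counts in every sample; "
            "median-of-ratios undefined (consider a pseudo-reference fallback)"
        )
    logmat = np.log(mat[allpos])
    loggeo = logmat.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logmat - loggeo, axis=0))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def _fit_group_mean(counts: np.ndarray, sf: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Per-gene NB MLE of the group mean m with known dispersion and size
    factors (log-link Newton iteration, vectorized over genes).

    Score in eta=log m:  U = sum_i (c_i - mu_i) / (1 + alpha*mu_i),
    information:         I = sum_i mu_i / (1 + alpha*mu_i),  mu_i = sf_i*m.
    """
    # moment start: mean of normalized counts
    m = np.maximum((counts / sf).mean(axis=1), _MIN_MEAN)
    eta = np.log(m)
    for _ in range(50):
        mu = sf * np.exp(eta)[:, None]
        denom = 1.0 + alpha[:, None] * mu
        score = ((counts - mu) / denom).sum(axis=1)
        info = (mu / denom).sum(axis=1)
        step = score / np.maximum(info, 1e-12)
        step = np.clip(step, -5.0, 5.0)
        eta = eta + step
        eta = np.maximum(eta, np.log(_MIN_MEAN))
        if np.max(np.abs(step)) < 1e-10:
            break
    return np.exp(eta)


def _mom_dispersion(counts: np.ndarray, sf: np.ndarray, groups: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Method-of-moments gene-wise dispersion from within-group variability
    of normalized counts, and the gene-wise base mean."""
    q = counts / sf
    base_mean = q.mean(axis=1)
    resid_ss = np.zeros(counts.shape[0])
    df = 0
    for g in np.unique(groups):
        cols = groups == g
        n = cols.sum()
        gm = q[:, cols].mean(axis=1, keepdims=True)
        resid_ss += ((q[:, cols] - gm) ** 2).sum(axis=1)
        df += n - 1
    var = resid_ss / max(df, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (var - base_mean) / base_mean**2
    alpha = np.where(np.isfinite(alpha), alpha, 0.0)
    return np.maximum(alpha, 0.0), base_mean


def _trend_fit(alpha_mom: np.ndarray, base_mean: np.ndarray) -> np.ndarray:
    """Least-squares fit of the dispersion trend a0 + a1/mu over genes with a
    positive moment estimate; evaluated at every gene's base mean."""
    ok = (alpha_mom > 0) & (base_mean > 0)
    if ok.sum() >= 2:
        X = np.column_stack([np.ones(ok.sum()), 1.0 / base_mean[ok]])
        coef, *_ = np.linalg.lstsq(X, alpha_mom[ok], rcond=None)
    else:  # degenerate: flat fallback at the median moment estimate
        coef = np.array([np.median(alpha_mom[ok]) if ok.any() else _MIN_DISPERSION, 0.0])
    with np.errstate(divide="ignore"):
        trend = coef[0] + coef[1] / np.maximum(base_mean, _MIN_MEAN)
    return np.maximum(trend, _MIN_DISPERSION)


def nb_wald_test(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    sf: pd.Series | None = None,
    shrinkage_weight: float = 0.5,
) -> pd.DataFrame:
    """Per-gene NB Wald test of GA vs SP.

    Returns a frame with ``log2fc`` (positive = gametophyte-biased), ``se``,
    ``pvalue`` and ``padj`` (BH over genes with any nonzero count; all-zero
    genes get NA and are excluded from the correction).
    """
    gens = samples.loc[counts.columns, "generation"].to_numpy()
    for g in ("GA", "SP"):
        if (gens == g).sum() < 2:
            raise ValueError(f"need >=2 replicates in generation {g}")
    if sf is None:
        sf = size_factors(counts)
    sfv = sf.loc[counts.columns].to_numpy(dtype=float)
    if (sfv <= 0).any():
        raise ValueError("size factors must be positive")

    mat = counts.to_numpy(dtype=float)
    nonzero = mat.sum(axis=1) > 0

    alpha_mom, base_mean = _mom_dispersion(mat, sfv, gens)
    trend = _trend_fit(alpha_mom, base_mean)
    # geometric interpolation between the gene-wise and trend dispersions;
    # genes whose moment estimate collapses to zero fall back to the trend
    w = shrinkage_weight
    with np.errstate(divide="ignore"):
        alpha = np.where(
            alpha_mom > 0,
            np.exp((1 - w) * np.log(np.maximum(alpha_mom, _MIN_DISPERSION)) + w * np.log(trend)),
            trend,
        )
    alpha = np.maximum(alpha, _MIN_DISPERSION)

    ga, sp = gens == "GA", gens == "SP"
    m_ga = _fit_group_mean(mat[:, ga], sfv[ga], alpha)
    m_sp = _fit_group_mean(mat[:, sp], sfv[sp], alpha)

    beta = np.log(m_ga) - np.log(m_sp)  # natural-log generation effect

    def info(m, cols):
        mu = sfv[cols] * m[:, None]
        return (mu / (1.0 + alpha[:, None] * mu)).sum(axis=1)

    var = 1.0 / np.maximum(info(m_ga, ga), 1e-12) + 1.0 / np.maximum(info(m_sp, sp), 1e-12)
    se = np.sqrt(var)
    z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))

    res = pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2fc": beta / np.log(2.0),
            "se": se / np.log(2.0),
            "pvalue": p,
            "dispersion": alpha,
        },
        index=counts.index,
    )
    res.loc[~nonzero, ["log2fc", "se", "pvalue"]] = np.nan
    res["padj"] = np.nan
    res.loc[nonzero, "padj"] = bh_adjust(res.loc[nonzero, "pvalue"].to_numpy())
    return res


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


@dataclass(frozen=True)
class BiasThresholds:
    """Classification thresholds: fold-change cut is inclusive (>= twofold),
    the FDR cut strict (< 0.05)."""

    min_abs_log2fc: float = 1.0
    max_padj: float = 0.05


def classify_bias(
    test: pd.DataFrame,
    gen_means: pd.DataFrame,
    floor: float,
    expressed: pd.Index | None = None,
    thresholds: BiasThresholds = BiasThresholds(),
) -> pd.DataFrame:
    """Assemble the per-gene bias-call table.

    GA-biased iff log2fc >= 1 and padj < 0.05 (SP-biased mirrored); a biased
    gene is generation-specific when the disfavored generation's mean TPM is
    below the species floor; |FC| is binned into [2,6), [6,20), >=20.
    """
    if floor is None or floor < 0:
        raise ValueError("a non-negative expression floor is required")
    if expressed is None:
        expressed = test.index
    out = test.copy()
    out["GA_mean_tpm"] = gen_means["GA"]
    out["SP_mean_tpm"] = gen_means["SP"]

    lfc, padj = out["log2fc"], out["padj"]
    is_expr = out.index.isin(expressed)
    sig = padj.notna() & (padj < thresholds.max_padj)
    ga = is_expr & sig & (lfc >= thresholds.min_abs_log2fc)
    sp = is_expr & sig & (lfc <= -thresholds.min_abs_log2fc)

    cls = np.where(~is_expr, "not-expressed", np.where(ga, "GA-biased", np.where(sp, "SP-biased", "unbiased")))
    out["class"] = cls

    losing = np.where(ga, out["SP_mean_tpm"], np.where(sp, out["GA_mean_tpm"], np.nan))
    out["specific"] = (ga | sp) & (losing < floor)

    # bins compared on the log2 scale to keep the edges exact
    alfc = lfc.abs()
    e1, e2, e3 = (np.log2(e) for e in FC_BIN_EDGES)
    bins = pd.Series("none", index=out.index, dtype=object)
    biased = ga | sp
    bins[biased & (alfc >= e1) & (alfc < e2)] = FC_BINS[0]
    bins[biased & (alfc >= e2) & (alfc < e3)] = FC_BINS[1]
    bins[biased & (alfc >= e3)] = FC_BINS[2]
    out["fc_bin"] = bins
    return out


def fc_bins(calls: pd.DataFrame) -> pd.DataFrame:
    """Counts of biased genes per |FC| bin per direction (unbiased excluded)."""
    biased = calls[calls["class"].isin(["GA-biased", "SP-biased"])]
    table = (
        biased.groupby(["class", "fc_bin"], observed=False).size().unstack(fill_value=0)
    )
    for b in FC_BINS:
        if b not in table.columns:
            table[b] = 0
    for c in ("GA-biased", "SP-biased"):
        if c not in table.index:
            table.loc[c] = 0
    return table[list(FC_BINS)].sort_index()
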