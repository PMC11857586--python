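"""Negative-binomial differential testing, applied three ways.

The same engine serves site-level editing counts (alt reads per site),
gene-aggregated editing counts, and annotation-based gene expression
counts. The model is the standard NB GLM with log link and a single
condition indicator: variance = mu + alpha * mu^2, per-sample
median-of-ratios size factors as offsets, per-feature method-of-moments
dispersion shrunk toward a mean-dispersion trend, and a Wald test on
the condition coefficient with Benjamini-Hochberg correction. This is
the statistical behavior of the DESeq2 family of tools; numerical
equivalence with any particular implementation is not a goal and the
engine deliberately omits LFC shrinkage, Cox-Reid adjustment, and
independent filtering.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .formats import Gene, SampleSheet

LN2 = np.log(2.0)


# ---------------------------------------------------------------------------
# Count assembly

def editing_counts(sites: pd.DataFrame, sample_ids: list[str]) -> pd.DataFrame:
    """Site-level matrix of editing reads (alt counts) per sample."""
    idx = [f"{r.chrom}:{r.pos}:{r.alt}" for r in sites.itertuples()]
    return pd.DataFrame(
        {sid: sites[f"{sid}_alt"].to_numpy() for sid in sample_ids},
        index=pd.Index(idx, name="site"),
    )


def aggregate_gene(
    site_counts: pd.DataFrame, site_to_gene: pd.Series
) -> pd.DataFrame:
    """Sum each gene's site rows; sites without a host gene are dropped."""
    genes = site_to_gene.reindex(site_counts.index)
    keep = genes.notna() & (genes != "intergenic") & (genes != ".")
    out = site_counts.loc[keep].groupby(genes[keep]).sum()
    out.index.name = "gene"
    return out


def gene_lengths(genes: list[Gene]) -> pd.Series:
    """Merged-exon (union) length per gene, for TPM."""
    out = {}
    for g in genes:
        ivs = sorted(
            (s, e) for tx in g.transcripts for s, e in tx.exons
        )
        total, cur_s, cur_e = 0, None, None
        for s, e in ivs:
            if cur_e is None or s > cur_e + 1:
                if cur_e is not None:
                    total += cur_e - cur_s + 1
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        if cur_e is not None:
            total += cur_e - cur_s + 1
        out[g.id] = total
    return pd.Series(out, name="length")


def count_reads_per_gene(
    sheet: SampleSheet, genes: list[Gene], chrom_lengths: dict[str, int]
) -> pd.DataFrame:
    """Annotation-based expression counts: reads assigned to the gene whose
    exons they overlap most (ties to the lower gene index); reads touching
    no exon are unassigned."""
    from .formats import AlignmentReader

    gene_ids = [g.id for g in genes]
    posmap = {
        chrom: np.full(ln, -1, dtype=np.int32) for chrom, ln in chrom_lengths.items()
    }
    for gi, g in enumerate(genes):
        arr = posmap[g.chrom]
        for tx in g.transcripts:
            for s, e in tx.exons:
                arr[s - 1 : e] = gi
    counts = np.zeros((len(genes), len(sheet.samples)), dtype=np.int64)
    for j, s in enumerate(sheet.samples):
        with AlignmentReader(s.path) as reader:
            for rec in reader:
                arr = posmap.get(rec.reference_name)
                if arr is None:
                    continue
                span = arr[rec.reference_start : rec.reference_end]
                hit = span[span >= 0]
                if len(hit) == 0:
                    continue
                counts[np.bincount(hit).argmax(), j] += 1
    return pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene"), columns=sheet.ids)


# ---------------------------------------------------------------------------
# Normalization and dispersion

def size_factors(matrix: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Falls back (with a warning) to total-count ratios when no feature is
    positive in every sample.
    """
    X = np.asarray(matrix, dtype=float)
    allpos = (X > 0).all(axis=1)
    if allpos.sum() == 0:
        warnings.warn(
            "no feature is positive in all samples; using total-count ratios",
            RuntimeWarning,
        )
        totals = X.sum(axis=0)
        if (totals == 0).any():
            raise ValueError("a sample has zero total counts")
        sf = totals
    else:
        ref = X[allpos]
        geo = np.exp(np.mean(np.log(ref), axis=1))
        sf = np.median(ref / geo[:, None], axis=0)
    sf = sf / np.exp(np.mean(np.log(sf)))
    return sf


def estimate_dispersion(
    matrix: pd.DataFrame | np.ndarray,
    factors: np.ndarray,
    conditions: np.ndarray | list[str],
    trend_weight: float = 1.0,
) -> np.ndarray:
    """Per-feature NB dispersion alpha (variance = mu + alpha mu^2).

    Method-of-moments on size-factor-normalized counts, pooling the
    within-condition variance across the two groups, then shrunk toward
    a fitted a0 + a1/mu trend with weight ``trend_weight``.
    """
    X = np.asarray(matrix, dtype=float) / np.asarray(factors)[None, :]
    conditions = np.asarray(conditions)
    groups = [X[:, conditions == c] for c in pd.unique(conditions)]
    if any(g.shape[1] < 2 for g in groups):
        raise ValueError("need >= 2 replicates per condition for dispersion")
    num = sum((g.shape[1] - 1) * g.var(axis=1, ddof=1) for g in groups)
    den = sum(g.shape[1] - 1 for g in groups)
    s2 = num / den
    mu = X.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        raw = np.where(mu > 0, (s2 - mu) / np.maximum(mu, 1e-12) ** 2, 0.0)

    # mean-dispersion trend alpha(mu) = a0 + a1/mu, fitted to the UNCLIPPED
    # moment estimates: E[(s2 - mu)/mu^2] ~ alpha, so including negative
    # estimates keeps the fit unbiased near alpha = 0; only the fitted curve
    # is clamped. Fitting clipped values would inflate the trend for
    # low-dispersion data and cost power.
    use = mu > 0
    if use.sum() >= 10:
        A = np.column_stack([np.ones(use.sum()), 1.0 / mu[use]])
        coef, *_ = np.linalg.lstsq(A, raw[use], rcond=None)
        trend = np.clip(coef[0] + coef[1] / np.maximum(mu, 1e-12), 0.0, None)
    else:
        med = float(np.median(raw[use])) if use.any() else 0.0
        trend = np.full_like(raw, max(med, 0.0))
    alpha = (1.0 - trend_weight) * np.clip(raw, 0.0, None) + trend_weight * trend
    return np.clip(alpha, 0.0, None)


# ---------------------------------------------------------------------------
# Testing

def _moment_fallback(y, sf, x, alpha):
    """Pseudocount moment estimate when the GLM fails to converge."""
    xn = (y + 0.5) / sf
    g1, g2 = xn[x == 0], xn[x == 1]
    m1, m2 = g1.mean(), g2.mean()
    beta = np.log(m2 / m1)
    var1 = (m1 + alpha * m1**2) / len(g1)
    var2 = (m2 + alpha * m2**2) / len(g2)
    se = np.sqrt(var1 / m1**2 + var2 / m2**2)
    return beta, se


def nb_wald_test(
    matrix: pd.DataFrame,
    factors: np.ndarray,
    dispersions: np.ndarray,
    conditions: np.ndarray | list[str],
    ref_condition: str | None = None,
) -> pd.DataFrame:
    """Per-feature NB GLM Wald test of the two-condition contrast.

    Returns a table with baseMean, log2FoldChange (treated vs control),
    lfcSE, stat, pvalue, padj. Features with all-zero counts get NA
    statistics and do not enter the multiplicity correction.

    The GLM is fitted to size-factor-normalized counts (the same scale on
    which dispersion is estimated) rather than to raw counts with offsets:
    with size factors near 1 the two fits are numerically indistinguishable,
    and the normalized-scale fit makes log2 fold changes exactly invariant
    to rescaling any sample's column.
    """
    conditions = np.asarray(conditions)
    levels = list(pd.unique(conditions))
    if len(levels) != 2:
        raise ValueError(f"need exactly two conditions, got {levels}")
    if ref_condition is None:
        ref_condition = levels[0]
    x = (conditions != ref_condition).astype(float)
    X = np.column_stack([np.ones_like(x), x])
    sf = np.asarray(factors, dtype=float)
    Y = np.asarray(matrix, dtype=float)
    Yn = Y / sf[None, :]

    n = Y.shape[0]
    base_mean = (Y / sf[None, :]).mean(axis=1)
    lfc = np.full(n, np.nan)
    se = np.full(n, np.nan)
    stat = np.full(n, np.nan)
    pval = np.full(n, np.nan)
    for i in range(n):
        y = Y[i]
        if y.sum() == 0:
            continue
        alpha = float(dispersions[i])
        fam = (
            sm.families.Poisson()
            if alpha < 1e-8
            else sm.families.NegativeBinomial(alpha=alpha)
        )
        beta = s = None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = sm.GLM(Yn[i], X, family=fam).fit(maxiter=100, tol=1e-10)
                beta, s = res.params[1], res.bse[1]
            except Exception:
                pass
        if beta is None or not np.isfinite(beta) or not np.isfinite(s) or s > 20:
            beta, s = _moment_fallback(y, sf, x, alpha)
        lfc[i] = beta / LN2
        se[i] = s / LN2
        stat[i] = beta / s
        pval[i] = 2.0 * _norm_sf(abs(stat[i]))

    padj = bh_adjust(pval)
    # pseudocount-based naive estimate for display on zero-heavy rows
    xn = (Y + 0.5) / sf[None, :]
    naive = np.log2(xn[:, x == 1].mean(axis=1) / xn[:, x == 0].mean(axis=1))
    return pd.DataFrame(
        {
            "baseMean": base_mean,
            "log2FoldChange": lfc,
            "lfcSE": se,
            "stat": stat,
            "pvalue": pval,
            "padj": padj,
            "log2FC_pseudo": naive,
        },
        index=matrix.index if isinstance(matrix, pd.DataFrame) else None,
    )


def _norm_sf(z: float) -> float:
    from scipy.stats import norm

    return float(norm.sf(z))


def bh_adjust(pvalues: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up with monotonicity; NaN propagated and
    excluded from m."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = int(ok.sum())
    if m == 0:
        return out
    ps = p[ok]
    order = np.argsort(ps, kind="mergesort")
    ranked = ps[order] * m / (np.arange(m) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.clip(adj, 0.0, 1.0)
    res = np.empty(m)
    res[order] = adj
    out[ok] = res
    return out


def de_call(
    results: pd.DataFrame, fdr: float = 0.05, lfc: float = 0.0
) -> pd.DataFrame:
    """Attach a significance call: up / down / ns.

    Expression analysis uses fdr=0.05, lfc=1.2 (|log2FC| gate); editing
    analyses use the adjusted-p criterion only (lfc=0).
    """
    out = results.copy()
    sig = out["padj"].notna() & (out["padj"] < fdr)
    up = sig & (out["log2FoldChange"] > lfc)
    down = sig & (out["log2FoldChange"] < -lfc)
    out["call"] = np.where(up, "up", np.where(down, "down", "ns"))
    return out


def significant_sets(results_with_call: pd.DataFrame) -> dict[str, set]:
    return {
        "up": set(results_with_call.index[results_with_call["call"] == "up"]),
        "down": set(results_with_call.index[results_with_call["call"] == "down"]),
    }


# ---------------------------------------------------------------------------
# TPM

def tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts-per-million from gene counts and merged-exon lengths.

    Every column sums to 1e6 (within floating-point error) unless the
    sample has no assigned reads at all.
    """
    lens = lengths.reindex(counts.index)
    if lens.isna().any():
        missing = list(counts.index[lens.isna()])
        raise ValueError(f"no length for genes {missing[:5]}")
    if (lens <= 0).any():
        raise ValueError("gene lengths must be positive")
    rate = counts.div(lens, axis=0)
    denom = rate.sum(axis=0)
    return rate.div(denom.replace(0, np.nan), axis=1) * 1e6


def run_differential(
    matrix: pd.DataFrame,
    conditions: list[str] | np.ndarray,
    ref_condition: str,
    fdr: float = 0.05,
    lfc_gate: float = 0.0,
    trend_weight: float = 1.0,
) -> pd.DataFrame:
    """Size factors -> dispersion -> Wald test -> BH -> call, in one step."""
    nonzero = matrix.sum(axis=1) > 0
    sf = size_factors(matrix.loc[nonzero]) if nonzero.any() else np.ones(matrix.shape[1])
    disp = np.zeros(matrix.shape[0])
    disp[nonzero.to_numpy()] = estimate_dispersion(
        matrix.loc[nonzero], sf, conditions, trend_weight
    )
    res = nb_wald_test(matrix, sf, disp, conditions, ref_condition)
    return de_call(res, fdr=fdr, lfc=lfc_gate)
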