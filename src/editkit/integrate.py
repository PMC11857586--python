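"""Integration of the editing and expression layers.

Covers the set overlap of the three differential analyses, the
nine-quadrant editing-vs-expression classification, PCA of editing
frequencies across replicates, editing-enzyme correlation (mean allele
frequency of a target gene's sites vs expression of an enzyme gene),
and the cohort summary report. The Venn is computed on host-gene ids
throughout, since site and gene results must share an id space to be
intersected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .formats import SampleSheet


# ---------------------------------------------------------------------------
# Venn

def venn3(a: set, b: set, c: set) -> dict[str, int]:
    """Counts of the seven regions of a three-set Venn diagram."""
    return {
        "a_only": len(a - b - c),
        "b_only": len(b - a - c),
        "c_only": len(c - a - b),
        "ab": len((a & b) - c),
        "ac": len((a & c) - b),
        "bc": len((b & c) - a),
        "abc": len(a & b & c),
        "union": len(a | b | c),
    }


# ---------------------------------------------------------------------------
# Nine-quadrant classification

COLOR_CLASSES = ("both", "editing_only", "expression_only", "neither")


def quadrant_classify(
    editing: pd.DataFrame, expression: pd.DataFrame
) -> pd.DataFrame:
    """Per-gene 3x3 classification from two called result tables.

    Both inputs need ``log2FoldChange`` and ``call`` columns indexed by
    gene. Genes missing from one table take the ns state on that axis.
    The color class follows the usual legend: significant in both /
    editing only / expression only / neither.
    """
    genes = editing.index.union(expression.index)
    ed = editing.reindex(genes)
    ex = expression.reindex(genes)
    ed_call = ed["call"].fillna("ns")
    ex_call = ex["call"].fillna("ns")
    quadrant = "editing_" + ed_call + "|expression_" + ex_call
    ed_sig = ed_call != "ns"
    ex_sig = ex_call != "ns"
    color = np.where(
        ed_sig & ex_sig,
        "both",
        np.where(ed_sig, "editing_only", np.where(ex_sig, "expression_only", "neither")),
    )
    return pd.DataFrame(
        {
            "editing_log2fc": ed["log2FoldChange"],
            "expression_log2fc": ex["log2FoldChange"],
            "editing_call": ed_call,
            "expression_call": ex_call,
            "quadrant": quadrant,
            "color": color,
        },
        index=genes,
    )


# ---------------------------------------------------------------------------
# PCA of editing frequencies

def editing_pca(
    freq_matrix: pd.DataFrame, n_components: int | None = None
) -> tuple[pd.DataFrame, np.ndarray]:
    """Project samples from the sites x samples frequency matrix via SVD.

    Missing entries are imputed with the per-site mean across samples;
    sites missing everywhere are dropped. Returns (sample coordinates,
    percent variance per component, non-increasing).
    """
    X = freq_matrix.to_numpy(dtype=float)
    all_missing = np.isnan(X).all(axis=1)
    X = X[~all_missing]
    if X.shape[0] == 0 or X.shape[1] < 2:
        raise ValueError("need >= 1 usable site and >= 2 samples")
    row_mean = np.nanmean(X, axis=1)
    nan_r, nan_c = np.nonzero(np.isnan(X))
    X[nan_r, nan_c] = row_mean[nan_r]
    Xc = X - X.mean(axis=1, keepdims=True)
    # samples are observations: decompose the samples x sites matrix
    U, s, Vt = np.linalg.svd(Xc.T, full_matrices=False)
    var = s**2
    total = var.sum()
    # centering residue on constant data is O(eps); treat it as zero variance
    if total <= (np.finfo(float).eps * max(X.shape) * max(1.0, np.abs(X).max())) ** 2:
        pct = np.zeros_like(var)
    else:
        pct = 100.0 * var / total
    k = n_components or min(len(s), freq_matrix.shape[1])
    coords = (U[:, :k] * s[:k])
    out = pd.DataFrame(
        coords,
        index=freq_matrix.columns,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    return out, pct[:k]


# ---------------------------------------------------------------------------
# MAF-expression correlation

@dataclass
class CorrelationResult:
    enzyme_gene: str
    target_gene: str
    maf: np.ndarray
    expression: np.ndarray
    r: float
    pvalue: float
    n: int


def gene_maf(
    sites: pd.DataFrame,
    gene_id: str,
    sample_ids: list[str],
    depth_weighted: bool = False,
) -> pd.Series:
    """Per-sample mean allele frequency across a gene's retained sites.

    Unweighted by default; ``depth_weighted`` averages site frequencies
    weighted by ref+alt depth instead. Missing frequencies are ignored.
    """
    sub = sites[sites["gene"] == gene_id]
    if len(sub) == 0:
        raise ValueError(f"gene {gene_id!r} has no retained editing sites")
    out = {}
    for sid in sample_ids:
        f = sub[f"{sid}_freq"].to_numpy(dtype=float)
        if depth_weighted:
            w = (sub[f"{sid}_ref"] + sub[f"{sid}_alt"]).to_numpy(dtype=float)
            ok = ~np.isnan(f) & (w > 0)
            out[sid] = float(np.average(f[ok], weights=w[ok])) if ok.any() else np.nan
        else:
            out[sid] = float(np.nanmean(f)) if (~np.isnan(f)).any() else np.nan
    return pd.Series(out)


def maf_expression_correlation(
    target_gene: str,
    sites: pd.DataFrame,
    enzyme_gene: str,
    tpm_matrix: pd.DataFrame,
    depth_weighted: bool = False,
) -> CorrelationResult:
    """Pearson correlation of a target's mean MAF with an enzyme's TPM.

    Two-sided p from the t reference on n-2 degrees of freedom; raises
    when fewer than 3 paired samples or either vector is constant.
    """
    maf = gene_maf(sites, target_gene, list(tpm_matrix.columns), depth_weighted)
    expr = tpm_matrix.loc[enzyme_gene]
    ok = maf.notna() & expr.notna()
    n = int(ok.sum())
    if n < 3:
        raise ValueError(f"correlation undefined: only {n} paired samples")
    mv, ev = maf[ok].to_numpy(), expr[ok].to_numpy(dtype=float)
    if np.ptp(mv) == 0 or np.ptp(ev) == 0:
        raise ValueError("correlation undefined: zero variance in a vector")
    r, p = stats.pearsonr(ev, mv)
    return CorrelationResult(enzyme_gene, target_gene, mv, ev, float(r), float(p), n)


# ---------------------------------------------------------------------------
# Cohort report

def group_totals(per_sample_counts: dict[str, list[int]]) -> dict[str, int]:
    """Group totals as the SUM of per-sample locus counts (the tabular
    reporting convention: a locus detected in k samples counts k times)."""
    return {cond: int(sum(v)) for cond, v in per_sample_counts.items()}


def significant_site_totals(calls: pd.Series) -> dict[str, int]:
    """Up / down / total tallies of a per-site significance call vector."""
    up = int((calls == "up").sum())
    down = int((calls == "down").sum())
    return {"up": up, "down": down, "total": up + down}


def cohort_report(
    annotated_sites: pd.DataFrame,
    sheet: SampleSheet,
    site_results: pd.DataFrame | None = None,
) -> dict:
    """Summary document of the editing cohort.

    Per-sample locus counts use the per-sample pass flags; group totals
    are sums of per-sample counts. When a called site-level differential
    table is supplied, up/down/total significant sites and their host
    gene accounting (including genes carrying both directions) are
    included.
    """
    per_sample = {
        sid: int(annotated_sites[f"{sid}_pass"].astype(bool).sum())
        for sid in sheet.ids
    }
    per_condition = {
        cond: [per_sample[sid] for sid in sheet.ids_for(cond)]
        for cond in sheet.conditions
    }
    report: dict = {
        "n_retained_sites": int(len(annotated_sites)),
        "per_sample_loci": per_sample,
        "group_totals": group_totals(per_condition),
        "class_counts": annotated_sites["class"].value_counts().to_dict(),
        "region_counts": annotated_sites["region"].value_counts().to_dict(),
    }
    total = len(annotated_sites)
    if total:
        report["class_proportions"] = {
            k: v / total for k, v in report["class_counts"].items()
        }
    if site_results is not None:
        merged = annotated_sites.copy()
        merged.index = [
            f"{r.chrom}:{r.pos}:{r.alt}" for r in annotated_sites.itertuples()
        ]
        calls = site_results["call"].reindex(merged.index).fillna("ns")
        up_sites = merged.index[calls == "up"]
        down_sites = merged.index[calls == "down"]
        gene_of = merged["gene"]
        up_genes = {
            g for g in gene_of.loc[up_sites] if g not in (".", "intergenic")
        }
        down_genes = {
            g for g in gene_of.loc[down_sites] if g not in (".", "intergenic")
        }
        report["significant_sites"] = significant_site_totals(calls)
        report["significant_site_genes"] = {
            "up": len(up_genes),
            "down": len(down_genes),
            "both_directions": len(up_genes & down_genes),
            "total": len(up_genes | down_genes),
        }
    return report
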