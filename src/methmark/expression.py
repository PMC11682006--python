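"""Methylation–expression concordance for panel CpGs.

Each panel CpG is classified by genomic context — *promoter* (TSS−1500 to
TSS+300 on the gene's strand-oriented axis), *gene body* (inside the gene
span but outside the promoter window) or *intergenic* (no gene assigned).
The host gene's differential expression between tumor and control samples
is then tested with a normality-gated test (D'Agostino–Pearson on each
group at α = 0.05; Student t if both groups look normal, Mann–Whitney U
otherwise), and the direction is scored against the textbook expectation:
promoter CGI hypermethylation represses transcription, gene-body CGI
hypermethylation accompanies activation.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

REGIONS = ("promoter", "gene_body", "intergenic")
EXPR_STATUSES = ("not_expressed", "unchanged", "down", "up")

PROMOTER_UPSTREAM = 1500
PROMOTER_DOWNSTREAM = 300


def classify_region(entry: Mapping) -> str:
    """Promoter / gene-body / intergenic class for one manifest entry.

    The promoter window is closed on both ends and strand-oriented:
    "upstream" means 5' of the TSS.  A probe inside both the promoter
    window and the gene span is promoter (the window overlaps first exons
    by construction).
    """
    gene = entry.get("gene")
    if gene is None or (isinstance(gene, float) and np.isnan(gene)) or gene == "":
        return "intergenic"
    tss = entry.get("tss_pos")
    if tss is None or (isinstance(tss, float) and np.isnan(tss)):
        raise ValueError(f"gene {gene!r} assigned but tss_pos missing")
    pos, tss = float(entry["pos"]), float(tss)
    if entry.get("strand") == "-":
        lo, hi = tss - PROMOTER_DOWNSTREAM, tss + PROMOTER_UPSTREAM
    else:
        lo, hi = tss - PROMOTER_UPSTREAM, tss + PROMOTER_DOWNSTREAM
    if lo <= pos <= hi:
        return "promoter"
    gs, ge = entry.get("gene_start"), entry.get("gene_end")
    if gs is not None and ge is not None and not (
            np.isnan(float(gs)) or np.isnan(float(ge))):
        if float(gs) <= pos <= float(ge):
            return "gene_body"
    raise ValueError(
        f"probe at {pos:.0f} has gene {gene!r} but lies in neither the "
        "promoter window nor the gene span")


def log_cpm(counts: pd.DataFrame, pseudocount: float = 0.5) -> pd.DataFrame:
    """log2(CPM + pseudocount) from a raw gene × sample count matrix."""
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise ValueError(f"samples with zero total count: {bad[:5]}")
    cpm = counts / totals * 1e6
    return np.log2(cpm + pseudocount)


def _cpm_from_log(logcpm: pd.Series, pseudocount: float) -> pd.Series:
    return (2.0 ** logcpm - pseudocount).clip(lower=0.0)


def expression_status(gene: str, logcpm: pd.DataFrame, sheet: pd.DataFrame,
                      alpha: float = 0.001, not_expressed_cpm: float = 1.0,
                      pseudocount: float = 0.5,
                      control_group: str = "adjacent") -> str:
    """not_expressed / unchanged / down / up call for one panel gene.

    A gene is *not expressed* when its median CPM is below
    ``not_expressed_cpm`` in both tumor and control groups.  Otherwise the
    groups are compared with a two-sided Student t-test when both pass the
    D'Agostino–Pearson normality check (α = 0.05), and Mann–Whitney U
    otherwise; groups with fewer than 8 samples fall back to Mann–Whitney
    with a warning (the normality test is undefined there).  ``down`` / ``up``
    require p < ``alpha`` (default 0.001).
    """
    if gene not in logcpm.index:
        raise ValueError(f"gene {gene!r} absent from expression matrix")
    t_cols = sheet.loc[sheet["group"] == "tumor", "sample_id"].tolist()
    c_cols = sheet.loc[sheet["group"] == control_group, "sample_id"].tolist()
    if not t_cols or not c_cols:
        raise ValueError("need tumor and control samples")
    t_log = logcpm.loc[gene, t_cols].to_numpy(dtype=float)
    c_log = logcpm.loc[gene, c_cols].to_numpy(dtype=float)

    t_cpm = _cpm_from_log(pd.Series(t_log), pseudocount)
    c_cpm = _cpm_from_log(pd.Series(c_log), pseudocount)
    if (np.median(t_cpm) < not_expressed_cpm
            and np.median(c_cpm) < not_expressed_cpm):
        return "not_expressed"

    if len(t_log) >= 8 and len(c_log) >= 8:
        normal = (stats.normaltest(t_log).pvalue > 0.05
                  and stats.normaltest(c_log).pvalue > 0.05)
    else:
        warnings.warn(f"{gene}: group too small for normality test; "
                      "using Mann-Whitney U", stacklevel=2)
        normal = False
    if np.var(t_log) == 0 and np.var(c_log) == 0:
        p = 1.0 if np.mean(t_log) == np.mean(c_log) else 0.0
    elif normal:
        p = stats.ttest_ind(t_log, c_log, equal_var=False).pvalue
    else:
        p = stats.mannwhitneyu(t_log, c_log,
                               alternative="two-sided").pvalue
    if p < alpha:
        return "up" if np.mean(t_log) > np.mean(c_log) else "down"
    return "unchanged"


def concordance(region: str, expr_status: str) -> bool | None:
    """Does the expression change match the CpG's location class?

    Concordant = promoter CpG with downregulation, or gene-body CpG with
    upregulation.  Returns ``None`` (not applicable) for intergenic probes
    or genes without a significant change.
    """
    if region == "intergenic" or expr_status in ("not_expressed", "unchanged"):
        return None
    return (region == "promoter" and expr_status == "down") or \
           (region == "gene_body" and expr_status == "up")


def tissue_repression(gene: str, tpm: pd.DataFrame,
                      index_tissue: str = "liver", low_tpm: float = 1.0,
                      ratio: float = 0.25) -> str:
    """Tissue-of-origin expression pattern of a hypermethylated gene.

    ``broadly_silent``: median TPM over all tissues < ``low_tpm``;
    ``repressed_in_index``: index-tissue TPM < ``low_tpm`` and below
    ``ratio`` × the median of the other tissues; else ``expressed_in_index``.
    Genes repressed specifically in the index tissue are the expected
    substrate of index-tumor-specific hypermethylation.
    """
    if gene not in tpm.index:
        raise ValueError(f"gene {gene!r} absent from TPM table")
    if index_tissue not in tpm.columns:
        raise ValueError(f"tissue {index_tissue!r} absent from TPM table")
    if tpm.shape[1] < 2:
        raise ValueError("need at least two tissues")
    row = tpm.loc[gene]
    if float(row.median()) < low_tpm:
        return "broadly_silent"
    idx = float(row[index_tissue])
    others = row.drop(index_tissue)
    if idx < low_tpm and idx < ratio * float(others.median()):
        return "repressed_in_index"
    return "expressed_in_index"


def concordance_table(panel: Sequence[str], manifest: pd.DataFrame,
                      logcpm: pd.DataFrame, sheet: pd.DataFrame,
                      alpha: float = 0.001, not_expressed_cpm: float = 1.0,
                      pseudocount: float = 0.5,
                      control_group: str = "adjacent") -> pd.DataFrame:
    """One region/expression/concordance record per panel probe."""
    rows = []
    status_cache: dict[str, str] = {}
    for p in panel:
        entry = manifest.loc[p].to_dict()
        entry["pos"] = manifest.at[p, "pos"]
        region = classify_region(entry)
        gene = entry.get("gene")
        gene = "" if (gene is None or (isinstance(gene, float)
                                       and np.isnan(gene))) else str(gene)
        if region == "intergenic" or not gene:
            status = "not_applicable"
        else:
            if gene not in status_cache:
                status_cache[gene] = expression_status(
                    gene, logcpm, sheet, alpha=alpha,
                    not_expressed_cpm=not_expressed_cpm,
                    pseudocount=pseudocount, control_group=control_group)
            status = status_cache[gene]
        conc = (None if status == "not_applicable"
                else concordance(region, status))
        rows.append({"probe_id": p, "gene": gene, "region": region,
                     "expr_status": status,
                     "concordant": conc})
    return pd.DataFrame(rows)


def location_expression_table(records: pd.DataFrame) -> pd.DataFrame:
    """Cross-tabulate CpG location against host-gene expression outcome.

    Rows: promoter / gene_body / intergenic / total.  Columns: number of
    CpGs, number of distinct genes, and distinct-gene counts per expression
    status.  A gene with several probes counts once per gene-level cell and
    once per probe in the CpG column.
    """
    cols = ["n_cpgs", "n_genes"] + [f"genes_{s}" for s in EXPR_STATUSES]
    table = pd.DataFrame(0, index=list(REGIONS) + ["total"], columns=cols)
    table.index.name = "region"
    for region in REGIONS:
        sub = records[records["region"] == region]
        genes = sub.loc[sub["gene"] != "", "gene"]
        table.loc[region, "n_cpgs"] = len(sub)
        table.loc[region, "n_genes"] = genes.nunique()
        for s in EXPR_STATUSES:
            table.loc[region, f"genes_{s}"] = \
                sub.loc[sub["expr_status"] == s, "gene"].nunique()
    all_genes = records.loc[records["gene"] != "", "gene"]
    table.loc["total", "n_cpgs"] = len(records)
    table.loc["total", "n_genes"] = all_genes.nunique()
    for s in EXPR_STATUSES:
        table.loc["total", f"genes_{s}"] = \
            records.loc[records["expr_status"] == s, "gene"].nunique()
    return table
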