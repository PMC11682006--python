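"""Per-CpG differential methylation between sample groups.

The core statistic is Δβ = mean β(case) − mean β(control), tested per CpG
with a two-sided Student t-test (equal variance by default, Welch behind a
flag) and corrected over all tested probes with the Benjamini–Hochberg
step-up.  A probe is called *hypermethylated* when Δβ > ``delta_thresh``
and q < ``fdr_thresh``, *hypomethylated* when Δβ < −``delta_thresh`` and
q < ``fdr_thresh``, otherwise *ns* — all inequalities strict.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from statsmodels.stats.multitest import multipletests

from .config import NON_TUMOR_GROUPS

DMC_COLUMNS = ["probe_id", "mean_beta_case", "mean_beta_control",
               "delta", "p_value", "q_value", "status", "zero_variance"]


def group_samples(sheet: pd.DataFrame, groups: str | Iterable[str]) -> list[str]:
    """Sample ids belonging to one group or an iterable of groups."""
    if isinstance(groups, str):
        groups = [groups]
    groups = list(groups)
    ids = sheet.loc[sheet["group"].isin(groups), "sample_id"].tolist()
    if not ids:
        raise ValueError(f"no samples in group(s) {groups}")
    return ids


def group_mean_beta(beta: pd.DataFrame, sheet: pd.DataFrame,
                    group: str | Iterable[str]) -> pd.Series:
    """Arithmetic mean β per probe over the samples of ``group``."""
    cols = group_samples(sheet, group)
    return beta[cols].mean(axis=1)


def bh_adjust(p: np.ndarray | Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values over one family of tests."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def classify_dmc(delta: float, significant: bool,
                 delta_thresh: float = 0.2) -> str:
    """Hyper / hypo / ns call for one probe; thresholds strict."""
    if significant and delta > delta_thresh:
        return "hyper"
    if significant and delta < -delta_thresh:
        return "hypo"
    return "ns"


def dmc_test(beta: pd.DataFrame, sheet: pd.DataFrame,
             case: str | Iterable[str], control: str | Iterable[str],
             delta_thresh: float = 0.2, fdr_thresh: float = 0.05,
             equal_var: bool = True) -> pd.DataFrame:
    """Per-probe Δβ with t-test p, BH q and hyper/hypo/ns status.

    ``case`` and ``control`` name sample-sheet groups (one or several, e.g.
    ``["healthy", "adjacent", "cirrhotic"]`` pooled as the control set).
    Both sets need at least two samples.  Probes where both groups have zero
    variance get p = 1 when Δβ = 0 and p = 0 (flagged ``zero_variance``)
    otherwise, so degenerate simulations do not abort the scan.

    Returns a frame sorted by ascending q, then descending Δβ, then probe id.
    """
    case_cols = group_samples(sheet, case)
    ctrl_cols = group_samples(sheet, control)
    if len(case_cols) < 2 or len(ctrl_cols) < 2:
        raise ValueError("dmc_test requires >= 2 samples per side")
    x = beta[case_cols].to_numpy(dtype=float)
    y = beta[ctrl_cols].to_numpy(dtype=float)

    mean_case = x.mean(axis=1)
    mean_ctrl = y.mean(axis=1)
    delta = mean_case - mean_ctrl

    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(x, y, axis=1, equal_var=equal_var)

    # constant groups detected by range (variance of a constant float array
    # can be a tiny non-zero due to cancellation)
    degenerate = (np.ptp(x, axis=1) == 0) & (np.ptp(y, axis=1) == 0)
    p = np.where(degenerate & (delta == 0), 1.0, p)
    p = np.where(degenerate & (delta != 0), 0.0, p)
    if np.isnan(p).any():
        raise ValueError("NaN p-values (missing β values in tested matrix?)")

    q = bh_adjust(p)
    significant = q < fdr_thresh
    status = np.where(significant & (delta > delta_thresh), "hyper",
                      np.where(significant & (delta < -delta_thresh),
                               "hypo", "ns"))

    out = pd.DataFrame({
        "probe_id": beta.index,
        "mean_beta_case": mean_case,
        "mean_beta_control": mean_ctrl,
        "delta": delta,
        "p_value": p,
        "q_value": q,
        "status": status,
        "zero_variance": degenerate,
    })
    out = out.sort_values(["q_value", "delta", "probe_id"],
                          ascending=[True, False, True], kind="mergesort")
    return out.reset_index(drop=True)


def cgi_subset(beta: pd.DataFrame, manifest: pd.DataFrame) -> pd.DataFrame:
    """Restrict a β matrix to probes inside CpG islands, order preserved."""
    absent = beta.index.difference(manifest.index)
    if len(absent) > 0:
        raise ValueError(
            f"probes absent from manifest: {sorted(absent)[:5]}")
    keep = manifest.loc[beta.index, "in_cgi"].to_numpy(bool)
    return beta.loc[keep]


def global_hyper_enrichment(records: pd.DataFrame) -> tuple[int, int, float]:
    """Exact two-sided binomial test of hyper vs hypo counts against 0.5.

    Quantifies whether significant CpG-island changes skew toward
    hypermethylation, the expected direction in tumors.
    """
    n_hyper = int((records["status"] == "hyper").sum())
    n_hypo = int((records["status"] == "hypo").sum())
    if n_hyper + n_hypo == 0:
        raise ValueError("no significant hyper/hypo records")
    p = stats.binomtest(n_hyper, n_hyper + n_hypo, 0.5,
                        alternative="two-sided").pvalue
    return n_hyper, n_hypo, float(p)


def cluster_qc(beta: pd.DataFrame, sheet: pd.DataFrame
               ) -> tuple[dict[str, int], float]:
    """Ward-linkage clustering QC: do samples split tumor vs non-tumor?

    Agglomerative clustering (Ward criterion, Euclidean distance) on the
    sample β profiles, tree cut at two clusters.  Agreement is the best
    over the two cluster↔status mappings of the fraction of samples whose
    cluster matches their tumor / non-tumor status.
    """
    if beta.isna().any().any():
        raise ValueError("cluster_qc requires a complete (no-missing) matrix")
    if beta.shape[0] < 2 or beta.shape[1] < 2:
        raise ValueError("need >= 2 probes and >= 2 samples")
    X = beta.to_numpy(dtype=float).T
    status = sheet.set_index("sample_id").loc[beta.columns, "group"] == "tumor"
    is_tumor = status.to_numpy(bool)
    if np.ptp(X, axis=0).max() == 0:
        # all profiles identical: a single cluster; agreement is the
        # majority-class frequency
        labels = np.ones(X.shape[0], dtype=int)
    else:
        Z = linkage(X, method="ward")
        labels = fcluster(Z, t=2, criterion="maxclust")
    agree1 = float(np.mean((labels == 1) == is_tumor))
    agreement = max(agree1, 1.0 - agree1)
    return dict(zip(beta.columns, (int(c) for c in labels))), agreement


def candidate_hyper_probes(records: pd.DataFrame) -> list[str]:
    """Probe ids called hypermethylated, in the frame's (ranked) order."""
    return records.loc[records["status"] == "hyper", "probe_id"].tolist()
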