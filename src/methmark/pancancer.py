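"""Pan-cancer specificity of panel CpGs across tumor-type cohorts.

Each tumor-type cohort is summarized to per-probe tumor (T) and, when
enough peritumoral samples exist, non-tumor (NT) group means.  Cohorts with
controls support a hypermethylation call (mean Δβ = T − NT > 0.2); cohorts
without controls can only corroborate that the tumor tissue is methylated
(T mean > 0.2) and never contribute to specificity decisions.  A probe is
*index-exclusive* when the index tumor type (LIHC by default) is the only
control-bearing cohort where it is hypermethylated, and *pan-cancer* when
it is hypermethylated in ``pan_min`` (default 10) or more tumor types.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd


@dataclass
class TumorCohortSummary:
    """Per-probe group means for one tumor-type cohort."""

    tissue_code: str
    has_controls: bool
    mean_beta_t: pd.Series
    mean_beta_nt: pd.Series | None
    n_t: int
    n_nt: int


def summarize_cohort(beta: pd.DataFrame, sheet: pd.DataFrame,
                     tissue_code: str, min_controls: int = 5
                     ) -> TumorCohortSummary:
    """Summarize one cohort to tumor / non-tumor mean β per probe.

    The cohort counts as control-bearing only when it has *more than*
    ``min_controls`` non-tumoral (peritumoral/healthy) samples; smaller
    control arms are ignored rather than trusted.
    """
    t_cols = sheet.loc[sheet["group"] == "tumor", "sample_id"].tolist()
    if not t_cols:
        raise ValueError(f"{tissue_code}: no tumor samples")
    nt_cols = sheet.loc[sheet["group"].isin(("adjacent", "healthy")),
                        "sample_id"].tolist()
    has_controls = len(nt_cols) > min_controls
    return TumorCohortSummary(
        tissue_code=tissue_code,
        has_controls=has_controls,
        mean_beta_t=beta[t_cols].mean(axis=1),
        mean_beta_nt=beta[nt_cols].mean(axis=1) if has_controls else None,
        n_t=len(t_cols),
        n_nt=len(nt_cols),
    )


def baseline_tissue_status(summaries: Sequence[TumorCohortSummary],
                           probe: str, meth_thresh: float = 0.2) -> int:
    """Number of control-bearing tissues whose NT mean β exceeds the threshold.

    Establishes the probe's physiological baseline: panel markers are
    expected to be unmethylated in (nearly) all healthy tissues.
    """
    return sum(1 for s in summaries
               if s.has_controls and s.mean_beta_nt[probe] > meth_thresh)


def hyper_calls(summaries: Sequence[TumorCohortSummary], probe: str,
                delta_thresh: float = 0.2, meth_thresh: float = 0.2
                ) -> tuple[set[str], set[str]]:
    """(hyper_tumors, meth_tumor_only) tissue sets for one probe.

    Control-bearing cohorts enter ``hyper_tumors`` on mean Δβ > delta_thresh;
    tumor-only cohorts enter ``meth_tumor_only`` on T mean β > meth_thresh.
    """
    hyper, meth_only = set(), set()
    for s in summaries:
        if s.has_controls:
            if s.mean_beta_t[probe] - s.mean_beta_nt[probe] > delta_thresh:
                hyper.add(s.tissue_code)
        elif s.mean_beta_t[probe] > meth_thresh:
            meth_only.add(s.tissue_code)
    return hyper, meth_only


def classify_specificity(hyper_tumors: set[str],
                         control_tissues: Sequence[str],
                         index_tissue: str = "LIHC",
                         pan_min: int = 10) -> str:
    """Specificity class: ``index_exclusive``, ``pan`` or ``shared_k``."""
    if index_tissue not in control_tissues:
        raise ValueError(
            f"index tissue {index_tissue!r} not among control-bearing cohorts")
    if hyper_tumors == {index_tissue}:
        return "index_exclusive"
    if len(hyper_tumors) >= pan_min:
        return "pan"
    return f"shared_{len(hyper_tumors)}"


def specificity_table(summaries: Sequence[TumorCohortSummary],
                      probes: Sequence[str], index_tissue: str = "LIHC",
                      pan_min: int = 10, delta_thresh: float = 0.2,
                      meth_thresh: float = 0.2) -> pd.DataFrame:
    """One specificity call per probe across all cohorts.

    Baseline NT-methylated tissue counts are reported alongside the calls
    without feeding into them.  Deterministic regardless of cohort order.
    """
    ordered = sorted(summaries, key=lambda s: s.tissue_code)
    control_tissues = [s.tissue_code for s in ordered if s.has_controls]
    rows = []
    for p in probes:
        hyper, meth_only = hyper_calls(ordered, p, delta_thresh, meth_thresh)
        rows.append({
            "probe_id": p,
            "nt_methylated_tissues": baseline_tissue_status(
                ordered, p, meth_thresh),
            "n_hyper_tumors": len(hyper),
            "hyper_tumors": ",".join(sorted(hyper)),
            "meth_tumor_only": ",".join(sorted(meth_only)),
            "specificity": classify_specificity(
                hyper, control_tissues, index_tissue, pan_min),
        })
    return pd.DataFrame(rows)


def heatmap_order(calls: pd.DataFrame,
                  summaries: Sequence[TumorCohortSummary]
                  ) -> tuple[list[str], list[str]]:
    """Deterministic display order for the specificity heatmap.

    Probes are ranked by the number of tumor types in which they are
    hypermethylated (most to least); tissues by how many probes they
    hypermethylate (control-bearing cohorts) or methylate (tumor-only
    cohorts).  Ties break lexicographically.
    """
    probe_rank = calls.sort_values(
        ["n_hyper_tumors", "probe_id"], ascending=[False, True],
        kind="mergesort")["probe_id"].tolist()

    tissue_counts: dict[str, int] = {}
    hyper_sets = [set(s.split(",")) - {""}
                  for s in calls["hyper_tumors"]]
    meth_sets = [set(s.split(",")) - {""}
                 for s in calls["meth_tumor_only"]]
    for s in summaries:
        col = hyper_sets if s.has_controls else meth_sets
        tissue_counts[s.tissue_code] = sum(
            1 for probeset in col if s.tissue_code in probeset)
    tissue_rank = sorted(tissue_counts,
                         key=lambda t: (-tissue_counts[t], t))
    return probe_rank, tissue_rank


def heatmap_matrix(summaries: Sequence[TumorCohortSummary],
                   calls: pd.DataFrame) -> pd.DataFrame:
    """Mean-β matrix (probe × tissue:T/NT columns) in heatmap order."""
    probe_order, tissue_order = heatmap_order(calls, summaries)
    by_code = {s.tissue_code: s for s in summaries}
    cols = {}
    for code in tissue_order:
        s = by_code[code]
        if s.has_controls:
            cols[f"{code}:NT"] = s.mean_beta_nt.loc[probe_order]
        cols[f"{code}:T"] = s.mean_beta_t.loc[probe_order]
    return pd.DataFrame(cols, index=pd.Index(probe_order, name="probe_id"))
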