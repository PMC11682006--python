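"""Marker-panel selection: exclusion filters and the two selection branches.

Starting from CpGs called hypermethylated in tumors, the cascade

1. drops probes methylated (β > ``meth_thresh``) in *any* healthy whole-blood
   sample — marks that would confound cell-free DNA assays,
2. drops probes on the epigenetic aging clock,
3. selects branch A: probes unmethylated (β < ``unmeth_thresh``) in **every**
   non-tumoral sample (healthy, cirrhotic and tumor-adjacent) with
   Δβ(tumor − non-tumor) > ``branch_a_delta``,
4. selects branch B: probes unmethylated in every healthy and cirrhotic
   sample but already methylated in tumor-adjacent tissue (field effect)
   and in tumors, with Δβ(tumor − healthy+cirrhotic) > ``branch_b_delta``,

and returns the union as the panel, verifying the summary criterion
(tumor mean β > ``panel_tumor_beta``; healthy and cirrhotic group means
< ``unmeth_thresh``) on every member.  Branches A and B are mutually
exclusive whenever ``unmeth_thresh <= meth_thresh``: a probe with every
adjacent β below ``unmeth_thresh`` cannot have an adjacent mean above
``meth_thresh``.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import FilterConfig, NON_TUMOR_GROUPS
from .dmc import group_samples


def blood_filter(candidates: Sequence[str], blood: pd.DataFrame,
                 meth_thresh: float = 0.2) -> list[str]:
    """Retain probes not methylated in any blood sample.

    A probe is excluded as soon as one blood sample shows β > ``meth_thresh``
    (strict; β exactly at the threshold does not exclude).
    """
    missing = [p for p in candidates if p not in blood.index]
    if missing:
        raise ValueError(f"candidates absent from blood matrix: {missing[:5]}")
    sub = blood.loc[list(candidates)]
    methylated_somewhere = (sub > meth_thresh).any(axis=1)
    return [p for p in candidates if not methylated_somewhere[p]]


def clock_filter(candidates: Sequence[str], clock: set[str]
                 ) -> tuple[list[str], list[str]]:
    """Split candidates into (retained, clock-overlap).

    The overlap is reported rather than assumed empty, so an age-related
    methylation signal sneaking through the cascade is visible.
    """
    retained = [p for p in candidates if p not in clock]
    overlap = [p for p in candidates if p in clock]
    return retained, overlap


def _unmeth_in_all(sub: pd.DataFrame, cols: Sequence[str],
                   thresh: float) -> pd.Series:
    return (sub[cols] < thresh).all(axis=1)


def branch_a(candidates: Sequence[str], beta: pd.DataFrame,
             sheet: pd.DataFrame, cfg: FilterConfig) -> list[str]:
    """Probes unmethylated in every non-tumoral sample, strongly tumor-gained.

    Selected iff β < ``unmeth_thresh`` in each healthy, cirrhotic **and**
    adjacent sample, and mean β(tumor) − mean β(all non-tumoral samples)
    > ``branch_a_delta``.
    """
    nt_cols = group_samples(sheet, NON_TUMOR_GROUPS)
    t_cols = group_samples(sheet, "tumor")
    sub = beta.loc[list(candidates)]
    unmeth = _unmeth_in_all(sub, nt_cols, cfg.unmeth_thresh)
    delta = sub[t_cols].mean(axis=1) - sub[nt_cols].mean(axis=1)
    sel = unmeth & (delta > cfg.branch_a_delta)
    return [p for p in candidates if sel[p]]


def branch_b(candidates: Sequence[str], beta: pd.DataFrame,
             sheet: pd.DataFrame, cfg: FilterConfig) -> list[str]:
    """Probes with field-effect methylation in tumor-adjacent tissue.

    Selected iff β < ``unmeth_thresh`` in every healthy and cirrhotic sample,
    the adjacent group is methylated (> ``meth_thresh``, rule set by
    ``cfg.branch_b_adjacent_rule``), the tumor group mean is methylated, and
    mean β(tumor) − mean β(healthy + cirrhotic) > ``branch_b_delta``.
    """
    hc_cols = group_samples(sheet, ["healthy", "cirrhotic"])
    adj_cols = group_samples(sheet, "adjacent")
    t_cols = group_samples(sheet, "tumor")
    sub = beta.loc[list(candidates)]

    unmeth_hc = _unmeth_in_all(sub, hc_cols, cfg.unmeth_thresh)
    adj = sub[adj_cols]
    if cfg.branch_b_adjacent_rule == "mean":
        adj_meth = adj.mean(axis=1) > cfg.meth_thresh
    elif cfg.branch_b_adjacent_rule == "all":
        adj_meth = (adj > cfg.meth_thresh).all(axis=1)
    else:  # fraction
        adj_meth = ((adj > cfg.meth_thresh).mean(axis=1)
                    >= cfg.branch_b_adjacent_fraction)
    tumor_mean = sub[t_cols].mean(axis=1)
    delta = tumor_mean - sub[hc_cols].mean(axis=1)
    sel = (unmeth_hc & adj_meth & (tumor_mean > cfg.meth_thresh)
           & (delta > cfg.branch_b_delta))
    return [p for p in candidates if sel[p]]


def combine_panel(a: Sequence[str], b: Sequence[str], beta: pd.DataFrame,
                  sheet: pd.DataFrame, cfg: FilterConfig
                  ) -> tuple[list[str], pd.DataFrame]:
    """Union of the two branches plus a summary-criterion audit.

    The audit re-checks each member against the headline description of the
    panel — tumor group mean β > ``panel_tumor_beta`` and healthy / cirrhotic
    group means < ``unmeth_thresh`` — and flags (never drops) discrepancies,
    since the branch rules, not the summary, define membership.
    """
    overlap = sorted(set(a) & set(b))
    panel = list(a) + [p for p in b if p not in set(a)]
    if not panel:
        return [], pd.DataFrame(columns=["probe_id", "branch_a", "branch_b",
                                         "summary_ok", "branch_overlap"])
    sub = beta.loc[panel]
    t_mean = sub[group_samples(sheet, "tumor")].mean(axis=1)
    h_mean = sub[group_samples(sheet, "healthy")].mean(axis=1)
    c_mean = sub[group_samples(sheet, "cirrhotic")].mean(axis=1)
    audit = pd.DataFrame({
        "probe_id": panel,
        "branch_a": [p in set(a) for p in panel],
        "branch_b": [p in set(b) for p in panel],
        "summary_ok": ((t_mean > cfg.panel_tumor_beta)
                       & (h_mean < cfg.unmeth_thresh)
                       & (c_mean < cfg.unmeth_thresh)).to_numpy(),
        "branch_overlap": [p in overlap for p in panel],
    })
    return panel, audit


def disease_exclusion_check(panel: Sequence[str],
                            disease_cohorts: Sequence[tuple[pd.DataFrame,
                                                            pd.DataFrame]],
                            cfg: FilterConfig) -> dict[str, bool]:
    """Flag panel probes hypermethylated in any non-tumor liver-disease cohort.

    For each cohort the probe's Δβ (disease group mean minus within-cohort
    control mean) is compared to ``delta_thresh``; a probe is flagged when
    Δβ > ``delta_thresh`` in at least one cohort.  Panel markers should stay
    unflagged: their methylation tracks malignant transformation, not liver
    damage.
    """
    flags = {p: False for p in panel}
    for beta, sheet in disease_cohorts:
        d_cols = group_samples(sheet, "disease")
        ctrl = sheet.loc[sheet["group"] != "disease", "sample_id"].tolist()
        if not ctrl:
            raise ValueError("disease cohort lacks a control group")
        sub = beta.loc[list(panel)]
        delta = sub[d_cols].mean(axis=1) - sub[ctrl].mean(axis=1)
        for p in panel:
            if delta[p] > cfg.delta_thresh:
                flags[p] = True
    return flags


def tumor_methylation_fraction(panel: Sequence[str],
                               validation: Sequence[tuple[pd.DataFrame,
                                                          pd.DataFrame]],
                               meth_thresh: float = 0.2) -> dict[str, float]:
    """Fraction of pooled validation tumors with β > ``meth_thresh`` per probe.

    Descriptive penetrance of each marker across independent tumor cohorts;
    no threshold is applied.
    """
    cols_per_cohort = []
    for beta, sheet in validation:
        t_cols = sheet.loc[sheet["group"] == "tumor", "sample_id"].tolist()
        if t_cols:
            cols_per_cohort.append(beta.loc[list(panel), t_cols])
    if not cols_per_cohort:
        raise ValueError("no tumor samples in validation cohorts")
    pooled = pd.concat(cols_per_cohort, axis=1)
    frac = (pooled > meth_thresh).mean(axis=1)
    return {p: float(frac[p]) for p in panel}


def build_panel_ledger(candidates: Sequence[str], blood_pass: Sequence[str],
                       clock_pass: Sequence[str], a: Sequence[str],
                       b: Sequence[str], blood: pd.DataFrame,
                       delta_hcc: Mapping[str, float],
                       disease_flags: Mapping[str, bool] | None = None,
                       tumor_fraction: Mapping[str, float] | None = None,
                       ) -> pd.DataFrame:
    """One row per candidate recording every filter decision.

    ``in_panel = branch_a OR branch_b`` and implies both upstream passes;
    per-probe statistics (max blood β, Δβ vs controls, disease flag,
    validation tumor fraction) ride along for the report.
    """
    columns = ["probe_id", "pass_blood", "pass_clock", "branch_a",
               "branch_b", "in_panel", "max_blood_beta", "delta_hcc",
               "disease_flag", "tumor_fraction"]
    if not candidates:
        return pd.DataFrame(columns=columns)
    blood_set, clock_set = set(blood_pass), set(clock_pass)
    a_set, b_set = set(a), set(b)
    max_blood = blood.loc[list(candidates)].max(axis=1)
    rows = []
    for p in candidates:
        in_a, in_b = p in a_set, p in b_set
        rows.append({
            "probe_id": p,
            "pass_blood": p in blood_set,
            "pass_clock": p in clock_set,
            "branch_a": in_a,
            "branch_b": in_b,
            "in_panel": in_a or in_b,
            "max_blood_beta": float(max_blood[p]),
            "delta_hcc": float(delta_hcc[p]),
            "disease_flag": bool(disease_flags.get(p, False))
            if disease_flags else False,
            "tumor_fraction": float(tumor_fraction[p])
            if tumor_fraction and p in tumor_fraction else np.nan,
        })
    ledger = pd.DataFrame(rows)
    bad = ledger["in_panel"] & ~(ledger["pass_blood"] & ledger["pass_clock"])
    if bad.any():
        raise ValueError("panel member failed an upstream filter: "
                         f"{ledger.loc[bad, 'probe_id'].tolist()}")
    return ledger
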