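"""End-to-end orchestration of the marker-discovery workflow.

Stage order is fixed: merge cohorts → CpG-island restriction →
differential-methylation test → blood exclusion → clock exclusion →
selection branches A and B → panel union → disease-specificity check →
validation tumor-fraction → pan-cancer specificity → expression
concordance.  Every stage's table can be written to disk, together with a
run summary holding the thresholds actually applied and the probe-count
funnel (universe → CGI → hyper-DMC → blood-pass → clock-pass → A → B →
panel).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import dmc, expression, io as mio, pancancer, panel as panel_mod
from .config import NON_TUMOR_GROUPS, FilterConfig


@dataclass
class PipelineInputs:
    """Everything one pipeline run consumes (in-memory form)."""

    manifest: pd.DataFrame
    discovery: list[tuple[pd.DataFrame, pd.DataFrame]]
    blood: tuple[pd.DataFrame, pd.DataFrame]
    clock_ids: set[str]
    disease: list[tuple[pd.DataFrame, pd.DataFrame]] = field(default_factory=list)
    validation: list[tuple[pd.DataFrame, pd.DataFrame]] = field(default_factory=list)
    pancancer: list[tuple[str, pd.DataFrame, pd.DataFrame]] = field(default_factory=list)
    counts: pd.DataFrame | None = None
    expr_sheet: pd.DataFrame | None = None
    tpm: pd.DataFrame | None = None

    @classmethod
    def from_simulation(cls, data) -> "PipelineInputs":
        """Wire a :class:`methmark.simulate.SimulatedData` into the pipeline."""
        return cls(manifest=data.manifest, discovery=data.cohorts.discovery,
                   blood=data.cohorts.blood, clock_ids=data.truth.clock_ids,
                   disease=data.cohorts.disease,
                   validation=data.cohorts.validation,
                   pancancer=data.cohorts.pancancer, counts=data.counts,
                   expr_sheet=data.expr_sheet, tpm=data.tpm)


@dataclass
class PipelineResult:
    funnel: dict[str, int]
    dmc_records: pd.DataFrame
    panel: list[str]
    panel_ledger: pd.DataFrame
    panel_audit: pd.DataFrame
    branch_a: list[str]
    branch_b: list[str]
    clock_overlap: list[str]
    enrichment: tuple[int, int, float]
    disease_flags: dict[str, bool]
    tumor_fraction: dict[str, float]
    specificity: pd.DataFrame | None
    concordance: pd.DataFrame | None
    location_table: pd.DataFrame | None
    summary: dict


def run_pipeline(inputs: PipelineInputs, cfg: FilterConfig | None = None,
                 case: str = "tumor",
                 control: Sequence[str] = NON_TUMOR_GROUPS,
                 index_tissue: str = "LIHC", pan_min: int = 10,
                 min_controls: int = 5, seed: int | None = None,
                 outdir: str | Path | None = None) -> PipelineResult:
    """Run the full cascade and (optionally) write every stage table.

    ``control`` names the sample-sheet groups pooled as the control side of
    the discovery contrast.  The summary funnel is strictly non-increasing
    up to the panel stage; branches A and B partition the panel.
    """
    cfg = cfg or FilterConfig()
    merged, sheet = mio.merge_cohorts(
        [m for m, _ in inputs.discovery], [s for _, s in inputs.discovery])
    funnel = {"universe": int(merged.shape[0])}

    cgi = dmc.cgi_subset(merged, inputs.manifest)
    funnel["cgi"] = int(cgi.shape[0])

    records = dmc.dmc_test(cgi, sheet, case=case, control=list(control),
                           delta_thresh=cfg.delta_thresh,
                           fdr_thresh=cfg.fdr_thresh,
                           equal_var=cfg.equal_var)
    candidates = dmc.candidate_hyper_probes(records)
    funnel["hyper_dmc"] = len(candidates)
    enrichment = (0, 0, float("nan"))
    if (records["status"] != "ns").any():
        enrichment = dmc.global_hyper_enrichment(records)

    blood_beta = inputs.blood[0]
    blood_pass = panel_mod.blood_filter(candidates, blood_beta,
                                        cfg.meth_thresh)
    funnel["blood_pass"] = len(blood_pass)

    clock_pass, clock_overlap = panel_mod.clock_filter(blood_pass,
                                                       inputs.clock_ids)
    funnel["clock_pass"] = len(clock_pass)

    a = panel_mod.branch_a(clock_pass, merged, sheet, cfg)
    b = panel_mod.branch_b(clock_pass, merged, sheet, cfg)
    final_panel, audit = panel_mod.combine_panel(a, b, merged, sheet, cfg)
    funnel["branch_a"] = len(a)
    funnel["branch_b"] = len(b)
    funnel["panel"] = len(final_panel)

    disease_flags = {}
    if inputs.disease and final_panel:
        disease_flags = panel_mod.disease_exclusion_check(
            final_panel, inputs.disease, cfg)
    tumor_fraction = {}
    if inputs.validation and final_panel:
        tumor_fraction = panel_mod.tumor_methylation_fraction(
            final_panel, inputs.validation, cfg.meth_thresh)

    delta_map = records.set_index("probe_id")["delta"]
    ledger = panel_mod.build_panel_ledger(
        candidates, blood_pass, clock_pass, a, b, blood_beta,
        delta_hcc=delta_map, disease_flags=disease_flags,
        tumor_fraction=tumor_fraction)

    specificity = None
    if inputs.pancancer and final_panel:
        summaries = [pancancer.summarize_cohort(beta, psheet, code,
                                                min_controls=min_controls)
                     for code, beta, psheet in inputs.pancancer]
        specificity = pancancer.specificity_table(
            summaries, final_panel, index_tissue=index_tissue,
            pan_min=pan_min, delta_thresh=cfg.delta_thresh,
            meth_thresh=cfg.meth_thresh)

    conc = table1 = None
    if inputs.counts is not None and final_panel:
        logcpm = expression.log_cpm(inputs.counts)
        conc = expression.concordance_table(
            final_panel, inputs.manifest, logcpm, inputs.expr_sheet)
        table1 = expression.location_expression_table(conc)

    summary = {
        "seed": seed,
        "thresholds": cfg.to_dict(),
        "case": case,
        "control": list(control),
        "index_tissue": index_tissue,
        "pan_min": pan_min,
        "funnel": funnel,
        "clock_overlap": clock_overlap,
        "global_enrichment": {"n_hyper": enrichment[0],
                              "n_hypo": enrichment[1],
                              "p_value": enrichment[2]},
    }
    result = PipelineResult(
        funnel=funnel, dmc_records=records, panel=final_panel,
        panel_ledger=ledger, panel_audit=audit, branch_a=a, branch_b=b,
        clock_overlap=clock_overlap, enrichment=enrichment,
        disease_flags=disease_flags, tumor_fraction=tumor_fraction,
        specificity=specificity, concordance=conc, location_table=table1,
        summary=summary)
    if outdir is not None:
        write_outputs(result, inputs.manifest, Path(outdir))
    return result


def write_outputs(result: PipelineResult, manifest: pd.DataFrame,
                  outdir: Path) -> None:
    """Write every stage table, the panel BED and the JSON run summary."""
    outdir.mkdir(parents=True, exist_ok=True)
    mio.write_report(result.dmc_records, outdir / "dmc.tsv")
    mio.write_report(result.panel_ledger, outdir / "panel_ledger.tsv",
                     summary=result.summary)
    mio.write_report(result.panel_audit, outdir / "panel_audit.tsv")
    mio.write_panel_bed(result.panel, manifest, outdir / "panel.bed")
    if result.specificity is not None:
        mio.write_report(result.specificity, outdir / "specificity.tsv")
    if result.concordance is not None:
        mio.write_report(result.concordance, outdir / "concordance.tsv")
        result.location_table.to_csv(outdir / "location_expression.tsv",
                                     sep="\t")


# ---------------------------------------------------------------------------
# file-driven entry point
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def load_inputs(config: dict, base: Path) -> tuple[PipelineInputs, dict]:
    """Materialize :class:`PipelineInputs` from a run-config mapping.

    Expected keys: ``manifest``, ``clock``, ``discovery`` (list of
    ``{beta, sheet}``), ``blood`` (``{beta, sheet}``) and optionally
    ``disease`` / ``validation`` (lists of ``{beta, sheet}``),
    ``pancancer`` (list of ``{tissue, beta, sheet}``), ``counts``,
    ``expression_sheet``, ``tpm``.  Paths are resolved against ``base``.
    Returns the inputs plus a fingerprint (sha256) per input file.
    """
    fingerprints: dict[str, str] = {}

    def path_of(rel: str) -> Path:
        p = Path(rel)
        p = p if p.is_absolute() else base / p
        fingerprints[str(rel)] = _sha256(p)
        return p

    def pair(entry: dict) -> tuple[pd.DataFrame, pd.DataFrame]:
        return (mio.read_beta_matrix(path_of(entry["beta"])),
                mio.read_sample_sheet(path_of(entry["sheet"])))

    inputs = PipelineInputs(
        manifest=mio.read_manifest(path_of(config["manifest"])),
        discovery=[pair(e) for e in config["discovery"]],
        blood=pair(config["blood"]),
        clock_ids=mio.read_clock_list(path_of(config["clock"])),
        disease=[pair(e) for e in config.get("disease", [])],
        validation=[pair(e) for e in config.get("validation", [])],
        pancancer=[(e["tissue"], *pair(e))
                   for e in config.get("pancancer", [])],
    )
    if "counts" in config:
        inputs.counts = pd.read_csv(path_of(config["counts"]), sep="\t",
                                    index_col=0)
        inputs.expr_sheet = mio.read_sample_sheet(
            path_of(config["expression_sheet"]))
    if "tpm" in config:
        inputs.tpm = pd.read_csv(path_of(config["tpm"]), sep="\t",
                                 index_col=0)
    return inputs, fingerprints


def run_pipeline_from_config(config_path: str | Path,
                             outdir: str | Path | None = None
                             ) -> PipelineResult:
    """Run the pipeline as described by a YAML run config."""
    config_path = Path(config_path)
    with open(config_path) as fh:
        config = yaml.safe_load(fh)
    cfg = FilterConfig.from_dict(config.get("thresholds", {}))
    inputs, fingerprints = load_inputs(config, config_path.parent)
    result = run_pipeline(
        inputs, cfg,
        case=config.get("case", "tumor"),
        control=config.get("control", list(NON_TUMOR_GROUPS)),
        index_tissue=config.get("index_tissue", "LIHC"),
        pan_min=config.get("pan_min", 10),
        min_controls=config.get("min_controls", 5),
        seed=config.get("seed"),
        outdir=outdir or config.get("outdir"))
    result.summary["input_fingerprints"] = fingerprints
    if outdir or config.get("outdir"):
        out = Path(outdir or config["outdir"])
        with open(out / "run_summary.json", "w") as fh:
            json.dump(result.summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return result
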