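import numpy as np
import pandas as pd
import pytest

from methmark import (FilterConfig, PipelineInputs, SimConfig, run_pipeline,
                      simulate_all)
from methmark.pancancer import specificity_table, summarize_cohort

#: Reduced-size study for unit tests; the acceptance suite uses SimConfig().
SMALL_CFG = SimConfig(
    seed=7, n_probes=3000, n_tumor=40, n_adjacent=16, n_cirrhotic=6,
    n_healthy=6, n_blood=60, n_disease=16, n_disease_controls=6,
    n_tumor_val=150, n_pan_t=12, n_pan_nt=8,
    panel_branch_a=15, panel_branch_b=6, blood_methylated=20,
    clock_overlap=5, disease_only=10, hypo_in_tumor=30,
    pan_cancer=3, index_exclusive=4, clock_size=80, n_background_genes=60)


@pytest.fixture(scope="session")
def small_data():
    return simulate_all(SMALL_CFG)


@pytest.fixture(scope="session")
def small_result(small_data):
    return run_pipeline(PipelineInputs.from_simulation(small_data),
                        seed=SMALL_CFG.seed)


def make_beta(values, probes=None, samples=None):
    values = np.asarray(values, dtype=float)
    probes = probes or [f"cg{i:05d}" for i in range(values.shape[0])]
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    return pd.DataFrame(values, index=pd.Index(probes, name="probe_id"),
                        columns=samples)


def make_sheet(sample_ids, groups, cohort="c0", tissue="LIHC"):
    return pd.DataFrame({"sample_id": list(sample_ids), "cohort": cohort,
                         "group": list(groups), "tissue": tissue})


def planted_recovery_metrics(seed: int) -> dict:
    """Run the default-conditions pipeline for one seed; keep only metrics."""
    data = simulate_all(SimConfig(seed=seed))
    result = run_pipeline(PipelineInputs.from_simulation(data), seed=seed)
    truth = data.truth
    truth_panel = set(truth.panel_probes)
    got = set(result.panel)
    contaminant_classes = ("blood_methylated", "clock_overlap", "disease_only")
    contaminants = {c: len(got & set(truth.probes_of(c)))
                    for c in contaminant_classes}

    summaries = [summarize_cohort(beta, sheet, code)
                 for code, beta, sheet in data.cohorts.pancancer]
    planted = truth.probes_of("pan_cancer") + truth.probes_of("index_exclusive")
    calls = specificity_table(summaries, planted).set_index("probe_id")
    pan_ok = all(calls.loc[p, "specificity"] == "pan"
                 for p in truth.probes_of("pan_cancer"))
    idx_ok = all(calls.loc[p, "specificity"] == "index_exclusive"
                 for p in truth.probes_of("index_exclusive"))

    effects = dict(zip(truth.genes["gene"], truth.genes["effect"]))
    coupled = {g for g, e in effects.items() if e in ("down", "up")
               and g in set(result.concordance["gene"])}
    by_gene = (result.concordance[result.concordance["gene"] != ""]
               .drop_duplicates("gene").set_index("gene"))
    recovered = sum(1 for g in coupled
                    if by_gene.loc[g, "expr_status"] == effects[g]
                    and bool(by_gene.loc[g, "concordant"]))

    return {
        "seed": seed,
        "funnel": result.funnel,
        "sensitivity": len(got & truth_panel) / len(truth_panel),
        "false_discoveries": len(got - truth_panel),
        "contaminants": contaminants,
        "disease_flagged": sum(result.disease_flags.values()),
        "pan_correct": pan_ok,
        "index_correct": idx_ok,
        "n_coupled": len(coupled),
        "coupling_recovered": recovered / len(coupled) if coupled else 1.0,
        "tumor_fraction": dict(result.tumor_fraction),
        "panel_specificity": result.specificity["specificity"].tolist(),
    }


@pytest.fixture(scope="session")
def default_metrics():
    """Planted-truth recovery metrics under default conditions, 5 seeds."""
    return [planted_recovery_metrics(seed) for seed in range(5)]
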