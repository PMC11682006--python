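"""Seeded synthetic methylation + expression cohorts with planted truth.

The generator emulates the statistical structure the pipeline assumes:
β values per probe per sample are Beta-distributed around tissue-specific
baselines (unmethylated probes ~ Beta(2, 38), mean 0.05; methylated probes
~ Beta(30, 10), mean 0.75), with planted probe classes —

``panel_branch_a``
    hypermethylated in tumors, unmethylated in every non-tumoral sample.
``panel_branch_b``
    hypermethylated in tumors *and* field-effect methylated (mean ≈ 0.35)
    in tumor-adjacent tissue, unmethylated in healthy/cirrhotic liver.
``blood_methylated``
    tumor-hypermethylated but also methylated in healthy whole blood
    (the contaminant the blood filter must remove).
``clock_overlap``
    tumor-hypermethylated probes that sit on the epigenetic aging clock.
``disease_only``
    methylated in non-tumor liver disease, not in tumors.
``hypo_in_tumor``
    methylated everywhere except tumors (hypomethylation background).
``pan_cancer`` / ``index_exclusive``
    hypermethylated across many / only the index tumor-type cohorts.

Planted *panel* probes are constitutively unmethylated in blood and
non-tumoral liver: their draws in those cohorts come from the baseline
Beta truncated below the unmethylated threshold.  This is part of the
class definition — the pipeline's per-sample filters are strict, so a
marker "unmethylated in all non-tumoral samples" must actually be so in
every simulated sample, not merely on average.

Everything is driven by a single integer seed; identical seeds yield
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import io as mio
from .expression import classify_region

#: Paired pan-cancer cohorts (tumor + >5 peritumoral samples); index first.
PAIRED_TISSUES = ("LIHC", "CHOL", "COADREAD", "BRCA", "PAAD", "BLCA",
                  "LUAD", "PRAD", "ESCA", "HNSC", "UCEC", "LUSC",
                  "KIRC", "THCA")
#: Tumor-only pan-cancer cohorts (no control methylomes available).
TUMOR_ONLY_TISSUES = ("STAD", "CESC", "SKCM", "GBM", "ACC", "MESO",
                      "UCS", "SARC", "OV", "LAML", "TGCT", "THYM", "LUNG")

PLANTED_CLASSES = ("panel_branch_a", "panel_branch_b", "blood_methylated",
                   "clock_overlap", "disease_only", "hypo_in_tumor",
                   "pan_cancer", "index_exclusive")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of the synthetic cohorts (all sizes per cohort)."""

    seed: int = 0
    n_probes: int = 20_000
    cgi_fraction: float = 0.3
    # index-organ cohorts
    n_tumor: int = 100
    n_adjacent: int = 30
    n_cirrhotic: int = 10
    n_healthy: int = 10
    n_blood: int = 200
    n_disease: int = 30
    n_disease_controls: int = 10
    n_tumor_val: int = 500
    validation_penetrance: float = 0.7
    # pan-cancer cohorts
    n_pan_t: int = 20
    n_pan_nt: int = 8
    pan_effect_cohorts: int = 11      # paired cohorts carrying the pan effect
    pan_tumor_only_meth: int = 4      # tumor-only cohorts methylated for pan probes
    # planted class sizes
    panel_branch_a: int = 30
    panel_branch_b: int = 12
    blood_methylated: int = 50
    clock_overlap: int = 10
    disease_only: int = 20
    hypo_in_tumor: int = 100
    pan_cancer: int = 5
    index_exclusive: int = 10
    # β noise
    beta_base: tuple[float, float] = (2.0, 38.0)       # mean 0.05
    beta_meth: tuple[float, float] = (30.0, 10.0)      # mean 0.75
    beta_adjacent: tuple[float, float] = (14.0, 26.0)  # mean 0.35 field effect
    unmeth_thresh: float = 0.2
    # clock
    clock_size: int = 353
    # expression
    nb_dispersion: float = 0.1
    nb_baseline_mean: float = 200.0
    coupling_fold: float = 2.0
    silent_fraction: float = 0.3
    n_background_genes: int = 160
    n_tissues: int = 20
    index_tissue_name: str = "liver"
    # panel-probe region split, promoter : gene body : intergenic
    region_ratio: tuple[int, int, int] = (21, 16, 2)

    def __post_init__(self) -> None:
        planted = (self.panel_branch_a + self.panel_branch_b
                   + self.blood_methylated + self.clock_overlap
                   + self.disease_only + self.hypo_in_tumor
                   + self.pan_cancer + self.index_exclusive)
        if planted > self.n_probes:
            raise ValueError("planted classes exceed n_probes")
        for name in PLANTED_CLASSES:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for pair in (self.beta_base, self.beta_meth, self.beta_adjacent):
            if min(pair) <= 0:
                raise ValueError("Beta parameters must be positive")

    @property
    def n_panel(self) -> int:
        return self.panel_branch_a + self.panel_branch_b


@dataclass
class TruthTable:
    """Ground truth of one simulation run."""

    probes: pd.DataFrame     # probe_id, class, gene, region
    genes: pd.DataFrame      # gene, effect, tissue_pattern
    clock_ids: set[str]

    def probes_of(self, cls: str) -> list[str]:
        return self.probes.loc[self.probes["class"] == cls,
                               "probe_id"].tolist()

    @property
    def panel_probes(self) -> list[str]:
        return self.probes.loc[self.probes["class"].isin(
            ("panel_branch_a", "panel_branch_b")), "probe_id"].tolist()


@dataclass
class SimulatedCohorts:
    """All β-matrix cohorts of one run, grouped by pipeline role."""

    discovery: list[tuple[pd.DataFrame, pd.DataFrame]]
    blood: tuple[pd.DataFrame, pd.DataFrame]
    disease: list[tuple[pd.DataFrame, pd.DataFrame]]
    validation: list[tuple[pd.DataFrame, pd.DataFrame]]
    pancancer: list[tuple[str, pd.DataFrame, pd.DataFrame]]


@dataclass
class SimulatedData:
    manifest: pd.DataFrame
    cohorts: SimulatedCohorts
    truth: TruthTable
    counts: pd.DataFrame
    expr_sheet: pd.DataFrame
    tpm: pd.DataFrame
    config: SimConfig


# ---------------------------------------------------------------------------
# deterministic bookkeeping
# ---------------------------------------------------------------------------

def _probe_ids(n: int) -> list[str]:
    return [f"cg{i:08d}" for i in range(n)]


def _largest_remainder(total: int, ratio: Sequence[int]) -> list[int]:
    shares = [total * r / sum(ratio) for r in ratio]
    counts = [int(s) for s in shares]
    order = sorted(range(len(ratio)), key=lambda i: shares[i] - counts[i],
                   reverse=True)
    for i in order[: total - sum(counts)]:
        counts[i] += 1
    return counts


def assign_truth_indices(cfg: SimConfig) -> dict[str, np.ndarray]:
    """Seed-deterministic assignment of probe indices to planted classes."""
    rng = np.random.default_rng([cfg.seed, 101])
    perm = rng.permutation(cfg.n_probes)
    out, start = {}, 0
    for cls in PLANTED_CLASSES:
        k = getattr(cfg, cls)
        out[cls] = np.sort(perm[start:start + k])
        start += k
    return out


# ---------------------------------------------------------------------------
# manifest
# ---------------------------------------------------------------------------

def simulate_manifest(cfg: SimConfig) -> pd.DataFrame:
    """Synthetic CpG manifest with planted panel genes and regions.

    Probes are spread over 22 synthetic chromosomes with increasing
    positions; exactly ``round(n_probes * cgi_fraction)`` probes are inside
    CpG islands, always including every planted probe.  Panel probes (and
    the pan-cancer / index-exclusive probes) receive host genes whose TSS
    and span place each probe in its planted region class — promoter,
    gene body or intergenic, split by ``region_ratio``.
    """
    ids = _probe_ids(cfg.n_probes)
    idx = np.arange(cfg.n_probes)
    chrom = [f"chr{1 + (i % 22)}" for i in idx]
    pos = 10_000 + (idx // 22) * 2_000
    strand = np.where(idx % 2 == 0, "+", "-")

    classes = assign_truth_indices(cfg)
    planted = np.sort(np.concatenate([v for v in classes.values()]))

    n_cgi = int(round(cfg.n_probes * cfg.cgi_fraction))
    if n_cgi < planted.size:
        raise ValueError("cgi_fraction too small to hold planted probes")
    in_cgi = np.zeros(cfg.n_probes, dtype=bool)
    in_cgi[planted] = True
    rng = np.random.default_rng([cfg.seed, 102])
    null_idx = np.setdiff1d(idx, planted)
    extra = rng.choice(null_idx, size=n_cgi - planted.size, replace=False)
    in_cgi[extra] = True

    gene = np.array([""] * cfg.n_probes, dtype=object)
    tss = np.full(cfg.n_probes, np.nan)
    g_start = np.full(cfg.n_probes, np.nan)
    g_end = np.full(cfg.n_probes, np.nan)

    panel_idx = np.concatenate([classes["panel_branch_a"],
                                classes["panel_branch_b"]])
    n_prom, n_body, n_inter = _largest_remainder(panel_idx.size,
                                                 cfg.region_ratio)
    regions = (["promoter"] * n_prom + ["gene_body"] * n_body
               + ["intergenic"] * n_inter)
    gene_counter = 0

    def plant_gene(i: int, region: str) -> None:
        nonlocal gene_counter
        gene_counter += 1
        gene[i] = f"GENE{gene_counter:04d}"
        p, minus = pos[i], strand[i] == "-"
        if region == "promoter":
            # probe 500 nt upstream of the TSS, inside the promoter window
            t = p + 500 if not minus else p - 500
            tss[i] = t
            g_start[i], g_end[i] = (t, t + 5_000) if not minus else (t - 5_000, t)
        else:  # gene_body: probe deep inside the span, far from the TSS
            g_start[i], g_end[i] = p - 2_000, p + 2_000
            tss[i] = g_start[i] if not minus else g_end[i]

    for i, region in zip(panel_idx, regions):
        if region != "intergenic":
            plant_gene(int(i), region)
    for i in classes["pan_cancer"]:
        plant_gene(int(i), "promoter")
    for i in classes["index_exclusive"]:
        plant_gene(int(i), "promoter")

    mf = pd.DataFrame({
        "chrom": chrom, "pos": pos.astype(float), "strand": strand,
        "in_cgi": in_cgi, "gene": gene, "tss_pos": tss,
        "gene_start": g_start, "gene_end": g_end,
    }, index=pd.Index(ids, name="probe_id"))
    return mf


# ---------------------------------------------------------------------------
# β cohorts
# ---------------------------------------------------------------------------

def _beta_draw(rng: np.random.Generator, params: tuple[float, float],
               shape) -> np.ndarray:
    return np.clip(rng.beta(params[0], params[1], size=shape), 0.0, 1.0)


def _beta_truncated_below(rng: np.random.Generator,
                          params: tuple[float, float], upper: float,
                          shape) -> np.ndarray:
    """Baseline draws conditioned on β < ``upper`` (inverse-CDF sampling)."""
    cap = stats.beta.cdf(upper, *params)
    u = rng.uniform(0.0, cap, size=shape)
    x = stats.beta.ppf(u, *params)
    return np.clip(x, 0.0, np.nextafter(upper, 0.0))


def _sheet(sample_ids: Sequence[str], cohort: str, groups: Sequence[str],
           tissue: str) -> pd.DataFrame:
    return pd.DataFrame({"sample_id": list(sample_ids),
                         "cohort": cohort, "group": list(groups),
                         "tissue": tissue})


def simulate_beta_cohorts(cfg: SimConfig, manifest: pd.DataFrame
                          ) -> tuple[SimulatedCohorts, TruthTable]:
    """Generate every β cohort plus the ground-truth table.

    Discovery samples are split across two cohorts (so the probe-universe
    merge is exercised); blood, disease, validation and the pan-cancer
    cohorts are generated separately.  All draws are determined by
    ``cfg.seed``.
    """
    ids = manifest.index.to_numpy()
    n = cfg.n_probes
    classes = assign_truth_indices(cfg)
    a_idx = classes["panel_branch_a"]
    b_idx = classes["panel_branch_b"]
    panel_idx = np.concatenate([a_idx, b_idx])
    qualifying = np.concatenate([panel_idx, classes["clock_overlap"]])
    blood_idx = classes["blood_methylated"]
    clock_idx = classes["clock_overlap"]
    disease_idx = classes["disease_only"]
    hypo_idx = classes["hypo_in_tumor"]
    pan_idx = classes["pan_cancer"]
    index_idx = classes["index_exclusive"]
    hyper_like = np.concatenate([panel_idx, blood_idx, clock_idx])

    rng = np.random.default_rng([cfg.seed, 103])

    def baseline(n_samples: int) -> np.ndarray:
        return _beta_draw(rng, cfg.beta_base, (n, n_samples))

    def meth(rows: np.ndarray, mat: np.ndarray) -> None:
        mat[rows] = _beta_draw(rng, cfg.beta_meth, (rows.size, mat.shape[1]))

    def clean(rows: np.ndarray, mat: np.ndarray) -> None:
        mat[rows] = _beta_truncated_below(
            rng, cfg.beta_base, cfg.unmeth_thresh, (rows.size, mat.shape[1]))

    # --- index-organ discovery cohorts -------------------------------------
    def liver_block(n_tumor: int, n_adjacent: int, n_cirrhotic: int,
                    n_healthy: int, cohort: str
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
        cols, groups = [], []
        mats = []
        # tumor: hyper-like probes methylated, hypo probes unmethylated
        t = baseline(n_tumor)
        meth(hyper_like, t)
        mats.append(t)
        cols += [f"{cohort}_T{i:03d}" for i in range(n_tumor)]
        groups += ["tumor"] * n_tumor
        # adjacent: branch_b field effect; panel-A kept constitutively clean
        adj = baseline(n_adjacent)
        clean(np.concatenate([a_idx, classes["clock_overlap"],
                              blood_idx]), adj)
        adj[b_idx] = _beta_draw(rng, cfg.beta_adjacent,
                                (b_idx.size, n_adjacent))
        adj[hypo_idx] = _beta_draw(rng, cfg.beta_meth,
                                   (hypo_idx.size, n_adjacent))
        mats.append(adj)
        cols += [f"{cohort}_A{i:03d}" for i in range(n_adjacent)]
        groups += ["adjacent"] * n_adjacent
        # cirrhotic + healthy: every tumor-qualifying probe clean
        for label, size, gname in (("C", n_cirrhotic, "cirrhotic"),
                                   ("H", n_healthy, "healthy")):
            if size == 0:
                continue
            m = baseline(size)
            clean(np.concatenate([qualifying, blood_idx]), m)
            m[hypo_idx] = _beta_draw(rng, cfg.beta_meth, (hypo_idx.size, size))
            mats.append(m)
            cols += [f"{cohort}_{label}{i:03d}" for i in range(size)]
            groups += [gname] * size
        beta = pd.DataFrame(np.hstack(mats), index=pd.Index(ids, name="probe_id"),
                            columns=cols)
        return beta, _sheet(cols, cohort, groups, "LIHC")

    t_half, a_half = cfg.n_tumor // 2, cfg.n_adjacent // 2
    discovery = [
        liver_block(t_half, a_half, cfg.n_cirrhotic, 0, "simA"),
        liver_block(cfg.n_tumor - t_half, cfg.n_adjacent - a_half, 0,
                    cfg.n_healthy, "simB"),
    ]

    # --- whole blood --------------------------------------------------------
    bl = baseline(cfg.n_blood)
    clean(qualifying, bl)                      # panel + clock: blood-clean
    meth(blood_idx, bl)                        # the planted contaminants
    bl[hypo_idx] = _beta_draw(rng, cfg.beta_meth, (hypo_idx.size, cfg.n_blood))
    bcols = [f"blood_{i:03d}" for i in range(cfg.n_blood)]
    blood = (pd.DataFrame(bl, index=pd.Index(ids, name="probe_id"),
                          columns=bcols),
             _sheet(bcols, "simBlood", ["blood"] * cfg.n_blood, "blood"))

    # --- non-tumor liver disease -------------------------------------------
    dis = baseline(cfg.n_disease + cfg.n_disease_controls)
    dis[disease_idx, :cfg.n_disease] = _beta_draw(
        rng, cfg.beta_meth, (disease_idx.size, cfg.n_disease))
    dcols = ([f"dis_{i:03d}" for i in range(cfg.n_disease)]
             + [f"disctl_{i:03d}" for i in range(cfg.n_disease_controls)])
    dgroups = (["disease"] * cfg.n_disease
               + ["healthy"] * cfg.n_disease_controls)
    disease = [(pd.DataFrame(dis, index=pd.Index(ids, name="probe_id"),
                             columns=dcols),
                _sheet(dcols, "simDisease", dgroups, "liver_disease"))]

    # --- validation tumors (penetrance < 1) --------------------------------
    val = baseline(cfg.n_tumor_val)
    hit = rng.random((panel_idx.size, cfg.n_tumor_val)) < cfg.validation_penetrance
    meth_draws = _beta_draw(rng, cfg.beta_meth,
                            (panel_idx.size, cfg.n_tumor_val))
    val[panel_idx] = np.where(hit, meth_draws, val[panel_idx])
    vcols = [f"val_T{i:03d}" for i in range(cfg.n_tumor_val)]
    validation = [(pd.DataFrame(val, index=pd.Index(ids, name="probe_id"),
                                columns=vcols),
                   _sheet(vcols, "simVal", ["tumor"] * cfg.n_tumor_val,
                          "LIHC"))]

    # --- pan-cancer cohorts -------------------------------------------------
    pan_effect = set(PAIRED_TISSUES[:cfg.pan_effect_cohorts])
    pan_meth_only = set(TUMOR_ONLY_TISSUES[:cfg.pan_tumor_only_meth])
    pancancer = []
    for code in PAIRED_TISSUES:
        m = baseline(cfg.n_pan_t + cfg.n_pan_nt)
        tumor_rows = []
        if code in pan_effect:
            tumor_rows.append(pan_idx)
        if code == PAIRED_TISSUES[0]:          # index cohort: panel + index probes
            tumor_rows += [panel_idx, index_idx]
        for rows in tumor_rows:
            m[rows, :cfg.n_pan_t] = _beta_draw(rng, cfg.beta_meth,
                                               (rows.size, cfg.n_pan_t))
        cols = ([f"{code}_T{i:02d}" for i in range(cfg.n_pan_t)]
                + [f"{code}_NT{i:02d}" for i in range(cfg.n_pan_nt)])
        groups = ["tumor"] * cfg.n_pan_t + ["adjacent"] * cfg.n_pan_nt
        pancancer.append((code,
                          pd.DataFrame(m, index=pd.Index(ids, name="probe_id"),
                                       columns=cols),
                          _sheet(cols, f"sim{code}", groups, code)))
    for code in TUMOR_ONLY_TISSUES:
        m = baseline(cfg.n_pan_t)
        if code in pan_meth_only:
            m[pan_idx] = _beta_draw(rng, cfg.beta_meth,
                                    (pan_idx.size, cfg.n_pan_t))
        cols = [f"{code}_T{i:02d}" for i in range(cfg.n_pan_t)]
        pancancer.append((code,
                          pd.DataFrame(m, index=pd.Index(ids, name="probe_id"),
                                       columns=cols),
                          _sheet(cols, f"sim{code}", ["tumor"] * cfg.n_pan_t,
                                 code)))

    # --- truth --------------------------------------------------------------
    rows = []
    for cls in PLANTED_CLASSES:
        for i in classes[cls]:
            g = manifest.iat[int(i), manifest.columns.get_loc("gene")]
            region = ""
            if g:
                region = classify_region(manifest.iloc[int(i)].to_dict())
            elif cls in ("panel_branch_a", "panel_branch_b"):
                region = "intergenic"
            rows.append({"probe_id": ids[int(i)], "class": cls,
                         "gene": g, "region": region})
    probes = pd.DataFrame(rows).sort_values("probe_id").reset_index(drop=True)

    genes = _gene_truth(cfg, probes)
    clock_ids = set(ids[clock_idx])
    filler = {f"cg9{i:07d}" for i in range(cfg.clock_size - clock_idx.size)}
    truth = TruthTable(probes=probes, genes=genes,
                       clock_ids=clock_ids | filler)
    return SimulatedCohorts(discovery=discovery, blood=blood, disease=disease,
                            validation=validation, pancancer=pancancer), truth


def _gene_truth(cfg: SimConfig, probes: pd.DataFrame) -> pd.DataFrame:
    """Planted expression effect and tissue pattern per host gene."""
    rng = np.random.default_rng([cfg.seed, 104])
    rows = []
    panel = probes[probes["class"].isin(("panel_branch_a", "panel_branch_b"))]
    panel_genes = [(g, r) for g, r in
                   zip(panel["gene"], panel["region"]) if g]
    n_silent = int(round(cfg.silent_fraction * len(panel_genes)))
    silent_pick = set(rng.choice(len(panel_genes), size=n_silent,
                                 replace=False).tolist())
    for k, (g, region) in enumerate(panel_genes):
        if k in silent_pick:
            effect, pattern = "silent", "broadly_silent"
        else:
            effect = "down" if region == "promoter" else "up"
            pattern = "repressed_in_index"
        rows.append({"gene": g, "effect": effect, "tissue_pattern": pattern})
    for cls, pattern in (("pan_cancer", "broadly_silent"),
                         ("index_exclusive", "repressed_in_index")):
        for g in probes.loc[probes["class"] == cls, "gene"]:
            if g:
                rows.append({"gene": g, "effect": "silent" if
                             pattern == "broadly_silent" else "down",
                             "tissue_pattern": pattern})
    return pd.DataFrame(rows).sort_values("gene").reset_index(drop=True)


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def simulate_counts(cfg: SimConfig, truth: TruthTable, sheet: pd.DataFrame
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Negative-binomial RNA counts coupled to planted methylation effects.

    Tumor and adjacent (control) samples from ``sheet`` get counts for every
    truth gene plus background genes.  Promoter-hypermethylated genes are
    halved in tumors, gene-body-hypermethylated genes doubled
    (``coupling_fold``); silent genes have mean 0.1 everywhere.  The TPM
    table spans ``n_tissues`` healthy tissues with index-repressed genes
    low in the index tissue only.
    """
    rng = np.random.default_rng([cfg.seed, 105])
    t_cols = sheet.loc[sheet["group"] == "tumor", "sample_id"].tolist()
    c_cols = sheet.loc[sheet["group"] == "adjacent", "sample_id"].tolist()
    if not t_cols or not c_cols:
        raise ValueError("sheet must contain tumor and adjacent samples")

    genes = truth.genes["gene"].tolist()
    background = [f"BG{i:04d}" for i in range(cfg.n_background_genes)]
    all_genes = genes + background
    effects = dict(zip(truth.genes["gene"], truth.genes["effect"]))

    base = cfg.nb_baseline_mean
    mean_ctrl = np.array([0.1 if effects.get(g) == "silent" else base
                          for g in all_genes])
    mean_tum = np.array([
        0.1 if effects.get(g) == "silent"
        else base / cfg.coupling_fold if effects.get(g) == "down"
        else base * cfg.coupling_fold if effects.get(g) == "up"
        else base
        for g in all_genes])

    nb_n = 1.0 / cfg.nb_dispersion

    def draw(means: np.ndarray, n_samples: int) -> np.ndarray:
        p = nb_n / (nb_n + means[:, None])
        return rng.negative_binomial(nb_n, p,
                                     size=(means.size, n_samples))

    counts = pd.DataFrame(
        np.hstack([draw(mean_tum, len(t_cols)), draw(mean_ctrl, len(c_cols))]),
        index=pd.Index(all_genes, name="gene"), columns=t_cols + c_cols)

    # --- tissue-wide TPM ----------------------------------------------------
    tissues = [cfg.index_tissue_name] + [f"tissue_{i:02d}"
                                         for i in range(1, cfg.n_tissues)]
    patterns = dict(zip(truth.genes["gene"], truth.genes["tissue_pattern"]))
    tpm = np.empty((len(all_genes), len(tissues)))
    for gi, g in enumerate(all_genes):
        pattern = patterns.get(g, "expressed")
        if pattern == "broadly_silent":
            tpm[gi] = rng.uniform(0.0, 0.5, size=len(tissues))
        elif pattern == "repressed_in_index":
            tpm[gi] = rng.gamma(8.0, 3.0, size=len(tissues))  # ~24 TPM
            tpm[gi, 0] = rng.uniform(0.0, 0.5)
        else:
            tpm[gi] = rng.gamma(8.0, 3.0, size=len(tissues))
    tpm_df = pd.DataFrame(tpm, index=pd.Index(all_genes, name="gene"),
                          columns=tissues)
    return counts, tpm_df


# ---------------------------------------------------------------------------
# one-call generator + on-disk layout
# ---------------------------------------------------------------------------

def simulate_all(cfg: SimConfig) -> SimulatedData:
    """Generate manifest, all β cohorts, truth, counts and TPM in one call."""
    manifest = simulate_manifest(cfg)
    cohorts, truth = simulate_beta_cohorts(cfg, manifest)
    expr_sheet = pd.concat([s for _, s in cohorts.discovery],
                           ignore_index=True)
    counts, tpm = simulate_counts(cfg, truth, expr_sheet)
    return SimulatedData(manifest=manifest, cohorts=cohorts, truth=truth,
                         counts=counts, expr_sheet=expr_sheet, tpm=tpm,
                         config=cfg)


def write_simulation(data: SimulatedData, outdir: str | Path) -> None:
    """Write every cohort, the manifest, clock list, counts, TPM and truth."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    mio.write_manifest(data.manifest, out / "manifest.csv")
    mio.write_clock_list(data.truth.clock_ids, out / "clock.txt")
    for i, (beta, sheet) in enumerate(data.cohorts.discovery):
        mio.write_beta_matrix(beta, out / f"discovery{i}.beta.tsv")
        mio.write_sample_sheet(sheet, out / f"discovery{i}.sheet.csv")
    mio.write_beta_matrix(data.cohorts.blood[0], out / "blood.beta.tsv")
    mio.write_sample_sheet(data.cohorts.blood[1], out / "blood.sheet.csv")
    for i, (beta, sheet) in enumerate(data.cohorts.disease):
        mio.write_beta_matrix(beta, out / f"disease{i}.beta.tsv")
        mio.write_sample_sheet(sheet, out / f"disease{i}.sheet.csv")
    for i, (beta, sheet) in enumerate(data.cohorts.validation):
        mio.write_beta_matrix(beta, out / f"validation{i}.beta.tsv")
        mio.write_sample_sheet(sheet, out / f"validation{i}.sheet.csv")
    for code, beta, sheet in data.cohorts.pancancer:
        mio.write_beta_matrix(beta, out / f"pancancer_{code}.beta.tsv")
        mio.write_sample_sheet(sheet, out / f"pancancer_{code}.sheet.csv")
    data.counts.to_csv(out / "counts.tsv", sep="\t", index_label="gene")
    data.tpm.to_csv(out / "tpm.tsv", sep="\t", index_label="gene",
                    float_format="%.6g")
    mio.write_sample_sheet(data.expr_sheet, out / "expression.sheet.csv")
    data.truth.probes.to_csv(out / "truth_probes.tsv", sep="\t", index=False)
    data.truth.genes.to_csv(out / "truth_genes.tsv", sep="\t", index=False)
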