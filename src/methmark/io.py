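"""Readers, writers and multi-cohort assembly for methylation-array data.

In-memory conventions
---------------------
* **β matrix** — :class:`pandas.DataFrame`, rows indexed by probe id,
  columns by sample id, float values in ``[0, 1]`` with ``NaN`` for missing.
* **sample sheet** — :class:`pandas.DataFrame` with columns
  ``sample_id, cohort, group, tissue``; ``group`` is drawn from the closed
  vocabulary in :data:`methmark.config.GROUPS`.
* **manifest** — :class:`pandas.DataFrame` indexed by probe id with columns
  ``chrom, pos, strand, in_cgi, gene, tss_pos, gene_start, gene_end``.
  Coordinates are 1-based (array-manifest convention); exported BED is
  0-based half-open.
* **clock list** — plain ``set`` of probe ids.
"""

from __future__ import annotations

import json
import time
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import GROUPS

MISSING_TOKENS = ("NA", "NaN", "nan", "")

MANIFEST_COLUMNS = ["chrom", "pos", "strand", "in_cgi",
                    "gene", "tss_pos", "gene_start", "gene_end"]


# ---------------------------------------------------------------------------
# β matrices
# ---------------------------------------------------------------------------

def validate_beta_matrix(beta: pd.DataFrame, name: str = "beta matrix") -> pd.DataFrame:
    """Enforce the β-matrix invariants; return the (unchanged) frame.

    Raises ``ValueError`` naming the offending probe/sample for any
    non-missing value outside [0, 1] and for duplicate probe or sample ids.
    """
    if beta.index.has_duplicates:
        dups = beta.index[beta.index.duplicated()].unique().tolist()
        raise ValueError(f"{name}: duplicate probe ids {dups[:5]}")
    if beta.columns.has_duplicates:
        dups = beta.columns[beta.columns.duplicated()].unique().tolist()
        raise ValueError(f"{name}: duplicate sample ids {dups[:5]}")
    vals = beta.to_numpy(dtype=float)
    bad = (vals < 0.0) | (vals > 1.0)
    bad &= ~np.isnan(vals)
    if bad.any():
        i, j = map(int, np.argwhere(bad)[0])
        raise ValueError(
            f"{name}: β={vals[i, j]!r} out of [0, 1] at probe "
            f"{beta.index[i]!r}, sample {beta.columns[j]!r}")
    return beta


def read_beta_matrix(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Read a probes × samples β matrix from TSV/CSV.

    First column holds probe ids, header row holds sample ids.  Cells may be
    numeric or one of the missing tokens ``NA``/``NaN``/empty.  The delimiter
    is sniffed from the extension when ``sep`` is not given.
    """
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    beta = pd.read_csv(path, sep=sep, index_col=0,
                       na_values=list(MISSING_TOKENS), keep_default_na=False)
    beta.index = beta.index.astype(str)
    beta.index.name = "probe_id"
    try:
        beta = beta.astype(float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric β cell ({exc})") from None
    return validate_beta_matrix(beta, name=str(path))


def write_beta_matrix(beta: pd.DataFrame, path: str | Path,
                      sep: str | None = None) -> None:
    """Write a β matrix as TSV/CSV with ``NA`` for missing values."""
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    beta.to_csv(path, sep=sep, na_rep="NA", index_label="probe_id")


# ---------------------------------------------------------------------------
# sample sheets, manifests, clock lists
# ---------------------------------------------------------------------------

def validate_sample_sheet(sheet: pd.DataFrame,
                          beta: pd.DataFrame | None = None) -> pd.DataFrame:
    required = {"sample_id", "cohort", "group", "tissue"}
    missing = required - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns {sorted(missing)}")
    if sheet["sample_id"].duplicated().any():
        dups = sheet.loc[sheet["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids in sheet: {dups[:5]}")
    bad = set(sheet["group"]) - set(GROUPS)
    if bad:
        raise ValueError(f"unknown groups {sorted(bad)}; allowed: {GROUPS}")
    if beta is not None:
        absent = set(beta.columns) - set(sheet["sample_id"])
        if absent:
            raise ValueError(
                f"samples missing from sheet: {sorted(absent)[:5]}")
    return sheet


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path, dtype=str)
    return validate_sample_sheet(sheet)


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    sheet.to_csv(path, index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a CpG manifest CSV (probe_id,chrom,pos,strand,in_cgi,gene,...)."""
    mf = pd.read_csv(path, index_col="probe_id",
                     na_values=list(MISSING_TOKENS), keep_default_na=False,
                     dtype={"chrom": str, "strand": str, "gene": str})
    mf.index = mf.index.astype(str)
    if mf.index.has_duplicates:
        raise ValueError("manifest probe ids are not unique")
    mf["in_cgi"] = mf["in_cgi"].astype(str).str.lower().isin(
        ("true", "1", "yes"))
    for col in ("pos", "tss_pos", "gene_start", "gene_end"):
        mf[col] = pd.to_numeric(mf[col], errors="raise")
    gene_missing = mf["gene"].isna() | (mf["gene"] == "")
    if (gene_missing & mf["tss_pos"].notna()).any():
        raise ValueError("manifest: tss_pos present for probes without a gene")
    span = mf["gene_start"].notna() & mf["gene_end"].notna()
    if (mf.loc[span, "gene_start"] > mf.loc[span, "gene_end"]).any():
        raise ValueError("manifest: gene_start > gene_end")
    return mf[MANIFEST_COLUMNS]


def write_manifest(mf: pd.DataFrame, path: str | Path) -> None:
    mf.to_csv(path, na_rep="", index_label="probe_id")


def read_clock_list(path: str | Path) -> set[str]:
    """Read an epigenetic-clock CpG list: one probe id per line."""
    ids = {line.strip() for line in Path(path).read_text().splitlines()
           if line.strip()}
    if not ids:
        raise ValueError(f"{path}: empty clock list")
    bad = [p for p in ids if not p.startswith("cg")]
    if bad:
        raise ValueError(f"{path}: invalid probe ids {sorted(bad)[:5]}")
    return ids


def write_clock_list(ids: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(sorted(ids)) + "\n")


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

def merge_cohorts(matrices: Sequence[pd.DataFrame],
                  sheets: Sequence[pd.DataFrame],
                  max_missing_frac: float = 0.0,
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble cohorts on a common probe universe.

    A probe enters the merged universe when it is present in every cohort
    and its fraction of missing values across all samples is at most
    ``max_missing_frac`` (default 0: non-missing in *every* sample, the
    "present in all samples" rule).  Probe order follows the first cohort;
    sample ids are prefixed ``"<cohort>:"`` to guarantee uniqueness, unless
    already so prefixed (which makes the operation idempotent).
    """
    if len(matrices) == 0:
        raise ValueError("merge_cohorts needs at least one cohort")
    if len(matrices) != len(sheets):
        raise ValueError("one sample sheet per β matrix required")

    prefixed, new_sheets = [], []
    for beta, sheet in zip(matrices, sheets):
        validate_sample_sheet(sheet, beta)
        cohorts = sheet.set_index("sample_id")["cohort"]
        mapping = {
            s: s if str(s).startswith(f"{cohorts[s]}:") else f"{cohorts[s]}:{s}"
            for s in beta.columns}
        prefixed.append(beta.rename(columns=mapping))
        ns = sheet.copy()
        ns["sample_id"] = ns["sample_id"].map(
            lambda s: mapping.get(s, s))
        new_sheets.append(ns)

    universe = prefixed[0].index
    for beta in prefixed[1:]:
        universe = universe[universe.isin(beta.index)]
    merged = pd.concat([beta.loc[universe] for beta in prefixed], axis=1)
    missing_frac = merged.isna().mean(axis=1)
    merged = merged.loc[missing_frac <= max_missing_frac]
    if merged.shape[0] == 0:
        raise ValueError("merged probe universe is empty")

    sheet = pd.concat(new_sheets, ignore_index=True)
    if sheet["sample_id"].duplicated().any():
        raise ValueError("sample ids collide after cohort prefixing")
    return validate_beta_matrix(merged, "merged matrix"), sheet


# ---------------------------------------------------------------------------
# exports
# ---------------------------------------------------------------------------

def write_panel_bed(panel: Sequence[str], manifest: pd.DataFrame,
                    path: str | Path) -> None:
    """Export panel probes as BED6, one single-base interval per CpG.

    Intervals are 0-based half-open (``start = pos - 1``, ``end = pos``),
    sorted by chromosome then start.  An empty panel yields an empty file.
    """
    missing = [p for p in panel if p not in manifest.index
               or pd.isna(manifest.at[p, "pos"])]
    if missing:
        raise ValueError(f"probes without coordinates: {sorted(missing)}")
    rows = []
    for p in panel:
        entry = manifest.loc[p]
        strand = entry["strand"] if entry["strand"] in ("+", "-") else "."
        rows.append((str(entry["chrom"]), int(entry["pos"]) - 1,
                     int(entry["pos"]), p, ".", strand))
    rows.sort(key=lambda r: (r[0], r[1]))
    with open(path, "w") as fh:
        for r in rows:
            fh.write("\t".join(map(str, r)) + "\n")


def write_report(records: pd.DataFrame, path: str | Path,
                 summary: dict | None = None) -> None:
    """Write a pipeline table as TSV plus an optional JSON run summary.

    The TSV keeps the frame's column order; the JSON sidecar
    (``<path>.summary.json``) records thresholds, stage counts and the seed,
    plus a wall-clock timestamp (the only non-deterministic field).
    """
    if records is None:
        raise ValueError("records must not be None")
    path = Path(path)
    records.to_csv(path, sep="\t", index=False, na_rep="NA",
                   float_format="%.10g")
    if summary is not None:
        payload = dict(summary)
        payload["timestamp"] = time.strftime("%Y-%m-%dT%H:%M:%S")
        with open(path.with_suffix(path.suffix + ".summary.json"), "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")
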