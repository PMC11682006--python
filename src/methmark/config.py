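"""Shared configuration objects for the marker-discovery pipeline.

All β thresholds are strict inequalities: a CpG counts as *unmethylated*
when β < ``unmeth_thresh`` and as *methylated* when β > ``meth_thresh``.
Boundary values (β exactly equal to a threshold) therefore fail the
stricter side of whichever rule is being applied.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields
from pathlib import Path

import yaml

#: Closed vocabulary of sample groups used throughout the pipeline.
GROUPS = ("tumor", "adjacent", "cirrhotic", "healthy", "blood", "disease")

#: Groups that constitute "non-tumoral" tissue in the index organ.
NON_TUMOR_GROUPS = ("adjacent", "cirrhotic", "healthy")


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the differential-methylation and panel-selection cascade.

    Parameters
    ----------
    unmeth_thresh
        β below which a CpG is called unmethylated in a single sample.
    meth_thresh
        β above which a CpG is called methylated in a single sample (and,
        for group-level rules, above which a group mean counts as methylated).
    branch_a_delta
        Minimum tumor-vs-non-tumor Δβ for the branch that requires every
        non-tumoral sample (healthy, cirrhotic and adjacent) to be
        unmethylated.
    branch_b_delta
        Minimum tumor-vs-(healthy+cirrhotic) Δβ for the branch that allows
        field-effect methylation in tissue adjacent to the tumor.
    panel_tumor_beta
        Tumor-group mean β every final panel member is checked against.
    delta_thresh
        |Δβ| beyond which a significant CpG is called hyper/hypomethylated.
    fdr_thresh
        Benjamini–Hochberg FDR cut-off for significance.
    equal_var
        Use the equal-variance Student t-test (default); set False for Welch.
    branch_b_adjacent_rule
        How "methylated in adjacent tissue" is operationalized for branch B:
        ``"mean"`` (group mean > meth_thresh, default), ``"all"`` (every
        adjacent sample > meth_thresh) or ``"fraction"`` (at least
        ``branch_b_adjacent_fraction`` of adjacent samples > meth_thresh).
    """

    unmeth_thresh: float = 0.2
    meth_thresh: float = 0.2
    branch_a_delta: float = 0.3
    branch_b_delta: float = 0.4
    panel_tumor_beta: float = 0.3
    delta_thresh: float = 0.2
    fdr_thresh: float = 0.05
    equal_var: bool = True
    branch_b_adjacent_rule: str = "mean"
    branch_b_adjacent_fraction: float = 0.5

    def __post_init__(self) -> None:
        for name in ("unmeth_thresh", "meth_thresh", "branch_a_delta",
                     "branch_b_delta", "panel_tumor_beta", "delta_thresh",
                     "fdr_thresh"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v!r}")
        if self.branch_b_adjacent_rule not in ("mean", "all", "fraction"):
            raise ValueError(
                f"unknown branch_b_adjacent_rule {self.branch_b_adjacent_rule!r}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "FilterConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown FilterConfig keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FilterConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data.get("thresholds", data))
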