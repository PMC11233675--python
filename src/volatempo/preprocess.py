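"""Variable filtering and scaling of longitudinal peak tables.

Two filters run in a fixed order before modelling: a detection-consistency
filter (a compound must be detected in all replicates of at least one
group x time condition) and a coefficient-of-variation filter that removes
variables near-constant across the experimental conditions.  The surviving
table is pivoted to an observations x variables matrix, imputed, centred and
scaled — the input to RM-ASCA, PCA and clustering.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["FilterReport", "ScaledMatrix", "consistency_filter", "cv_filter",
           "scale_matrix"]


@dataclass
class FilterReport:
    """Per-compound keep/drop decisions with reasons."""

    filter_name: str
    decisions: pd.DataFrame  # columns: compound, kept, reason, cv (optional)
    n_before: int
    n_after: int

    def __post_init__(self):
        if self.n_before != len(self.decisions):
            raise ValueError("decision count does not match n_before")
        if self.n_after != int(self.decisions["kept"].sum()):
            raise ValueError("kept count does not match n_after")

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {
                "filter": self.filter_name,
                "n_before": self.n_before,
                "n_after": self.n_after,
                "decisions": self.decisions.to_dict(orient="records"),
            },
            indent=2,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


def _require_columns(table: pd.DataFrame, cols):
    missing = set(cols) - set(table.columns)
    if missing:
        raise ValueError(f"peak table lacks columns: {sorted(missing)}")


def consistency_filter(table: pd.DataFrame, design=None
                       ) -> tuple[pd.DataFrame, FilterReport]:
    """Keep compounds consistently detected within at least one condition.

    A compound passes iff it is detected (non-missing intensity) in *all*
    replicates of at least one (group, time) condition; everything else is
    discarded as not consistently detected.  ``design`` may supply the
    expected replicate count per condition; otherwise the replicates present
    in the table are used.
    """
    _require_columns(table, ["group", "replicate", "time_h", "compound", "intensity"])
    compounds = sorted(table["compound"].unique())
    if not compounds:
        report = FilterReport("consistency", pd.DataFrame(
            columns=["compound", "kept", "reason"]), 0, 0)
        return table.copy(), report
    n_reps = (
        design.replicates_per_group
        if design is not None
        else table.groupby(["group"], observed=True)["replicate"].nunique().max()
    )
    detected = (
        table.assign(ok=table["intensity"].notna())
        .groupby(["compound", "group", "time_h"], observed=True)["ok"]
        .sum()
    )
    kept_set = set(detected[detected >= n_reps].reset_index()["compound"].unique())
    decisions = pd.DataFrame(
        {
            "compound": compounds,
            "kept": [c in kept_set for c in compounds],
            "reason": [
                "detected in all replicates of >=1 condition"
                if c in kept_set
                else "not consistently detected in any condition"
                for c in compounds
            ],
        }
    )
    filtered = table[table["compound"].isin(kept_set)].reset_index(drop=True)
    report = FilterReport("consistency", decisions, len(compounds), len(kept_set))
    return filtered, report


def cv_filter(table: pd.DataFrame, threshold: float = 0.05
              ) -> tuple[pd.DataFrame, FilterReport]:
    """Remove near-constant variables by coefficient of variation.

    For each compound the mean intensity of every (group, time) condition is
    computed; the CV is the sample standard deviation (n−1 denominator) of
    those condition means divided by their mean.  Compounds with CV below
    ``threshold`` carry no usable condition-to-condition variation and are
    dropped.  A compound whose condition means average to zero is flagged
    and treated as zero-CV.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    _require_columns(table, ["group", "time_h", "compound", "intensity"])
    compounds = sorted(table["compound"].unique())
    means = (
        table.groupby(["compound", "group", "time_h"], observed=True)["intensity"]
        .mean()
    )
    records = []
    for c in compounds:
        m = means.loc[c].to_numpy(dtype=float)
        m = m[np.isfinite(m)]
        grand = m.mean() if m.size else 0.0
        if grand == 0.0 or m.size < 2:
            cv = 0.0
            flag = "; zero-mean or degenerate, treated as zero-CV"
        else:
            cv = float(np.std(m, ddof=1) / grand)
            flag = ""
        kept = cv >= threshold
        reason = (
            f"CV {cv:.4g} >= threshold {threshold}" if kept
            else f"CV {cv:.4g} < threshold {threshold}"
        ) + flag
        records.append({"compound": c, "kept": kept, "reason": reason, "cv": cv})
    decisions = pd.DataFrame(records)
    kept_set = set(decisions.loc[decisions["kept"], "compound"])
    filtered = table[table["compound"].isin(kept_set)].reset_index(drop=True)
    report = FilterReport("cv", decisions, len(compounds), len(kept_set))
    return filtered, report


@dataclass
class ScaledMatrix:
    """Observations x variables matrix ready for multivariate modelling.

    Carries the row metadata (group, replicate vessel, time) aligned with the
    matrix, plus the centring/scaling record needed to invert the transform.
    """

    values: pd.DataFrame          # index: sample_id, columns: compounds
    row_meta: pd.DataFrame        # sample_id, group, replicate, time_h
    method: str
    centers: pd.Series
    scales: pd.Series
    imputed: dict = field(default_factory=dict)  # compound -> fill value used

    @property
    def variables(self) -> list[str]:
        return list(self.values.columns)

    def matrix(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def unscale(self) -> pd.DataFrame:
        """Invert centring and scaling (imputation is not undone)."""
        return self.values * self.scales + self.centers


def scale_matrix(table: pd.DataFrame, method: str = "unit-sd",
                 baseline_time: float | None = None) -> ScaledMatrix:
    """Pivot a peak table to wide format, impute, centre and scale.

    methods
    -------
    unit-sd
        Per-variable mean centring and division by the overall standard
        deviation (autoscaling; every column ends with mean 0, sd 1).
    baseline-sd
        Mean centring and division by the standard deviation among baseline
        (first time point) observations, which preserves the relative growth
        of effects over time.
    none
        No centring or scaling — for data already on a common (e.g.
        residual-noise) scale; imputation still applies.

    Residual missing values (possible after the consistency filter, which
    only demands one fully detected condition) are imputed as half the
    minimum observed positive intensity of the compound — a standard
    below-detection-limit surrogate — and recorded in ``imputed``.
    Zero-variance variables are rejected: they should have been filtered.
    """
    if method not in ("unit-sd", "baseline-sd", "none"):
        raise ValueError(f"unknown scaling method {method!r}")
    _require_columns(table, ["sample_id", "group", "replicate", "time_h",
                             "compound", "intensity"])
    wide = table.pivot_table(index="sample_id", columns="compound",
                             values="intensity", aggfunc="mean", dropna=False)
    meta = (
        table[["sample_id", "group", "replicate", "time_h"]]
        .drop_duplicates("sample_id")
        .set_index("sample_id")
        .loc[wide.index]
        .reset_index()
    )
    imputed = {}
    for c in wide.columns:
        col = wide[c]
        if col.isna().any():
            positive = col[col > 0]
            fill = float(positive.min() / 2.0) if not positive.empty else 0.0
            wide[c] = col.fillna(fill)
            imputed[c] = fill
    if method == "none":
        centers = pd.Series(0.0, index=wide.columns)
        scales = pd.Series(1.0, index=wide.columns)
        return ScaledMatrix(values=wide, row_meta=meta, method=method,
                            centers=centers, scales=scales, imputed=imputed)
    centers = wide.mean(axis=0)
    if method == "unit-sd":
        scales = wide.std(axis=0, ddof=1)
    else:
        t0 = baseline_time if baseline_time is not None else meta["time_h"].min()
        base_ids = meta.loc[meta["time_h"] == t0, "sample_id"]
        if base_ids.empty:
            raise ValueError(f"no observations at baseline time {t0}")
        scales = wide.loc[base_ids].std(axis=0, ddof=1)
    bad = scales[~(scales > 0)].index.tolist()
    if bad:
        raise ValueError(
            f"zero-variance variables cannot be scaled (filter them first): {bad}"
        )
    values = (wide - centers) / scales
    return ScaledMatrix(values=values, row_meta=meta, method=method,
                        centers=centers, scales=scales, imputed=imputed)
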