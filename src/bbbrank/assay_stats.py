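"""Plate-assay normalization and group-comparison statistics.

Screening signals (viability, ROS, NO, DNA damage, COX activity) are read
as long-format well tables with the study's two-control design: a positive
control (no insult) and a negative control (LPS or microglia supernatant).
Effects are expressed as E/E0 ratios, where E is a treated group's mean
signal and E0 the reference-control mean — by default the negative control
whenever both controls are present.

The statistics contract is the parametric screening standard: Shapiro-Wilk
normality and Levene variance-homogeneity checks, one-way ANOVA, and Tukey
HSD pairwise post-hoc comparisons.  Failed assumption checks annotate the
report with warnings rather than switching tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

ASSAYS = ("MTT", "DCFDA", "Griess", "FHA", "COX_total", "COX1", "COX2")

CONTROL_TAGS = ("positive_control", "negative_control")

INSULTS = ("none", "LPS5", "LPS50", "supernatant")

PLATE_COLUMNS = (
    "experiment_id", "assay", "well", "group", "compound_id",
    "insult", "concentration_uM", "signal",
)


@dataclass
class PlateAssay:
    """Well records for one assay: a validated long-format table."""

    assay: str
    wells: pd.DataFrame  # PLATE_COLUMNS minus "assay"

    def __post_init__(self) -> None:
        if self.assay not in ASSAYS:
            raise ValueError(f"unknown assay {self.assay!r} (known: {', '.join(ASSAYS)})")
        if not np.isfinite(self.wells["signal"].to_numpy(dtype=float)).all():
            raise ValueError(f"{self.assay}: non-finite signal values")
        dup = self.wells.duplicated(subset=["experiment_id", "well"])
        if dup.any():
            row = self.wells[dup].iloc[0]
            raise ValueError(
                f"{self.assay}: duplicated well {row['well']!r} in experiment "
                f"{row['experiment_id']!r}"
            )

    @property
    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.wells["group"]))

    def flag_negative_signals(self) -> pd.DataFrame:
        return self.wells[self.wells["signal"] < 0]


@dataclass
class EndpointSummary:
    """Per-group mean/SD/n and E/E0 ratio for one assay.

    ``table`` columns: group, mean, sd, n, ratio, ratio_sd.  The reference
    group's ratio is exactly 1.
    """

    assay: str
    reference: str
    table: pd.DataFrame
    per_experiment: bool = True

    def ratio(self, group: str) -> float:
        sub = self.table[self.table["group"] == group]
        if sub.empty:
            raise KeyError(f"no group {group!r} in {self.assay} summary")
        return float(sub["ratio"].iloc[0])


@dataclass
class StatsReport:
    """One-way ANOVA with assumption checks and Tukey HSD post-hoc table."""

    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    shapiro_p: Optional[float]
    levene_p: Optional[float]
    posthoc: pd.DataFrame  # group1, group2, mean_diff, p_adj
    warnings: list = field(default_factory=list)
    degenerate: bool = False


def load_plate(path: str | Path) -> list[PlateAssay]:
    """Read a plate CSV into one :class:`PlateAssay` per assay present.

    Row order is irrelevant; missing columns and non-numeric signals raise
    ``ValueError`` naming the problem (with the offending row for signals).
    Blank concentration cells (controls) parse as absent.
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#",
                     dtype={"experiment_id": str, "well": str, "group": str})
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing column(s) {', '.join(missing)}")
    signals = pd.to_numeric(df["signal"], errors="coerce")
    bad = df.index[signals.isna() & df["signal"].notna() | df["signal"].isna()]
    if len(bad):
        raise ValueError(f"{path.name}: non-numeric signal at row {bad[0] + 2}")
    df["signal"] = signals.astype(float)
    df["concentration_uM"] = pd.to_numeric(df["concentration_uM"], errors="coerce")
    plates = []
    for assay, sub in df.groupby("assay", sort=False):
        plates.append(PlateAssay(assay=str(assay), wells=sub.drop(columns="assay").reset_index(drop=True)))
    return plates


def _pick_reference(groups: Sequence[str], reference: Optional[str]) -> str:
    if reference is not None:
        return reference
    present = [t for t in CONTROL_TAGS if t in groups]
    if not present:
        raise ValueError("no control group present and no reference given")
    # Negative control is the reference whenever both controls exist.
    return "negative_control" if "negative_control" in present else present[0]


def normalize_to_control(
    plate: PlateAssay,
    reference: Optional[str] = None,
    per_experiment: bool = True,
) -> EndpointSummary:
    """Normalize group means to E/E0 ratios against the reference control.

    With ``per_experiment`` (default) the ratio is computed within each
    experiment — each replicate's groups are divided by that replicate's
    reference mean — and then averaged across experiments, matching a
    design where the independent experiment is the replication unit.
    ``per_experiment=False`` pools all wells before dividing.
    """
    ref = _pick_reference(plate.groups, reference)
    df = plate.wells
    if ref not in set(df["group"]):
        raise ValueError(f"{plate.assay}: reference group {ref!r} absent")

    overall = df.groupby("group", sort=False)["signal"].agg(["mean", "std", "count"])
    ref_wells = df[df["group"] == ref]
    if len(ref_wells) < 2:
        raise ValueError(f"{plate.assay}: reference group {ref!r} has n < 2")

    if per_experiment:
        ratios: dict[str, list[float]] = {g: [] for g in plate.groups}
        for _, exp in df.groupby("experiment_id", sort=False):
            means = exp.groupby("group", sort=False)["signal"].mean()
            if ref not in means.index:
                continue
            e0 = means[ref]
            if e0 == 0:
                raise ValueError(f"{plate.assay}: reference mean is zero")
            for g, m in means.items():
                ratios[g].append(m / e0)
        rows = []
        for g in plate.groups:
            vals = np.asarray(ratios[g], dtype=float)
            if vals.size == 0:
                raise ValueError(f"{plate.assay}: group {g!r} never co-occurs with reference")
            ratio = 1.0 if g == ref else float(vals.mean())
            rsd = 0.0 if vals.size < 2 else float(vals.std(ddof=1))
            rows.append((g, ratio, rsd))
    else:
        e0 = float(ref_wells["signal"].mean())
        if e0 == 0:
            raise ValueError(f"{plate.assay}: reference mean is zero")
        rows = [
            (g, 1.0 if g == ref else float(overall.loc[g, "mean"] / e0), float("nan"))
            for g in plate.groups
        ]

    table = pd.DataFrame(
        {
            "group": [r[0] for r in rows],
            "mean": [float(overall.loc[r[0], "mean"]) for r in rows],
            "sd": [float(overall.loc[r[0], "std"]) for r in rows],
            "n": [int(overall.loc[r[0], "count"]) for r in rows],
            "ratio": [r[1] for r in rows],
            "ratio_sd": [r[2] for r in rows],
        }
    )
    return EndpointSummary(assay=plate.assay, reference=ref, table=table,
                           per_experiment=per_experiment)


def anova_with_posthoc(groups: Mapping[str, Sequence[float]]) -> StatsReport:
    """One-way ANOVA with Shapiro-Wilk, Levene and Tukey HSD.

    Zero within-group variance with distinct means is reported as a
    flagged infinite F rather than an exception; failed assumption checks
    append warnings but never change the tests run.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    labels = list(groups)
    arrays = [np.asarray(groups[g], dtype=float) for g in labels]
    for g, arr in zip(labels, arrays):
        if arr.size < 2:
            raise ValueError(f"group {g!r} has n < 2")

    k = len(arrays)
    n_total = sum(a.size for a in arrays)
    df_between, df_within = k - 1, n_total - k

    grand = np.concatenate(arrays).mean()
    ssb = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays)

    warnings: list[str] = []
    degenerate = False
    if ssw == 0:
        degenerate = True
        if ssb == 0:
            f_stat, p_value = 0.0, 1.0
            warnings.append("all observations identical; F set to 0")
        else:
            f_stat, p_value = math.inf, 0.0
            warnings.append("zero within-group variance; F reported as +inf")
    else:
        f_stat = (ssb / df_between) / (ssw / df_within)
        p_value = float(stats.f.sf(f_stat, df_between, df_within))

    residuals = np.concatenate([a - a.mean() for a in arrays])
    shapiro_p: Optional[float] = None
    if residuals.size >= 3 and np.ptp(residuals) > 0:
        shapiro_p = float(stats.shapiro(residuals).pvalue)
        if shapiro_p < 0.05:
            warnings.append(f"normality check failed (Shapiro-Wilk p={shapiro_p:.3g})")
    levene_p: Optional[float] = None
    if not degenerate:
        levene_p = float(stats.levene(*arrays, center="mean").pvalue)
        if levene_p < 0.05:
            warnings.append(f"variance homogeneity check failed (Levene p={levene_p:.3g})")

    rows = []
    if not degenerate:
        tk = stats.tukey_hsd(*arrays)
        for i in range(k):
            for j in range(i + 1, k):
                rows.append(
                    (labels[i], labels[j],
                     float(arrays[i].mean() - arrays[j].mean()),
                     float(tk.pvalue[i, j]))
                )
    else:
        for i in range(k):
            for j in range(i + 1, k):
                diff = float(arrays[i].mean() - arrays[j].mean())
                rows.append((labels[i], labels[j], diff, 1.0 if diff == 0 else 0.0))
    posthoc = pd.DataFrame(rows, columns=["group1", "group2", "mean_diff", "p_adj"])

    return StatsReport(
        f_statistic=float(f_stat), df_between=df_between, df_within=df_within,
        p_value=float(p_value), shapiro_p=shapiro_p, levene_p=levene_p,
        posthoc=posthoc, warnings=warnings, degenerate=degenerate,
    )


def plate_statistics(plate: PlateAssay) -> StatsReport:
    """Run the ANOVA/post-hoc contract over a plate's groups (all wells pooled)."""
    groups = {g: sub["signal"].to_numpy() for g, sub in plate.wells.groupby("group", sort=False)}
    return anova_with_posthoc(groups)


def report_to_dict(report: StatsReport) -> dict:
    """JSON-serializable view of a :class:`StatsReport`."""
    return {
        "F": report.f_statistic,
        "df_between": report.df_between,
        "df_within": report.df_within,
        "p": report.p_value,
        "shapiro_p": report.shapiro_p,
        "levene_p": report.levene_p,
        "warnings": list(report.warnings),
        "degenerate": report.degenerate,
        "pairwise": report.posthoc.to_dict(orient="records"),
    }
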