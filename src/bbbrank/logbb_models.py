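"""Blood-brain partition (logBB) models and permeability classification.

logBB = log10(C_brain / C_blood) is the standard steady-state measure of
brain penetration.  Four published linear models are evaluated:

1. ``logBB = 0.139 + 0.152 logP - 0.0148 PSA`` — lipophilicity/polarity.
2. ``logBB = 0.054 Gsolv + 0.43`` — free energy of solvation (kcal/mol).
3. ``logBB = 0.044 + 0.511 E - 0.886 S - 0.724 A - 0.666 B + 0.861 V`` —
   Abraham LFER over the five solute descriptors.
4. ``logBB = 0.934 - 0.743 A - 0.768 B - 0.605 S + 0.191 E + 0.545 V`` —
   a second LFER.  The source prints "-0.605" with no variable attached;
   by default it is read as the S coefficient (mirroring model 3's LFER
   structure), with a ``literal_constant`` reading available that folds
   -0.605 into the intercept.  The interpretation used is always recorded.

Classification uses the conventional cut-offs: compounds with logBB > 0.3
cross the barrier readily, logBB < -1 means poor brain distribution, and
everything between (boundaries included) is intermediate.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .chem_descriptors import DescriptorSet

READILY_THRESHOLD = 0.3
POOR_THRESHOLD = -1.0

MODEL_IDS = (1, 2, 3, 4)

#: Required descriptor fields per model.
MODEL_INPUTS = {
    1: ("logP", "PSA"),
    2: ("Gsolv",),
    3: ("E", "S", "A", "B", "V"),
    4: ("E", "S", "A", "B", "V"),
}

EQ4_INTERPRETATIONS = ("s_coefficient", "literal_constant")


def logbb_model1(logP: float, PSA: float) -> float:
    """logP/PSA model: 0.139 + 0.152 logP - 0.0148 PSA."""
    return 0.139 + 0.152 * logP - 0.0148 * PSA


def logbb_model2(Gsolv: float) -> float:
    """Solvation model: 0.054 Gsolv + 0.43 with Gsolv in kcal/mol."""
    return 0.054 * Gsolv + 0.43


def logbb_model3(E: float, S: float, A: float, B: float, V: float) -> float:
    """Abraham LFER: 0.044 + 0.511E - 0.886S - 0.724A - 0.666B + 0.861V."""
    return 0.044 + 0.511 * E - 0.886 * S - 0.724 * A - 0.666 * B + 0.861 * V


def logbb_model4(
    E: float, S: float, A: float, B: float, V: float,
    interpretation: str = "s_coefficient",
) -> float:
    """Second LFER with the ambiguous -0.605 term (see module docstring)."""
    if interpretation not in EQ4_INTERPRETATIONS:
        raise ValueError(f"unknown eq4 interpretation {interpretation!r}")
    base = 0.934 - 0.743 * A - 0.768 * B + 0.191 * E + 0.545 * V
    if interpretation == "s_coefficient":
        return base - 0.605 * S
    return base - 0.605


def classify_bbb(logbb: float) -> str:
    """Classify a logBB value as ``readily`` / ``intermediate`` / ``poor``.

    Strict inequalities: exactly 0.3 or exactly -1 is ``intermediate``.
    """
    if not math.isfinite(logbb):
        raise ValueError(f"non-finite logBB: {logbb}")
    if logbb > READILY_THRESHOLD:
        return "readily"
    if logbb < POOR_THRESHOLD:
        return "poor"
    return "intermediate"


@dataclass
class LogBBResult:
    """Per-compound logBB under each evaluable model plus permeability class."""

    compound_id: str
    logbb_by_model: dict = field(default_factory=dict)
    class_by_model: dict = field(default_factory=dict)
    eq4_interpretation: str = "s_coefficient"
    missing_models: dict = field(default_factory=dict)  # model -> reason


def _evaluate_model(model: int, ds: DescriptorSet, eq4_interpretation: str) -> float:
    if model == 1:
        return logbb_model1(ds.logP, ds.PSA)
    if model == 2:
        return logbb_model2(ds.Gsolv)
    if model == 3:
        return logbb_model3(ds.E, ds.S, ds.A, ds.B, ds.V)
    if model == 4:
        return logbb_model4(ds.E, ds.S, ds.A, ds.B, ds.V, eq4_interpretation)
    raise ValueError(f"unknown model {model}")


def logbb_table(
    descriptor_sets: Iterable[DescriptorSet],
    models: Sequence[int] = MODEL_IDS,
    eq4_interpretation: str = "s_coefficient",
) -> list[LogBBResult]:
    """Evaluate every requested model for every compound.

    A model whose inputs are incomplete for a compound is recorded under
    ``missing_models`` with the absent fields named, not raised.
    """
    if eq4_interpretation not in EQ4_INTERPRETATIONS:
        raise ValueError(f"unknown eq4 interpretation {eq4_interpretation!r}")
    results = []
    for ds in descriptor_sets:
        res = LogBBResult(compound_id=ds.compound_id, eq4_interpretation=eq4_interpretation)
        for model in models:
            absent = [f for f in MODEL_INPUTS[model] if ds.get(f) is None]
            if absent:
                res.missing_models[model] = f"missing {', '.join(absent)}"
                continue
            value = _evaluate_model(model, ds, eq4_interpretation)
            res.logbb_by_model[model] = value
            res.class_by_model[model] = classify_bbb(value)
        results.append(res)
    return results


def results_to_frame(results: Sequence[LogBBResult], decimals: int = 2) -> pd.DataFrame:
    """Flatten results to the output table, rounding logBB for presentation.

    Values are carried at full precision internally; rounding (default two
    decimals, the conventional print precision) happens only here.
    """
    rows = []
    for res in results:
        row: dict = {"compound_id": res.compound_id}
        for model in MODEL_IDS:
            if model in res.logbb_by_model:
                row[f"logbb_eq{model}"] = round(res.logbb_by_model[model], decimals)
                row[f"class_eq{model}"] = res.class_by_model[model]
            else:
                row[f"logbb_eq{model}"] = None
                row[f"class_eq{model}"] = res.missing_models.get(model, "not requested")
        row["eq4_interpretation"] = res.eq4_interpretation
        rows.append(row)
    return pd.DataFrame(rows)


def load_reference_logbb() -> pd.DataFrame:
    """Published logBB values for the eight 1,2-thiazine derivatives.

    Columns ``eq1``..``eq4`` hold the literature values (two decimals) for
    the TP compound series under models 1-4.  These feed classification
    consistency checks only — the pipeline does not regenerate them, since
    they depend on external descriptor software and DFT solvation energies.
    """
    with resources.files("bbbrank.data").joinpath("reference_logbb.csv").open() as fh:
        return pd.read_csv(fh)
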