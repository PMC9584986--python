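"""Multi-criteria weighted-sum ranking of compounds over assay endpoints.

Each compound is characterized by E/E_LPS50 ratios on a panel of endpoints
(viability, ROS, NO, DNA damage, COX activities) measured relative to the
inflamed negative control.  The weighted-sum model turns these into one
percentage score per compound:

* benefit ``d(c,e) = dir(e) * (ratio(c,e) - 1)`` — the signed improvement
  over the control, positive = beneficial (``dir`` is +1 where a higher
  ratio is better, e.g. viability, and -1 where lower is better, e.g. ROS);
* weights standardize endpoint significance by the maximum observed
  difference: ``w(e) = base(e) / max_c |d(c,e)|`` (COX-1 carries half the
  base weight of the other endpoints — its inhibition drives side effects
  rather than benefit);
* ``score(c) = 100 * sum_e w(e) d(c,e) / sum_e base(e)``, so a compound
  that dominates every endpoint scores 100 and one indistinguishable from
  the control scores 0.

An alternative per-endpoint min-max normalization is available behind
``normalization='minmax'``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

#: Default endpoint panel: (direction, base weight, analysis concentration uM).
DEFAULT_ENDPOINTS = {
    "MTT": ("higher_is_better", 1.0, 10.0),
    "DCFDA": ("lower_is_better", 1.0, 10.0),
    "Griess": ("lower_is_better", 1.0, 10.0),
    "FHA": ("lower_is_better", 1.0, 10.0),
    "COX_total": ("lower_is_better", 1.0, 100.0),
    "COX1": ("lower_is_better", 0.5, 100.0),
}

DIRECTIONS = ("higher_is_better", "lower_is_better")


@dataclass
class EndpointMatrix:
    """Compound x endpoint table of E/E_LPS50 ratios with per-endpoint config.

    ``ratios`` rows are compounds, columns endpoints; the control is
    implicit as ratio 1 everywhere.  ``directions`` and ``base_weights``
    map endpoint -> direction / base weight; ``concentrations`` (optional)
    records the concentration each endpoint was analyzed at, since panels
    may legitimately mix concentrations (e.g. COX endpoints measured only
    at the highest dose).
    """

    ratios: pd.DataFrame
    directions: dict
    base_weights: dict
    concentrations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for e in self.ratios.columns:
            if e not in self.directions:
                raise ValueError(f"no direction for endpoint {e!r}")
            if self.directions[e] not in DIRECTIONS:
                raise ValueError(f"bad direction {self.directions[e]!r} for {e!r}")
            self.base_weights.setdefault(e, 1.0)
        if (self.ratios.to_numpy(dtype=float) <= 0).any():
            raise ValueError("endpoint ratios must be positive")


@dataclass
class MCDAResult:
    """Weighted-sum scores (percent), ranks and the audit trail."""

    scores: pd.Series        # compound -> percent
    ranks: pd.Series         # compound -> rank, 1 = best, ties share min rank
    weights: pd.Series       # endpoint -> standardized weight
    base_weights: dict
    directions: dict
    normalization: str


def benefit_matrix(m: EndpointMatrix) -> pd.DataFrame:
    """Signed benefit d(c,e) = dir(e) * (ratio - 1); positive = beneficial."""
    signs = pd.Series(
        {e: 1.0 if m.directions[e] == "higher_is_better" else -1.0
         for e in m.ratios.columns}
    )
    return (m.ratios - 1.0) * signs


def standardized_weights(d: pd.DataFrame, base_weights: Mapping[str, float]) -> pd.Series:
    """w(e) = base(e) / max_c |d(c,e)|; errors on an all-zero endpoint column."""
    maxabs = d.abs().max(axis=0)
    zero = maxabs[maxabs == 0]
    if not zero.empty:
        raise ValueError(f"endpoint {zero.index[0]!r} shows no difference from control")
    return pd.Series({e: base_weights.get(e, 1.0) / maxabs[e] for e in d.columns})


def mcda_scores(m: EndpointMatrix, normalization: str = "max") -> MCDAResult:
    """Score and rank every compound by the weighted-sum model.

    ``normalization='max'`` (default): max-difference standardization as in
    the module docstring.  ``'minmax'``: each endpoint's benefits are
    rescaled to [0, 1] by (d - min)/(max - min) before the base-weighted
    average; scores remain percentages.
    """
    if normalization not in ("max", "minmax"):
        raise ValueError(f"unknown normalization {normalization!r}")
    d = benefit_matrix(m)
    base_total = sum(m.base_weights[e] for e in d.columns)

    if normalization == "max":
        w = standardized_weights(d, m.base_weights)
        scores = 100.0 * (d * w).sum(axis=1) / base_total
    else:
        span = d.max(axis=0) - d.min(axis=0)
        zero = span[span == 0]
        if not zero.empty:
            raise ValueError(f"endpoint {zero.index[0]!r} shows no spread")
        dnorm = (d - d.min(axis=0)) / span
        base = pd.Series({e: m.base_weights[e] for e in d.columns})
        scores = 100.0 * (dnorm * base).sum(axis=1) / base_total
        w = base / span

    ranks = scores.rank(method="min", ascending=False).astype(int)
    return MCDAResult(
        scores=scores, ranks=ranks, weights=w,
        base_weights=dict(m.base_weights), directions=dict(m.directions),
        normalization=normalization,
    )


def rank_report(result: MCDAResult) -> pd.DataFrame:
    """Ranked table ``rank, compound_id, score_percent`` ordered best-first."""
    df = pd.DataFrame(
        {
            "rank": result.ranks.to_numpy(),
            "compound_id": list(result.scores.index),
            "score_percent": result.scores.to_numpy(),
        }
    ).sort_values(["rank", "compound_id"], kind="stable")
    return df.reset_index(drop=True)


def audit_dict(result: MCDAResult) -> dict:
    """JSON audit record: weights, directions, normalization and scores."""
    return {
        "normalization": result.normalization,
        "directions": dict(result.directions),
        "base_weights": dict(result.base_weights),
        "standardized_weights": {k: float(v) for k, v in result.weights.items()},
        "scores_percent": {k: float(v) for k, v in result.scores.items()},
        "ranks": {k: int(v) for k, v in result.ranks.items()},
    }


def read_endpoint_csv(path: str | Path) -> EndpointMatrix:
    """Load the long-format endpoint CSV into an :class:`EndpointMatrix`.

    Schema: ``compound_id,endpoint,ratio,direction,base_weight,
    concentration_uM`` (the last two optional per row; defaults 1.0 and
    absent).
    """
    df = pd.read_csv(path)
    required = {"compound_id", "endpoint", "ratio", "direction"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{Path(path).name}: missing column(s) {', '.join(sorted(missing))}")
    ratios = df.pivot(index="compound_id", columns="endpoint", values="ratio")
    if ratios.isna().any().any():
        raise ValueError(f"{Path(path).name}: incomplete compound x endpoint grid")
    directions, base_weights, concentrations = {}, {}, {}
    for e, sub in df.groupby("endpoint"):
        dirs = sub["direction"].unique()
        if len(dirs) != 1:
            raise ValueError(f"{Path(path).name}: conflicting directions for {e!r}")
        directions[e] = dirs[0]
        if "base_weight" in sub.columns and sub["base_weight"].notna().any():
            base_weights[e] = float(sub["base_weight"].dropna().iloc[0])
        if "concentration_uM" in sub.columns and sub["concentration_uM"].notna().any():
            concentrations[e] = float(sub["concentration_uM"].dropna().iloc[0])
    return EndpointMatrix(ratios=ratios, directions=directions,
                          base_weights=base_weights, concentrations=concentrations)


def endpoint_matrix_from_summaries(
    summaries: Mapping[str, "EndpointSummary"],
    compounds: Sequence[str],
    analysis_concentration: float = 10.0,
    cox_concentration: float = 100.0,
    endpoints: Optional[Mapping[str, tuple]] = None,
) -> EndpointMatrix:
    """Assemble the MCDA input from per-assay normalization summaries.

    ``summaries`` maps assay name -> :class:`bbbrank.assay_stats.EndpointSummary`
    whose groups are labelled ``"{compound}@{concentration:g}"`` (the
    convention the synthetic plate generator and CLI use).  Each endpoint
    is read at ``analysis_concentration`` except COX endpoints, read at
    ``cox_concentration`` — mirroring panels where COX activity is assayed
    only at the top dose.
    """
    spec = dict(endpoints or DEFAULT_ENDPOINTS)
    cols = [a for a in spec if a in summaries]
    if not cols:
        raise ValueError("no overlapping endpoints between spec and summaries")
    data = {}
    concentrations = {}
    for assay in cols:
        conc = cox_concentration if assay.startswith("COX") else analysis_concentration
        concentrations[assay] = conc
        summary = summaries[assay]
        data[assay] = [summary.ratio(f"{c}@{conc:g}") for c in compounds]
    ratios = pd.DataFrame(data, index=list(compounds))
    directions = {a: spec[a][0] for a in cols}
    base_weights = {a: spec[a][1] for a in cols}
    return EndpointMatrix(ratios=ratios, directions=directions,
                          base_weights=base_weights, concentrations=concentrations)
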