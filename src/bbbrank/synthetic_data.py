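"""Synthetic inputs with known ground truth for the whole pipeline.

Three generators mirror the study design the pipeline targets:

* :func:`simulate_plate` — plate-assay well tables: a positive control
  (no insult, mean 1 AU), a negative control under an inflammatory insult
  (per-assay effect multiplier), and compound groups that recover part of
  the insult, with multiplicative Gaussian well noise (CV-based, matching
  strictly positive assay signals).  Defaults: 5 independent experiments,
  5 wells per group, 8 compounds at 10/50/100 uM, COX endpoints only at
  the top dose.
* :func:`simulate_endpoint_matrix` — E/E_LPS50 ratio matrices built so the
  noise-free weighted-sum ranking recovers a planted compound ordering
  exactly.
* :func:`simulate_halo_image` — DAPI-like nucleus images: a bright core
  disk plus a linearly decaying chromatin halo over a flat background,
  with additive Gaussian noise, and the true core/halo diameters returned
  as ground truth.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .assay_stats import PlateAssay
from .halo_quant import HaloImage
from .mcda_ranking import DEFAULT_ENDPOINTS, EndpointMatrix

#: Compound labels of the study's screening series.
DEFAULT_COMPOUNDS = ("TP1", "TP4", "TP5", "TP6", "TP7", "TP8", "TP9", "TP10")

#: Per-assay insult effect multipliers under LPS 50 ug/ml: viability drops,
#: stress/damage/COX endpoints rise.
DEFAULT_INSULT_MULTIPLIERS = {
    "MTT": 0.6,
    "DCFDA": 1.8,
    "Griess": 1.7,
    "FHA": 1.5,
    "COX_total": 1.5,
    "COX1": 1.15,
    "COX2": 1.7,
}

#: Default compound recovery fractions (0 = no rescue, 1 = full return to
#: the no-insult control), echoing the screen's qualitative outcome: the
#: six/seven-membered-ring derivatives strongest, halogenated ones weakest.
DEFAULT_POTENCIES = {
    "TP1": 0.72, "TP4": 0.90, "TP5": 0.75, "TP6": 0.55,
    "TP7": 0.48, "TP8": 0.88, "TP9": 0.82, "TP10": 0.76,
}


@dataclass
class PlateSimConfig:
    """Study-design parameters for the plate-assay generator."""

    n_experiments: int = 5
    wells_per_group: int = 5
    compounds: Sequence[str] = DEFAULT_COMPOUNDS
    concentrations: Sequence[float] = (10.0, 50.0, 100.0)
    assays: Sequence[str] = ("MTT", "DCFDA", "Griess", "FHA", "COX_total", "COX1")
    insult: str = "LPS50"
    insult_multipliers: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_INSULT_MULTIPLIERS))
    potency: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_POTENCIES))
    #: concentration -> potency scaling (flat by default; the generator is
    #: phenomenological, not a dose-response model)
    conc_response: Mapping[float, float] = field(
        default_factory=lambda: {10.0: 1.0, 50.0: 1.0, 100.0: 1.0})
    #: COX endpoints are assayed only at this concentration
    cox_concentration: float = 100.0
    noise_cv: float = 0.1
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError("noise CV must be >= 0")
        if self.n_experiments < 1 or self.wells_per_group < 1:
            raise ValueError("need at least one experiment and one well per group")
        for assay in self.assays:
            m = self.insult_multipliers.get(assay)
            if m is None or m <= 0:
                raise ValueError(f"insult multiplier for {assay!r} must be positive")
        for c in self.compounds:
            if c not in self.potency:
                raise ValueError(f"no potency for compound {c!r}")


@dataclass
class HaloSimConfig:
    """Geometry and noise for one synthetic nucleus image."""

    d_nucleus_px: float = 40.0
    d_halo_px: float = 80.0
    peak: float = 1000.0
    background: float = 100.0
    noise_sd: float = 0.0
    size: Optional[int] = None  # square side; default fits the halo
    f_core: float = 0.5         # halo intensity at the core edge, x peak
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.d_halo_px < self.d_nucleus_px:
            raise ValueError("halo diameter must be >= nucleus diameter")
        if self.d_nucleus_px <= 0:
            raise ValueError("nucleus diameter must be positive")
        if self.size is None:
            self.size = max(64, int(math.ceil(self.d_halo_px * 1.3)) | 1)
        if self.size < self.d_halo_px + 8:
            raise ValueError("image size does not fit the halo")


def planted_potencies(
    best: str,
    compounds: Sequence[str] = DEFAULT_COMPOUNDS,
    best_potency: float = 0.9,
    other_potency: float = 0.6,
) -> dict:
    """Potency table with one clearly dominant compound (for recovery tests)."""
    if best not in compounds:
        raise ValueError(f"{best!r} not among compounds")
    return {c: (best_potency if c == best else other_potency) for c in compounds}


def group_mean(insult_multiplier: float, recovery: float) -> float:
    """True mean of a compound group: control mean 1 AU, insult m, recovery r.

    mean = m + r * (1 - m): r = 0 leaves the insult effect, r = 1 restores
    the no-insult control, for both suppressed (m < 1) and elevated (m > 1)
    endpoints.
    """
    return insult_multiplier + recovery * (1.0 - insult_multiplier)


def simulate_plate(cfg: PlateSimConfig) -> tuple[list[PlateAssay], pd.DataFrame]:
    """Generate plate-assay wells plus the ground-truth group means.

    Returns one :class:`PlateAssay` per configured assay and a truth table
    (``assay, group, true_mean, true_ratio``) where ``true_ratio`` is the
    group mean over the negative-control mean.  Well signal =
    ``true_mean * (1 + Normal(0, CV))``.
    """
    rng = np.random.default_rng(cfg.seed)
    plates: list[PlateAssay] = []
    truth_rows = []
    for assay in cfg.assays:
        m = cfg.insult_multipliers[assay]
        concs = [cfg.cox_concentration] if assay.startswith("COX") else list(cfg.concentrations)
        groups: list[tuple[str, str, str, object, float]] = [
            ("positive_control", "", "none", "", 1.0),
            ("negative_control", "", cfg.insult, "", m),
        ]
        for comp in cfg.compounds:
            for conc in concs:
                r = cfg.potency[comp] * cfg.conc_response.get(conc, 1.0)
                groups.append(
                    (f"{comp}@{conc:g}", comp, cfg.insult, conc, group_mean(m, r))
                )
        rows = []
        for exp in range(1, cfg.n_experiments + 1):
            for gname, comp, insult, conc, mu in groups:
                noise = rng.normal(0.0, cfg.noise_cv, size=cfg.wells_per_group)
                for w, eps in enumerate(noise, start=1):
                    rows.append(
                        (f"E{exp}", f"{gname}:w{w}", gname, comp, insult, conc,
                         mu * (1.0 + eps))
                    )
        wells = pd.DataFrame(
            rows,
            columns=["experiment_id", "well", "group", "compound_id",
                     "insult", "concentration_uM", "signal"],
        )
        wells["concentration_uM"] = pd.to_numeric(wells["concentration_uM"], errors="coerce")
        plates.append(PlateAssay(assay=assay, wells=wells))
        for gname, _, _, _, mu in groups:
            truth_rows.append((assay, gname, mu, mu / m))
    truth = pd.DataFrame(truth_rows, columns=["assay", "group", "true_mean", "true_ratio"])
    return plates, truth


def write_plate_csv(plates: Sequence[PlateAssay], path: str | Path,
                    seed: Optional[int] = None) -> None:
    """Write plates to the long-format CSV; the seed is echoed in a header comment."""
    path = Path(path)
    frames = []
    for p in plates:
        df = p.wells.copy()
        df.insert(1, "assay", p.assay)
        frames.append(df)
    combined = pd.concat(frames, ignore_index=True)
    with path.open("w", newline="") as fh:
        if seed is not None:
            fh.write(f"# generator seed: {seed}\n")
        combined.to_csv(fh, index=False)


def simulate_endpoint_matrix(
    planted_scores: Mapping[str, float],
    endpoints: Optional[Mapping[str, tuple]] = None,
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
    max_benefit: float = 0.5,
) -> tuple[EndpointMatrix, pd.Series]:
    """Ratio matrix whose noise-free weighted-sum ranking is the planted order.

    ``planted_scores`` maps compound -> relative merit in [0, 1]; every
    endpoint's benefit column is proportional to it (scaled to
    ``max_benefit``), so with no noise the MCDA score equals
    ``100 * planted / max(planted)`` and ties are preserved.  Gaussian
    noise (SD ``noise_sd``) is added per ratio cell, floored at 0.01 to
    keep ratios positive.
    """
    spec = dict(endpoints or DEFAULT_ENDPOINTS)
    rng = np.random.default_rng(seed)
    compounds = list(planted_scores)
    planted = pd.Series({c: float(planted_scores[c]) for c in compounds})
    if (planted < 0).any() or (planted > 1).any():
        raise ValueError("planted scores must lie in [0, 1]")

    data = {}
    for e, (direction, _base, _conc) in spec.items():
        sign = 1.0 if direction == "higher_is_better" else -1.0
        d = planted.to_numpy() * max_benefit
        ratio = 1.0 + sign * d
        if noise_sd > 0:
            ratio = ratio + rng.normal(0.0, noise_sd, size=ratio.size)
        data[e] = np.clip(ratio, 0.01, None)
    matrix = EndpointMatrix(
        ratios=pd.DataFrame(data, index=compounds),
        directions={e: spec[e][0] for e in spec},
        base_weights={e: spec[e][1] for e in spec},
        concentrations={e: spec[e][2] for e in spec},
    )
    return matrix, planted


def simulate_halo_image(cfg: HaloSimConfig) -> tuple[HaloImage, dict]:
    """Render one synthetic nucleus with a known core and halo diameter.

    Intensity: ``background + peak`` inside the core (r <= r_nucleus);
    in the halo the above-background signal decays linearly from
    ``f_core * peak`` at the core edge to 0 at the halo edge; flat
    background outside.  Additive Gaussian noise, clipped at 0.  Truth
    dict carries ``d_nucleus_px`` and ``d_halo_px``.
    """
    rng = np.random.default_rng(cfg.seed)
    n = int(cfg.size)
    c = (n - 1) / 2.0
    yy, xx = np.indices((n, n))
    r = np.hypot(yy - c, xx - c)

    r_nuc = cfg.d_nucleus_px / 2.0
    r_halo = cfg.d_halo_px / 2.0
    img = np.full((n, n), cfg.background, dtype=float)
    img[r <= r_nuc] += cfg.peak
    if r_halo > r_nuc:
        in_halo = (r > r_nuc) & (r <= r_halo)
        falloff = (r_halo - r[in_halo]) / (r_halo - r_nuc)
        img[in_halo] += cfg.f_core * cfg.peak * falloff
    if cfg.noise_sd > 0:
        img = img + rng.normal(0.0, cfg.noise_sd, size=img.shape)
    img = np.clip(img, 0.0, None)

    truth = {"d_nucleus_px": cfg.d_nucleus_px, "d_halo_px": cfg.d_halo_px,
             "center": (c, c)}
    return HaloImage(pixels=img, source=f"synthetic(seed={cfg.seed})"), truth


def write_halo_image(img: HaloImage, path: str | Path) -> None:
    """Save a synthetic image as 16-bit PNG/TIFF."""
    import imageio.v3 as iio

    arr = np.clip(img.pixels, 0, 65535).astype(np.uint16)
    iio.imwrite(Path(path), arr)
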