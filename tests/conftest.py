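import numpy as np
import pytest

from bbbrank.assay_stats import normalize_to_control
from bbbrank.mcda_ranking import endpoint_matrix_from_summaries, mcda_scores
from bbbrank.synthetic_data import PlateSimConfig, planted_potencies, simulate_plate


@pytest.fixture
def rng():
    return np.random.default_rng(20220921)


def run_full_chain(seed: int, best: str = "TP4", noise_cv: float = 0.1):
    """simulate plates -> normalize -> endpoint matrix -> MCDA result."""
    cfg = PlateSimConfig(seed=seed, noise_cv=noise_cv,
                         potency=planted_potencies(best))
    plates, _ = simulate_plate(cfg)
    summaries = {p.assay: normalize_to_control(p) for p in plates}
    matrix = endpoint_matrix_from_summaries(summaries, cfg.compounds)
    return mcda_scores(matrix)
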