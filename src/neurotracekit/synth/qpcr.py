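"""RT-qPCR Ct-table generator for nuclear/cytoplasmic fractionation."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .params import GroundTruth

__all__ = ["simulate_ct_table"]


def simulate_ct_table(
    proportions: dict[str, float] | None = None,
    n_replicates: int = 4,
    ct_cyt_mean: float = 24.0,
    ct_between_sd: float = 1.0,
    ct_noise_sd: float = 0.1,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate Ct values consistent with known nuclear proportions.

    cDNA from proportionally equal volumes of the two fractions and perfect
    doubling per cycle imply ``ct_nuc − ct_cyt = log2((1−p)/p)`` for nuclear
    proportion ``p``.  Replicates vary the cytoplasmic Ct between
    preparations (sd ``ct_between_sd``) and add technical noise
    (sd ``ct_noise_sd``) to every well.
    """
    if proportions is None:
        proportions = {"nuclear_enriched": 0.8, "balanced": 0.5, "cytoplasmic": 0.15}
    for gene, p in proportions.items():
        if not 0 < p < 1:
            raise ValueError(f"proportion for {gene!r} must be in (0, 1)")
    rng = np.random.default_rng(seed)
    rows = []
    for gene, p in proportions.items():
        delta = np.log2((1.0 - p) / p)
        for rep in range(n_replicates):
            base = ct_cyt_mean + rng.normal(0.0, ct_between_sd)
            rows.append((gene, "cytoplasmic", base + rng.normal(0.0, ct_noise_sd), rep))
            rows.append((gene, "nuclear", base + delta + rng.normal(0.0, ct_noise_sd), rep))
    table = pd.DataFrame(rows, columns=["gene", "fraction", "ct", "replicate"])
    return table, GroundTruth(proportions=dict(proportions))
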