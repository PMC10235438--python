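"""Nuclear–cytoplasmic distribution from RT-qPCR Ct values.

With cDNA synthesised from proportionally equal volumes of nuclear and
cytoplasmic RNA and perfect doubling per cycle, relative abundance is
proportional to 2^(−Ct), so the nuclear proportion is
``2^(−Ct_nuc) / (2^(−Ct_nuc) + 2^(−Ct_cyt))``.  Proportions are arcsine
(square-root) transformed for statistics and back-transformed for
presentation.  The same 2^(−ΔCt) core backs reference-gene-normalised
expression levels (2^(−ΔΔCt)).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "compartment_proportion",
    "arcsine_transform",
    "inverse_arcsine",
    "proportion_table",
    "fold_change_ddct",
]


def compartment_proportion(ct_nuc, ct_cyt):
    """Nuclear proportion in [0, 1] from a pair of Ct values.

    Computed as ``1 / (1 + 2^(ct_nuc − ct_cyt))``, which is numerically
    stable for any Ct difference and gives the correct limits (0 as
    ct_nuc → ∞, 1 as ct_cyt → ∞).  Accepts scalars or arrays; NaN input
    raises.
    """
    ct_nuc = np.asarray(ct_nuc, float)
    ct_cyt = np.asarray(ct_cyt, float)
    if np.any(np.isnan(ct_nuc)) or np.any(np.isnan(ct_cyt)):
        raise ValueError("Ct values must be finite (non-NaN)")
    with np.errstate(over="ignore"):
        p = 1.0 / (1.0 + np.exp2(ct_nuc - ct_cyt))
    return p if p.ndim else float(p)


def arcsine_transform(p):
    """Variance-stabilising arcsine-square-root transform, asin(√p) (radians)."""
    p = np.asarray(p, float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("proportions must lie in [0, 1]")
    x = np.arcsin(np.sqrt(p))
    return x if x.ndim else float(x)


def inverse_arcsine(x):
    """Back-transform: sin²(x), the inverse of :func:`arcsine_transform`."""
    x = np.asarray(x, float)
    if np.any((x < 0) | (x > np.pi / 2)):
        raise ValueError("transformed values must lie in [0, pi/2]")
    p = np.sin(x) ** 2
    return p if p.ndim else float(p)


def proportion_table(ct_table: pd.DataFrame) -> pd.DataFrame:
    """Per-gene nuclear proportions with transformed-scale summary statistics.

    ``ct_table`` is tidy with columns ``gene``, ``fraction`` (``nuclear`` /
    ``cytoplasmic``), ``ct`` and ``replicate``; both fractions must be
    present for every (gene, replicate).  Returns one row per gene with the
    per-replicate proportions' mean and sd computed on the arcsine scale and
    back-transformed for presentation.
    """
    required = {"gene", "fraction", "ct", "replicate"}
    if not required.issubset(ct_table.columns):
        raise ValueError(f"ct_table needs columns {sorted(required)}")
    wide = ct_table.pivot_table(index=["gene", "replicate"], columns="fraction",
                                values="ct")
    if wide[["nuclear", "cytoplasmic"]].isna().any().any():
        raise ValueError("both fractions required for every (gene, replicate)")
    p = compartment_proportion(wide["nuclear"].to_numpy(),
                               wide["cytoplasmic"].to_numpy())
    frame = wide.reset_index()[["gene", "replicate"]].assign(proportion_nuclear=p)
    rows = []
    for gene, grp in frame.groupby("gene", sort=False):
        z = arcsine_transform(grp["proportion_nuclear"].to_numpy())
        zm = z.mean()
        zsd = z.std(ddof=1) if z.size > 1 else np.nan
        rows.append({
            "gene": gene,
            "n": z.size,
            "proportion_nuclear": inverse_arcsine(zm),
            "ci_low": inverse_arcsine(max(0.0, zm - zsd)) if z.size > 1 else np.nan,
            "ci_high": inverse_arcsine(min(np.pi / 2, zm + zsd)) if z.size > 1 else np.nan,
        })
    return pd.DataFrame(rows)


def fold_change_ddct(ct_target, ct_ref, ct_target_baseline, ct_ref_baseline):
    """Reference-gene-normalised expression fold change, 2^(−ΔΔCt)."""
    ddct = (np.asarray(ct_target, float) - np.asarray(ct_ref, float)) - (
        np.asarray(ct_target_baseline, float) - np.asarray(ct_ref_baseline, float))
    fc = np.exp2(-ddct)
    return fc if fc.ndim else float(fc)
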