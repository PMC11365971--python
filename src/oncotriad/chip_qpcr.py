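"""ΔΔCt-family quantification for ChIP-qPCR occupancy and RT-qPCR expression.

Replicate Ct values are averaged on the Ct (cycle) scale before
exponentiation, and the amplification efficiency is fixed at perfect
doubling (base 2) by default but exposed as a parameter.
"""

from __future__ import annotations

import numpy as np


def _mean_ct(values, name: str) -> float:
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError(f"{name}: at least one replicate Ct is required")
    if not np.isfinite(arr).all() or (arr <= 0).any():
        raise ValueError(f"{name}: Ct values must be finite and positive")
    return float(arr.mean())


def fold_enrichment(ct_specific, ct_igg, efficiency: float = 2.0) -> float:
    """ChIP fold enrichment over the IgG background control.

    FE = efficiency^-(mean(Ct_specific) - mean(Ct_IgG)); equal mean Cts
    give 1, and every cycle earlier of the specific antibody multiplies
    the enrichment by the efficiency.
    """
    if efficiency <= 1.0:
        raise ValueError("amplification efficiency must exceed 1")
    delta = _mean_ct(ct_specific, "ct_specific") - _mean_ct(ct_igg, "ct_igg")
    return float(efficiency ** (-delta))


def relative_expression(
    ct_target_case,
    ct_ref_case,
    ct_target_ctrl,
    ct_ref_ctrl,
    efficiency: float = 2.0,
) -> float:
    """Relative quantity by the ΔΔCt method with a reference gene.

    RQ = efficiency^-[(Ct_target - Ct_ref)_case - (Ct_target - Ct_ref)_control].
    """
    if efficiency <= 1.0:
        raise ValueError("amplification efficiency must exceed 1")
    d_case = _mean_ct(ct_target_case, "ct_target_case") - _mean_ct(ct_ref_case, "ct_ref_case")
    d_ctrl = _mean_ct(ct_target_ctrl, "ct_target_ctrl") - _mean_ct(ct_ref_ctrl, "ct_ref_ctrl")
    return float(efficiency ** (-(d_case - d_ctrl)))
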