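"""Aortic valve impedance and simplified-Bernoulli trans-valvular gradient."""
from __future__ import annotations

from .traces import KPA_PER_MMHG


def estimate_zv(dp_av: float, q_peak: float) -> float:
    """Valve impedance Zv ~ dp_av / q_peak of the resistive-diode valve model.

    Parameters
    ----------
    dp_av : peak trans-valvular pressure drop, kPa (>= 0; 0 for a healthy valve).
    q_peak : peak aortic flow, ml/ms (> 0).

    Returns
    -------
    Zv in kPa ms/ml.
    """
    if q_peak <= 0:
        raise ValueError(f"q_peak must be positive, got {q_peak}")
    if dp_av < 0:
        raise ValueError(f"dp_av must be non-negative, got {dp_av}")
    return dp_av / q_peak


def bernoulli_dp(v_peak: float) -> float:
    """Simplified-Bernoulli pressure drop from the peak jet velocity.

    The echo convention dp[mmHg] = 4 * v_peak[m/s]^2 is applied and the result
    converted to kPa; both the coefficient's unit assumptions and the
    conversion factor are explicit.
    """
    if v_peak < 0:
        raise ValueError(f"v_peak must be non-negative, got {v_peak}")
    return 4.0 * v_peak**2 * KPA_PER_MMHG
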