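"""Tube-current protocol dose arithmetic.

Models per-phase dose as proportional to tube current: a gated MP-CTA
protocol delivers full current inside the pulsing window and a reduced
fraction outside. Replacing it with a constant reduced current lowers the
summed relative dose accordingly.
"""

from __future__ import annotations

__all__ = ["relative_dose", "dose_reduction_percent"]


def relative_dose(n_full: int, n_low: int, low_fraction: float) -> float:
    """Summed relative dose of ``n_full`` phases at weight 1.0 plus
    ``n_low`` phases at weight ``low_fraction``."""
    if n_full < 0 or n_low < 0:
        raise ValueError("phase counts must be nonnegative")
    if not 0.0 <= low_fraction <= 1.0:
        raise ValueError("low_fraction must lie in [0, 1]")
    return n_full * 1.0 + n_low * low_fraction


def dose_reduction_percent(
    total_phases: int = 20,
    full_phases: int = 6,
    low_fraction: float = 0.2,
    round_to: float = 5.0,
) -> float:
    """Percentage dose reduction when the gated protocol (``full_phases``
    at full current, the rest at ``low_fraction``) is replaced by a
    constant ``low_fraction`` current across all ``total_phases``.

    With the defaults (6 of 20 phases at full current, 20% elsewhere) the
    baseline relative dose is 6 + 14*0.2 = 8.8, the constant-low protocol
    delivers 20*0.2 = 4.0, a ~55% reduction. ``round_to=0`` disables
    rounding.
    """
    if full_phases > total_phases:
        raise ValueError("full_phases cannot exceed total_phases")
    baseline = relative_dose(full_phases, total_phases - full_phases, low_fraction)
    constant = relative_dose(0, total_phases, low_fraction)
    reduction = 100.0 * (baseline - constant) / baseline
    if round_to:
        reduction = round(reduction / round_to) * round_to
    return reduction
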