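"""EDSS measurement grid utilities.

The EDSS is recorded on the half-point grid {0.0} ∪ {1.0, 1.5, ..., 10.0};
there is no 0.5 step.
"""

from __future__ import annotations

import numpy as np

#: All legal EDSS values, ascending.
EDSS_GRID = np.concatenate([[0.0], np.arange(1.0, 10.01, 0.5)])

_LEGAL = set(np.round(EDSS_GRID, 1))


def is_on_grid(value: float, atol: float = 1e-9) -> bool:
    """True if ``value`` is a legal EDSS score."""
    return any(abs(value - g) <= atol for g in EDSS_GRID)


def round_to_grid(value):
    """Round a latent disability value to the nearest legal EDSS score.

    Values are clamped to [0, 10] and rounded to the nearest half point with
    ties going up; a half-point result of 0.5 (which does not exist on the
    EDSS) maps to 0.0, so latent values in (0, 0.75) emit 0.0.
    """
    arr = np.asarray(value, dtype=float)
    clipped = np.clip(arr, 0.0, 10.0)
    # nearest half point, ties up
    half = np.floor(2.0 * clipped + 0.5) / 2.0
    half = np.where(half == 0.5, 0.0, half)
    half = np.clip(half, 0.0, 10.0)
    if np.isscalar(value) or arr.ndim == 0:
        return float(half)
    return half
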