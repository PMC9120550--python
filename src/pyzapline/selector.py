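"""Choosing how many spatial components to remove per chunk.

The component scores produced by the joint decorrelation drop off sharply
after the genuine noise components ("elbow").  Rather than eyeballing that
elbow, outliers are counted by an iterative mean + sigma*SD rule: remove all
scores above the threshold, recompute mean and SD on what remains, repeat
until nothing is removed.  The count is then reconciled with the configured
fixed minimum and capped at one fifth of the components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EmptyScoresError

__all__ = ["RemovalDecision", "iterative_outlier_count", "resolve_nremove"]


@dataclass
class RemovalDecision:
    """Outcome of the per-chunk component selection."""

    n_outliers: int
    n_removed: int
    sigma_used: float


def iterative_outlier_count(scores, sigma: float) -> int:
    """Count outliers by iterated mean + sigma*SD thresholding.

    SD is the sample standard deviation (n-1 denominator); comparisons are
    strict, so a constant score vector yields zero outliers.  Robust location
    estimates (median/MAD) are deliberately not used here: the outliers to be
    counted sit at the top and drag those estimators with them.
    """
    remaining = np.asarray(scores, dtype=np.float64)
    if remaining.size == 0:
        raise EmptyScoresError("score vector is empty")
    if not np.all(np.isfinite(remaining)):
        raise EmptyScoresError("score vector contains non-finite values")
    total = 0
    while remaining.size >= 2:
        thresh = remaining.mean() + sigma * remaining.std(ddof=1)
        out = remaining > thresh
        n_out = int(out.sum())
        if n_out == 0:
            break
        total += n_out
        remaining = remaining[~out]
    return total


def resolve_nremove(
    n_outliers: int,
    fixed_nremove: int,
    n_components: int,
    noise_present: bool,
    adaptive: bool,
) -> int:
    """Final removal count after minimum and cap rules.

    When the chunk carries the artifact and adaptive selection is on, the
    larger of the outlier count and the fixed minimum is used; otherwise only
    the fixed number is removed (so chunks without the artifact are barely
    touched).  The result is capped at one fifth of the components to bound
    the damage a runaway detection could do.
    """
    if n_components < 1:
        raise EmptyScoresError("need at least one component")
    if noise_present and adaptive:
        n = max(n_outliers, fixed_nremove)
    else:
        n = fixed_nremove
    n = min(n, n_components // 5)
    return max(n, 0)
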