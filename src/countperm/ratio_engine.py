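"""Log-ratios against the averaged control pool, plus platform p-values.

Each sample's expression is expressed as the log10 ratio of its intensity to
the arithmetic mean intensity of the control group for that probe — for
control samples as well as treated ones, so the control group's own spread
around its pool mean is visible downstream.

Platform p-values (a per-measurement confidence that a signal differs from
the reference pool, produced by array-platform error models) are either
supplied externally (``passthrough``), replaced by a simple z-model against
the control-sample log-ratio spread (``control-spread``), or switched off
(``disabled``, every p = 0 so flagging reduces to the fold-change cutoff).
"""

from __future__ import annotations

from dataclasses import replace
from typing import Optional

import numpy as np
from scipy import stats

from .datatypes import ExpressionMatrix, RatioTable

P_MODES = ("passthrough", "control-spread", "disabled")

# ratios are floored before log10 so zero intensities give a large finite
# negative log-ratio instead of -inf (flags still read it as strongly down)
_RATIO_FLOOR = 1e-12


def pool_log_ratios(
    intensities: np.ndarray, control_idx: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Log10 ratios of every sample to the control-pool arithmetic mean.

    Returns ``(log_ratios, usable)`` where ``usable`` marks probes with a
    positive pool mean; unusable rows are zeroed.
    """
    pool = intensities[:, control_idx].mean(axis=1)
    usable = pool > 0
    lr = np.zeros_like(intensities, dtype=float)
    if np.any(usable):
        ratio = intensities[usable] / pool[usable, None]
        lr[usable] = np.log10(np.maximum(ratio, _RATIO_FLOOR))
    return lr, usable


def control_spread_pvalues(
    log_ratios: np.ndarray, control_idx: np.ndarray, sd_floor: float = 1e-3
) -> np.ndarray:
    """Two-sided normal p for each log-ratio against the control-sample SD.

    A per-probe z-score ``log_ratio / sd(control log-ratios)`` is converted
    to ``2 * (1 - Phi(|z|))``.  The SD floor guards degenerate probes whose
    simulated control replicates coincide.
    """
    if control_idx.size < 3:
        raise ValueError("control-spread p-values need at least 3 control samples")
    sd = np.std(log_ratios[:, control_idx], axis=1, ddof=1)
    sd = np.maximum(sd, sd_floor)
    z = log_ratios / sd[:, None]
    return 2.0 * stats.norm.sf(np.abs(z))


def compute_log_ratios(expr: ExpressionMatrix) -> RatioTable:
    """Build the per-sample log10 ratio table (p-values unset)."""
    lr, usable = pool_log_ratios(expr.intensities, expr.control_idx)
    return RatioTable(
        probe_ids=list(expr.probe_ids),
        sample_ids=list(expr.sample_ids),
        log_ratios=lr,
        group_of=dict(expr.group_of),
        usable=usable,
    )


def platform_pvalues(
    ratios: RatioTable,
    mode: str = "control-spread",
    pvalues: Optional[np.ndarray] = None,
    sd_floor: float = 1e-3,
) -> RatioTable:
    """Attach a platform p-value matrix to a ratio table.

    mode
        ``passthrough`` copies an externally supplied matrix verbatim,
        ``control-spread`` derives two-sided z-model p-values from the
        control-sample log-ratio spread, ``disabled`` sets every p to 0 so
        the p-criterion always passes.
    """
    if mode not in P_MODES:
        raise ValueError(f"unknown p-value mode {mode!r}; expected one of {P_MODES}")
    if mode == "passthrough":
        if pvalues is None:
            raise ValueError("passthrough mode requires an external p-value matrix")
        return ratios.with_pvalues(pvalues)
    if mode == "disabled":
        return replace(ratios, p_values=np.zeros_like(ratios.log_ratios))
    p = control_spread_pvalues(ratios.log_ratios, ratios.control_idx, sd_floor=sd_floor)
    return replace(ratios, p_values=p)


def ratio_table(
    expr: ExpressionMatrix,
    p_mode: str = "control-spread",
    pvalues: Optional[np.ndarray] = None,
    sd_floor: float = 1e-3,
) -> RatioTable:
    """Convenience: log-ratios plus p-values in one call."""
    return platform_pvalues(
        compute_log_ratios(expr), mode=p_mode, pvalues=pvalues, sd_floor=sd_floor
    )
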