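"""Step 1: flag each (probe, sample) as up/down/unchanged and count per group.

A sample is flagged for a probe when |log10 ratio| >= theta_r (default 0.097,
the printed equivalent of a 1.25-fold change) AND platform p <= theta_p
(default 0.1).  Note the literal cutoff: log10(1.25) = 0.09691 is strictly
below 0.097, so a sample at exactly 1.25-fold does NOT pass the default;
use ``theta_from_fold`` to get the exact log cutoff for a chosen fold.

Per probe, |S| counts samples flagged up and |R| samples flagged down,
separately in the control and treated groups.  A probe whose treated-group
counts tie (S = R > 0) shows equal up and down movement and is designated
non-interpretable: the permutation step is skipped for it and it can never
be called significant.
"""

from __future__ import annotations

import numpy as np

from .datatypes import DirectionalCounts, FlagMatrix, RatioTable

DEFAULT_THETA_R = 0.097
DEFAULT_THETA_P = 0.1


def theta_from_fold(fold: float) -> float:
    """Log10-ratio cutoff equivalent to a linear fold-change cutoff."""
    if fold <= 1:
        raise ValueError("fold cutoff must exceed 1")
    return float(np.log10(fold))


def flag_array(
    log_ratios: np.ndarray,
    p_values: np.ndarray,
    theta_r: float = DEFAULT_THETA_R,
    theta_p: float = DEFAULT_THETA_P,
    usable: np.ndarray | None = None,
) -> np.ndarray:
    """Vectorized flag computation on raw arrays (used under permutation too)."""
    if theta_r < 0:
        raise ValueError("log-ratio cutoff must be non-negative")
    if not 0 <= theta_p <= 1:
        raise ValueError("p-value cutoff must lie in [0, 1]")
    pass_p = p_values <= theta_p
    up = pass_p & (log_ratios >= theta_r)
    down = pass_p & (log_ratios <= -theta_r)
    if theta_r == 0:
        # keep sign(flag) == sign(log_ratio): a zero ratio is unchanged
        up &= log_ratios > 0
        down &= log_ratios < 0
    flags = np.zeros(log_ratios.shape, dtype=np.int8)
    flags[up] = 1
    flags[down] = -1
    if usable is not None:
        flags[~usable] = 0
    return flags


def flag_samples(
    ratios: RatioTable,
    theta_r: float = DEFAULT_THETA_R,
    theta_p: float = DEFAULT_THETA_P,
) -> FlagMatrix:
    """Apply the fold-change + p-value criteria to every (probe, sample)."""
    if ratios.p_values is None:
        raise ValueError("ratio table has no p-values; attach them first")
    flags = flag_array(
        ratios.log_ratios, ratios.p_values, theta_r, theta_p, usable=ratios.usable
    )
    return FlagMatrix(
        probe_ids=list(ratios.probe_ids),
        sample_ids=list(ratios.sample_ids),
        flags=flags,
        theta_r=theta_r,
        theta_p=theta_p,
        group_of=dict(ratios.group_of),
        usable=ratios.usable,
    )


def count_array(
    flags: np.ndarray, control_idx: np.ndarray, treated_idx: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(S_control, R_control, S_treated, R_treated) from a flag matrix."""
    S_c = (flags[:, control_idx] == 1).sum(axis=1)
    R_c = (flags[:, control_idx] == -1).sum(axis=1)
    S_t = (flags[:, treated_idx] == 1).sum(axis=1)
    R_t = (flags[:, treated_idx] == -1).sum(axis=1)
    return S_c, R_c, S_t, R_t


def count_directional(flags: FlagMatrix) -> DirectionalCounts:
    """Per-probe directional counts |S| and |R| for each group."""
    ctrl, trt = flags.control_idx, flags.treated_idx
    S_c, R_c, S_t, R_t = count_array(flags.flags, ctrl, trt)
    return DirectionalCounts(
        probe_ids=list(flags.probe_ids),
        S_control=S_c,
        R_control=R_c,
        S_treated=S_t,
        R_treated=R_t,
        n_control=int(ctrl.size),
        n_treated=int(trt.size),
        usable=flags.usable,
    )


def mark_noninterpretable(counts: DirectionalCounts) -> np.ndarray:
    """True where treated up and down counts tie at a nonzero value.

    The rule is scoped to the treated group: mixed directions among controls
    are informative to the permutation step (which compares within one
    direction) rather than disqualifying.
    """
    return (counts.S_treated == counts.R_treated) & (counts.S_treated > 0)


def search_max_control_flags(
    n_samples: int = 5,
    theta_r: float = DEFAULT_THETA_R,
    n_trials: int = 50_000,
    rng: np.random.Generator | None = None,
    log10_range: tuple[float, float] = (-3.0, 3.0),
) -> int:
    """Brute-force the max number of same-direction flags a control group can
    produce against its own pool mean.

    Draws positive intensity vectors with log10-uniform entries and counts,
    per vector, how many samples clear the cutoff upward and downward.  The
    pool-mean constraint caps the answer below the group size: k samples at
    fold f above the mean force k*f <= n, and symmetric reasoning in the
    down direction still leaves one sample above the mean.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    lo, hi = log10_range
    exponents = rng.uniform(lo, hi, size=(n_trials, n_samples))
    x = 10.0 ** exponents
    lr = np.log10(x / x.mean(axis=1, keepdims=True))
    up = (lr >= theta_r).sum(axis=1)
    down = (lr <= -theta_r).sum(axis=1)
    return int(max(up.max(), down.max()))
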