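"""Step 2: exhaustive label-permutation null and the (t, j) FDR matrix.

The null hypothesis for a probe is that the samples it flags are equally
distributed between the two groups.  Group labels are reassigned over every
C(n_control + n_treated, n_treated) partition (252 for a 5-vs-5 design; a
uniform sample of partitions is taken above ``max_exhaustive``), and for
each partition the entire step-1 computation — control-pool mean,
log-ratios, p-values, flags, directional counts — is redone from scratch
against the permuted "control" pool.

Each probe lands in a grid cell (t, j): j flagged samples in the (permuted)
treated group in the dominant direction, t = j plus the matching-direction
control count.  The FDR for a cell is the mean per-permutation count of
probes in that cell divided by the observed count, clipped to [0, 1].  A
probe is called significant when its cell FDR is at or below the cutoff
(default 0.05), the treated count strictly exceeds the matching control
count, and the probe is not non-interpretable.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import flag_counter, ratio_engine
from .datatypes import DECall, DirectionalCounts, ExpressionMatrix, FDRMatrix

MIN_RECOMMENDED_TOTAL = 10  # below this the exhaustive null is too coarse


@dataclass
class PermutationPlan:
    """A set of label partitions: which sample positions play "treated"."""

    n_control: int
    n_treated: int
    assignments: np.ndarray  # (k, n_treated) sorted sample positions
    exhaustive: bool
    seed: int
    small_group_warning: bool = False

    @property
    def n_permutations(self) -> int:
        return self.assignments.shape[0]


def make_permutation_plan(
    n_control: int,
    n_treated: int,
    max_exhaustive: int = 100_000,
    seed: int = 1,
) -> PermutationPlan:
    """Enumerate (or sample) the label partitions for the null.

    Exhaustive when C(n_control + n_treated, n_treated) <= ``max_exhaustive``
    — 252 partitions for 5 vs 5, 70 for 4 vs 4 — which necessarily includes
    the observed labelling.  Larger designs draw that many distinct
    partitions uniformly with the given seed.
    """
    if n_control < 1 or n_treated < 1:
        raise ValueError("both groups need at least one sample")
    n = n_control + n_treated
    total = math.comb(n, n_treated)
    small = n < MIN_RECOMMENDED_TOTAL
    if small:
        warnings.warn(
            f"total group size {n} < {MIN_RECOMMENDED_TOTAL}: only {total} label "
            "partitions exist, too few for an informative null",
            stacklevel=2,
        )
    if total <= max_exhaustive:
        assignments = np.array(
            list(itertools.combinations(range(n), n_treated)), dtype=np.intp
        )
        return PermutationPlan(n_control, n_treated, assignments, True, seed, small)
    rng = np.random.default_rng(seed)
    chosen: set[tuple[int, ...]] = set()
    while len(chosen) < max_exhaustive:
        draw = rng.permutation(n)[:n_treated]
        chosen.add(tuple(sorted(int(i) for i in draw)))
    assignments = np.array(sorted(chosen), dtype=np.intp)
    return PermutationPlan(n_control, n_treated, assignments, False, seed, small)


def cells_from_counts(
    S_c: np.ndarray, R_c: np.ndarray, S_t: np.ndarray, R_t: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Map directional counts to grid coordinates.

    Returns (t, j, direction, non_interpretable) with direction in
    {+1 up, -1 down, 0 none}.  Ties at zero treated flags sit in column
    j = 0 with t taken from the larger control count (never significant:
    the treated-majority rule requires j > t - j).
    """
    noninterp = (S_t == R_t) & (S_t > 0)
    up = S_t > R_t
    down = R_t > S_t
    j = np.where(up, S_t, np.where(down, R_t, 0))
    t = j + np.where(up, S_c, np.where(down, R_c, np.maximum(S_c, R_c)))
    direction = np.where(up, 1, np.where(down, -1, 0)).astype(np.int8)
    return t.astype(np.intp), j.astype(np.intp), direction, noninterp


def _cell_histogram(
    t: np.ndarray, j: np.ndarray, keep: np.ndarray, shape: tuple[int, int]
) -> np.ndarray:
    t_k, j_k = t[keep], j[keep]
    if t_k.size and t_k.max() >= shape[0]:
        raise ValueError(
            f"t = {int(t_k.max())} exceeds the grid bound {shape[0] - 1}; a whole "
            "group was flagged in one direction (possible only with degenerate "
            "thresholds such as theta_r = 0)"
        )
    flat = np.bincount(t_k * shape[1] + j_k, minlength=shape[0] * shape[1])
    return flat.reshape(shape).astype(float)


def _partition_cells(
    X: np.ndarray,
    ctrl_pos: np.ndarray,
    trt_pos: np.ndarray,
    theta_r: float,
    theta_p: float,
    p_mode: str,
    pvalues: Optional[np.ndarray],
    sd_floor: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Full step-1 recomputation for one labelling; returns (t, j, keep)."""
    lr, usable = ratio_engine.pool_log_ratios(X, ctrl_pos)
    if p_mode == "disabled":
        p = np.zeros_like(lr)
    elif p_mode == "passthrough":
        assert pvalues is not None
        p = pvalues
    else:
        p = ratio_engine.control_spread_pvalues(lr, ctrl_pos, sd_floor=sd_floor)
    flags = flag_counter.flag_array(lr, p, theta_r, theta_p, usable=usable)
    S_c, R_c, S_t, R_t = flag_counter.count_array(flags, ctrl_pos, trt_pos)
    t, j, _, noninterp = cells_from_counts(S_c, R_c, S_t, R_t)
    return t, j, usable & ~noninterp


def grid_shape(n_control: int, n_treated: int) -> tuple[int, int]:
    """Rows t in 0 .. n_total - 1, columns j in 0 .. n_treated.

    The pool-mean constraint keeps the matching-direction control count at
    or below n_control - 1, so t never reaches n_control + n_treated with
    sane thresholds.
    """
    return (n_control + n_treated, n_treated + 1)


def observed_cell_counts(
    counts: DirectionalCounts, shape: Optional[tuple[int, int]] = None
) -> np.ndarray:
    """Histogram of probes over (t, j) cells, excluding non-interpretable
    and unusable probes."""
    shape = shape or grid_shape(counts.n_control, counts.n_treated)
    t, j, _, noninterp = cells_from_counts(
        counts.S_control, counts.R_control, counts.S_treated, counts.R_treated
    )
    return _cell_histogram(t, j, counts.usable & ~noninterp, shape)


def null_cell_counts(
    expr: ExpressionMatrix,
    plan: PermutationPlan,
    theta_r: float = flag_counter.DEFAULT_THETA_R,
    theta_p: float = flag_counter.DEFAULT_THETA_P,
    p_mode: str = "control-spread",
    pvalues: Optional[np.ndarray] = None,
    sd_floor: float = 1e-3,
    null_mode: str = "recompute",
) -> np.ndarray:
    """Mean per-permutation (t, j) cell counts under label reassignment.

    ``recompute`` (default) redoes the whole of step 1 against each permuted
    control pool.  ``label-shuffle`` keeps the observed flags fixed and only
    re-partitions them into groups — a cheaper, purely combinatorial null
    provided for comparison.
    """
    if null_mode not in ("recompute", "label-shuffle"):
        raise ValueError(f"unknown null mode {null_mode!r}")
    if plan.n_control + plan.n_treated != expr.n_samples:
        raise ValueError("plan group sizes do not cover the matrix samples")
    X = expr.intensities
    n = expr.n_samples
    shape = grid_shape(plan.n_control, plan.n_treated)
    hist = np.zeros(shape)
    all_pos = np.arange(n)
    if null_mode == "label-shuffle":
        ratios = ratio_engine.ratio_table(
            expr, p_mode=p_mode, pvalues=pvalues, sd_floor=sd_floor
        )
        fixed_flags = flag_counter.flag_array(
            ratios.log_ratios, ratios.p_values, theta_r, theta_p, usable=ratios.usable
        )
    for trt_pos in plan.assignments:
        ctrl_pos = np.setdiff1d(all_pos, trt_pos, assume_unique=True)
        if null_mode == "recompute":
            t, j, keep = _partition_cells(
                X, ctrl_pos, trt_pos, theta_r, theta_p, p_mode, pvalues, sd_floor
            )
        else:
            S_c, R_c, S_t, R_t = flag_counter.count_array(
                fixed_flags, ctrl_pos, trt_pos
            )
            t, j, _, noninterp = cells_from_counts(S_c, R_c, S_t, R_t)
            keep = ratios.usable & ~noninterp
        hist += _cell_histogram(t, j, keep, shape)
    return hist / plan.n_permutations


def fdr_matrix(observed_counts: np.ndarray, null_counts: np.ndarray) -> FDRMatrix:
    """FDR per cell: mean null count over observed count, clipped to [0, 1].

    Cells with no observed probes get FDR 1 (nothing to call); occupied
    cells never reached under permutation get FDR 0.
    """
    if observed_counts.shape != null_counts.shape:
        raise ValueError("observed and null grids have different shapes")
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(
            observed_counts > 0,
            np.clip(null_counts / np.maximum(observed_counts, 1e-300), 0.0, 1.0),
            1.0,
        )
    shape = observed_counts.shape
    return FDRMatrix(
        fdr=fdr,
        observed_counts=observed_counts.astype(float),
        null_counts=null_counts.astype(float),
        n_control=shape[0] - (shape[1] - 1),
        n_treated=shape[1] - 1,
    )


def representative_fold(expr_or_ratios, treated_idx=None) -> np.ndarray:
    """Signed linear fold per probe from the mean treated log-ratio.

    Positive values mean up-regulation (e.g. 2.0 = 2-fold up), negative
    down (-1.5 = 1.5-fold down), matching the usual reporting convention
    for averaged fold changes across a treatment group.
    """
    ratios = expr_or_ratios
    if isinstance(ratios, ExpressionMatrix):
        ratios = ratio_engine.compute_log_ratios(ratios)
    trt = ratios.treated_idx if treated_idx is None else treated_idx
    m = ratios.log_ratios[:, trt].mean(axis=1)
    fold = np.where(m >= 0, 10.0 ** m, -(10.0 ** (-m)))
    fold[~ratios.usable] = np.nan
    return fold


def call_significant(
    counts: DirectionalCounts,
    fdrm: FDRMatrix,
    fold_change: np.ndarray,
    q: float = 0.05,
) -> list[DECall]:
    """Per-probe verdicts at FDR cutoff ``q``.

    significant requires fdr[t, j] <= q, a strict treated majority in the
    dominant direction (j > t - j), and an interpretable probe.
    """
    t, j, direction, noninterp = cells_from_counts(
        counts.S_control, counts.R_control, counts.S_treated, counts.R_treated
    )
    if t.size and t.max() > fdrm.t_max:
        raise RuntimeError("observed (t, j) outside the FDR grid — invariant breach")
    dir_name = {1: "up", -1: "down", 0: "none"}
    calls: list[DECall] = []
    for i, pid in enumerate(counts.probe_ids):
        ni = bool(noninterp[i])
        usable = bool(counts.usable[i])
        fdr = float("nan") if (ni or not usable) else float(fdrm.fdr[t[i], j[i]])
        sig = (
            usable
            and not ni
            and j[i] > t[i] - j[i]
            and fdr <= q
        )
        calls.append(
            DECall(
                probe_id=pid,
                direction=dir_name[int(direction[i])] if usable and not ni else "none",
                S_treated=int(counts.S_treated[i]),
                R_treated=int(counts.R_treated[i]),
                S_control=int(counts.S_control[i]),
                R_control=int(counts.R_control[i]),
                t=int(t[i]),
                j=int(j[i]),
                fdr=fdr,
                significant=bool(sig),
                non_interpretable=ni,
                fold_change=float(fold_change[i]),
            )
        )
    return calls


def differential_expression(
    expr: ExpressionMatrix,
    theta_r: float = flag_counter.DEFAULT_THETA_R,
    theta_p: float = flag_counter.DEFAULT_THETA_P,
    p_mode: str = "control-spread",
    pvalues: Optional[np.ndarray] = None,
    sd_floor: float = 1e-3,
    q: float = 0.05,
    max_perms: int = 100_000,
    seed: int = 1,
    null_mode: str = "recompute",
) -> tuple[list[DECall], FDRMatrix]:
    """The full two-step caller: flagging, counting, permutation FDR, calls."""
    ratios = ratio_engine.ratio_table(
        expr, p_mode=p_mode, pvalues=pvalues, sd_floor=sd_floor
    )
    flags = flag_counter.flag_samples(ratios, theta_r=theta_r, theta_p=theta_p)
    counts = flag_counter.count_directional(flags)
    observed = observed_cell_counts(counts)
    plan = make_permutation_plan(
        counts.n_control, counts.n_treated, max_exhaustive=max_perms, seed=seed
    )
    null = null_cell_counts(
        expr,
        plan,
        theta_r=theta_r,
        theta_p=theta_p,
        p_mode=p_mode,
        pvalues=pvalues,
        sd_floor=sd_floor,
        null_mode=null_mode,
    )
    fdrm = fdr_matrix(observed, null)
    fold = representative_fold(ratios)
    calls = call_significant(counts, fdrm, fold, q=q)
    return calls, fdrm
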