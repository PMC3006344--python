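"""Core containers shared across the pipeline.

The analysis operates on a genes x samples intensity matrix with a two-group
(control / treated) design.  Every downstream object keeps the probe and
sample orderings of the input so that results can be joined back to it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

CONTROL = "control"
TREATED = "treated"
GROUPS = (CONTROL, TREATED)


def _group_indices(sample_ids: list[str], group_of: dict[str, str]) -> tuple[np.ndarray, np.ndarray]:
    ctrl = [i for i, s in enumerate(sample_ids) if group_of[s] == CONTROL]
    trt = [i for i, s in enumerate(sample_ids) if group_of[s] == TREATED]
    return np.asarray(ctrl, dtype=np.intp), np.asarray(trt, dtype=np.intp)


@dataclass
class ExpressionMatrix:
    """Probes x samples linear-scale intensities with a control/treated map.

    Intensities are arbitrary linear units (e.g. summarized array signal);
    log transforms happen downstream.  Validation enforces unique ids,
    finite non-negative values and the presence of both groups.
    """

    probe_ids: list[str]
    sample_ids: list[str]
    intensities: np.ndarray
    group_of: dict[str, str]

    def __post_init__(self) -> None:
        self.probe_ids = list(self.probe_ids)
        self.sample_ids = list(self.sample_ids)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise ValueError("duplicate probe ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if self.intensities.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValueError(
                f"intensity matrix shape {self.intensities.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("non-finite intensity values")
        if np.any(self.intensities < 0):
            raise ValueError("negative intensity values")
        missing = [s for s in self.sample_ids if s not in self.group_of]
        if missing:
            raise KeyError(f"samples missing from group map: {missing}")
        bad = {s: g for s, g in self.group_of.items() if g not in GROUPS}
        if bad:
            raise ValueError(f"unknown group labels: {bad}")
        ctrl, trt = _group_indices(self.sample_ids, self.group_of)
        if ctrl.size == 0 or trt.size == 0:
            raise ValueError("need at least one control and one treated sample")

    @property
    def control_idx(self) -> np.ndarray:
        return _group_indices(self.sample_ids, self.group_of)[0]

    @property
    def treated_idx(self) -> np.ndarray:
        return _group_indices(self.sample_ids, self.group_of)[1]

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


@dataclass
class RatioTable:
    """Per-sample log10 ratios to the averaged control pool.

    ``usable`` marks probes whose control-pool mean is positive; unusable
    probes carry zero log-ratios and are excluded downstream.  ``p_values``
    holds per-measurement platform p-values once attached.
    """

    probe_ids: list[str]
    sample_ids: list[str]
    log_ratios: np.ndarray
    group_of: dict[str, str]
    usable: np.ndarray
    p_values: Optional[np.ndarray] = None

    @property
    def control_idx(self) -> np.ndarray:
        return _group_indices(self.sample_ids, self.group_of)[0]

    @property
    def treated_idx(self) -> np.ndarray:
        return _group_indices(self.sample_ids, self.group_of)[1]

    def with_pvalues(self, p: np.ndarray) -> "RatioTable":
        p = np.asarray(p, dtype=float)
        if p.shape != self.log_ratios.shape:
            raise ValueError("p-value matrix shape does not match log-ratio matrix")
        if np.any((p < 0) | (p > 1)):
            raise ValueError("p-values outside [0, 1]")
        return replace(self, p_values=p)


@dataclass
class FlagMatrix:
    """Per-probe per-sample calls in {+1, -1, 0} at fixed thresholds."""

    probe_ids: list[str]
    sample_ids: list[str]
    flags: np.ndarray  # int8, +1 up / -1 down / 0 unchanged
    theta_r: float  # |log10 ratio| cutoff
    theta_p: float  # platform p-value cutoff
    group_of: dict[str, str]
    usable: np.ndarray

    @property
    def control_idx(self) -> np.ndarray:
        return _group_indices(self.sample_ids, self.group_of)[0]

    @property
    def treated_idx(self) -> np.ndarray:
        return _group_indices(self.sample_ids, self.group_of)[1]


@dataclass
class DirectionalCounts:
    """Per-probe counts of up (S) and down (R) flagged samples per group."""

    probe_ids: list[str]
    S_control: np.ndarray
    R_control: np.ndarray
    S_treated: np.ndarray
    R_treated: np.ndarray
    n_control: int
    n_treated: int
    usable: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.usable is None:
            self.usable = np.ones(len(self.probe_ids), dtype=bool)
        for arr in (self.S_control, self.R_control, self.S_treated, self.R_treated):
            if np.any(arr < 0):
                raise ValueError("negative count")
        if np.any(self.S_control + self.R_control > self.n_control):
            raise ValueError("control counts exceed group size")
        if np.any(self.S_treated + self.R_treated > self.n_treated):
            raise ValueError("treated counts exceed group size")


@dataclass
class FDRMatrix:
    """False-discovery-rate grid over (t, j) cells.

    ``t`` indexes the total number of flagged samples in the dominant
    direction across both groups (rows, 0 .. n_samples - 1) and ``j`` the
    flagged treated samples (columns, 0 .. n_treated).  ``fdr[t, j]`` is the
    mean per-permutation cell count divided by the observed cell count,
    clipped to [0, 1]; empty observed cells carry 1 and cells never reached
    under permutation carry 0.
    """

    fdr: np.ndarray
    observed_counts: np.ndarray
    null_counts: np.ndarray
    n_control: int
    n_treated: int

    @property
    def t_max(self) -> int:
        return self.fdr.shape[0] - 1

    @property
    def j_max(self) -> int:
        return self.fdr.shape[1] - 1

    def monotone(self) -> "FDRMatrix":
        """Variant with FDR enforced non-increasing in j at fixed t.

        Per-cell estimates can be non-monotone at sparse cells; this takes a
        running minimum from the right within each row.
        """
        f = np.minimum.accumulate(self.fdr, axis=1)
        return replace(self, fdr=f)


@dataclass
class DECall:
    """Per-probe differential-expression verdict."""

    probe_id: str
    direction: str  # "up" | "down" | "none"
    S_treated: int
    R_treated: int
    S_control: int
    R_control: int
    t: int
    j: int
    fdr: float
    significant: bool
    non_interpretable: bool
    fold_change: float  # signed linear fold (negative = down)
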