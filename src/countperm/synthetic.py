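"""Synthetic expression matrices with known ground truth.

Emulates a small two-group array study (default 5 vehicle vs 5 treated):
per-probe baselines on the log10-intensity scale, multiplicative Gaussian
noise, a chosen fraction of truly differential probes shifting responding
treated samples by a fixed or log-uniform fold, per-(probe, sample)
treated-group non-responders, and occasional control-group outliers.  The
per-sample non-responder model lets a probe respond in, say, 3 of 5 treated
animals — the inconsistent-group behaviour the count-based caller is built
to tolerate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import CONTROL, TREATED, ExpressionMatrix


@dataclass
class SyntheticSpec:
    """Generator parameters (all scales log10 unless noted)."""

    n_probes: int = 2000
    n_control: int = 5
    n_treated: int = 5
    de_fraction: float = 0.04
    fold: float | tuple[float, float] = 2.0  # fixed, or log-uniform (low, high)
    direction_mix: float = 0.5  # fraction of DE probes that go up
    nonresponder_fraction: float = 0.0  # per (DE probe, treated sample)
    outlier_fraction: float = 0.0  # per (probe, control sample)
    outlier_fold: float = 3.0
    noise_sd: float = 0.05
    baseline_log10_mean: float = 2.5
    baseline_log10_sd: float = 0.5
    seed: int = 1

    def __post_init__(self) -> None:
        for name in ("de_fraction", "direction_mix", "nonresponder_fraction", "outlier_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_control < 1 or self.n_treated < 1:
            raise ValueError("both groups need at least one sample")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_probes < 1:
            raise ValueError("need at least one probe")
        fold = self.fold
        if isinstance(fold, tuple):
            if fold[0] <= 1 or fold[1] < fold[0]:
                raise ValueError("fold range must satisfy 1 < low <= high")
        elif fold <= 1:
            raise ValueError("fold must exceed 1")
        if self.outlier_fold <= 1:
            raise ValueError("outlier_fold must exceed 1")


@dataclass
class GroundTruth:
    """Per-probe truth: DE status, direction, fold and responder mask."""

    probe_ids: list[str]
    is_de: np.ndarray  # bool
    true_direction: np.ndarray  # +1 / -1 / 0
    true_fold: np.ndarray  # linear fold (1.0 for null probes)
    responder_mask: np.ndarray  # (n_probes, n_treated) bool
    outlier_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "probe_id": self.probe_ids,
                "is_de": self.is_de.astype(int),
                "true_direction": self.true_direction,
                "true_fold": self.true_fold,
            }
        )
        for k in range(self.responder_mask.shape[1]):
            df[f"responder_T{k + 1}"] = self.responder_mask[:, k].astype(int)
        return df

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GroundTruth":
        df = pd.read_csv(path, sep="\t")
        resp_cols = [c for c in df.columns if c.startswith("responder_T")]
        return cls(
            probe_ids=[str(p) for p in df.probe_id],
            is_de=df.is_de.to_numpy(dtype=bool),
            true_direction=df.true_direction.to_numpy(dtype=int),
            true_fold=df.true_fold.to_numpy(dtype=float),
            responder_mask=df[resp_cols].to_numpy(dtype=bool),
        )


def generate_dataset(spec: SyntheticSpec) -> tuple[ExpressionMatrix, GroundTruth]:
    """Draw one matrix + ground truth, fully reproducible from the seed."""
    rng = np.random.default_rng(spec.seed)
    p, nc, nt = spec.n_probes, spec.n_control, spec.n_treated
    n = nc + nt

    baseline = rng.normal(spec.baseline_log10_mean, spec.baseline_log10_sd, size=p)
    log10 = baseline[:, None] + rng.normal(0.0, spec.noise_sd, size=(p, n))

    n_de = int(round(spec.de_fraction * p))
    is_de = np.zeros(p, dtype=bool)
    is_de[rng.choice(p, size=n_de, replace=False)] = True

    direction = np.zeros(p, dtype=int)
    direction[is_de] = np.where(rng.random(n_de) < spec.direction_mix, 1, -1)

    fold = np.ones(p)
    if isinstance(spec.fold, tuple):
        lo, hi = np.log10(spec.fold[0]), np.log10(spec.fold[1])
        fold[is_de] = 10.0 ** rng.uniform(lo, hi, size=n_de)
    else:
        fold[is_de] = spec.fold

    responder = np.zeros((p, nt), dtype=bool)
    responder[is_de] = rng.random((n_de, nt)) >= spec.nonresponder_fraction
    shift = direction[:, None] * np.log10(fold)[:, None] * responder
    log10[:, nc:] += shift

    outlier = rng.random((p, nc)) < spec.outlier_fraction
    out_sign = np.where(rng.random((p, nc)) < 0.5, 1.0, -1.0)
    log10[:, :nc] += outlier * out_sign * np.log10(spec.outlier_fold)

    probe_ids = [f"probe_{i + 1:05d}" for i in range(p)]
    sample_ids = [f"C{k + 1}" for k in range(nc)] + [f"T{k + 1}" for k in range(nt)]
    group_of = {s: CONTROL for s in sample_ids[:nc]}
    group_of.update({s: TREATED for s in sample_ids[nc:]})
    expr = ExpressionMatrix(
        probe_ids=probe_ids,
        sample_ids=sample_ids,
        intensities=10.0 ** log10,
        group_of=group_of,
    )
    truth = GroundTruth(
        probe_ids=probe_ids,
        is_de=is_de,
        true_direction=direction,
        true_fold=fold,
        responder_mask=responder,
        outlier_mask=outlier,
    )
    return expr, truth


def generate_null(
    n_probes: int = 2000,
    n_control: int = 5,
    n_treated: int = 5,
    noise_sd: float = 0.05,
    seed: int = 1,
) -> ExpressionMatrix:
    """Pure-null matrix (no DE probes) for calibration suites."""
    spec = SyntheticSpec(
        n_probes=n_probes,
        n_control=n_control,
        n_treated=n_treated,
        de_fraction=0.0,
        noise_sd=noise_sd,
        seed=seed,
    )
    return generate_dataset(spec)[0]
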