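"""Human-readable summaries and method-comparison set logic."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import DECall, FDRMatrix
from .sam import SAMResult


def fdr_matrix_frame(fdrm: FDRMatrix) -> pd.DataFrame:
    """FDR grid as a table with rows t and columns j."""
    return pd.DataFrame(
        fdrm.fdr,
        index=pd.Index(range(fdrm.fdr.shape[0]), name="t"),
        columns=[f"j={j}" for j in range(fdrm.fdr.shape[1])],
    )


def summarize_calls(calls: list[DECall]) -> dict[str, int]:
    n_sig = sum(c.significant for c in calls)
    return {
        "n_probes": len(calls),
        "n_significant": n_sig,
        "n_up": sum(c.significant and c.direction == "up" for c in calls),
        "n_down": sum(c.significant and c.direction == "down" for c in calls),
        "n_non_interpretable": sum(c.non_interpretable for c in calls),
        "n_excluded": sum(np.isnan(c.fold_change) for c in calls),
    }


def summary_text(calls: list[DECall]) -> str:
    s = summarize_calls(calls)
    return (
        f"probes: {s['n_probes']}\n"
        f"significant: {s['n_significant']} (up {s['n_up']}, down {s['n_down']})\n"
        f"non-interpretable (treated up = down > 0): {s['n_non_interpretable']}\n"
        f"excluded (zero control-pool mean): {s['n_excluded']}"
    )


@dataclass
class MethodComparison:
    n_both: int
    n_count_only: int
    n_sam_only: int
    below_cutoff_fraction: float  # of SAM-only calls, fraction under the fold cutoff
    count_only: set[str]
    sam_only: set[str]
    both: set[str]

    def summary(self) -> str:
        return (
            f"called by both methods: {self.n_both}\n"
            f"count-method only: {self.n_count_only}\n"
            f"SAM only: {self.n_sam_only}\n"
            f"SAM-only calls below the fold cutoff: "
            f"{100 * self.below_cutoff_fraction:.1f}%"
        )


def compare_methods(
    calls_count: list[DECall],
    sam_result: SAMResult,
    fold_cutoff: float = 1.25,
) -> MethodComparison:
    """Overlap of the two call sets plus the sub-cutoff diagnostic.

    The diagnostic is the fraction of SAM-only significant probes whose
    representative |fold change| (from the count pipeline) stays below the
    fold cutoff — the statistically-but-not-biologically significant class.
    """
    count_by_id = {c.probe_id: c for c in calls_count}
    sam_universe = set(sam_result.probe_ids)
    if set(count_by_id) != sam_universe:
        warnings.warn(
            "probe universes differ between the two methods; using the "
            "intersection",
            stacklevel=2,
        )
    universe = set(count_by_id) & sam_universe
    sig_count = {p for p, c in count_by_id.items() if c.significant and p in universe}
    sig_sam = sam_result.significant_probes & universe
    both = sig_count & sig_sam
    sam_only = sig_sam - sig_count
    count_only = sig_count - sig_sam
    if sam_only:
        below = sum(
            1
            for p in sam_only
            if not np.isnan(count_by_id[p].fold_change)
            and abs(count_by_id[p].fold_change) < fold_cutoff
        )
        frac = below / len(sam_only)
    else:
        frac = 0.0
    return MethodComparison(
        n_both=len(both),
        n_count_only=len(count_only),
        n_sam_only=len(sam_only),
        below_cutoff_fraction=frac,
        count_only=count_only,
        sam_only=sam_only,
        both=both,
    )
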