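"""Concordance of DE calls between two experiments (e.g. WT vs knockout).

Each probe significant in at least one experiment is classified as changed
in A only, in B only, concordant (significant in both, same direction) or
discordant (significant in both, opposite directions).  Concordant probes
are the model-independent response; discordant probes are reported as their
own class and excluded from the concordant fraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .datatypes import DECall

CATEGORIES = ("A_only", "B_only", "concordant", "discordant", "neither")


@dataclass
class ConcordanceReport:
    category_of: dict[str, str]  # probes significant in >= 1 experiment
    counts: dict[str, int]
    n_significant_a: int
    n_significant_b: int
    fractions_a: dict[str, float] = field(default_factory=dict)
    fractions_b: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.category_of.items()), columns=["probe_id", "category"]
        )

    def summary(self) -> str:
        lines = [
            f"significant in A: {self.n_significant_a}",
            f"significant in B: {self.n_significant_b}",
        ]
        for cat in ("A_only", "B_only", "concordant", "discordant"):
            lines.append(f"{cat}: {self.counts.get(cat, 0)}")
        for cat, frac in self.fractions_a.items():
            lines.append(f"{cat} / significant-in-A: {100 * frac:.1f}%")
        for cat, frac in self.fractions_b.items():
            lines.append(f"{cat} / significant-in-B: {100 * frac:.1f}%")
        return "\n".join(lines)


def classify_concordance(
    calls_a: list[DECall], calls_b: list[DECall]
) -> ConcordanceReport:
    """Classify the union of significant probes from two call lists.

    Probes present in only one experiment's universe are treated as not
    significant in the other (with a warning).
    """
    a = {c.probe_id: c for c in calls_a}
    b = {c.probe_id: c for c in calls_b}
    only_one = set(a) ^ set(b)
    if only_one:
        warnings.warn(
            f"{len(only_one)} probes present in only one experiment's universe; "
            "treated as not significant there",
            stacklevel=2,
        )
    sig_a = {p for p, c in a.items() if c.significant}
    sig_b = {p for p, c in b.items() if c.significant}
    category_of: dict[str, str] = {}
    for p in sig_a | sig_b:
        in_a, in_b = p in sig_a, p in sig_b
        if in_a and in_b:
            same = a[p].direction == b[p].direction
            category_of[p] = "concordant" if same else "discordant"
        elif in_a:
            category_of[p] = "A_only"
        else:
            category_of[p] = "B_only"
    counts = {cat: 0 for cat in CATEGORIES[:4]}
    for cat in category_of.values():
        counts[cat] += 1
    frac_a = (
        {
            cat: counts[cat] / len(sig_a)
            for cat in ("A_only", "concordant", "discordant")
        }
        if sig_a
        else {}
    )
    frac_b = (
        {
            cat: counts[cat] / len(sig_b)
            for cat in ("B_only", "concordant", "discordant")
        }
        if sig_b
        else {}
    )
    return ConcordanceReport(
        category_of=category_of,
        counts=counts,
        n_significant_a=len(sig_a),
        n_significant_b=len(sig_b),
        fractions_a=frac_a,
        fractions_b=frac_b,
    )
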