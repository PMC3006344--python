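"""Fisher's-exact (hypergeometric) over-representation of gene sets.

One-sided upper-tail test per set: the probability of drawing at least the
observed overlap when sampling the DE list's size from the universe.  No
multiple-testing correction by default (a Benjamini-Hochberg option is
available), mirroring the common pathway-mapping convention of calling
sets with raw p <= 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
from scipy import stats

from .data_io import GeneSetCollection


@dataclass
class EnrichmentResult:
    set_name: str
    overlap: int
    set_size: int
    list_size: int
    universe_size: int
    p_value: float
    significant: bool
    p_adjusted: Optional[float] = None


def _bh_adjust(pvals: np.ndarray) -> np.ndarray:
    n = pvals.size
    order = np.argsort(pvals)
    ranked = pvals[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def fisher_enrichment(
    de_genes: Iterable[str],
    collection: GeneSetCollection,
    alpha: float = 0.05,
    universe: Optional[set[str]] = None,
    adjust: bool = False,
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric p per gene set, sorted by p.

    The universe defaults to the collection's own universe, else the union
    of all set members; the DE list is intersected with it.  When
    ``adjust`` is set, significance is judged on Benjamini-Hochberg
    adjusted p-values instead of raw ones.
    """
    if universe is None:
        universe = collection.universe
    if universe is None:
        universe = set().union(*collection.sets.values())
    de = set(de_genes) & universe
    n_universe, n_list = len(universe), len(de)
    results: list[EnrichmentResult] = []
    for name, members in collection.sets.items():
        members_in = members & universe
        if not members_in:
            warnings.warn(
                f"gene set {name!r} is disjoint from the universe; skipped",
                stacklevel=2,
            )
            continue
        k = len(de & members_in)
        if n_list == 0:
            p = 1.0
        else:
            # P(X >= k), X ~ Hypergeom(universe, set, draws = list size)
            p = float(stats.hypergeom.sf(k - 1, n_universe, len(members_in), n_list))
            p = min(max(p, 0.0), 1.0)
        results.append(
            EnrichmentResult(
                set_name=name,
                overlap=k,
                set_size=len(members_in),
                list_size=n_list,
                universe_size=n_universe,
                p_value=p,
                significant=False,
            )
        )
    results.sort(key=lambda r: (r.p_value, r.set_name))
    pvals = np.array([r.p_value for r in results])
    if adjust and results:
        padj = _bh_adjust(pvals)
        for r, pa in zip(results, padj):
            r.p_adjusted = float(pa)
            r.significant = pa <= alpha
    else:
        for r in results:
            r.significant = r.p_value <= alpha
    return results
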