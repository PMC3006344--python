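"""Reading and writing the pipeline's tab-delimited file formats.

All files are TSV, UTF-8, '.' decimal separator, no quoting:

* expression matrix — header row of sample ids, first column probe ids;
* group map — two columns, sample id and ``control``/``treated``;
* probe annotation — two columns, probe id and gene symbol;
* gene sets — GMT-like: set name, description, then member symbols;
* results — one row per probe with a stable column order.

Probe-level calls are collapsed to gene level by keeping, per gene, the
probe with the largest absolute fold change (ties broken by input order and
logged); probes without an annotation are dropped from the gene-level
output and their number reported.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .datatypes import CONTROL, GROUPS, TREATED, DECall, ExpressionMatrix, FDRMatrix

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "probe_id",
    "direction",
    "S_treated",
    "R_treated",
    "S_control",
    "R_control",
    "t",
    "j",
    "fdr",
    "significant",
    "non_interpretable",
    "fold_change",
]


@dataclass
class ProbeAnnotation:
    """Many-to-one map from probe ids to gene symbols."""

    gene_of: dict[str, str]

    def __contains__(self, probe_id: str) -> bool:
        return probe_id in self.gene_of

    def __getitem__(self, probe_id: str) -> str:
        return self.gene_of[probe_id]


@dataclass
class GeneSetCollection:
    """Named gene sets with an optional universe restriction."""

    sets: dict[str, set[str]]
    universe: Optional[set[str]] = None
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        empty = [name for name, members in self.sets.items() if not members]
        if empty:
            raise ValueError(f"empty gene sets: {empty}")
        if self.universe is not None:
            stray = {
                name: members - self.universe
                for name, members in self.sets.items()
                if members - self.universe
            }
            if stray:
                raise ValueError(f"set members outside the universe: {stray}")


def read_groups(path: str | Path) -> dict[str, str]:
    """Sample -> group map from a two-column TSV (no header required)."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: group map needs two tab-separated columns")
    # tolerate an optional header line
    first = df.iloc[0, 1].strip().lower()
    if first not in GROUPS:
        df = df.iloc[1:]
    group_of: dict[str, str] = {}
    for _, row in df.iterrows():
        sample, group = row.iloc[0].strip(), row.iloc[1].strip().lower()
        if sample in group_of:
            raise ValueError(f"{path}: duplicate sample id {sample!r}")
        if group not in GROUPS:
            raise ValueError(
                f"{path}: unknown group {group!r} for sample {sample!r}; "
                f"expected one of {GROUPS}"
            )
        group_of[sample] = group
    return group_of


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Tab-delimited numeric matrix with probe-id index and sample-id header."""
    # pandas silently mangles repeated header names, so check the raw header
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    sample_cols = header[1:]
    if len(set(sample_cols)) != len(sample_cols):
        dups = sorted({c for c in sample_cols if sample_cols.count(c) > 1})
        raise ValueError(f"{path}: duplicate sample ids in header: {dups}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate probe ids {dups}")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-numeric intensity value ({exc})") from exc
    if not np.all(np.isfinite(values)):
        raise ValueError(f"{path}: non-finite intensity values")
    return df


def read_expression(matrix_path: str | Path, groups_path: str | Path) -> ExpressionMatrix:
    """Validated expression matrix + group map; preserves file ordering."""
    df = read_matrix(matrix_path)
    group_of = read_groups(groups_path)
    missing = [s for s in df.columns if s not in group_of]
    if missing:
        raise KeyError(
            f"samples in {matrix_path} missing from group map {groups_path}: {missing}"
        )
    values = df.to_numpy(dtype=float)
    if np.any(values < 0):
        raise ValueError(f"{matrix_path}: negative intensity values")
    return ExpressionMatrix(
        probe_ids=[str(p) for p in df.index],
        sample_ids=[str(s) for s in df.columns],
        intensities=values,
        group_of={s: group_of[s] for s in df.columns},
    )


def write_expression(expr: ExpressionMatrix, matrix_path: str | Path, groups_path: str | Path | None = None) -> None:
    df = pd.DataFrame(expr.intensities, index=expr.probe_ids, columns=expr.sample_ids)
    df.index.name = "probe_id"
    df.to_csv(matrix_path, sep="\t")
    if groups_path is not None:
        with open(groups_path, "w") as fh:
            fh.write("sample_id\tgroup\n")
            for s in expr.sample_ids:
                fh.write(f"{s}\t{expr.group_of[s]}\n")


def read_pvalue_matrix(path: str | Path, expr: ExpressionMatrix) -> np.ndarray:
    """External platform p-value matrix aligned to an expression matrix."""
    df = read_matrix(path)
    if list(df.index) != expr.probe_ids or list(df.columns) != expr.sample_ids:
        raise ValueError(
            f"{path}: p-value matrix rows/columns do not match the expression matrix"
        )
    p = df.to_numpy(dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError(f"{path}: p-values outside [0, 1]")
    return p


def read_annotation(path: str | Path) -> ProbeAnnotation:
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: annotation needs two tab-separated columns")
    if df.iloc[0, 0].strip().lower() in ("probe_id", "probe", "probeset"):
        df = df.iloc[1:]
    gene_of: dict[str, str] = {}
    for _, row in df.iterrows():
        probe, gene = row.iloc[0].strip(), row.iloc[1].strip()
        if probe in gene_of:
            raise ValueError(f"{path}: probe {probe!r} annotated more than once")
        if gene:
            gene_of[probe] = gene
    return ProbeAnnotation(gene_of)


def read_gene_sets(path: str | Path, universe: Optional[set[str]] = None) -> GeneSetCollection:
    """GMT-like format: name TAB description TAB member1 TAB member2 ..."""
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{line_no}: expected name, description and members"
                )
            name, desc, members = parts[0], parts[1], [m for m in parts[2:] if m]
            if name in sets:
                raise ValueError(f"{path}:{line_no}: duplicate set name {name!r}")
            sets[name] = set(members)
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, universe=universe, descriptions=descriptions)


def read_gene_list(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip() and not line.startswith("#")]


def calls_to_frame(calls: list[DECall]) -> pd.DataFrame:
    df = pd.DataFrame([vars(c) for c in calls])
    return df[RESULT_COLUMNS]


def frame_to_calls(df: pd.DataFrame) -> list[DECall]:
    calls = []
    for row in df.itertuples(index=False):
        calls.append(
            DECall(
                probe_id=str(row.probe_id),
                direction=str(row.direction),
                S_treated=int(row.S_treated),
                R_treated=int(row.R_treated),
                S_control=int(row.S_control),
                R_control=int(row.R_control),
                t=int(row.t),
                j=int(row.j),
                fdr=float(row.fdr),
                significant=bool(row.significant),
                non_interpretable=bool(row.non_interpretable),
                fold_change=float(row.fold_change),
            )
        )
    return calls


def write_results(calls: list[DECall], path: str | Path) -> None:
    calls_to_frame(calls).to_csv(path, sep="\t", index=False)


def read_results(path: str | Path) -> list[DECall]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: result table missing columns {missing}")
    return frame_to_calls(df)


def write_fdr_matrix(fdrm: FDRMatrix, path: str | Path) -> None:
    df = pd.DataFrame(
        fdrm.fdr,
        index=pd.Index(range(fdrm.fdr.shape[0]), name="t"),
        columns=[f"j={j}" for j in range(fdrm.fdr.shape[1])],
    )
    df.to_csv(path, sep="\t", float_format="%.6g")


def collapse_to_genes(
    calls: list[DECall], annotation: ProbeAnnotation
) -> tuple[list[DECall], int]:
    """One call per gene: the probe with the largest |fold change| wins.

    Ties keep the first probe in input order (logged).  Unannotated probes
    are dropped; the second return value is the number dropped.
    """
    best: dict[str, DECall] = {}
    n_dropped = 0
    for call in calls:
        if call.probe_id not in annotation:
            n_dropped += 1
            continue
        gene = annotation[call.probe_id]
        mag = abs(call.fold_change)
        if math.isnan(mag):
            mag = -1.0  # excluded probes lose to any measured probe
        if gene not in best:
            best[gene] = call
            continue
        incumbent = abs(best[gene].fold_change)
        if math.isnan(incumbent):
            incumbent = -1.0
        if mag > incumbent:
            best[gene] = call
        elif mag == incumbent:
            logger.info(
                "gene %s: tie on |fold change| (%.4g) between probes %s and %s; "
                "keeping the first",
                gene,
                mag,
                best[gene].probe_id,
                call.probe_id,
            )
    return list(best.values()), n_dropped
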