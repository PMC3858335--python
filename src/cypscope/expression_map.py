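"""Tissue expression body map: probe aggregation, z-scores, fold calls.

Probe-level intensity matrices are collapsed to genes by arithmetic mean,
standardised per gene across a baseline tissue set (relative expression
z-scores), and screened for tissues whose intensity is at least k-fold
above or below the mean of the remaining tissues (body-map calls, default
threshold 2.0 with 3.0 as a common alternative).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "ProbeGeneMap",
    "RelativeExpression",
    "BodyMapCall",
    "Direction",
    "aggregate_probes",
    "relative_expression",
    "body_map_calls",
    "export_heatmap_table",
    "read_heatmap_table",
    "export_calls",
]


class Direction(str, Enum):
    UP = "UP"
    DOWN = "DOWN"


@dataclass
class ExpressionMatrix:
    """Probe x tissue intensity matrix (non-negative, finite)."""

    probe_ids: list[str]
    tissue_ids: list[str]
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.shape != (len(self.probe_ids), len(self.tissue_ids)):
            raise ValueError(
                f"intensity shape {self.intensities.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.tissue_ids)} tissues"
            )
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.intensities, index=self.probe_ids, columns=self.tissue_ids)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if df.isna().any().any():
            raise ValueError(f"matrix {path} has missing values")
        return cls(list(df.index.astype(str)), list(df.columns.astype(str)), df.to_numpy())

    def to_tsv(self, path: str | Path) -> None:
        frame = self.to_frame()
        frame.index.name = "probe_id"
        frame.to_csv(path, sep="\t")


@dataclass
class ProbeGeneMap:
    entries: dict[str, str]  # probe_id -> gene

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ProbeGeneMap":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if not {"probe_id", "gene"} <= set(df.columns):
            raise ValueError(f"probe map {path} must have columns probe_id, gene")
        if df["probe_id"].duplicated().any():
            dupes = df.loc[df["probe_id"].duplicated(), "probe_id"].tolist()
            raise ValueError(f"probes mapped to more than one gene: {dupes}")
        return cls(dict(zip(df["probe_id"], df["gene"])))

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"probe_id": list(self.entries), "gene": list(self.entries.values())}
        ).to_csv(path, sep="\t", index=False)


@dataclass
class RelativeExpression:
    """Per-gene z-scores over a baseline tissue set.

    Rows with zero baseline variance are flagged degenerate and set to
    all-zero rather than dividing by zero.
    """

    z: pd.DataFrame                 # gene x tissue
    baseline_stats: pd.DataFrame    # gene -> mean, sd
    degenerate: pd.Series           # gene -> bool
    baseline: list[str]


@dataclass(frozen=True)
class BodyMapCall:
    gene: str
    tissue: str
    fold: float
    direction: Direction
    threshold_used: float

    def __post_init__(self) -> None:
        if self.direction is Direction.UP and self.fold < self.threshold_used:
            raise ValueError("UP call below threshold")
        if self.direction is Direction.DOWN and self.fold > 1.0 / self.threshold_used:
            raise ValueError("DOWN call above 1/threshold")


def aggregate_probes(matrix: ExpressionMatrix, probe_map: ProbeGeneMap) -> pd.DataFrame:
    """Collapse probes to genes by arithmetic mean per tissue.

    Probes missing from the map are excluded with a warning; an empty
    intersection is an error.
    """
    frame = matrix.to_frame()
    unmapped = [p for p in matrix.probe_ids if p not in probe_map.entries]
    if unmapped:
        logger.warning("%d unmapped probes excluded: %s...", len(unmapped), unmapped[:5])
    mapped = frame.loc[[p for p in matrix.probe_ids if p in probe_map.entries]]
    if mapped.empty:
        raise ValueError("no probes could be mapped to genes")
    genes = pd.Series({p: probe_map.entries[p] for p in mapped.index})
    out = mapped.groupby(genes).mean()
    out.index.name = "gene"
    return out


def relative_expression(
    gene_matrix: pd.DataFrame,
    baseline: Sequence[str] | None = None,
) -> RelativeExpression:
    """z[g, t] = (x[g, t] - mean_g) / sd_g with stats over the baseline tissues.

    The baseline defaults to all tissues; sd uses the n-1 denominator.
    """
    baseline = list(gene_matrix.columns) if baseline is None else list(baseline)
    missing = [t for t in baseline if t not in gene_matrix.columns]
    if missing:
        raise ValueError(f"baseline tissues not in matrix: {missing}")
    if len(baseline) < 2:
        raise ValueError("baseline must contain at least 2 tissues")
    base = gene_matrix[baseline]
    mean = base.mean(axis=1)
    sd = base.std(axis=1, ddof=1)
    degenerate = sd == 0
    safe_sd = sd.mask(degenerate, 1.0)
    z = gene_matrix.sub(mean, axis=0).div(safe_sd, axis=0)
    z.loc[degenerate] = 0.0
    stats = pd.DataFrame({"mean": mean, "sd": sd})
    return RelativeExpression(z=z, baseline_stats=stats, degenerate=degenerate, baseline=baseline)


def body_map_calls(
    gene_matrix: pd.DataFrame,
    fold_threshold: float = 2.0,
) -> list[BodyMapCall]:
    """Flag (gene, tissue) cells k-fold above/below the mean of other tissues.

    fold = x[g, t] / mean(x[g, others]); UP when fold >= threshold, DOWN when
    fold <= 1/threshold. Cells whose other-tissue mean is zero are skipped
    with a warning; constant (degenerate) genes are skipped entirely.
    """
    if fold_threshold <= 1.0:
        raise ValueError(f"fold_threshold must be > 1, got {fold_threshold}")
    if gene_matrix.shape[1] < 2:
        raise ValueError("need at least 2 tissues for body-map calls")
    x = gene_matrix.to_numpy(dtype=float)
    n_tissues = x.shape[1]
    calls: list[BodyMapCall] = []
    row_sums = x.sum(axis=1)
    for gi, gene in enumerate(gene_matrix.index):
        if np.ptp(x[gi]) == 0:
            continue  # constant row: every fold is 1, nothing to call
        for ti, tissue in enumerate(gene_matrix.columns):
            mean_others = (row_sums[gi] - x[gi, ti]) / (n_tissues - 1)
            if mean_others == 0:
                logger.warning("zero mean of other tissues for %s/%s; call suppressed", gene, tissue)
                continue
            fold = x[gi, ti] / mean_others
            if fold >= fold_threshold:
                calls.append(BodyMapCall(str(gene), str(tissue), fold, Direction.UP, fold_threshold))
            elif fold <= 1.0 / fold_threshold:
                calls.append(BodyMapCall(str(gene), str(tissue), fold, Direction.DOWN, fold_threshold))
    return calls


def export_heatmap_table(relexp: RelativeExpression, path: str | Path) -> None:
    """Long-format TSV (gene, tissue, z, degenerate) for heat-map software."""
    long = relexp.z.stack().rename("z").reset_index()
    long.columns = ["gene", "tissue", "z"]
    long["degenerate"] = long["gene"].map(relexp.degenerate).astype(bool)
    long.to_csv(path, sep="\t", index=False)


def read_heatmap_table(path: str | Path) -> tuple[pd.DataFrame, pd.Series]:
    """Inverse of :func:`export_heatmap_table`: (z matrix, degenerate flags)."""
    long = pd.read_csv(path, sep="\t", dtype={"gene": str, "tissue": str})
    z = long.pivot(index="gene", columns="tissue", values="z")
    # restore original orderings
    z = z.loc[long["gene"].drop_duplicates(), long["tissue"].drop_duplicates()]
    z.index.name = None
    z.columns.name = None
    degenerate = long.drop_duplicates("gene").set_index("gene")["degenerate"].astype(bool)
    degenerate.index.name = None
    return z, degenerate


def export_calls(calls: Sequence[BodyMapCall], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "gene": c.gene,
                "tissue": c.tissue,
                "fold": c.fold,
                "direction": c.direction.value,
                "threshold": c.threshold_used,
            }
            for c in calls
        ],
        columns=["gene", "tissue", "fold", "direction", "threshold"],
    ).to_csv(path, sep="\t", index=False)
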