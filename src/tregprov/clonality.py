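"""Repertoire clonality statistics: expansion ratio, Gini evenness, overlap.

The clonal-expansion ratio is the proportion of cells that belong to a
clonotype containing two or more cells, among all cells analysed.  Repertoire
evenness is summarised by the population Gini coefficient of the clone-size
distribution,

    G = sum_ij |x_i - x_j| / (2 n^2 xbar),

which is 0 when every clonotype has equal abundance and approaches 1 when a
single clone dominates (exact upper bound (n-1)/n for n clonotypes).  The
companion Lorenz curve plots the cumulative proportion of cells against the
cumulative proportion of clonotypes, sorted ascending by clone size.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .repertoire import ClonotypeKey, Repertoire

__all__ = [
    "ClonalitySummary",
    "LorenzCurve",
    "OverlapResult",
    "expansion_ratio",
    "gini_coefficient",
    "lorenz_curve",
    "repertoire_overlap",
    "shared_clonotypes_across_samples",
    "summarize_repertoire",
    "aggregate_summaries",
]


class EmptyRepertoireError(ValueError):
    """A statistic was requested on an empty repertoire or size list."""


@dataclass(frozen=True, slots=True)
class ClonalitySummary:
    sample_id: str
    tissue: str
    n_cells: int
    n_clonotypes: int
    expansion_ratio: float
    gini: float
    largest_clone_fraction: float

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "tissue": self.tissue,
            "n_cells": self.n_cells,
            "n_clonotypes": self.n_clonotypes,
            "expansion_ratio": self.expansion_ratio,
            "gini": self.gini,
            "largest_clone_fraction": self.largest_clone_fraction,
        }


@dataclass(frozen=True, slots=True)
class LorenzCurve:
    """Cumulative clonotype proportion (x) vs cumulative cell proportion (y)."""

    x: np.ndarray
    y: np.ndarray

    @property
    def points(self) -> list[tuple[float, float]]:
        return list(zip(self.x.tolist(), self.y.tolist()))

    def gini(self) -> float:
        """Gini as twice the area between the diagonal and the curve."""
        area = float(np.trapezoid(self.y, self.x))
        return 1.0 - 2.0 * area


@dataclass(frozen=True, slots=True)
class OverlapResult:
    a_only: int
    b_only: int
    shared: int
    shared_keys: tuple[ClonotypeKey, ...]


def _check_sizes(sizes: Sequence[float]) -> np.ndarray:
    arr = np.asarray(sizes, dtype=float)
    if arr.size == 0 or not np.any(arr > 0):
        raise EmptyRepertoireError("need at least one positive count")
    if np.any(arr < 0):
        raise ValueError("negative counts are not valid abundances")
    return arr


def expansion_ratio(repertoire: Repertoire) -> float:
    """Fraction of cells in clonotypes of size >= 2."""
    if repertoire.is_empty:
        raise EmptyRepertoireError("expansion ratio undefined for an empty repertoire")
    expanded = sum(c.size for c in repertoire.clonotypes if c.size >= 2)
    return expanded / repertoire.n_cells


def gini_coefficient(sizes: Sequence[float]) -> float:
    """Population (uncorrected) Gini coefficient of a size distribution.

    Computed via the sorted-rank identity
    G = 2*sum_i i*x_(i) / (n*sum x) - (n+1)/n, equivalent to the pairwise
    mean-absolute-difference form; no small-sample correction is applied.
    """
    arr = np.sort(_check_sizes(sizes))
    n = arr.size
    ranks = np.arange(1, n + 1)
    total = arr.sum()
    return float(2.0 * (ranks * arr).sum() / (n * total) - (n + 1) / n)


def lorenz_curve(sizes: Sequence[float], keys: Sequence[str] | None = None) -> LorenzCurve:
    """Lorenz curve of clone abundances, sorted ascending by size.

    ``keys`` (optional, parallel to ``sizes``) break size ties so the curve
    is bit-reproducible regardless of input order.
    """
    arr = _check_sizes(sizes)
    if keys is not None:
        if len(keys) != arr.size:
            raise ValueError("keys must parallel sizes")
        order = np.lexsort((np.asarray(keys, dtype=object), arr))
    else:
        order = np.argsort(arr, kind="stable")
    arr = arr[order]
    n = arr.size
    x = np.concatenate([[0.0], np.arange(1, n + 1) / n])
    y = np.concatenate([[0.0], np.cumsum(arr) / arr.sum()])
    return LorenzCurve(x=x, y=y)


def repertoire_overlap(a: Repertoire, b: Repertoire) -> OverlapResult:
    """Set algebra over the distinct clonotype keys of two repertoires."""
    cfg_a, cfg_b = a.key_config(), b.key_config()
    if cfg_a is not None and cfg_b is not None and cfg_a != cfg_b:
        raise ValueError(
            f"clonotype key configurations differ: {cfg_a} vs {cfg_b}"
        )
    keys_a, keys_b = a.keys(), b.keys()
    shared = keys_a & keys_b
    shared_sorted = tuple(sorted(shared, key=lambda k: (k.alpha_component, k.beta_component)))
    return OverlapResult(
        a_only=len(keys_a - keys_b),
        b_only=len(keys_b - keys_a),
        shared=len(shared),
        shared_keys=shared_sorted,
    )


def shared_clonotypes_across_samples(
    repertoires: Sequence[Repertoire], min_samples: int = 2
) -> pd.DataFrame:
    """Clonotype keys recurring in at least ``min_samples`` distinct samples.

    Returns a table with one row per shared key: the key components, the
    samples carrying it, and its per-sample clone sizes; ordered by
    descending total size then key.
    """
    if len(repertoires) < 2:
        raise ValueError("need at least two repertoires")
    if min_samples < 2:
        raise ValueError("min_samples must be >= 2")
    configs = {r.key_config() for r in repertoires if not r.is_empty}
    if len(configs) > 1:
        raise ValueError(f"clonotype key configurations differ: {sorted(map(str, configs))}")

    occurrences: dict[ClonotypeKey, dict[str, int]] = {}
    for rep in repertoires:
        for c in rep.clonotypes:
            occurrences.setdefault(c.key, {})[rep.sample_id] = c.size

    rows = []
    for key, per_sample in occurrences.items():
        if len(per_sample) >= min_samples:
            samples = sorted(per_sample)
            rows.append({
                "alpha_component": key.alpha_component,
                "beta_component": key.beta_component,
                "n_samples": len(samples),
                "sample_ids": ";".join(samples),
                "sizes": ";".join(str(per_sample[s]) for s in samples),
                "total_size": sum(per_sample.values()),
            })
    df = pd.DataFrame(
        rows,
        columns=["alpha_component", "beta_component", "n_samples",
                 "sample_ids", "sizes", "total_size"],
    )
    if not df.empty:
        df = df.sort_values(
            ["total_size", "alpha_component", "beta_component"],
            ascending=[False, True, True],
            ignore_index=True,
        )
    return df


def summarize_repertoire(repertoire: Repertoire) -> ClonalitySummary:
    """Per-sample clonality summary (one row of the paper-style table)."""
    if repertoire.is_empty:
        raise EmptyRepertoireError("cannot summarise an empty repertoire")
    sizes = repertoire.sizes
    return ClonalitySummary(
        sample_id=repertoire.sample_id,
        tissue=repertoire.tissue,
        n_cells=repertoire.n_cells,
        n_clonotypes=repertoire.n_clonotypes,
        expansion_ratio=expansion_ratio(repertoire),
        gini=gini_coefficient(sizes),
        largest_clone_fraction=max(sizes) / repertoire.n_cells,
    )


def aggregate_summaries(summaries: Sequence[ClonalitySummary]) -> pd.DataFrame:
    """Mean +/- SEM of the clonality statistics per tissue group."""
    if not summaries:
        raise ValueError("no summaries to aggregate")
    df = pd.DataFrame([s.to_dict() for s in summaries])
    stats = ["expansion_ratio", "gini", "largest_clone_fraction"]
    agg = df.groupby("tissue")[stats].agg(["mean", "sem", "count"])
    agg.columns = [f"{stat}_{fn}" for stat, fn in agg.columns]
    return agg.reset_index()
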