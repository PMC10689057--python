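"""Pangenome gene-cluster classification and saturation analysis.

A cluster present in all N accessions is *core*; present in exactly one,
*private*; present in 2..N-1, *dispensable*. The three labels partition
the cluster set exactly, which keeps category totals additive. Saturation
curves report pan (union) and core (intersection) cluster counts over
genome subsets of increasing size, exhaustively when the subset count is
small and by uniform subset sampling otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .containers import OrthogroupMatrix
from .errors import InvariantError, ParameterError

CATEGORIES = ("core", "dispensable", "private")


@dataclass
class ClusterClassification:
    label: Dict[str, str]
    n_core: int
    n_dispensable: int
    n_private: int

    @property
    def total(self) -> int:
        return self.n_core + self.n_dispensable + self.n_private

    def summary(self) -> pd.DataFrame:
        """Counts and percentages per category plus the variable share."""
        return summarize_counts(self.n_core, self.n_dispensable, self.n_private)


def summarize_counts(n_core: int, n_dispensable: int, n_private: int) -> pd.DataFrame:
    """Category percentages from raw counts.

    Also reports the 'variable' share (dispensable + private), the usual
    headline figure for gene-content variability of a pangenome.
    """
    total = n_core + n_dispensable + n_private
    if total <= 0:
        raise ParameterError("counts must sum to a positive total")
    rows = [
        ("core", n_core, 100.0 * n_core / total),
        ("dispensable", n_dispensable, 100.0 * n_dispensable / total),
        ("private", n_private, 100.0 * n_private / total),
        ("variable", n_dispensable + n_private,
         100.0 * (n_dispensable + n_private) / total),
        ("total", total, 100.0),
    ]
    return pd.DataFrame(rows, columns=["category", "n_clusters", "percent"])


def classify_clusters(matrix: OrthogroupMatrix) -> ClusterClassification:
    """Label every cluster core / dispensable / private by presence count."""
    presence = matrix.presence().to_numpy()
    n_acc = presence.shape[1]
    n_present = presence.sum(axis=1)
    if (n_present == 0).any():
        raise InvariantError("cluster with zero presence")
    labels = np.where(
        n_present == n_acc, "core", np.where(n_present == 1, "private", "dispensable")
    )
    label_map = dict(zip(matrix.clusters, labels))
    return ClusterClassification(
        label=label_map,
        n_core=int((labels == "core").sum()),
        n_dispensable=int((labels == "dispensable").sum()),
        n_private=int((labels == "private").sum()),
    )


@dataclass
class SaturationCurve:
    """Pan/core cluster counts vs number of genomes.

    ``table`` columns: k, pan_mean, pan_sd, core_mean, core_sd, n_subsets,
    exhaustive. SDs are population SDs over the evaluated subsets (zero
    when only one subset exists).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.table["core_mean"] > self.table["pan_mean"] + 1e-9).any():
            raise InvariantError("core_mean must be <= pan_mean for every k")


def saturation_curves(
    matrix: OrthogroupMatrix,
    max_exhaustive: int = 1000,
    n_samples: int = 200,
    seed: int = 0,
) -> SaturationCurve:
    """Pan/core saturation over genome subsets of size k = 1..N.

    For each k, all C(N, k) subsets are enumerated when their number is at
    most ``max_exhaustive``; otherwise ``n_samples`` subsets are drawn
    uniformly (with replacement across draws). Averaging is over subsets,
    not genome orderings.
    """
    presence = matrix.presence().to_numpy()
    n_acc = presence.shape[1]
    if n_acc < 2:
        raise ParameterError("need at least 2 accessions")
    rng = np.random.default_rng(seed)
    rows = []
    for k in range(1, n_acc + 1):
        n_subsets = math.comb(n_acc, k)
        exhaustive = n_subsets <= max_exhaustive
        if not exhaustive and n_samples < 1:
            raise ParameterError("n_samples must be >= 1 when sampling is required")
        if exhaustive:
            subsets = combinations(range(n_acc), k)
            count = n_subsets
        else:
            subsets = (
                rng.choice(n_acc, size=k, replace=False) for _ in range(n_samples)
            )
            count = n_samples
        pan_vals = np.empty(count)
        core_vals = np.empty(count)
        for i, cols in enumerate(subsets):
            sub = presence[:, list(cols)]
            pan_vals[i] = sub.any(axis=1).sum()
            core_vals[i] = sub.all(axis=1).sum()
        rows.append(
            (
                k,
                pan_vals.mean(),
                pan_vals.std(),
                core_vals.mean(),
                core_vals.std(),
                count,
                exhaustive,
            )
        )
    table = pd.DataFrame(
        rows,
        columns=["k", "pan_mean", "pan_sd", "core_mean", "core_sd",
                 "n_subsets", "exhaustive"],
    )
    return SaturationCurve(table)


def per_genome_composition(
    matrix: OrthogroupMatrix, classification: ClusterClassification
) -> pd.DataFrame:
    """Gene-level category percentages per accession.

    Every gene inherits the label of its cluster; percentages are over the
    genes each accession contributes to the matrix and sum to 100.
    """
    if set(classification.label) != set(matrix.clusters):
        raise ParameterError("classification does not match matrix clusters")
    labels = pd.Series(
        [classification.label[c] for c in matrix.clusters], index=matrix.counts.index
    )
    rows = []
    for acc in matrix.accessions:
        col = matrix.counts[acc]
        total = int(col.sum())
        if total == 0:
            raise ParameterError(f"accession {acc!r} has no genes")
        by_cat = col.groupby(labels).sum()
        rows.append(
            [acc, total]
            + [100.0 * by_cat.get(cat, 0) / total for cat in CATEGORIES]
        )
    return pd.DataFrame(
        rows, columns=["accession", "n_genes", "core_pct", "dispensable_pct",
                       "private_pct"],
    )


def compare_categories(
    stats_df: pd.DataFrame, metric: str
) -> pd.DataFrame:
    """Pairwise two-sided Wilcoxon rank-sum tests between gene categories.

    ``stats_df`` holds per-gene records with a ``category`` column and the
    metric column (``cds_length``, ``expression`` or ``kaks``). Exact
    p-values are used for combined n <= 20 without ties, the tie-corrected
    normal approximation otherwise. Categories with fewer than 2
    observations are excluded with a warning.
    """
    import logging

    if metric not in stats_df.columns:
        raise ParameterError(f"metric {metric!r} not in stats table")
    logger = logging.getLogger("panploid")
    groups = {}
    for cat in CATEGORIES:
        vals = stats_df.loc[stats_df["category"] == cat, metric].dropna().to_numpy()
        if len(vals) < 2:
            logger.warning("category %s has <2 observations; excluded", cat)
            continue
        groups[cat] = vals
    rows = []
    cats = list(groups)
    for a, b in combinations(cats, 2):
        x, y = groups[a], groups[b]
        n = len(x) + len(y)
        has_ties = len(np.unique(np.concatenate([x, y]))) < n
        method = "exact" if (n <= 20 and not has_ties) else "asymptotic"
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
        rows.append(
            (a, b, float(np.median(x)), float(np.median(y)),
             float(res.statistic), float(res.pvalue), method)
        )
    return pd.DataFrame(
        rows,
        columns=["category_1", "category_2", "median_1", "median_2",
                 "statistic", "p_value", "method"],
    )
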