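"""Presence-absence variation (PAV) analysis on a backbone genome.

Covers non-redundant merging of per-sample call sets, genotype-matrix
filtering, identification of lineage-differentiated PAVs, annotation of
PAVs to genes via a cis-regulatory flank, and a permutation test for the
overlap between PAV-associated genes and differentially expressed genes.
"""

from __future__ import annotations

import logging
from typing import List, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .containers import ABSENT, MISSING, PRESENT, GeneModel, LineageDesign, PavTable
from .errors import ParameterError

logger = logging.getLogger("panploid")


def merge_pavs(
    call_sets: Sequence[PavTable],
    pos_tol_bp: int = 1000,
    size_ratio: float = 0.8,
) -> PavTable:
    """Merge per-sample PAV call sets into one non-redundant table.

    Two records merge iff they share svtype and chromosome, their start
    positions lie within ``pos_tol_bp`` and min(svlen)/max(svlen) >=
    ``size_ratio``. The merged record keeps the coordinates (and id) of
    its first-seen member; genotypes take the union with present
    dominating absent dominating missing.
    """
    if not call_sets:
        raise ParameterError("no call sets to merge")
    all_samples: List[str] = []
    for t in call_sets:
        for s in t.samples:
            if s not in all_samples:
                all_samples.append(s)

    clusters: List[dict] = []  # first-seen representative + genotype union
    by_key: dict = {}  # (chrom, svtype) -> list of cluster indices

    for table in call_sets:
        for _, row in table.records.iterrows():
            key = (row["chrom"], row["svtype"])
            merged_into = None
            for ci in by_key.get(key, ()):
                rep = clusters[ci]["rep"]
                if abs(int(row["start"]) - rep["start"]) <= pos_tol_bp:
                    lo, hi = sorted([int(row["svlen"]), rep["svlen"]])
                    if hi > 0 and lo / hi >= size_ratio:
                        merged_into = ci
                        break
            geno_row = table.genotypes.loc[row["id"]]
            if merged_into is None:
                clusters.append(
                    {
                        "rep": {
                            "id": row["id"],
                            "chrom": row["chrom"],
                            "start": int(row["start"]),
                            "end": int(row["end"]),
                            "svtype": row["svtype"],
                            "svlen": int(row["svlen"]),
                        },
                        "geno": {s: MISSING for s in all_samples},
                    }
                )
                ci = len(clusters) - 1
                by_key.setdefault(key, []).append(ci)
                merged_into = ci
            g = clusters[merged_into]["geno"]
            for s in table.samples:
                g[s] = max(g[s], int(geno_row[s]))  # PRESENT > ABSENT > MISSING

    records = pd.DataFrame([c["rep"] for c in clusters])
    genotypes = pd.DataFrame(
        [[c["geno"][s] for s in all_samples] for c in clusters],
        columns=all_samples,
        index=pd.Index(records["id"], name="id"),
        dtype=np.int8,
    )
    return PavTable(records.reset_index(drop=True), genotypes)


def filter_pavs(
    table: PavTable,
    max_missing: float = 0.2,
    min_minor_freq: float = 0.0,
) -> PavTable:
    """Drop records by missingness and minor presence-frequency.

    A record is removed when its missing fraction exceeds ``max_missing``
    or when its minor presence-frequency (min of presence and absence
    frequency over non-missing genotypes) is below ``min_minor_freq``.
    """
    g = table.genotypes.to_numpy()
    n_samples = g.shape[1]
    missing_frac = (g == MISSING).mean(axis=1)
    n_called = (g != MISSING).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq_present = np.where(
            n_called > 0, (g == PRESENT).sum(axis=1) / np.maximum(n_called, 1), np.nan
        )
    minor = np.minimum(freq_present, 1 - freq_present)
    keep = (missing_frac <= max_missing) & ~(
        np.nan_to_num(minor, nan=-1.0) < min_minor_freq
    )
    # all-missing records have no defined frequency; drop them unless the
    # filters are both fully permissive
    if min_minor_freq > 0:
        keep &= n_called > 0
    kept_ids = table.records.loc[keep, "id"]
    return table.subset(list(kept_ids))


def lineage_differentiated(
    table: PavTable,
    design: LineageDesign,
    min_freq_diff: float = 1.0,
) -> PavTable:
    """PAVs whose presence frequency differs between lineages.

    Frequencies are computed over non-missing genotypes within each
    lineage; a record is reported iff |freq_A - freq_B| >= min_freq_diff
    (inclusive). The default 1.0 demands a fixed difference. Records with
    an all-missing lineage are skipped with a warning.
    """
    missing = [
        s for s in design.samples_A + design.samples_B if s not in table.samples
    ]
    if missing:
        raise ParameterError(f"design samples not genotyped: {missing}")
    gA = table.genotypes[list(design.samples_A)].to_numpy()
    gB = table.genotypes[list(design.samples_B)].to_numpy()
    nA = (gA != MISSING).sum(axis=1)
    nB = (gB != MISSING).sum(axis=1)
    skip = (nA == 0) | (nB == 0)
    if skip.any():
        logger.warning(
            "%d records skipped: one lineage entirely missing", int(skip.sum())
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        fA = (gA == PRESENT).sum(axis=1) / np.maximum(nA, 1)
        fB = (gB == PRESENT).sum(axis=1) / np.maximum(nB, 1)
    hit = (np.abs(fA - fB) >= min_freq_diff - 1e-12) & ~skip
    return table.subset(list(table.records.loc[hit, "id"]))


def annotate_pavs_to_genes(
    pavs: PavTable,
    genes: Sequence[GeneModel],
    flank_bp: int = 2000,
) -> pd.DataFrame:
    """Associate PAVs with genes they overlap within a cis flank.

    A PAV is associated with a gene iff its interval overlaps
    [gene.start - flank_bp, gene.end + flank_bp). The flank extends both
    sides regardless of strand. Returns one row per (gene, PAV)
    association.
    """
    if flank_bp < 0:
        raise ParameterError("flank_bp must be >= 0")
    trees: dict = {}
    for g in genes:
        iv = g.interval
        lo = max(0, iv.start - flank_bp)
        hi = iv.end + flank_bp
        trees.setdefault(iv.chrom, IntervalTree()).addi(lo, hi, g.id)
    rows = []
    for _, row in pavs.records.iterrows():
        tree = trees.get(row["chrom"])
        if tree is None:
            continue
        for hit in sorted(tree.overlap(int(row["start"]), int(row["end"]))):
            rows.append((hit.data, row["id"], row["svtype"], int(row["svlen"])))
    return pd.DataFrame(rows, columns=["gene_id", "pav_id", "svtype", "svlen"])


def deg_overlap_permutation(
    target_genes: Set[str],
    deg_genes: Set[str],
    universe: Set[str],
    n_perm: int = 1000,
    seed: int = 0,
) -> Tuple[int, float, float]:
    """Permutation test: is the DEG overlap of a gene set above chance?

    Null draws are uniform samples of |target_genes| genes from the
    universe without replacement; the empirical p-value uses the add-one
    estimator p = (1 + #{null >= observed}) / (n_perm + 1), so p is never
    zero.
    """
    if not universe:
        raise ParameterError("empty universe")
    if not target_genes <= universe or not deg_genes <= universe:
        raise ParameterError("target and DEG sets must be subsets of the universe")
    if n_perm < 1:
        raise ParameterError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    uni = np.array(sorted(universe))
    deg_mask = np.isin(uni, sorted(deg_genes))
    k = len(target_genes)
    observed = len(target_genes & deg_genes)
    null = np.empty(n_perm, dtype=int)
    for i in range(n_perm):
        idx = rng.choice(len(uni), size=k, replace=False)
        null[i] = int(deg_mask[idx].sum())
    p = (1 + int((null >= observed).sum())) / (n_perm + 1)
    return observed, float(null.mean()), float(p)
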