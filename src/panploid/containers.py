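"""In-memory domain containers shared across the pipeline.

Conventions
-----------
* Coordinates: 0-based half-open everywhere (see :mod:`panploid.intervals`).
* PAV genotypes: integer codes ``PRESENT=1``, ``ABSENT=0``, ``MISSING=-1``.
  Missing genotypes are carried explicitly and never imputed; each
  downstream filter decides how to treat them.
* Tables are thin wrappers over :class:`pandas.DataFrame` so they can be
  validated once and then passed around without re-checking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .errors import InvariantError, ParameterError
from .intervals import GenomicInterval

PRESENT = 1
ABSENT = 0
MISSING = -1


# ---------------------------------------------------------------------------
# depth
# ---------------------------------------------------------------------------

@dataclass
class DepthTrack:
    """Ordered, non-overlapping fixed-width windows with mean read depth.

    ``windows`` has columns ``chrom``, ``start``, ``end``, ``depth``; all
    widths equal ``window_size`` except possibly the last window on each
    chromosome.
    """

    windows: pd.DataFrame
    window_size: int

    def __post_init__(self) -> None:
        required = ["chrom", "start", "end", "depth"]
        if list(self.windows.columns[:4]) != required:
            raise InvariantError(f"DepthTrack columns must start with {required}")
        if (self.windows["depth"] < 0).any():
            raise InvariantError("window depths must be >= 0")
        w = self.windows
        for chrom, grp in w.groupby("chrom", sort=False):
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            if (ends <= starts).any():
                raise InvariantError(f"window with end <= start on {chrom}")
            if (starts[1:] < ends[:-1]).any():
                raise InvariantError(f"overlapping or unsorted windows on {chrom}")

    def __len__(self) -> int:
        return len(self.windows)

    @property
    def chroms(self) -> List[str]:
        return list(dict.fromkeys(self.windows["chrom"]))


# ---------------------------------------------------------------------------
# orthogroups
# ---------------------------------------------------------------------------

@dataclass
class OrthogroupMatrix:
    """Cluster x accession gene-count table.

    ``counts`` is indexed by cluster ID with one integer column per
    accession; entry (c, a) is the number of genes accession *a*
    contributes to cluster *c*. Every cluster must be present (count >= 1)
    in at least one accession.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.shape[1] < 1:
            raise InvariantError("OrthogroupMatrix needs at least one accession")
        if (self.counts.to_numpy() < 0).any():
            raise InvariantError("gene counts must be non-negative")
        if (self.counts.sum(axis=1) == 0).any():
            bad = self.counts.index[self.counts.sum(axis=1) == 0][0]
            raise InvariantError(f"cluster {bad!r} present in no accession")

    @property
    def clusters(self) -> List[str]:
        return list(self.counts.index)

    @property
    def accessions(self) -> List[str]:
        return list(self.counts.columns)

    def presence(self) -> pd.DataFrame:
        """Boolean cluster x accession presence matrix."""
        return self.counts >= 1


# ---------------------------------------------------------------------------
# PAVs
# ---------------------------------------------------------------------------

@dataclass
class PavTable:
    """Non-redundant >=50-bp insertion/deletion records with genotypes.

    ``records``: columns ``id``, ``chrom``, ``start``, ``end``, ``svtype``
    (INS or DEL), ``svlen`` (positive bp), indexed 0..n-1.
    ``genotypes``: record-id x sample matrix of PRESENT/ABSENT/MISSING codes.
    """

    records: pd.DataFrame
    genotypes: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["id", "chrom", "start", "end", "svtype", "svlen"]
        missing = [c for c in required if c not in self.records.columns]
        if missing:
            raise InvariantError(f"PavTable records missing columns {missing}")
        if not set(self.records["svtype"]) <= {"INS", "DEL"}:
            raise InvariantError("svtype must be INS or DEL")
        if (self.records["svlen"] <= 0).any():
            raise InvariantError("svlen must be positive")
        if not self.records["id"].is_unique:
            raise InvariantError("PAV ids must be unique")
        if list(self.genotypes.index) != list(self.records["id"]):
            raise InvariantError("genotype rows must match record ids in order")
        vals = set(np.unique(self.genotypes.to_numpy()))
        if not vals <= {PRESENT, ABSENT, MISSING}:
            raise InvariantError(f"invalid genotype codes {vals}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def samples(self) -> List[str]:
        return list(self.genotypes.columns)

    def subset(self, ids: Sequence[str]) -> "PavTable":
        keep = self.records["id"].isin(set(ids))
        return PavTable(
            self.records[keep].reset_index(drop=True),
            self.genotypes.loc[self.records.loc[keep, "id"]],
        )


@dataclass(frozen=True)
class LineageDesign:
    """Assignment of samples to the two lineages being contrasted."""

    samples_A: Tuple[str, ...]
    samples_B: Tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.samples_A or not self.samples_B:
            raise ParameterError("both lineages need at least one sample")
        if set(self.samples_A) & set(self.samples_B):
            raise ParameterError("lineages must be disjoint")


@dataclass(frozen=True)
class GeneModel:
    id: str
    interval: GenomicInterval

    @property
    def strand(self) -> str:
        return self.interval.strand


# ---------------------------------------------------------------------------
# homeolog pairs
# ---------------------------------------------------------------------------

@dataclass
class HomeologPairSet:
    """1:1 syntenic gene pairs between the two subgenomes.

    ``pairs``: columns ``pair_id``, ``gene_A``, ``gene_B``, ``chrom_pair``.
    No gene may appear in two pairs.
    """

    pairs: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["pair_id", "gene_A", "gene_B", "chrom_pair"]
        missing = [c for c in required if c not in self.pairs.columns]
        if missing:
            raise InvariantError(f"HomeologPairSet missing columns {missing}")
        genes = pd.concat([self.pairs["gene_A"], self.pairs["gene_B"]])
        if genes.duplicated().any():
            raise InvariantError("a gene appears in more than one homeolog pair")
        if self.pairs["pair_id"].duplicated().any():
            raise InvariantError("pair_ids must be unique")

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class HomeologIntervalMap:
    """Syntenic interval correspondences between the two parental genomes.

    Each element maps a block on genome A to its homeologous block on
    genome B; within each genome the mapped intervals must not overlap.
    """

    blocks: List[Tuple[GenomicInterval, GenomicInterval]]

    def __post_init__(self) -> None:
        for side in (0, 1):
            ivs = sorted(
                (b[side] for b in self.blocks), key=lambda i: (i.chrom, i.start)
            )
            for a, b in zip(ivs, ivs[1:]):
                if a.overlaps(b):
                    raise InvariantError(
                        f"map intervals overlap on side {'AB'[side]}: {a} / {b}"
                    )

    def __len__(self) -> int:
        return len(self.blocks)


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Raw RNA-seq counts, genes x samples, with tissue/replicate metadata.

    ``samples``: DataFrame indexed by sample name with columns ``tissue``
    and ``replicate``; index order must match the count columns.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.samples.index):
            raise InvariantError("count columns must match sample-sheet order")
        for col in ("tissue", "replicate"):
            if col not in self.samples.columns:
                raise InvariantError(f"sample sheet missing column {col!r}")
        arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise InvariantError("counts must be non-negative")
        if not np.allclose(arr, np.round(arr)):
            raise InvariantError("counts must be integral")

    @property
    def tissues(self) -> List[str]:
        return list(dict.fromkeys(self.samples["tissue"]))

    def samples_for(self, tissue: str) -> List[str]:
        return list(self.samples.index[self.samples["tissue"] == tissue])


# ---------------------------------------------------------------------------
# TE families
# ---------------------------------------------------------------------------

@dataclass
class TeFamilyTable:
    """Per-family total length (bp) in each genome, with lineage labels.

    ``sizes``: family x genome total length; ``lineage``: genome -> 'A'|'B'.
    """

    sizes: pd.DataFrame
    lineage: Dict[str, str]

    def __post_init__(self) -> None:
        if (self.sizes.to_numpy() < 0).any():
            raise InvariantError("family sizes must be >= 0")
        missing = [g for g in self.sizes.columns if g not in self.lineage]
        if missing:
            raise InvariantError(f"genomes without lineage assignment: {missing}")
        values = set(self.lineage[g] for g in self.sizes.columns)
        if not values <= {"A", "B"}:
            raise InvariantError("lineage labels must be 'A' or 'B'")
        if values != {"A", "B"}:
            raise InvariantError("need at least one genome per lineage")


# ---------------------------------------------------------------------------
# simulation ground truth
# ---------------------------------------------------------------------------

@dataclass
class SimTruth:
    """Ground truth attached to every synthetic dataset.

    Only the fields relevant to a given generator are populated; the rest
    stay None/empty. ``true_params`` records scalar generator settings
    (dispersion, substitution counts, LTR age, ...).
    """

    cluster_labels: Optional[Dict[str, str]] = None
    implanted_segments: List[Tuple[GenomicInterval, str]] = field(default_factory=list)
    biased_pairs: Dict[str, float] = field(default_factory=dict)
    differentiated_pavs: Set[str] = field(default_factory=set)
    true_params: Dict[str, object] = field(default_factory=dict)
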