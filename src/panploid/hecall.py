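"""Read-depth homeologous-exchange (HE) caller.

In an allopolyploid, a segment of one subgenome replaced by its homeolog
from the other appears, after mapping the tetraploid's reads to the two
parental genomes jointly, as a depth gain on the donor parent and a
matching depth loss on the recipient. The caller:

1. computes the genome-wide mean depth (length-weighted);
2. flags 10-kb windows at >= dup_factor x mean as duplication candidates
   and <= del_factor x mean as deletion candidates;
3. links same-kind flagged windows within ``link_gap_bp`` and keeps
   merged segments strictly longer than ``min_len_bp``;
4. pairs duplication segments on one parent with deletion segments on the
   other via a homeolog interval map, requiring reciprocal overlap, and
   reports each pair as a directional HE (donor -> recipient).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .containers import DepthTrack, HomeologIntervalMap
from .errors import ParameterError
from .intervals import GenomicInterval

logger = logging.getLogger("panploid")


@dataclass(frozen=True)
class FlaggedSegment:
    interval: GenomicInterval
    kind: str  # "dup" | "del"
    mean_depth: float
    n_windows: int


@dataclass(frozen=True)
class HECall:
    donor_interval: GenomicInterval
    recipient_interval: GenomicInterval
    direction: str  # e.g. "B->A"
    length_bp: int


def genome_mean_depth(track: DepthTrack) -> float:
    """Length-weighted mean window depth across the whole track."""
    if len(track) == 0:
        raise ParameterError("empty depth track")
    w = track.windows
    widths = (w["end"] - w["start"]).to_numpy(dtype=float)
    return float((w["depth"].to_numpy() * widths).sum() / widths.sum())


def flag_windows(
    track: DepthTrack,
    mean_depth: float,
    dup_factor: float = 1.5,
    del_factor: float = 0.25,
) -> pd.DataFrame:
    """Per-window dup/del/none flags against the genome mean.

    Thresholds are inclusive on both sides: depth >= dup_factor x mean is
    a duplication candidate, depth <= del_factor x mean a deletion
    candidate.
    """
    if not (0 < del_factor < 1 < dup_factor):
        raise ParameterError("require 0 < del_factor < 1 < dup_factor")
    w = track.windows.copy()
    depth = w["depth"].to_numpy()
    flags = np.where(
        depth >= dup_factor * mean_depth,
        "dup",
        np.where(depth <= del_factor * mean_depth, "del", "none"),
    )
    w["flag"] = flags
    return w


def merge_segments(
    flagged: pd.DataFrame,
    link_gap_bp: int = 50_000,
    min_len_bp: int = 80_000,
) -> List[FlaggedSegment]:
    """Link nearby same-kind flagged windows and length-filter segments.

    Two flagged windows of the same kind on one chromosome are linked when
    the gap between them (end of one to start of the next) is at most
    ``link_gap_bp``; any unflagged gap windows are absorbed into the merged
    interval. Only segments strictly longer than ``min_len_bp`` are kept.
    ``mean_depth`` of a segment averages only its flagged windows.
    """
    if link_gap_bp < 0:
        raise ParameterError("link_gap_bp must be >= 0")
    segments: List[FlaggedSegment] = []
    for kind in ("dup", "del"):
        sub = flagged[flagged["flag"] == kind]
        for chrom, grp in sub.groupby("chrom", sort=False):
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            depths = grp["depth"].to_numpy()
            if len(starts) == 0:
                continue
            run_start = 0
            for i in range(1, len(starts) + 1):
                if i < len(starts) and starts[i] - ends[i - 1] <= link_gap_bp:
                    continue
                seg_start = int(starts[run_start])
                seg_end = int(ends[i - 1])
                if seg_end - seg_start > min_len_bp:
                    segments.append(
                        FlaggedSegment(
                            GenomicInterval(chrom, seg_start, seg_end),
                            kind,
                            float(depths[run_start:i].mean()),
                            int(i - run_start),
                        )
                    )
                run_start = i
    segments.sort(key=lambda s: (s.interval.chrom, s.interval.start, s.kind))
    return segments


def call_segments(
    track: DepthTrack,
    dup_factor: float = 1.5,
    del_factor: float = 0.25,
    link_gap_bp: int = 50_000,
    min_len_bp: int = 80_000,
    mean_depth: Optional[float] = None,
) -> List[FlaggedSegment]:
    """Convenience pipeline: mean -> flags -> merged, filtered segments."""
    if mean_depth is None:
        mean_depth = genome_mean_depth(track)
    flagged = flag_windows(track, mean_depth, dup_factor, del_factor)
    return merge_segments(flagged, link_gap_bp, min_len_bp)


def _project(
    iv: GenomicInterval, imap: HomeologIntervalMap, source_side: int
) -> List[GenomicInterval]:
    """Project an interval through the syntenic map, block by block.

    Coordinates within a block map affinely; only the overlapping portion
    of each block is projected. Returns the (possibly empty) list of
    projected pieces on the other genome.
    """
    out: List[GenomicInterval] = []
    for block in imap.blocks:
        src, dst = block[source_side], block[1 - source_side]
        ov_start = max(iv.start, src.start)
        ov_end = min(iv.end, src.end)
        if iv.chrom != src.chrom or ov_end <= ov_start:
            continue
        scale = dst.length / src.length
        p_start = dst.start + int(round((ov_start - src.start) * scale))
        p_end = dst.start + int(round((ov_end - src.start) * scale))
        if p_end > p_start:
            out.append(GenomicInterval(dst.chrom, p_start, p_end))
    return out


def call_hes(
    dup_segments_A: Sequence[FlaggedSegment],
    del_segments_A: Sequence[FlaggedSegment],
    dup_segments_B: Sequence[FlaggedSegment],
    del_segments_B: Sequence[FlaggedSegment],
    imap: HomeologIntervalMap,
    min_reciprocal_overlap: float = 0.5,
) -> Tuple[List[HECall], List[FlaggedSegment]]:
    """Pair dup segments with homeologous del segments into directional HEs.

    A duplication on parent X whose projection through the map reciprocally
    overlaps a deletion on parent Y by at least ``min_reciprocal_overlap``
    (of both the projected dup and the del) yields one HE with direction
    X->Y; its length is the recipient deletion's length. Segments that pair
    with nothing are returned as unresolved.
    """
    if not (0 < min_reciprocal_overlap <= 1):
        raise ParameterError("min_reciprocal_overlap must be in (0, 1]")
    calls: List[HECall] = []
    unresolved: List[FlaggedSegment] = []
    if len(imap) == 0:
        logger.warning("empty homeolog map: all segments unresolved")
        unresolved = list(dup_segments_A) + list(del_segments_A) + \
            list(dup_segments_B) + list(del_segments_B)
        return calls, unresolved

    matched_dels: Dict[int, set] = {0: set(), 1: set()}

    def pair(dups, dels, source_side, direction):
        del_side = 1 - source_side
        for dup in dups:
            pieces = _project(dup.interval, imap, source_side)
            proj_len = sum(p.length for p in pieces)
            found = False
            if proj_len > 0:
                for j, dl in enumerate(dels):
                    ov = sum(p.overlap_length(dl.interval) for p in pieces)
                    if (
                        ov / proj_len >= min_reciprocal_overlap
                        and ov / dl.interval.length >= min_reciprocal_overlap
                    ):
                        calls.append(
                            HECall(
                                donor_interval=dup.interval,
                                recipient_interval=dl.interval,
                                direction=direction,
                                length_bp=dl.interval.length,
                            )
                        )
                        matched_dels[del_side].add(j)
                        found = True
            if not found:
                unresolved.append(dup)

    pair(dup_segments_A, del_segments_B, 0, "A->B")
    pair(dup_segments_B, del_segments_A, 1, "B->A")
    for j, dl in enumerate(del_segments_A):
        if j not in matched_dels[0]:
            unresolved.append(dl)
    for j, dl in enumerate(del_segments_B):
        if j not in matched_dels[1]:
            unresolved.append(dl)
    return calls, unresolved


def summarize_hes(calls: Sequence[HECall]) -> pd.DataFrame:
    """Per-direction HE count and total recipient length (bp and Mb)."""
    rows = []
    for direction in sorted({c.direction for c in calls}):
        sub = [c for c in calls if c.direction == direction]
        total = sum(c.length_bp for c in sub)
        rows.append((direction, len(sub), total, total / 1e6))
    return pd.DataFrame(rows, columns=["direction", "n_calls", "total_bp", "total_mb"])
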