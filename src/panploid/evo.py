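"""Molecular-evolution utilities.

* Nei–Gojobori (1986) Ka/Ks on codon alignments: synonymous site counts
  per codon as the synonymous fraction of the nine single-nucleotide
  mutations (x3 sites), multi-difference codons averaged over all
  orderings of single steps with pathways through stop codons excluded,
  and Jukes–Cantor correction of both proportions.
* JC69 distance and LTR insertion-time estimation T = K / (2 mu). The
  substitution rate mu is a required user input: no silent default exists
  that would make an age meaningful.
* TE-family size contrasts between the A- and B-lineages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from . import genetic_code as gc
from .containers import TeFamilyTable
from .errors import ParameterError

INFINITE = float("inf")


# ---------------------------------------------------------------------------
# NG86 Ka/Ks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KaKsResult:
    ka: float
    ks: float
    ratio: Optional[float]  # None when Ks == 0 or a distance is infinite
    sd: float  # synonymous differences
    nd: float  # nonsynonymous differences
    s_sites: float
    n_sites: float

    @property
    def undefined(self) -> bool:
        return self.ratio is None


def _check_coding(seq: str, name: str) -> None:
    if len(seq) < 3 or len(seq) % 3 != 0:
        raise ParameterError(f"{name}: length must be a positive multiple of 3")
    if set(seq) - set("ACGT"):
        raise ParameterError(f"{name}: alphabet must be A/C/G/T")
    for i in range(0, len(seq), 3):
        if gc.is_stop(seq[i : i + 3]):
            raise ParameterError(f"{name}: internal stop codon at position {i}")


def _syn_sites(codon: str) -> float:
    """Synonymous sites of a codon: syn fraction of the 9 mutations x 3."""
    n_syn = 0
    aa = gc.AA[codon]
    for i in range(3):
        for b in "ACGT":
            if b == codon[i]:
                continue
            if gc.AA[codon[:i] + b + codon[i + 1 :]] == aa:
                n_syn += 1
    return n_syn / 3.0


def _codon_differences(c1: str, c2: str) -> Tuple[float, float]:
    """Average (syn, nonsyn) difference counts over mutational pathways.

    All orderings of the single-nucleotide steps from c1 to c2 are
    weighted equally; orderings passing through a stop codon are excluded
    and the weights renormalized. If every ordering crosses a stop (rare),
    all orderings are used.
    """
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0

    def walk(order, allow_stops):
        cur = c1
        sd = nd = 0
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if not allow_stops and gc.is_stop(nxt):
                return None
            if gc.AA[nxt] == gc.AA[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        return sd, nd

    results = [r for o in permutations(diff_pos) if (r := walk(o, False)) is not None]
    if not results:
        results = [walk(o, True) for o in permutations(diff_pos)]
    sd = sum(r[0] for r in results) / len(results)
    nd = sum(r[1] for r in results) / len(results)
    return sd, nd


def jc69_distance(p: float) -> float:
    """Jukes–Cantor corrected distance K = -(3/4) ln(1 - 4p/3).

    Returns inf when p >= 0.75 (saturation).
    """
    if p < 0:
        raise ParameterError("mismatch fraction must be >= 0")
    if p >= 0.75:
        return INFINITE
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def ng86_kaks(seq1: str, seq2: str) -> KaKsResult:
    """Nei–Gojobori Ka/Ks between two aligned, gap-free coding sequences."""
    seq1, seq2 = seq1.upper(), seq2.upper()
    if len(seq1) != len(seq2):
        raise ParameterError("sequences must have equal length")
    _check_coding(seq1, "seq1")
    _check_coding(seq2, "seq2")

    s_sites = sd = nd = 0.0
    n_codons = len(seq1) // 3
    for i in range(n_codons):
        c1 = seq1[3 * i : 3 * i + 3]
        c2 = seq2[3 * i : 3 * i + 3]
        s_sites += (_syn_sites(c1) + _syn_sites(c2)) / 2.0
        d_s, d_n = _codon_differences(c1, c2)
        sd += d_s
        nd += d_n
    n_sites = 3.0 * n_codons - s_sites

    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    ks = jc69_distance(ps)
    ka = jc69_distance(pn)
    if ks == 0 or not math.isfinite(ks) or not math.isfinite(ka):
        ratio = None
    else:
        ratio = ka / ks
    return KaKsResult(ka, ks, ratio, sd, nd, s_sites, n_sites)


# ---------------------------------------------------------------------------
# LTR insertion time
# ---------------------------------------------------------------------------

def mismatch_fraction(seq1: str, seq2: str) -> float:
    """Raw per-site mismatch fraction of two equal-length sequences."""
    if len(seq1) != len(seq2) or not seq1:
        raise ParameterError("sequences must be non-empty and equal length")
    diffs = sum(1 for a, b in zip(seq1.upper(), seq2.upper()) if a != b)
    return diffs / len(seq1)


def ltr_insertion_time(
    p: float, mutation_rate: float
) -> Tuple[float, float]:
    """Insertion age of an LTR retrotransposon from 5'/3' LTR divergence.

    The two LTRs are identical at insertion, so their JC69 distance K
    dates the element: T = K / (2 mu) with mu in substitutions per site
    per year. Returns (years, Mya); inf when divergence is saturated.
    """
    if mutation_rate <= 0:
        raise ParameterError("mutation_rate must be > 0")
    k = jc69_distance(p)
    years = k / (2.0 * mutation_rate)
    return years, years / 1e6


def ltr_insertion_time_from_k(k: float, mutation_rate: float) -> Tuple[float, float]:
    if mutation_rate <= 0:
        raise ParameterError("mutation_rate must be > 0")
    years = k / (2.0 * mutation_rate)
    return years, years / 1e6


# ---------------------------------------------------------------------------
# TE family contrasts
# ---------------------------------------------------------------------------

def te_family_contrast(
    table: TeFamilyTable, threshold_bp: int = 10_000
) -> pd.DataFrame:
    """Mean family size per lineage and the A-minus-B difference.

    A family is flagged when |mean_A - mean_B| >= threshold_bp
    (inclusive). Families absent from all genomes have difference 0 and
    stay unflagged.
    """
    genomes_A = [g for g in table.sizes.columns if table.lineage[g] == "A"]
    genomes_B = [g for g in table.sizes.columns if table.lineage[g] == "B"]
    mean_A = table.sizes[genomes_A].mean(axis=1)
    mean_B = table.sizes[genomes_B].mean(axis=1)
    diff = mean_A - mean_B
    flagged = diff.abs() >= threshold_bp
    return pd.DataFrame(
        {
            "family": table.sizes.index,
            "mean_A_bp": mean_A.to_numpy(),
            "mean_B_bp": mean_B.to_numpy(),
            "difference_bp": diff.to_numpy(),
            "flagged": flagged.to_numpy(),
        }
    ).reset_index(drop=True)


def summarize_te_contrast(contrast: pd.DataFrame) -> Dict[str, int | float]:
    """Counts of flagged families larger in each lineage."""
    flagged = contrast[contrast["flagged"]]
    larger_a = int((flagged["difference_bp"] > 0).sum())
    larger_b = int((flagged["difference_bp"] < 0).sum())
    n = len(flagged)
    return {
        "n_flagged": n,
        "larger_in_A": larger_a,
        "larger_in_B": larger_b,
        "pct_larger_in_A": (100.0 * larger_a / n) if n else float("nan"),
    }
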