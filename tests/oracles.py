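"""Independent brute-force oracles used only by the test suite.

The Ka/Ks oracle enumerates every mutational pathway between codons
recursively and re-derives site counts from first principles, sharing no
code with the package implementation beyond the universal genetic code.
"""

from __future__ import annotations

import math
from typing import List, Tuple

from Bio.Seq import Seq

BASES = "ACGT"


def _aa(codon: str) -> str:
    return str(Seq(codon).translate())


def oracle_syn_sites(codon: str) -> float:
    """Synonymous fraction of the nine point mutations, times three."""
    syn = 0
    for i in range(3):
        for b in BASES:
            if b == codon[i]:
                continue
            if _aa(codon[:i] + b + codon[i + 1:]) == _aa(codon):
                syn += 1
    return 3.0 * syn / 9.0


def _paths(cur: str, target: str, sd: int, nd: int, hit_stop: bool,
           out: List[Tuple[int, int, bool]]) -> None:
    if cur == target:
        out.append((sd, nd, hit_stop))
        return
    for i in range(3):
        if cur[i] == target[i]:
            continue
        nxt = cur[:i] + target[i] + cur[i + 1:]
        syn = _aa(nxt) == _aa(cur)
        _paths(nxt, target, sd + syn, nd + (not syn),
               hit_stop or _aa(nxt) == "*", out)


def oracle_codon_diffs(c1: str, c2: str) -> Tuple[float, float]:
    """Pathway-averaged (syn, nonsyn) differences; stop paths excluded."""
    if c1 == c2:
        return 0.0, 0.0
    paths: List[Tuple[int, int, bool]] = []
    _paths(c1, c2, 0, 0, False, paths)
    clean = [(s, n) for s, n, stop in paths if not stop]
    if not clean:
        clean = [(s, n) for s, n, _ in paths]
    return (sum(s for s, _ in clean) / len(clean),
            sum(n for _, n in clean) / len(clean))


def oracle_kaks(seq1: str, seq2: str):
    """Full NG86 re-derivation: returns (ka, ks, sd, nd, s_sites, n_sites)."""
    n_codons = len(seq1) // 3
    s_sites = sd = nd = 0.0
    for i in range(n_codons):
        c1, c2 = seq1[3 * i:3 * i + 3], seq2[3 * i:3 * i + 3]
        s_sites += (oracle_syn_sites(c1) + oracle_syn_sites(c2)) / 2.0
        d_s, d_n = oracle_codon_diffs(c1, c2)
        sd += d_s
        nd += d_n
    n_sites = 3.0 * n_codons - s_sites
    ps = sd / s_sites if s_sites else 0.0
    pn = nd / n_sites if n_sites else 0.0

    def jc(p):
        return math.inf if p >= 0.75 else -0.75 * math.log(1 - 4 * p / 3)

    return jc(pn), jc(ps), sd, nd, s_sites, n_sites
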