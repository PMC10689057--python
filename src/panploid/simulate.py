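"""Synthetic-data generators with known ground truth.

Every input the pipeline consumes can be emulated here: orthogroup
matrices with chosen core/dispensable/private proportions, windowed depth
tracks with implanted duplication/deletion segments, two-lineage PAV
genotype matrices, negative-binomial homeolog count matrices with a
chosen biased fraction, and codon-aligned sequence pairs with exact
implanted synonymous/nonsynonymous substitution counts.

All generators are deterministic given their seed and return a
:class:`~panploid.containers.SimTruth` describing exactly what was
implanted, so downstream callers can be scored against truth.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .containers import (
    ABSENT,
    MISSING,
    PRESENT,
    CountMatrix,
    DepthTrack,
    HomeologPairSet,
    OrthogroupMatrix,
    PavTable,
    SimTruth,
)
from .errors import ParameterError
from .intervals import GenomicInterval
from . import genetic_code as gc

DEFAULT_TISSUES = ("FB", "FF", "JF", "L")


# ---------------------------------------------------------------------------
# orthogroup matrices
# ---------------------------------------------------------------------------

def make_orthogroup_matrix(
    n_accessions: int,
    n_clusters: int,
    proportions: Tuple[float, float, float],
    seed: int,
    mean_extra_genes: float = 0.3,
) -> Tuple[OrthogroupMatrix, SimTruth]:
    """Simulate a cluster x accession gene-count matrix.

    ``proportions`` = (core, dispensable, private) must lie on the
    simplex. Core clusters are present in every accession, private in
    exactly one (uniform), dispensable in k accessions with k uniform on
    [2, n_accessions - 1]. Where present, a cluster contributes
    1 + Poisson(mean_extra_genes) genes.
    """
    if n_accessions < 2:
        raise ParameterError("n_accessions must be >= 2")
    p = np.asarray(proportions, dtype=float)
    if p.shape != (3,) or (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
        raise ParameterError("proportions must be a 3-simplex point")
    rng = np.random.default_rng(seed)

    n_core = int(round(n_clusters * p[0]))
    n_priv = int(round(n_clusters * p[2]))
    n_disp = n_clusters - n_core - n_priv
    if n_disp < 0:  # rounding collision
        n_disp = 0
        n_priv = n_clusters - n_core
    if n_disp > 0 and n_accessions < 3:
        raise ParameterError("dispensable clusters need n_accessions >= 3")

    accessions = [f"acc{i + 1}" for i in range(n_accessions)]
    labels: Dict[str, str] = {}
    presence = np.zeros((n_clusters, n_accessions), dtype=bool)
    order = ["core"] * n_core + ["dispensable"] * n_disp + ["private"] * n_priv
    for idx, lab in enumerate(order):
        cid = f"OG{idx:07d}"
        labels[cid] = lab
        if lab == "core":
            presence[idx, :] = True
        elif lab == "private":
            presence[idx, rng.integers(n_accessions)] = True
        else:
            k = int(rng.integers(2, n_accessions))  # uniform on [2, N-1]
            cols = rng.choice(n_accessions, size=k, replace=False)
            presence[idx, cols] = True

    counts = np.zeros_like(presence, dtype=int)
    extra = rng.poisson(mean_extra_genes, size=presence.shape)
    counts[presence] = 1 + extra[presence]
    matrix = OrthogroupMatrix(
        pd.DataFrame(counts, index=list(labels), columns=accessions)
    )
    truth = SimTruth(
        cluster_labels=labels,
        true_params={"proportions": tuple(p), "n_clusters": n_clusters},
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# depth tracks
# ---------------------------------------------------------------------------

def make_depth_track(
    chrom_lengths: Dict[str, int],
    window: int,
    base_depth: float,
    noise_sd: float,
    implants: Sequence[Tuple[GenomicInterval, str]],
    seed: int,
    dup_multiplier: float = 2.0,
    del_multiplier: float = 0.05,
) -> Tuple[DepthTrack, SimTruth]:
    """Simulate a windowed depth track with implanted dup/del segments.

    Background windows draw from Normal(base_depth, noise_sd) clipped at
    zero; implanted duplications from Normal(2 x base, sd) and deletions
    from Normal(0.05 x base, sd), also clipped. A deletion is simulated at
    a small residual depth (not exactly zero) so that the "low or no
    coverage" threshold of the caller is genuinely exercised. Implanted
    intervals must be window-aligned, non-overlapping and inside their
    chromosome.
    """
    rng = np.random.default_rng(seed)
    for iv, kind in implants:
        if kind not in ("dup", "del"):
            raise ParameterError(f"implant kind must be dup or del, got {kind!r}")
        if iv.chrom not in chrom_lengths:
            raise ParameterError(f"implant chrom {iv.chrom!r} not in chrom_lengths")
        if iv.end > chrom_lengths[iv.chrom]:
            raise ParameterError(f"implant {iv} exceeds chromosome length")
        if iv.start % window or iv.end % window:
            raise ParameterError(f"implant {iv} not aligned to {window}-bp windows")
    ivs = sorted((iv for iv, _ in implants), key=lambda i: (i.chrom, i.start))
    for a, b in zip(ivs, ivs[1:]):
        if a.overlaps(b):
            raise ParameterError(f"implants overlap: {a} / {b}")

    rows = []
    for chrom in chrom_lengths:
        length = chrom_lengths[chrom]
        starts = np.arange(0, length, window)
        ends = np.minimum(starts + window, length)
        mean = np.full(starts.shape, base_depth, dtype=float)
        for iv, kind in implants:
            if iv.chrom != chrom:
                continue
            mask = (starts >= iv.start) & (ends <= iv.end)
            mean[mask] = base_depth * (
                dup_multiplier if kind == "dup" else del_multiplier
            )
        depth = mean if noise_sd == 0 else np.clip(
            rng.normal(mean, noise_sd), 0.0, None
        )
        for s, e, d in zip(starts, ends, depth):
            rows.append((chrom, int(s), int(e), float(d)))
    track = DepthTrack(
        pd.DataFrame(rows, columns=["chrom", "start", "end", "depth"]), window
    )
    truth = SimTruth(
        implanted_segments=[(iv, kind) for iv, kind in implants],
        true_params={
            "base_depth": base_depth,
            "noise_sd": noise_sd,
            "dup_multiplier": dup_multiplier,
            "del_multiplier": del_multiplier,
        },
    )
    return track, truth


# ---------------------------------------------------------------------------
# PAV matrices
# ---------------------------------------------------------------------------

def make_pav_matrix(
    n_pavs: int,
    samples_A: Sequence[str],
    samples_B: Sequence[str],
    frac_differentiated: float,
    missing_rate: float,
    seed: int,
    chrom: str = "chr1",
    min_len: int = 50,
    max_len: int = 5000,
) -> Tuple[PavTable, SimTruth]:
    """Simulate a PAV genotype matrix with two-lineage structure.

    A ``frac_differentiated`` fraction of records is fixed present in one
    lineage and absent in the other (direction by fair coin). Remaining
    records share one presence probability (uniform per record) across all
    samples; genotype draws that would mimic a fixed inter-lineage
    difference are redrawn so the truth set is exact. Genotypes are then
    masked to MISSING at ``missing_rate``.
    """
    if set(samples_A) & set(samples_B):
        raise ParameterError("sample lists must be disjoint")
    if not (0 <= frac_differentiated <= 1) or not (0 <= missing_rate <= 1):
        raise ParameterError("rates must be in [0, 1]")
    rng = np.random.default_rng(seed)
    samples = list(samples_A) + list(samples_B)
    nA, nB = len(samples_A), len(samples_B)

    n_diff = int(round(n_pavs * frac_differentiated))
    diff_idx = set(rng.choice(n_pavs, size=n_diff, replace=False).tolist())

    geno = np.empty((n_pavs, nA + nB), dtype=np.int8)
    for i in range(n_pavs):
        if i in diff_idx:
            present_in_A = bool(rng.integers(2))
            geno[i, :nA] = PRESENT if present_in_A else ABSENT
            geno[i, nA:] = ABSENT if present_in_A else PRESENT
        else:
            p_present = rng.uniform()
            while True:
                row = (rng.uniform(size=nA + nB) < p_present).astype(np.int8)
                fa, fb = row[:nA].mean(), row[nA:].mean()
                if not ((fa == 1 and fb == 0) or (fa == 0 and fb == 1)):
                    break
            geno[i] = row
    if missing_rate > 0:
        mask = rng.uniform(size=geno.shape) < missing_rate
        geno[mask] = MISSING

    # backbone coordinates: spaced, non-overlapping records
    svlen = rng.integers(min_len, max_len + 1, size=n_pavs)
    svtype = np.where(rng.integers(2, size=n_pavs) == 0, "DEL", "INS")
    gaps = rng.integers(100, 10_000, size=n_pavs)
    starts = np.cumsum(gaps + np.where(svtype == "DEL", svlen, 1)) - np.where(
        svtype == "DEL", svlen, 1
    )
    ends = starts + np.where(svtype == "DEL", svlen, 1)
    ids = [f"pav{i:07d}" for i in range(n_pavs)]
    records = pd.DataFrame(
        {
            "id": ids,
            "chrom": chrom,
            "start": starts.astype(int),
            "end": ends.astype(int),
            "svtype": svtype,
            "svlen": svlen.astype(int),
        }
    )
    genotypes = pd.DataFrame(geno, index=pd.Index(ids, name="id"), columns=samples)
    table = PavTable(records, genotypes)
    truth = SimTruth(
        differentiated_pavs={ids[i] for i in diff_idx},
        true_params={
            "frac_differentiated": frac_differentiated,
            "missing_rate": missing_rate,
        },
    )
    return table, truth


# ---------------------------------------------------------------------------
# homeolog counts
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB draws parameterized by mean and dispersion (var = m + a m^2)."""
    if dispersion == 0:
        return rng.poisson(mean)
    size_param = 1.0 / dispersion
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p)


def make_homeolog_counts(
    n_pairs: int,
    n_tissues: int,
    n_reps: int,
    frac_biased: float,
    bias_log2fc: float,
    nb_dispersion: float,
    mean_log_range: Tuple[float, float] = (np.log(5.0), np.log(500.0)),
    seed: int = 0,
    n_chrom_pairs: int = 24,
) -> Tuple[CountMatrix, HomeologPairSet, SimTruth]:
    """Simulate raw homeolog counts with a biased fraction of pairs.

    Each pair draws a base mean (log-uniform over ``mean_log_range``).
    Unbiased pairs share this mean between the A and B homeolog in every
    tissue; biased pairs multiply the B-homeolog mean by
    ``2**bias_log2fc`` in every tissue. Counts are negative binomial with
    dispersion ``nb_dispersion`` (variance m + a m^2); dispersion 0 means
    Poisson.
    """
    if nb_dispersion < 0:
        raise ParameterError("nb_dispersion must be >= 0")
    if nb_dispersion == 0 and frac_biased > 0 and bias_log2fc == 0:
        pass  # degenerate but harmless
    if not (0 <= frac_biased <= 1):
        raise ParameterError("frac_biased must be in [0, 1]")
    if n_reps < 1 or n_tissues < 1 or n_pairs < 1:
        raise ParameterError("n_pairs, n_tissues, n_reps must be >= 1")
    rng = np.random.default_rng(seed)

    tissues = list(DEFAULT_TISSUES[:n_tissues])
    tissues += [f"T{i + 1}" for i in range(len(tissues), n_tissues)]
    sample_names = [f"{t}_r{r + 1}" for t in tissues for r in range(n_reps)]
    sample_sheet = pd.DataFrame(
        {
            "tissue": [t for t in tissues for _ in range(n_reps)],
            "replicate": [r + 1 for _ in tissues for r in range(n_reps)],
        },
        index=pd.Index(sample_names, name="sample"),
    )

    pair_ids = [f"pair{i:06d}" for i in range(n_pairs)]
    genes_A = [f"gA{i:06d}" for i in range(n_pairs)]
    genes_B = [f"gB{i:06d}" for i in range(n_pairs)]
    chrom_pairs = [f"chr{(i % n_chrom_pairs) + 1}A|chr{(i % n_chrom_pairs) + 1}B"
                   for i in range(n_pairs)]
    pairs = HomeologPairSet(
        pd.DataFrame(
            {
                "pair_id": pair_ids,
                "gene_A": genes_A,
                "gene_B": genes_B,
                "chrom_pair": chrom_pairs,
            }
        )
    )

    n_biased = int(round(n_pairs * frac_biased))
    biased_idx = rng.choice(n_pairs, size=n_biased, replace=False)
    biased_mask = np.zeros(n_pairs, dtype=bool)
    biased_mask[biased_idx] = True

    lo, hi = mean_log_range
    base_mean = np.exp(rng.uniform(lo, hi, size=n_pairs))
    mean_A = np.repeat(base_mean[:, None], n_tissues * n_reps, axis=1)
    mean_B = mean_A.copy()
    mean_B[biased_mask] *= 2.0 ** bias_log2fc

    counts_A = _nb_draw(rng, mean_A, nb_dispersion)
    counts_B = _nb_draw(rng, mean_B, nb_dispersion)
    counts = pd.DataFrame(
        np.vstack([counts_A, counts_B]).astype(int),
        index=genes_A + genes_B,
        columns=sample_names,
    )
    cm = CountMatrix(counts, sample_sheet)
    truth = SimTruth(
        biased_pairs={pair_ids[i]: float(bias_log2fc) for i in np.where(biased_mask)[0]},
        true_params={
            "frac_biased": frac_biased,
            "bias_log2fc": bias_log2fc,
            "nb_dispersion": nb_dispersion,
        },
    )
    return cm, pairs, truth


# ---------------------------------------------------------------------------
# sequence pairs
# ---------------------------------------------------------------------------

def make_sequence_pairs(
    n_codons: int,
    n_syn: int,
    n_nonsyn: int,
    seed: int,
) -> Tuple[str, str, SimTruth]:
    """Generate a codon-aligned pair with exact substitution counts.

    Starting from a random stop-free coding sequence, apply exactly
    ``n_syn`` synonymous and ``n_nonsyn`` nonsynonymous single-nucleotide
    changes, each in a distinct codon (so pathway counting has a closed
    truth). Neither sequence contains an internal stop codon.
    """
    if n_syn + n_nonsyn > n_codons:
        raise ParameterError("one change per codon: n_syn + n_nonsyn <= n_codons")
    if n_codons < 1:
        raise ParameterError("n_codons must be >= 1")
    rng = np.random.default_rng(seed)

    non_stop = [c for c in gc.ALL_CODONS if gc.AA[c] != "*"]
    syn_capable = [c for c in non_stop if _has_neighbor(c, synonymous=True)]
    nonsyn_capable = [c for c in non_stop if _has_neighbor(c, synonymous=False)]

    codons = [non_stop[i] for i in rng.integers(len(non_stop), size=n_codons)]
    positions = rng.choice(n_codons, size=n_syn + n_nonsyn, replace=False)
    syn_pos, nonsyn_pos = positions[:n_syn], positions[n_syn:]
    # make sure chosen codons admit the required change type
    for pos in syn_pos:
        if not _has_neighbor(codons[pos], synonymous=True):
            codons[pos] = syn_capable[rng.integers(len(syn_capable))]
    for pos in nonsyn_pos:
        if not _has_neighbor(codons[pos], synonymous=False):
            codons[pos] = nonsyn_capable[rng.integers(len(nonsyn_capable))]

    mutated = list(codons)
    for pos in syn_pos:
        mutated[pos] = _mutate(codons[pos], rng, synonymous=True)
    for pos in nonsyn_pos:
        mutated[pos] = _mutate(codons[pos], rng, synonymous=False)

    truth = SimTruth(
        true_params={"n_syn": n_syn, "n_nonsyn": n_nonsyn, "n_codons": n_codons}
    )
    return "".join(codons), "".join(mutated), truth


def _neighbors(codon: str) -> Iterable[str]:
    for i in range(3):
        for b in "ACGT":
            if b != codon[i]:
                yield codon[:i] + b + codon[i + 1:]


def _has_neighbor(codon: str, synonymous: bool) -> bool:
    for nb in _neighbors(codon):
        if gc.AA[nb] == "*":
            continue
        if (gc.AA[nb] == gc.AA[codon]) == synonymous:
            return True
    return False


def _mutate(codon: str, rng: np.random.Generator, synonymous: bool) -> str:
    options = [
        nb
        for nb in _neighbors(codon)
        if gc.AA[nb] != "*" and (gc.AA[nb] == gc.AA[codon]) == synonymous
    ]
    return options[rng.integers(len(options))]
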