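"""Readers and writers for every on-disk format the pipeline touches.

All other modules consume and produce only the in-memory containers; this
module is the single place where files are parsed or serialized. Formats:

* depth tracks — BED-like TSV ``chrom  start  end  mean_depth``
* gene models — GFF3 (1-based closed on disk, converted here)
* PAV tables — VCF with symbolic ``<INS>``/``<DEL>`` ALTs (via pysam)
* orthogroup matrices — OrthoFinder-style TSV (gene lists or gene counts)
* count matrices, homeolog pairs, interval maps, TE family sizes — TSV
* sequence pairs — FASTA (consecutive records pair up)
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO

from .containers import (
    ABSENT,
    MISSING,
    PRESENT,
    CountMatrix,
    DepthTrack,
    GeneModel,
    HomeologIntervalMap,
    HomeologPairSet,
    OrthogroupMatrix,
    PavTable,
    TeFamilyTable,
)
from .errors import FormatError
from .intervals import GenomicInterval

logger = logging.getLogger("panploid")


def setup_logging(level: int = logging.INFO) -> None:
    """Configure package logging to stderr (idempotent)."""
    root = logging.getLogger("panploid")
    if not root.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
        )
        root.addHandler(handler)
    root.setLevel(level)


# ---------------------------------------------------------------------------
# depth BED
# ---------------------------------------------------------------------------

def read_depth_bed(path: str | Path, window_size: int) -> DepthTrack:
    """Read a windowed mean-depth track from a BED-like TSV.

    Windows must be sorted by (chrom, start) and non-overlapping; every
    width must equal ``window_size`` except possibly the last window on
    each chromosome. Errors name the first offending line.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 tab-separated fields")
            chrom, start_s, end_s, depth_s = parts[:4]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
            try:
                depth = float(depth_s)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-numeric depth {depth_s!r}") from None
            if end <= start:
                raise FormatError(f"{path}:{lineno}: end <= start")
            if depth < 0:
                raise FormatError(f"{path}:{lineno}: negative depth")
            rows.append((lineno, chrom, start, end, depth))
    if not rows:
        raise FormatError(f"{path}: empty depth track")

    seen_done: Dict[str, bool] = {}
    prev_chrom: Optional[str] = None
    prev_end = 0
    prev_width_short_line: Optional[int] = None
    for lineno, chrom, start, end, _ in rows:
        if chrom != prev_chrom:
            if seen_done.get(chrom):
                raise FormatError(f"{path}:{lineno}: windows not grouped by chromosome")
            if prev_chrom is not None:
                seen_done[prev_chrom] = True
            prev_chrom, prev_end = chrom, 0
            prev_width_short_line = None
        if start < prev_end:
            raise FormatError(f"{path}:{lineno}: overlapping or unsorted windows")
        if prev_width_short_line is not None:
            # a short (non-window_size) window may only be the last per chrom
            raise FormatError(
                f"{path}:{prev_width_short_line}: window width != {window_size} "
                "before the last window of its chromosome"
            )
        if end - start != window_size:
            prev_width_short_line = lineno
        prev_end = end

    df = pd.DataFrame(
        [(c, s, e, d) for _, c, s, e, d in rows],
        columns=["chrom", "start", "end", "depth"],
    )
    return DepthTrack(df, window_size)


def write_depth_bed(track: DepthTrack, path: str | Path) -> None:
    track.windows.to_csv(
        path, sep="\t", header=False, index=False, float_format="%.6g"
    )


# ---------------------------------------------------------------------------
# GFF3 genes
# ---------------------------------------------------------------------------

def read_gff3_genes(path: str | Path) -> List[GeneModel]:
    """Extract ``gene`` records from a GFF3 file.

    GFF3 stores 1-based closed coordinates; the returned intervals are
    0-based half-open. Non-gene feature types are skipped (with a warning
    if the file contained features but no genes).
    """
    genes: List[GeneModel] = []
    n_features = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GFF3 columns")
            chrom, _, ftype, start_s, end_s, _, strand, _, attrs = parts
            n_features += 1
            if ftype != "gene":
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
            gene_id = None
            for item in attrs.split(";"):
                item = item.strip()
                if item.startswith("ID="):
                    gene_id = item[3:]
                    break
            if not gene_id:
                raise FormatError(f"{path}:{lineno}: gene record lacks ID attribute")
            if strand not in ("+", "-", "."):
                strand = "."
            genes.append(
                GeneModel(gene_id, GenomicInterval(chrom, start1 - 1, end1, strand))
            )
    if n_features and not genes:
        logger.warning("%s: no 'gene' features among %d records", path, n_features)
    return genes


def write_gff3_genes(genes: List[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            iv = g.interval
            fh.write(
                f"{iv.chrom}\tpanploid\tgene\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand if iv.strand != '.' else '.'}\t.\tID={g.id}\n"
            )


# ---------------------------------------------------------------------------
# PAV VCF
# ---------------------------------------------------------------------------

_GT_TO_CODE = {
    (1, 1): PRESENT,
    (1,): PRESENT,
    (0, 1): PRESENT,
    (1, 0): PRESENT,
    (0, 0): ABSENT,
    (0,): ABSENT,
}


def read_pav_vcf(path: str | Path, min_len: int = 50) -> PavTable:
    """Read symbolic INS/DEL records with per-sample presence genotypes.

    Records with ``|SVLEN| < min_len`` are dropped. Genotypes map to
    PRESENT (any ALT allele), ABSENT (hom-ref) or MISSING.
    """
    vcf = pysam.VariantFile(str(path))
    samples = list(vcf.header.samples)
    rec_rows = []
    geno_rows = []
    n_dropped = 0
    for rec in vcf:
        if "SVTYPE" not in rec.info:
            raise FormatError(f"{path}: record {rec.id or rec.pos} lacks SVTYPE")
        if "SVLEN" not in rec.info:
            raise FormatError(f"{path}: record {rec.id or rec.pos} lacks SVLEN")
        svtype = rec.info["SVTYPE"]
        svlen_raw = rec.info["SVLEN"]
        if isinstance(svlen_raw, tuple):
            svlen_raw = svlen_raw[0]
        svlen = abs(int(svlen_raw))
        if svtype not in ("INS", "DEL"):
            raise FormatError(f"{path}: unsupported SVTYPE {svtype!r}")
        if svlen < min_len:
            n_dropped += 1
            continue
        start = rec.start  # pysam is already 0-based
        end = start + svlen if svtype == "DEL" else start + 1
        rec_id = rec.id or f"{svtype}_{rec.chrom}_{start}"
        codes = []
        for s in samples:
            gt = rec.samples[s].get("GT")
            if gt is None or any(a is None for a in gt):
                codes.append(MISSING)
            else:
                codes.append(_GT_TO_CODE.get(tuple(gt), MISSING))
        rec_rows.append((rec_id, rec.chrom, start, end, svtype, svlen))
        geno_rows.append(codes)
    vcf.close()
    if n_dropped:
        logger.info("%s: dropped %d records with SVLEN < %d", path, n_dropped, min_len)
    records = pd.DataFrame(
        rec_rows, columns=["id", "chrom", "start", "end", "svtype", "svlen"]
    )
    genotypes = pd.DataFrame(
        geno_rows, columns=samples, index=records["id"], dtype=np.int8
    )
    return PavTable(records, genotypes)


_CODE_TO_GT = {PRESENT: (1, 1), ABSENT: (0, 0), MISSING: (None, None)}


def write_pav_vcf(
    table: PavTable, path: str | Path, contig_lengths: Optional[Dict[str, int]] = None
) -> None:
    header = pysam.VariantHeader()
    chroms = list(dict.fromkeys(table.records["chrom"]))
    if contig_lengths is None:
        contig_lengths = {}
        for chrom in chroms:
            sub = table.records[table.records["chrom"] == chrom]
            contig_lengths[chrom] = int(sub["end"].max()) + 1
    for chrom in chroms:
        header.contigs.add(chrom, length=contig_lengths[chrom])
    header.info.add("SVTYPE", 1, "String", "Structural variant type")
    header.info.add("SVLEN", 1, "Integer", "Structural variant length (bp)")
    header.formats.add("GT", 1, "String", "Genotype (presence of the variant)")
    for s in table.samples:
        header.add_sample(s)
    out = pysam.VariantFile(str(path), "w", header=header)
    for _, row in table.records.iterrows():
        rec = out.new_record(
            contig=row["chrom"],
            start=int(row["start"]),
            stop=int(row["end"]),
            alleles=("N", f"<{row['svtype']}>"),
            id=row["id"],
        )
        rec.info["SVTYPE"] = row["svtype"]
        rec.info["SVLEN"] = int(row["svlen"])
        for s in table.samples:
            rec.samples[s]["GT"] = _CODE_TO_GT[int(table.genotypes.at[row["id"], s])]
        out.write(rec)
    out.close()


# ---------------------------------------------------------------------------
# orthogroup TSV
# ---------------------------------------------------------------------------

def read_orthogroups(path: str | Path) -> OrthogroupMatrix:
    """Read an OrthoFinder-style orthogroup table.

    Accepts either a gene-count table (``Orthogroups.GeneCount.tsv``; a
    trailing ``Total`` column is ignored) or a gene-membership table in
    which each cell lists comma-separated gene IDs. The first column is
    the cluster ID.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    if df.columns.size and df.columns[-1].lower() == "total":
        df = df.iloc[:, :-1]
    if df.columns.empty:
        raise FormatError(f"{path}: no accession columns")

    def cell_count(v: str) -> int:
        v = v.strip()
        if not v:
            return 0
        try:
            return int(v)
        except ValueError:
            return len([g for g in v.split(",") if g.strip()])

    counts = df.map(cell_count).astype(int)
    counts.index.name = None  # in-memory convention: unnamed axes
    return OrthogroupMatrix(counts)


def write_orthogroups(matrix: OrthogroupMatrix, path: str | Path) -> None:
    out = matrix.counts.copy()
    out["Total"] = out.sum(axis=1)
    out.to_csv(path, sep="\t", index_label="Orthogroup")


# ---------------------------------------------------------------------------
# expression TSV
# ---------------------------------------------------------------------------

def read_counts(counts_path: str | Path, samples_path: str | Path) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    counts.index.name = None
    samples = pd.read_csv(samples_path, sep="\t", index_col=0)
    samples = samples.loc[counts.columns]
    return CountMatrix(counts, samples)


def write_counts(cm: CountMatrix, counts_path: str | Path, samples_path: str | Path) -> None:
    cm.counts.to_csv(counts_path, sep="\t", index_label="gene")
    cm.samples.to_csv(samples_path, sep="\t", index_label="sample")


def read_homeolog_pairs(path: str | Path) -> HomeologPairSet:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return HomeologPairSet(df)


def write_homeolog_pairs(pairs: HomeologPairSet, path: str | Path) -> None:
    pairs.pairs.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# homeolog interval map TSV
# ---------------------------------------------------------------------------

def read_interval_map(path: str | Path) -> HomeologIntervalMap:
    """TSV: chromA startA endA chromB startB endB (0-based half-open)."""
    df = pd.read_csv(
        path,
        sep="\t",
        names=["chromA", "startA", "endA", "chromB", "startB", "endB"],
        comment="#",
    )
    blocks = [
        (
            GenomicInterval(r.chromA, int(r.startA), int(r.endA)),
            GenomicInterval(r.chromB, int(r.startB), int(r.endB)),
        )
        for r in df.itertuples()
    ]
    return HomeologIntervalMap(blocks)


def write_interval_map(imap: HomeologIntervalMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for a, b in imap.blocks:
            fh.write(f"{a.chrom}\t{a.start}\t{a.end}\t{b.chrom}\t{b.start}\t{b.end}\n")


# ---------------------------------------------------------------------------
# TE family sizes
# ---------------------------------------------------------------------------

def read_te_table(sizes_path: str | Path, lineage_path: str | Path) -> TeFamilyTable:
    """Sizes TSV: family x genome bp totals; lineage TSV: genome, lineage."""
    sizes = pd.read_csv(sizes_path, sep="\t", index_col=0)
    lin = pd.read_csv(lineage_path, sep="\t", index_col=0)
    lineage = {g: str(lin.iloc[:, 0][g]) for g in lin.index}
    return TeFamilyTable(sizes, lineage)


# ---------------------------------------------------------------------------
# FASTA sequence pairs
# ---------------------------------------------------------------------------

def read_sequence_pairs(path: str | Path) -> List[Tuple[str, str, str]]:
    """Read an even-length FASTA; consecutive records form aligned pairs.

    Returns (pair_name, seq1, seq2) with pair_name taken from the first
    record of each pair.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) % 2 != 0:
        raise FormatError(f"{path}: odd number of sequences; expected pairs")
    out = []
    for i in range(0, len(records), 2):
        a, b = records[i], records[i + 1]
        out.append((a.id, str(a.seq).upper(), str(b.seq).upper()))
    return out


def write_sequence_pairs(
    pairs: List[Tuple[str, str, str]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for name, s1, s2 in pairs:
            fh.write(f">{name}_1\n{s1}\n>{name}_2\n{s2}\n")
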