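"""5' tRNA-half / YRNA-fragment calling from aligned small-RNA reads.

Circulating tRNA- and YRNA-derived small RNAs are overwhelmingly 30-34 nt
long and anchored at the 5' terminus of their parent gene.  This module
implements the corresponding read filter: a read is counted toward a locus
iff its length is within [30, 34], its strand matches the locus, and its
biological 5' terminus lies within ``tol`` nt of the locus 5' terminus
(plus-strand locus: 5' = start; minus-strand locus: 5' = end).

Conventions
-----------
* Coordinates are 1-based inclusive internally (the convention of printed
  tRNA gene tables); BED input (0-based half-open) and SAM input are
  converted on read.
* A read counts once toward EVERY locus whose 5' end it matches
  (per-locus counting; identical paralogs each receive the read).
* Bookkeeping is conserved: assigned + rejected = input reads, per sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FragmentCounts",
    "read_annotation",
    "read_alignments_bed",
    "read_alignments_sam",
    "classify_read",
    "count_fragments",
    "five_prime_fraction",
    "align_exact",
]

MIN_LEN = 30
MAX_LEN = 34

ANNOTATION_COLUMNS = ["locus_id", "chrom", "start", "end", "strand", "gene_class"]
READ_COLUMNS = ["read_id", "chrom", "start", "end", "strand", "length", "sample_id"]
REJECT_REASONS = ("length", "no_overlap", "strand", "position")


@dataclass
class FragmentCounts:
    """Per-locus x per-sample 5' fragment counts with QC bookkeeping."""

    counts: pd.DataFrame  # loci x samples, nonnegative ints
    library_sizes: pd.Series  # per-sample assigned-read totals (column sums)
    rejections: pd.DataFrame  # samples x rejection reason tallies
    n_input: pd.Series  # per-sample input read totals

    def conserved(self) -> bool:
        assigned = self.rejections["assigned"]
        rejected = self.rejections[list(REJECT_REASONS)].sum(axis=1)
        return bool(((assigned + rejected) == self.n_input).all())


def _validate_annotation(ann: pd.DataFrame) -> pd.DataFrame:
    if ann is None or len(ann) == 0:
        raise ValueError("annotation must be non-empty")
    missing = [c for c in ANNOTATION_COLUMNS[:5] if c not in ann.columns]
    if missing:
        raise ValueError(f"annotation missing columns: {missing}")
    if ann["locus_id"].duplicated().any():
        dup = ann.loc[ann["locus_id"].duplicated(), "locus_id"].iloc[0]
        raise ValueError(f"duplicate locus_id in annotation: {dup!r}")
    if (ann["start"] > ann["end"]).any():
        raise ValueError("annotation has start > end")
    if not ann["strand"].isin(["+", "-"]).all():
        raise ValueError("annotation strand must be '+' or '-'")
    return ann


def read_annotation(path) -> pd.DataFrame:
    """Read a BED-like TSV annotation (1-based inclusive coordinates).

    Expected columns: locus_id, chrom, start, end, strand and optionally
    gene_class (tRNA | YRNA).
    """
    ann = pd.read_csv(path, sep="\t", comment="#")
    if "gene_class" not in ann.columns:
        ann["gene_class"] = "tRNA"
    return _validate_annotation(ann)


def read_alignments_bed(path, sample_id: str | None = None) -> pd.DataFrame:
    """Read 6-column BED alignments (0-based half-open -> 1-based inclusive).

    The BED name field is the read id; an optional 7th column holds the
    sample id unless ``sample_id`` is given.
    """
    bed = pd.read_csv(path, sep="\t", header=None, comment="#")
    if bed.shape[1] < 6:
        raise ValueError("need at least 6 BED columns (chrom start end name score strand)")
    reads = pd.DataFrame(
        {
            "read_id": bed[3],
            "chrom": bed[0],
            "start": bed[1] + 1,
            "end": bed[2],
            "strand": bed[5],
        }
    )
    reads["length"] = reads["end"] - reads["start"] + 1
    if sample_id is not None:
        reads["sample_id"] = sample_id
    elif bed.shape[1] >= 7:
        reads["sample_id"] = bed[6]
    else:
        raise ValueError("sample_id missing: pass sample_id= or a 7th BED column")
    return reads[READ_COLUMNS]


def read_alignments_sam(path, sample_id: str | None = None) -> pd.DataFrame:
    """Read mapped reads from SAM/BAM via pysam; sample id from the RG tag
    or the ``sample_id`` argument."""
    import pysam

    rows = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh.fetch(until_eof=True):
            if aln.is_unmapped:
                continue
            sid = sample_id
            if sid is None:
                if aln.has_tag("RG"):
                    sid = aln.get_tag("RG")
                else:
                    raise ValueError(
                        f"sample_id missing for read {aln.query_name!r}: "
                        "no RG tag and no sample_id argument"
                    )
            rows.append(
                {
                    "read_id": aln.query_name,
                    "chrom": aln.reference_name,
                    "start": aln.reference_start + 1,
                    "end": aln.reference_end,
                    "strand": "-" if aln.is_reverse else "+",
                    "length": aln.reference_end - aln.reference_start,
                    "sample_id": sid,
                }
            )
    return pd.DataFrame(rows, columns=READ_COLUMNS)


def _locus_five_prime(ann: pd.DataFrame) -> np.ndarray:
    return np.where(ann["strand"].to_numpy() == "+", ann["start"].to_numpy(), ann["end"].to_numpy())


def _read_five_prime(reads: pd.DataFrame) -> np.ndarray:
    return np.where(
        reads["strand"].to_numpy() == "+", reads["start"].to_numpy(), reads["end"].to_numpy()
    )


def classify_read(read, ann: pd.DataFrame, tol: int = 0):
    """Classify one aligned read against the annotation.

    ``read`` is a mapping with chrom/start/end/strand (1-based inclusive).
    Returns ``("assigned", [locus_id, ...])`` with every matching locus, or
    ``("rejected", reason)`` with reason in {length, no_overlap, strand,
    position}.  Rejection reasons are assessed in that order.
    """
    _validate_annotation(ann)
    start, end = int(read["start"]), int(read["end"])
    if end < start:
        raise ValueError(f"malformed read: end {end} < start {start}")
    length = end - start + 1
    if not MIN_LEN <= length <= MAX_LEN:
        return "rejected", "length"
    on_chrom = ann[ann["chrom"] == read["chrom"]]
    overlap = on_chrom[(on_chrom["start"] <= end) & (on_chrom["end"] >= start)]
    if len(overlap) == 0:
        return "rejected", "no_overlap"
    same_strand = overlap[overlap["strand"] == read["strand"]]
    if len(same_strand) == 0:
        return "rejected", "strand"
    read5 = start if read["strand"] == "+" else end
    locus5 = _locus_five_prime(same_strand)
    hit = same_strand.loc[np.abs(locus5 - read5) <= tol, "locus_id"].tolist()
    if not hit:
        return "rejected", "position"
    return "assigned", hit


def count_fragments(reads: pd.DataFrame, ann: pd.DataFrame, tol: int = 0) -> FragmentCounts:
    """Count accepted 5' fragments per locus per sample (vectorized).

    Each accepted read increments every matching locus by one in its
    sample's column; rejected reads are tallied by reason per sample.
    """
    _validate_annotation(ann)
    if "sample_id" not in reads.columns or reads["sample_id"].isna().any():
        raise ValueError("every read needs a sample_id")
    samples = sorted(pd.unique(reads["sample_id"].astype(str)))
    loci = ann["locus_id"].tolist()
    counts = pd.DataFrame(
        0, index=pd.Index(loci, name="locus_id"), columns=samples, dtype=np.int64
    )
    rejections = pd.DataFrame(
        0, index=pd.Index(samples, name="sample_id"),
        columns=["assigned", *REJECT_REASONS], dtype=np.int64,
    )
    n_input = reads.groupby("sample_id").size().reindex(samples, fill_value=0)
    if len(reads) == 0:
        return FragmentCounts(counts, counts.sum(axis=0), rejections, n_input)
    if (reads["end"] < reads["start"]).any():
        raise ValueError("malformed read: end < start")

    length = (reads["end"] - reads["start"] + 1).to_numpy()
    len_ok = (length >= MIN_LEN) & (length <= MAX_LEN)
    read5 = _read_five_prime(reads)
    locus5 = _locus_five_prime(ann)
    ann_chrom = ann["chrom"].to_numpy()
    ann_strand = ann["strand"].to_numpy()
    ann_start = ann["start"].to_numpy()
    ann_end = ann["end"].to_numpy()

    r_chrom = reads["chrom"].to_numpy()
    r_strand = reads["strand"].to_numpy()
    r_start = reads["start"].to_numpy()
    r_end = reads["end"].to_numpy()
    r_sample = reads["sample_id"].astype(str).to_numpy()
    sample_pos = {s: i for i, s in enumerate(samples)}
    s_idx = np.fromiter((sample_pos[s] for s in r_sample), count=len(reads), dtype=np.int64)

    cmat = counts.to_numpy()
    rej = rejections.to_numpy()
    col = {c: i for i, c in enumerate(rejections.columns)}

    np.add.at(rej[:, col["length"]], s_idx[~len_ok], 1)

    # loci sets are small: broadcast reads x loci per chromosome
    idx_ok = np.nonzero(len_ok)[0]
    for chrom in np.unique(ann_chrom):
        lmask = ann_chrom == chrom
        l5 = locus5[lmask]
        lst, lend, lstr = ann_start[lmask], ann_end[lmask], ann_strand[lmask]
        lpos = np.nonzero(lmask)[0]
        rsel = idx_ok[r_chrom[idx_ok] == chrom]
        if len(rsel) == 0:
            continue
        ov = (r_start[rsel][:, None] <= lend[None, :]) & (r_end[rsel][:, None] >= lst[None, :])
        strand_match = r_strand[rsel][:, None] == lstr[None, :]
        anchor = np.abs(read5[rsel][:, None] - l5[None, :]) <= tol
        match = strand_match & anchor
        any_ov = ov.any(axis=1)
        any_strand = (ov & strand_match).any(axis=1)
        any_match = match.any(axis=1)
        np.add.at(rej[:, col["no_overlap"]], s_idx[rsel[~any_ov]], 1)
        np.add.at(rej[:, col["strand"]], s_idx[rsel[any_ov & ~any_strand]], 1)
        np.add.at(rej[:, col["position"]], s_idx[rsel[any_ov & any_strand & ~any_match]], 1)
        np.add.at(rej[:, col["assigned"]], s_idx[rsel[any_match]], 1)
        ri, li = np.nonzero(match)
        np.add.at(cmat, (lpos[li], s_idx[rsel[ri]]), 1)

    # length-passing reads on chromosomes with no annotated locus at all
    ann_chroms = set(np.unique(ann_chrom))
    off = idx_ok[~np.isin(r_chrom[idx_ok], list(ann_chroms))]
    np.add.at(rej[:, col["no_overlap"]], s_idx[off], 1)

    counts.iloc[:, :] = cmat
    rejections.iloc[:, :] = rej
    return FragmentCounts(counts, counts.sum(axis=0), rejections, n_input)


def five_prime_fraction(
    reads: pd.DataFrame, ann: pd.DataFrame, gene_class: str, tol: int = 0
) -> float:
    """Fraction of 30-34 nt reads over ``gene_class`` loci that are 5'-anchored.

    The denominator is every 30-34 nt read overlapping a locus of the class
    on the matching strand; the numerator restricts to reads whose 5'
    terminus lies within ``tol`` nt of the locus 5' terminus.
    """
    _validate_annotation(ann)
    sub = ann[ann["gene_class"] == gene_class]
    if len(sub) == 0:
        raise ValueError(f"no loci of class {gene_class!r} in annotation")
    length = (reads["end"] - reads["start"] + 1).to_numpy()
    len_ok = (length >= MIN_LEN) & (length <= MAX_LEN)
    read5 = _read_five_prime(reads)
    locus5 = _locus_five_prime(sub)
    n_den = 0
    n_num = 0
    for chrom in sub["chrom"].unique():
        lmask = (sub["chrom"] == chrom).to_numpy()
        rmask = len_ok & (reads["chrom"] == chrom).to_numpy()
        if not rmask.any():
            continue
        lst = sub["start"].to_numpy()[lmask]
        lend = sub["end"].to_numpy()[lmask]
        lstr = sub["strand"].to_numpy()[lmask]
        l5 = locus5[lmask]
        rs = reads["start"].to_numpy()[rmask]
        re = reads["end"].to_numpy()[rmask]
        rstr = reads["strand"].to_numpy()[rmask]
        r5 = read5[rmask]
        ov = (rs[:, None] <= lend[None, :]) & (re[:, None] >= lst[None, :])
        ov &= rstr[:, None] == lstr[None, :]
        anchored = ov & (np.abs(r5[:, None] - l5[None, :]) <= tol)
        in_den = ov.any(axis=1)
        n_den += int(in_den.sum())
        n_num += int((anchored.any(axis=1) & in_den).sum())
    if n_den == 0:
        raise ValueError(f"no qualifying 30-34 nt reads over {gene_class!r} loci")
    return n_num / n_den


def align_exact(
    reads: dict[str, str] | str,
    reference: dict[str, str] | str,
    ann: pd.DataFrame,
    sample_id: str = "S1",
) -> tuple[pd.DataFrame, int]:
    """Place reads by exact substring match against locus reference sequences.

    ``reads`` and ``reference`` are FASTA paths or {id: sequence} dicts;
    reference ids are locus_ids and must be unique.  A read is placed at the
    first exact occurrence within each matching reference (one placement per
    reference; identical paralogous references each yield a placement).
    Locus-relative offsets are converted to genomic coordinates via the
    annotation, honouring strand.  Returns ``(aligned_reads, n_unaligned)``.
    """
    _validate_annotation(ann)

    def _load(src) -> dict[str, str]:
        if isinstance(src, dict):
            return {str(k): str(v).upper() for k, v in src.items()}
        from Bio import SeqIO

        out: dict[str, str] = {}
        for rec in SeqIO.parse(str(src), "fasta"):
            if rec.id in out:
                raise ValueError(f"duplicate sequence id {rec.id!r}")
            out[rec.id] = str(rec.seq).upper()
        return out

    refs = _load(reference)
    if isinstance(reference, dict) and len(set(refs)) != len(refs):
        raise ValueError("duplicate locus_ids in reference")
    queries = _load(reads)
    ann_by_id = ann.set_index("locus_id")
    rows = []
    n_unaligned = 0
    for rid, seq in queries.items():
        placed = False
        for locus_id, ref_seq in refs.items():
            off = ref_seq.find(seq)
            if off < 0 or locus_id not in ann_by_id.index:
                continue
            locus = ann_by_id.loc[locus_id]
            if locus["strand"] == "+":
                start = int(locus["start"]) + off
                end = start + len(seq) - 1
            else:
                end = int(locus["end"]) - off
                start = end - len(seq) + 1
            rows.append(
                {
                    "read_id": rid,
                    "chrom": locus["chrom"],
                    "start": start,
                    "end": end,
                    "strand": locus["strand"],
                    "length": len(seq),
                    "sample_id": sample_id,
                }
            )
            placed = True
        if not placed:
            n_unaligned += 1
    return pd.DataFrame(rows, columns=READ_COLUMNS), n_unaligned
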