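"""Genotyping of TE insertion polymorphisms from short paired-end reads.

For every TIP locus a *presence construct* (up to 1 kb of left flank + TE +
up to 1 kb of right flank) and a companion *absence construct* (the two
flanks joined directly) are built.  Reads are mapped to both; genotype calls
follow the mapping patterns:

* presence evidence - a read spanning either TE junction with at least
  ``min_aln`` bases on both sides, or a pair with one mate in a flank and the
  other inside the TE;
* absence evidence - a read spanning the flank-flank junction of the absence
  construct, or a pair with mates in opposite flanks whose implied fragment is
  consistent with no intervening TE.

CC = homozygous TE presence, GG = absence, CG = heterozygous (both evidence
classes at a balanced ratio), NN = insufficient evidence.

The built-in mapper uses exact k-mer seeding with banded local extension
under the same scoring as the classifier's aligner; external SAM alignments
can be ingested instead.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from ._util import revcomp
from .align import make_aligner

DEFAULT_MIN_ALN = 20
DEFAULT_K = 21
DEFAULT_SEED_STRIDE = 13


@dataclass(frozen=True)
class LocusConstruct:
    """Mapping target for one TIP locus: left flank + TE + right flank."""

    locus_id: str
    sequence: str
    left_flank_len: int
    te_length: int
    right_flank_len: int

    def __post_init__(self):
        if self.te_length <= 0:
            raise ValueError(f"{self.locus_id}: TE sequence is empty")
        if len(self.sequence) != self.left_flank_len + self.te_length + self.right_flank_len:
            raise ValueError(f"{self.locus_id}: construct length mismatch")

    @property
    def junctionL(self) -> int:
        return self.left_flank_len

    @property
    def junctionR(self) -> int:
        return self.left_flank_len + self.te_length

    @property
    def absence_sequence(self) -> str:
        """The TE-absent allele: the two flanks joined directly."""
        return self.sequence[: self.junctionL] + self.sequence[self.junctionR :]

    @property
    def junctionA(self) -> int:
        """Flank-flank junction offset on the absence sequence."""
        return self.left_flank_len


def build_locus_construct(
    locus_id: str,
    contig_seq: str,
    position: int,
    te_sequence: str,
    flank: int = 1000,
) -> LocusConstruct:
    """Extract up to ``flank`` bp on each side of the insertion point.

    Flanks are truncated (never padded) at contig ends and the realized
    lengths recorded.
    """
    if not te_sequence:
        raise ValueError(f"{locus_id}: TE sequence is empty")
    if not 0 <= position <= len(contig_seq):
        raise ValueError(f"{locus_id}: position {position} outside contig")
    left = contig_seq[max(0, position - flank) : position]
    right = contig_seq[position : position + flank]
    return LocusConstruct(
        locus_id=locus_id,
        sequence=left + te_sequence + right,
        left_flank_len=len(left),
        te_length=len(te_sequence),
        right_flank_len=len(right),
    )


@dataclass
class ReadAlignment:
    """Placement of one read on one construct sequence.

    ``aln_length`` counts matched bases; the aligned interval is
    [astart, aend) on the construct.
    """

    read_id: str
    mate: int
    construct_key: tuple[str, str]  # (locus_id, "P"|"A")
    astart: int
    aend: int
    aln_length: int
    n_mismatch: int
    strand: str = "+"
    mapped: bool = True


class ConstructIndex:
    """Exact k-mer index over construct sequences with banded local extension.

    Seeding finds candidate (construct, diagonal) placements; each candidate
    is scored by ungapped comparison on the diagonal, falling back to an
    affine-gap local alignment of the read against a construct window when the
    diagonal placement looks poor (the banded extension path).
    """

    def __init__(
        self,
        constructs: list[LocusConstruct],
        *,
        k: int = DEFAULT_K,
        stride: int = DEFAULT_SEED_STRIDE,
        min_aln: int = DEFAULT_MIN_ALN,
        max_kmer_occ: int = 16,
        scoring: dict | None = None,
        gapped_rescue: bool = False,
    ):
        self.gapped_rescue = gapped_rescue
        self.constructs = constructs
        self.k = k
        self.stride = stride
        self.min_aln = min_aln
        self._aligner = make_aligner(scoring)
        self.keys: list[tuple[str, str]] = []
        self.seqs: list[bytes] = []
        for c in constructs:
            self.keys.append((c.locus_id, "P"))
            self.seqs.append(c.sequence.encode())
            self.keys.append((c.locus_id, "A"))
            self.seqs.append(c.absence_sequence.encode())
        index: dict[bytes, list[tuple[int, int]]] = defaultdict(list)
        for ci, seq in enumerate(self.seqs):
            for pos in range(0, len(seq) - k + 1):
                entry = index[seq[pos : pos + k]]
                if len(entry) < max_kmer_occ:
                    entry.append((ci, pos))
        self.index = dict(index)

    # -- per-read mapping ---------------------------------------------------

    def _candidates(self, read: bytes):
        """Yield (construct_idx, diagonal) candidates for one orientation."""
        k, stride = self.k, self.stride
        n = len(read) - k
        if n < 0:
            return ()
        seen = set()
        positions = list(range(0, n + 1, stride))
        if positions[-1] != n:
            positions.append(n)
        for p in positions:
            hits = self.index.get(read[p : p + k])
            if hits:
                for ci, cpos in hits:
                    seen.add((ci, cpos - p))
        return seen

    def _eval_diagonal(self, read: bytes, ci: int, diag: int):
        """Ungapped comparison of the read on one construct diagonal."""
        cseq = self.seqs[ci]
        astart = max(0, diag)
        aend = min(len(cseq), diag + len(read))
        if aend - astart <= self.min_aln:
            return None
        rs, re = astart - diag, aend - diag
        a = read[rs:re]
        b = cseq[astart:aend]
        if a == b:
            mism = 0
        else:
            mism = int(
                np.count_nonzero(
                    np.frombuffer(a, dtype=np.uint8) != np.frombuffer(b, dtype=np.uint8)
                )
            )
        overlap = aend - astart
        matched = overlap - mism
        if matched < 0.8 * overlap:
            # trim to the best-scoring contiguous segment on the diagonal
            # (match +1 / mismatch -2), the ungapped analogue of local
            # alignment; handles reads that only half-belong to this allele
            eq = np.frombuffer(a, dtype=np.uint8) == np.frombuffer(b, dtype=np.uint8)
            score = np.where(eq, 1.0, -2.0)
            prefix = np.concatenate(([0.0], np.cumsum(score)))
            run_min = np.minimum.accumulate(prefix[:-1])
            gains = prefix[1:] - run_min
            end = int(np.argmax(gains))
            if gains[end] <= 0:
                return None
            start = int(np.argmin(prefix[: end + 1]))
            seg_eq = int(np.count_nonzero(eq[start : end + 1]))
            astart, aend = astart + start, astart + end + 1
            matched, mism = seg_eq, (end + 1 - start) - seg_eq
        return astart, aend, matched, mism

    def _banded_fallback(self, read: str, ci: int, diag: int, pad: int = 30):
        """Affine-gap local alignment of the read against a construct window."""
        cseq = self.seqs[ci].decode()
        lo = max(0, diag - pad)
        hi = min(len(cseq), diag + len(read) + pad)
        window = cseq[lo:hi]
        if self._aligner.score(read, window) <= 0:
            return None
        aln = next(iter(self._aligner.align(read, window)))
        rblocks, wblocks = aln.aligned
        matches = 0
        for (qs, qe), (ws, we) in zip(rblocks, wblocks):
            matches += sum(x == y for x, y in zip(read[qs:qe], window[ws:we]))
        astart = lo + int(wblocks[0][0])
        aend = lo + int(wblocks[-1][1])
        mism = sum(we - ws for _, (ws, we) in zip(rblocks, wblocks)) - matches
        return astart, aend, matches, mism

    def map_read(self, read_id: str, mate: int, seq: str) -> list[ReadAlignment]:
        """Best placement of one read on every construct it seeds to.

        One alignment per construct sequence is kept (the genotyper needs the
        read's placement on both alleles of a locus); per construct, the
        placement maximizing matched bases wins, ties broken by position.
        """
        fwd = seq.encode()
        best: dict[int, tuple] = {}
        for strand in "+-":
            read = fwd if strand == "+" else revcomp(fwd)
            for ci, diag in self._candidates(read):
                res = self._eval_diagonal(read, ci, diag)
                if res is None:
                    continue
                astart, aend, matched, mism = res
                # optionally rescue indel-containing reads with a gapped
                # local alignment against the seeded window
                if self.gapped_rescue and matched < 0.8 * len(read):
                    res2 = self._banded_fallback(read.decode(), ci, diag)
                    if res2 is not None and res2[2] > matched:
                        astart, aend, matched, mism = res2
                cur = best.get(ci)
                cand = (matched, -astart, strand, aend, mism)
                if cur is None or cand > cur:
                    best[ci] = cand
            # a perfect full-length forward placement cannot be beaten on the
            # reverse strand; skip the second orientation
            if strand == "+" and best and max(v[0] for v in best.values()) == len(fwd):
                break
        out = []
        for ci, (matched, nastart, strand, aend, mism) in best.items():
            if matched <= self.min_aln:
                continue
            out.append(
                ReadAlignment(
                    read_id=read_id,
                    mate=mate,
                    construct_key=self.keys[ci],
                    astart=-nastart,
                    aend=aend,
                    aln_length=matched,
                    n_mismatch=mism,
                    strand=strand,
                )
            )
        return out


def map_reads(
    read_pairs,
    construct: LocusConstruct,
    min_aln: int = DEFAULT_MIN_ALN,
    **index_kwargs,
) -> list[ReadAlignment]:
    """Map read pairs against a single locus construct (both alleles).

    ``read_pairs`` is an iterable of objects with ``name``/``seq1``/``seq2``
    (mate 2 may be None for single-end reads).  Reads shorter than ``min_aln``
    are discarded.
    """
    idx = ConstructIndex([construct], min_aln=min_aln, **index_kwargs)
    out = []
    for rp in read_pairs:
        for mate, seq in ((1, rp.seq1), (2, getattr(rp, "seq2", None))):
            if seq is None or len(seq) < min_aln:
                continue
            out.extend(idx.map_read(rp.name, mate, seq))
    return out


@dataclass
class GenotypeCall:
    accession: str
    locus_id: str
    genotype: str
    n_presence: int
    n_absence: int


@dataclass(frozen=True)
class GenotypeParams:
    min_aln: int = DEFAULT_MIN_ALN
    min_presence: int = 1
    min_absence: int = 1
    het_fraction: float = 0.2
    #: maximum flank-to-flank pair span accepted as absence evidence when no
    #: genome-wide insert estimate is supplied
    max_pair_span: int = 2000


def _spans_junction(a: ReadAlignment, junction: int, min_aln: int) -> bool:
    return a.astart <= junction - min_aln and a.aend >= junction + min_aln


def genotype_locus(
    alignments: list[ReadAlignment],
    construct: LocusConstruct,
    params: GenotypeParams = GenotypeParams(),
    accession: str = "",
    insert_stats: tuple[float, float] | None = None,
    tol_sd: float = 3.0,
) -> GenotypeCall:
    """Call one accession's genotype at one locus from its read alignments.

    Evidence is deduplicated by alignment coordinates so PCR/optical duplicate
    pairs count once.  When both evidence classes pass their thresholds the
    call is CG if the minority class holds at least ``het_fraction`` of the
    evidence, otherwise the majority homozygote (NN is reserved for loci where
    neither class reaches its threshold).
    """
    jL, jR, jA = construct.junctionL, construct.junctionR, construct.junctionA
    min_aln = params.min_aln
    if insert_stats is not None:
        mean_ins, sd_ins = insert_stats
        max_span = mean_ins + tol_sd * sd_ins
    else:
        max_span = params.max_pair_span

    by_read: dict[tuple[str, int], dict[str, ReadAlignment]] = defaultdict(dict)
    for a in alignments:
        if a.construct_key[0] != construct.locus_id or not a.mapped:
            continue
        by_read[(a.read_id, a.mate)][a.construct_key[1]] = a

    presence: set[tuple] = set()
    absence: set[tuple] = set()

    # single-read junction evidence
    for (rid, mate), placements in by_read.items():
        p = placements.get("P")
        if p is not None and (_spans_junction(p, jL, min_aln) or _spans_junction(p, jR, min_aln)):
            # must beat the absence-allele placement: a read that maps at
            # least as well to the TE-absent allele is not junction evidence
            alt = placements.get("A")
            if alt is None or p.aln_length > alt.aln_length:
                presence.add((p.astart, p.aend, mate))
        a = placements.get("A")
        if a is not None and _spans_junction(a, jA, min_aln):
            alt = placements.get("P")
            if alt is None or a.aln_length > alt.aln_length:
                absence.add((a.astart, a.aend, mate))

    # read-pair pattern evidence
    mates: dict[str, dict[int, dict[str, ReadAlignment]]] = defaultdict(dict)
    for (rid, mate), placements in by_read.items():
        mates[rid][mate] = placements
    for rid, mm in mates.items():
        if len(mm) != 2:
            continue
        p1, p2 = mm[1].get("P"), mm[2].get("P")
        if p1 is not None and p2 is not None:
            in_te = [a.astart >= jL and a.aend <= jR for a in (p1, p2)]
            in_flank = [a.aend <= jL or a.astart >= jR for a in (p1, p2)]
            if (in_te[0] and in_flank[1]) or (in_te[1] and in_flank[0]):
                presence.add((p1.astart, p1.aend, p2.astart, p2.aend))
        a1, a2 = mm[1].get("A"), mm[2].get("A")
        if a1 is not None and a2 is not None:
            lo, hi = (a1, a2) if a1.astart <= a2.astart else (a2, a1)
            if lo.aend <= jA and hi.astart >= jA and hi.aend - lo.astart <= max_span:
                absence.add((a1.astart, a1.aend, a2.astart, a2.aend))

    n_p, n_a = len(presence), len(absence)
    if n_p >= params.min_presence and n_a < params.min_absence:
        gt = "CC"
    elif n_a >= params.min_absence and n_p < params.min_presence:
        gt = "GG"
    elif n_p >= params.min_presence and n_a >= params.min_absence:
        minority = min(n_p, n_a) / (n_p + n_a)
        if minority >= params.het_fraction:
            gt = "CG"
        else:
            gt = "CC" if n_p > n_a else "GG"
    else:
        gt = "NN"
    return GenotypeCall(accession, construct.locus_id, gt, n_p, n_a)


def estimate_insert_stats(spans) -> tuple[float, float]:
    """Genome-wide insert size mean/sd from observed pair spans."""
    spans = np.asarray(list(spans), dtype=float)
    if spans.size < 20:
        raise ValueError("need at least 20 pairs to estimate insert size")
    return float(spans.mean()), float(spans.std(ddof=1))


def insert_size_validate(
    span: float,
    te_length: int,
    mean_insert: float,
    insert_sd: float,
    tol_sd: float = 3.0,
) -> str:
    """Classify a flank-bracketing pair span measured on the TE-containing
    sequence.

    A fragment sequenced from a TE-lacking haplotype but placed on the
    TE-containing coordinates is stretched by exactly the TE length, so a
    span near mean_insert + te_length confirms an insertion of that length
    at the locus; a span near mean_insert is consistent with no insertion;
    anything else is unsupported.
    """
    if abs(span - (mean_insert + te_length)) <= tol_sd * insert_sd:
        return "presence"
    if abs(span - mean_insert) <= tol_sd * insert_sd:
        return "absence"
    return "unsupported"


def genotype_population(
    constructs: list[LocusConstruct],
    accession_reads: dict[str, list],
    params: GenotypeParams = GenotypeParams(),
    insert_stats: tuple[float, float] | None = None,
):
    """Genotype every locus in every accession; returns (codes, evidence).

    ``accession_reads`` maps accession id -> iterable of read pairs (objects
    with name/seq1/seq2).  An accession with no reads yields an all-NN column.
    ``codes`` is a loci x accessions DataFrame of CC/GG/CG/NN; ``evidence``
    a long-format DataFrame of per-call evidence counts.
    """
    import pandas as pd
    import warnings as _w

    index = ConstructIndex(constructs, min_aln=params.min_aln)
    by_locus = {c.locus_id: c for c in constructs}
    calls: dict[str, dict[str, GenotypeCall]] = {}
    for acc, reads in accession_reads.items():
        per_locus: dict[str, list[ReadAlignment]] = defaultdict(list)
        n_reads = 0
        for rp in reads:
            n_reads += 1
            for mate, seq in ((1, rp.seq1), (2, getattr(rp, "seq2", None))):
                if seq is None or len(seq) < params.min_aln:
                    continue
                for aln in index.map_read(rp.name, mate, seq):
                    per_locus[aln.construct_key[0]].append(aln)
        if n_reads == 0:
            _w.warn(f"accession {acc} has no reads; all calls NN")
        calls[acc] = {
            lid: genotype_locus(per_locus.get(lid, []), c, params, acc, insert_stats)
            for lid, c in by_locus.items()
        }
    loci = [c.locus_id for c in constructs]
    accs = list(accession_reads)
    codes = pd.DataFrame(
        [[calls[a][l].genotype for a in accs] for l in loci], index=loci, columns=accs
    )
    evidence = pd.DataFrame(
        [
            {
                "locus_id": l,
                "accession": a,
                "genotype": calls[a][l].genotype,
                "n_presence": calls[a][l].n_presence,
                "n_absence": calls[a][l].n_absence,
            }
            for l in loci
            for a in accs
        ]
    )
    return codes, evidence


def locus_summary(codes) -> "pd.DataFrame":
    """Per-locus missing rate, carrier frequency, and polymorphism flag.

    A locus is non-polymorphic when every non-NN call is the same genotype.
    """
    import pandas as pd

    arr = codes.to_numpy(dtype="U2")
    called = arr != "NN"
    n_called = called.sum(axis=1)
    carriers = ((arr == "CC") | (arr == "CG")).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        carrier_freq = np.where(n_called > 0, carriers / np.maximum(n_called, 1), np.nan)
    polymorphic = []
    for row, ok in zip(arr, called):
        kinds = set(row[ok])
        polymorphic.append(len(kinds) > 1)
    return pd.DataFrame(
        {
            "missing_rate": 1.0 - n_called / arr.shape[1],
            "carrier_freq": carrier_freq,
            "polymorphic": polymorphic,
        },
        index=codes.index,
    )


def alignments_from_sam(path, min_aln: int = DEFAULT_MIN_ALN) -> list[ReadAlignment]:
    """Ingest externally produced alignments (e.g. bwa mem) against construct
    references named ``<locus_id>|P`` / ``<locus_id>|A``; applies the same
    matched-bases > min_aln filter as the built-in mapper."""
    import pysam

    out = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.reference_name is None:
                continue
            locus_id, _, allele = rec.reference_name.partition("|")
            matched = sum(n for op, n in (rec.cigartuples or []) if op == 0)
            nm = rec.get_tag("NM") if rec.has_tag("NM") else 0
            matched -= int(nm)
            if matched <= min_aln:
                continue
            out.append(
                ReadAlignment(
                    read_id=rec.query_name,
                    mate=2 if rec.is_read2 else 1,
                    construct_key=(locus_id, allele or "P"),
                    astart=rec.reference_start,
                    aend=rec.reference_end,
                    aln_length=matched,
                    n_mismatch=int(nm),
                    strand="-" if rec.is_reverse else "+",
                )
            )
    return out
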