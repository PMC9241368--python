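"""TE classification of structural variants (the 80-80 rule), genic context
assignment, and SNP effect annotation.

A structural-variant insertion/deletion sequence is called a TE insertion when
its best local alignment against a TE library element reaches both 80%
identity and 80% query coverage.  Genic context places an insertion point into
one of five classes (CDS, intron, 2 kb upstream, 2 kb downstream, intergenic)
with a fixed precedence, and SNP effects are annotated against the standard
nuclear codon table.
"""

from __future__ import annotations

import warnings
from bisect import bisect_right
from dataclasses import dataclass, field

from Bio.Seq import Seq

from .align import AlignmentStats, local_align_stats
from ._util import revcomp

SUPERFAMILIES = ("Copia", "Gypsy", "DTA", "DTC", "DTH", "DTM", "DTT", "Helitron", "unknown")

#: SV sequences below this length are never classified (too short for a TE).
MIN_SV_LEN = 50


@dataclass(frozen=True)
class TESequence:
    """One TE library element with its superfamily label."""

    te_id: str
    superfamily: str
    sequence: str

    def __post_init__(self):
        if len(self.sequence) < MIN_SV_LEN:
            raise ValueError(f"TE {self.te_id}: sequence shorter than {MIN_SV_LEN} bp")
        if set(self.sequence) - set("ACGTN"):
            raise ValueError(f"TE {self.te_id}: sequence contains non-ACGTN characters")


@dataclass(frozen=True)
class SVRecord:
    """An insertion or deletion call from one pairwise genome comparison.

    ``position`` is the 0-based insertion point on ``contig`` (the SV sits
    between ``position - 1`` and ``position``).  Records whose sequence carries
    alignment-gap characters must be filtered out before reaching this stage.
    """

    source_genome: str
    contig: str
    position: int
    sv_type: str  # "insertion" | "deletion"
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class Classification:
    te_id: str
    superfamily: str
    stats: AlignmentStats


@dataclass(frozen=True)
class GeneModel:
    """Gene span with exon and CDS intervals, 0-based half-open."""

    gene_id: str
    contig: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...] = field(default_factory=tuple)
    cds: tuple[tuple[int, int], ...] = field(default_factory=tuple)

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        for ivs in (self.exons, self.cds):
            for (a, b), (c, d) in zip(ivs, ivs[1:]):
                if c < b:
                    raise ValueError(f"{self.gene_id}: intervals unsorted or overlapping")

    def cds_length(self) -> int:
        return sum(b - a for a, b in self.cds)


def classify_te(
    sv: SVRecord,
    library: list[TESequence],
    id_min: float = 80.0,
    cov_min: float = 80.0,
    *,
    reciprocal: bool = False,
    scoring: dict | None = None,
) -> Classification | None:
    """Classify an SV sequence against a TE library under the 80-80 rule.

    Returns the best-passing hit or None.  Ties are broken by higher identity,
    then longer alignment, then lexicographic te_id.  Sequences shorter than
    50 bp are never classified (reason: below minimum length).
    """
    if not library:
        raise ValueError("TE library is empty")
    if sv.length < MIN_SV_LEN:
        return None  # below minimum length
    hits = []
    for te in library:
        stats = local_align_stats(sv.sequence, te.sequence, scoring)
        if stats.passes(id_min, cov_min, reciprocal=reciprocal):
            hits.append((te, stats))
    if not hits:
        return None
    te, stats = min(hits, key=lambda h: (-h[1].identity_pct, -h[1].aln_length, h[0].te_id))
    return Classification(te.te_id, te.superfamily, stats)


#: Column order of blast-style tabular hit files (outfmt-6 convention).
TABULAR_HIT_COLUMNS = (
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
)


def classify_from_tabular_hits(
    hit_rows,
    query_lengths: dict[str, int],
    library: list[TESequence],
    id_min: float = 80.0,
    cov_min: float = 80.0,
) -> dict[str, Classification | None]:
    """Apply the 80-80 rule to externally computed tabular hits.

    ``hit_rows`` is an iterable of 12-column rows (sequences of values or
    tab-separated strings) in blast outfmt-6 order.  Per (query, subject),
    coverage sums query bases over hits after trimming overlaps, and identity
    is the alignment-length-weighted mean; the best passing subject is chosen
    with the same tie-breaks as :func:`classify_te`.  Queries with no passing
    subject map to None.
    """
    by_te = {te.te_id: te for te in library}
    grouped: dict[tuple[str, str], list[tuple[float, int, int, int]]] = {}
    for row in hit_rows:
        if isinstance(row, str):
            row = row.rstrip("\n").split("\t")
        q, s = str(row[0]), str(row[1])
        pident, length = float(row[2]), int(row[3])
        qstart, qend = sorted((int(row[6]), int(row[7])))
        grouped.setdefault((q, s), []).append((pident, length, qstart - 1, qend))
    per_query: dict[str, list[tuple[TESequence, AlignmentStats]]] = {}
    for (q, s), hits in grouped.items():
        if s not in by_te:
            continue
        covered = 0
        prev_end = -1
        w_ident = 0.0
        w_len = 0
        for pident, length, qs, qe in sorted(hits, key=lambda h: (h[2], h[3])):
            covered += max(0, qe - max(qs, prev_end))
            prev_end = max(prev_end, qe)
            w_ident += pident * length
            w_len += length
        stats = AlignmentStats(
            identity_pct=w_ident / w_len if w_len else 0.0,
            coverage_pct=100.0 * covered / query_lengths[q],
            aln_length=w_len,
            score=0.0,
            best_subject=s,
        )
        per_query.setdefault(q, []).append((by_te[s], stats))
    out: dict[str, Classification | None] = {}
    for q in query_lengths:
        passing = [
            (te, st) for te, st in per_query.get(q, [])
            if st.identity_pct >= id_min and st.coverage_pct >= cov_min
        ]
        if not passing:
            out[q] = None
            continue
        te, st = min(passing, key=lambda h: (-h[1].identity_pct, -h[1].aln_length, h[0].te_id))
        out[q] = Classification(te.te_id, te.superfamily, st)
    return out


def assign_genic_context(
    contig: str,
    position: int,
    gene_models: list[GeneModel],
    flank: int = 2000,
    contig_length: int | None = None,
) -> tuple[str, str | None]:
    """Assign a genic context to an insertion point.

    Precedence when several classes apply: CDS > intron > upstream > downstream
    (upstream/downstream are strand-aware, within ``flank`` bp of the gene
    body).  Among genes matching at equal precedence the nearest gene start
    wins.  Returns ``(context, gene_id)`` with gene_id None for intergenic.
    """
    if position < 0 or (contig_length is not None and position >= contig_length):
        raise ValueError(f"position {position} outside contig {contig} bounds")
    ranked: list[tuple[int, int, str, str]] = []  # (precedence, dist_to_start, context, gene)
    for g in gene_models:
        if g.contig != contig:
            continue
        dist = abs(position - g.start)
        if g.start <= position < g.end:
            if any(a <= position < b for a, b in g.cds):
                ranked.append((0, dist, "CDS", g.gene_id))
            elif not any(a <= position < b for a, b in g.exons):
                ranked.append((1, dist, "intron", g.gene_id))
            else:
                # inside a non-coding exon (UTR): treated with intron precedence
                ranked.append((1, dist, "intron", g.gene_id))
            continue
        before = position < g.start
        upstream = before if g.strand == "+" else not before
        gap = g.start - position if before else position - g.end + 1
        if 0 < gap <= flank:
            ranked.append((2 if upstream else 3, dist, "upstream2kb" if upstream else "downstream2kb", g.gene_id))
    if not ranked:
        return "intergenic", None
    _, _, context, gene_id = min(ranked)
    return context, gene_id


def classify_snp_effect(
    snp: tuple[str, int, str, str],
    gene: GeneModel,
    genome: dict[str, str],
) -> str:
    """Classify a SNP as synonymous / nonsynonymous / noncoding for one gene.

    The containing codon is translated before and after the substitution,
    strand-aware, with the standard nuclear code; an unchanged amino acid
    (stop included) is synonymous.
    """
    contig, pos, ref, alt = snp
    seq = genome[contig]
    if seq[pos] != ref:
        raise ValueError(f"ref base mismatch at {contig}:{pos}: genome has {seq[pos]}, SNP says {ref}")
    if gene.contig != contig or not any(a <= pos < b for a, b in gene.cds):
        return "noncoding"
    total = gene.cds_length()
    if total % 3 != 0:
        raise ValueError(f"{gene.gene_id}: CDS length {total} not divisible by 3")
    # position of the SNP within the spliced CDS, in genome-forward order
    offset = 0
    for a, b in gene.cds:
        if a <= pos < b:
            offset += pos - a
            break
        offset += b - a
    cds_fwd = "".join(seq[a:b] for a, b in gene.cds)
    alt_fwd = cds_fwd[:offset] + alt + cds_fwd[offset + 1 :]
    if gene.strand == "-":
        cds_ref, cds_alt = revcomp(cds_fwd), revcomp(alt_fwd)
        cpos = total - 1 - offset
    else:
        cds_ref, cds_alt = cds_fwd, alt_fwd
        cpos = offset
    ci = cpos - cpos % 3
    aa_ref = str(Seq(cds_ref[ci : ci + 3]).translate())
    aa_alt = str(Seq(cds_alt[ci : ci + 3]).translate())
    return "synonymous" if aa_ref == aa_alt else "nonsynonymous"


def ns_s_ratio(effects: list[str]) -> float | None:
    """Ratio of nonsynonymous to synonymous SNP counts.

    Returns None for an empty (or all-noncoding) list.  A positive
    nonsynonymous count with zero synonymous SNPs is undefined and raised as
    such rather than reported as a number.
    """
    n = sum(e == "nonsynonymous" for e in effects)
    s = sum(e == "synonymous" for e in effects)
    if n == 0 and s == 0:
        return None
    if s == 0:
        warnings.warn("nonsynonymous/synonymous ratio undefined (no synonymous SNPs)")
        return float("nan")
    return n / s
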