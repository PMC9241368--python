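"""Affine-gap local alignment statistics used throughout the pipeline.

The identity/coverage statistics computed here drive the 80-80 TE
classification rule: a structural-variant sequence is accepted as a copy of a
library element when both the alignment identity and the query coverage reach
80%.  Alignment itself is delegated to :class:`Bio.Align.PairwiseAligner`
(Smith-Waterman with affine gaps); this module defines how identity and
coverage are aggregated over one or more non-overlapping local hits.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align

#: Default scoring: match +1, mismatch -2, first gap base -5, each further -2.
DEFAULT_SCORING = {"match": 1.0, "mismatch": -2.0, "gap_open": -5.0, "gap_extend": -2.0}

#: Secondary local hits below this score are ignored when merging coverage;
#: guards against spurious short hits between unrelated sequences.
MIN_SECONDARY_SCORE = 25.0

#: Ignore query segments shorter than this when looking for secondary hits.
MIN_SEGMENT_LEN = 30


@dataclass(frozen=True)
class AlignmentStats:
    """Summary of the best local alignment(s) of a query against a subject.

    identity_pct
        Matching columns as a percentage of all aligned columns (gap columns
        included), aggregated over merged hits.
    coverage_pct
        Aligned query bases as a percentage of query length, summed over
        non-overlapping local hits to the same subject.
    aln_length
        Total aligned columns.
    """

    identity_pct: float
    coverage_pct: float
    aln_length: int
    score: float
    best_subject: str | None = None
    subject_coverage_pct: float = 0.0

    def passes(self, id_min: float = 80.0, cov_min: float = 80.0, *, reciprocal: bool = False) -> bool:
        if self.identity_pct < id_min or self.coverage_pct < cov_min:
            return False
        if reciprocal and self.subject_coverage_pct < cov_min:
            return False
        return True


def make_aligner(scoring: dict | None = None) -> Align.PairwiseAligner:
    s = dict(DEFAULT_SCORING)
    if scoring:
        s.update(scoring)
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = s["match"]
    aligner.mismatch_score = s["mismatch"]
    aligner.open_gap_score = s["gap_open"]
    aligner.extend_gap_score = s["gap_extend"]
    return aligner


def _alignment_counts(alignment) -> tuple[int, int, int, int, int, int, int]:
    """Return (matches, columns, qstart, qend, sstart, send, qcov_bases)."""
    # PairwiseAligner.align(A, B): A is "target", B is "query"; we call it as
    # align(our_query, our_subject), so target-side blocks are our query's.
    qblocks, sblocks = alignment.aligned
    query, subject = alignment.target, alignment.query
    matches = 0
    columns = 0
    qcov = 0
    prev_q = prev_s = None
    for (qs, qe), (ss, se) in zip(qblocks, sblocks):
        if prev_q is not None:
            columns += max(qs - prev_q, ss - prev_s)
        seg_q = query[qs:qe]
        seg_s = subject[ss:se]
        matches += sum(a == b for a, b in zip(seg_q, seg_s))
        columns += qe - qs
        qcov += qe - qs
        prev_q, prev_s = qe, se
    qstart, qend = int(qblocks[0][0]), int(qblocks[-1][1])
    sstart, send = int(sblocks[0][0]), int(sblocks[-1][1])
    return matches, columns, qstart, qend, sstart, send, qcov


def local_align_stats(
    query: str,
    subject: str,
    scoring: dict | None = None,
    *,
    merge_hits: bool = True,
    min_secondary_score: float = MIN_SECONDARY_SCORE,
) -> AlignmentStats:
    """Best local alignment of ``query`` against ``subject``.

    Identity is computed over aligned columns; coverage over the query length.
    When ``merge_hits`` is true, the unaligned query prefix/suffix left over by
    the best hit is re-aligned against the subject and any additional hits
    scoring at least ``min_secondary_score`` contribute to coverage and
    identity (fragmented elements align as several high-scoring pairs).
    """
    if not query or not subject:
        raise ValueError("query and subject must be non-empty")
    aligner = make_aligner(scoring)
    qlen = len(query)

    total_matches = 0
    total_columns = 0
    total_qcov = 0
    total_scov = 0
    best_score = 0.0

    # (segment_start_in_query, segment, is_primary)
    stack = [(0, query, True)]
    while stack:
        off, seg, primary = stack.pop()
        if len(seg) < (1 if primary else MIN_SEGMENT_LEN):
            continue
        score = aligner.score(seg, subject)
        if score <= 0 or (not primary and score < min_secondary_score):
            continue
        try:
            alignment = next(iter(aligner.align(seg, subject)))
        except StopIteration:  # pragma: no cover - score>0 implies an alignment
            continue
        m, cols, qs, qe, ss, se, qcov = _alignment_counts(alignment)
        total_matches += m
        total_columns += cols
        total_qcov += qcov
        total_scov += se - ss
        if primary:
            best_score = float(score)
        if merge_hits:
            stack.append((off, seg[:qs], False))
            stack.append((off + qe, seg[qe:], False))
        if primary and not merge_hits:
            break

    if total_columns == 0:
        return AlignmentStats(0.0, 0.0, 0, 0.0, None, 0.0)
    return AlignmentStats(
        identity_pct=100.0 * total_matches / total_columns,
        coverage_pct=100.0 * total_qcov / qlen,
        aln_length=total_columns,
        score=best_score,
        subject_coverage_pct=100.0 * min(total_scov, len(subject)) / len(subject),
    )
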