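"""Collation of per-reference SV calls into one nonredundant TIP dataset,
and the aligned/unaligned region partition of the pan-genome.

All SVs are first projected onto one designated anchor genome: a deletion in
the anchor at interval [s, e) is re-expressed as an insertion carried by the
other genome at position s, so that the presence allele ("CC") always means
the TE is present.  Nearby, near-identical insertions from different pairwise
comparisons collapse into a single locus.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field

from .align import local_align_stats
from .classify import Classification, SVRecord

DEFAULT_MERGE_WINDOW = 100
DEFAULT_MERGE_SIMILARITY = 80.0


@dataclass
class TIPLocus:
    """One nonredundant TE insertion site on the anchor genome."""

    locus_id: str
    anchor_genome: str
    contig: str
    position: int
    te_id: str
    superfamily: str
    sequence: str
    context: str = "unassigned"
    gene_id: str | None = None
    region_class: str = "unassigned"
    identity_pct: float = float("nan")
    coverage_pct: float = float("nan")
    support: list[tuple[str, str]] = field(default_factory=list)

    @property
    def te_length(self) -> int:
        return len(self.sequence)


def normalize_sv(sv: SVRecord, anchor_genome: str) -> SVRecord:
    """Project a deletion relative to the anchor into an insertion carried by
    the other genome (position = deleted interval start)."""
    if sv.sv_type == "deletion":
        return SVRecord(sv.source_genome, sv.contig, sv.position, "insertion", sv.sequence)
    return sv


def collate_insertions(
    classified: list[tuple[SVRecord, Classification]],
    anchor_genome: str = "anchor",
    merge_window: int = DEFAULT_MERGE_WINDOW,
    merge_similarity: float = DEFAULT_MERGE_SIMILARITY,
    known_contigs: set[str] | None = None,
) -> list[TIPLocus]:
    """Collapse classified SVs into nonredundant TIP loci.

    Two SVs merge when their anchor positions are within ``merge_window`` bp
    on the same contig and their sequences reach ``merge_similarity`` percent
    identity and query coverage in a local alignment.  The longest sequence represents the locus;
    every contributing (source_genome, sv_type) is recorded as support.
    Input order does not matter: records are processed in a deterministic
    sorted order, and collating an already-collated set is a no-op.
    """
    if known_contigs is not None:
        bad = sorted({sv.contig for sv, _ in classified} - known_contigs)
        if bad:
            raise ValueError(f"SVs on unknown contigs: {', '.join(bad)}")
    records = sorted(classified, key=lambda t: (t[0].contig, t[0].position, t[0].sequence))
    loci: list[TIPLocus] = []
    for sv, cls in records:
        sv = normalize_sv(sv, anchor_genome)
        merged = False
        for locus in reversed(loci):
            if locus.contig != sv.contig:
                break
            if sv.position - locus.position > merge_window:
                break
            stats = local_align_stats(sv.sequence, locus.sequence)
            # identity alone is meaningless on a short local hit between
            # unrelated sequences; require matching query coverage as well
            if stats.identity_pct >= merge_similarity and stats.coverage_pct >= merge_similarity:
                locus.support.append((sv.source_genome, sv.sv_type))
                if len(sv.sequence) > len(locus.sequence):
                    locus.sequence = sv.sequence
                    locus.te_id = cls.te_id
                    locus.superfamily = cls.superfamily
                    locus.identity_pct = cls.stats.identity_pct
                    locus.coverage_pct = cls.stats.coverage_pct
                merged = True
                break
        if not merged:
            loci.append(
                TIPLocus(
                    locus_id="",
                    anchor_genome=anchor_genome,
                    contig=sv.contig,
                    position=sv.position,
                    te_id=cls.te_id,
                    superfamily=cls.superfamily,
                    sequence=sv.sequence,
                    identity_pct=cls.stats.identity_pct,
                    coverage_pct=cls.stats.coverage_pct,
                    support=[(sv.source_genome, sv.sv_type)],
                )
            )
    loci.sort(key=lambda l: (l.contig, l.position, l.sequence))
    for i, locus in enumerate(loci):
        locus.locus_id = f"TIP{i + 1:05d}"
    return loci


class RegionMap:
    """Per-contig sorted disjoint intervals labelled *aligned*; everything
    else (including whole contigs absent from the map) is *unaligned*."""

    def __init__(self, intervals: dict[str, list[tuple[int, int]]]):
        self.intervals: dict[str, tuple[list[int], list[int]]] = {}
        for contig, ivs in intervals.items():
            merged: list[list[int]] = []
            for a, b in sorted(ivs):
                if a >= b:
                    raise ValueError(f"empty interval [{a},{b}) on {contig}")
                if merged and a <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], b)
                else:
                    merged.append([a, b])
            self.intervals[contig] = ([a for a, _ in merged], [b for _, b in merged])

    def contains(self, contig: str, position: int) -> bool:
        if contig not in self.intervals:
            return False
        starts, ends = self.intervals[contig]
        i = bisect_right(starts, position) - 1
        return i >= 0 and position < ends[i]


def partition_regions(bed_lines) -> RegionMap:
    """Build a RegionMap from BED text lines (0-based half-open intervals)."""
    intervals: dict[str, list[tuple[int, int]]] = {}
    for lineno, line in enumerate(bed_lines, 1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed BED at line {lineno}: expected >= 3 columns")
        try:
            start, end = int(parts[1]), int(parts[2])
        except ValueError as exc:
            raise ValueError(f"malformed BED at line {lineno}: {exc}") from exc
        if start < 0 or end <= start:
            raise ValueError(f"malformed BED at line {lineno}: bad interval [{start},{end})")
        intervals.setdefault(parts[0], []).append((start, end))
    return RegionMap(intervals)


def tag_region(locus: TIPLocus, region_map: RegionMap) -> str:
    """Label a locus *aligned* iff its insertion point lies in an aligned
    interval of the anchor map."""
    locus.region_class = "aligned" if region_map.contains(locus.contig, locus.position) else "unaligned"
    return locus.region_class
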