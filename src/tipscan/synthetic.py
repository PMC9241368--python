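"""Synthetic pan-genomes, TE libraries, paired-end reads, and population
genotype structures with known truth.

This generator emulates the study design the pipeline targets: a pan-genome
of donor assemblies that differ from a base genome by planted TE insertions
at known loci, short-read resequencing of every accession, and a two-group
population in which some loci are strongly enriched in one group.  Everything
is deterministic under the configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._util import mutate_substitutions, random_dna, revcomp, spawn_rngs
from .classify import SUPERFAMILIES, TESequence

#: Planted insertion points keep at least this distance from contig ends so
#: that full 1 kb genotyping flanks always exist.
FLANK_MIN = 1000


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for the synthetic generator.

    Defaults mirror a typical plant resequencing design: 150 bp paired-end
    reads at 20x coverage with a 500 +/- 50 bp insert, TE elements of 3-6 kb,
    and an Illumina-like 1e-3 per-base substitution error rate.
    """

    seed: int = 0
    genome_length: int = 100_000
    n_accessions: int = 20
    te_count: int = 8
    te_length_range: tuple[int, int] = (3000, 6000)
    insertion_rate: int = 10          # planted TIP loci per pan-genome
    carrier_frequency: float = 0.5    # per-locus probability an accession carries it
    read_length: int = 150
    insert_mean: int = 500
    insert_sd: float = 50.0
    coverage: float = 20.0
    error_rate: float = 1e-3
    divergence: float = 0.0           # per-locus point divergence of the planted copy
    min_locus_spacing: int = 2600     # keeps 1 kb flanks of neighbouring loci disjoint
    group_design: tuple[tuple[str, int, tuple[int, ...]], ...] = ()

    def __post_init__(self):
        for name in ("genome_length", "n_accessions", "te_count", "read_length", "insert_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 <= self.error_rate < 0.1:
            raise ValueError("error_rate must be in [0, 0.1)")
        if self.insert_mean < self.read_length:
            raise ValueError("insert_mean must be >= read_length")
        if not 0 <= self.carrier_frequency <= 1:
            raise ValueError("carrier_frequency must be in [0, 1]")


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated pan-genome.

    loci maps locus_id -> (contig, 0-based insertion point, te_id, te_length);
    carriers maps accession -> set of carried locus_ids.
    """

    loci: dict[str, tuple[str, int, str, int]]
    carriers: dict[str, set[str]]
    groups: dict[str, str] = field(default_factory=dict)

    def genotype_of(self, accession: str, locus_id: str) -> str:
        return "CC" if locus_id in self.carriers[accession] else "GG"


def simulate_te_library(
    n: int,
    length_range: tuple[int, int] = (3000, 6000),
    superfamilies: tuple[str, ...] = SUPERFAMILIES[:-1],
    seed: int = 0,
) -> list[TESequence]:
    """Uniform-random TE elements with superfamily labels assigned round-robin."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not superfamilies:
        raise ValueError("superfamily list must be non-empty")
    lo, hi = length_range
    if not (100 <= lo <= hi <= 20000):
        raise ValueError("length_range must lie within [100, 20000]")
    rng = np.random.default_rng(seed)
    lib = []
    for i in range(n):
        length = int(rng.integers(lo, hi + 1))
        lib.append(
            TESequence(
                te_id=f"TE{i + 1:04d}",
                superfamily=superfamilies[i % len(superfamilies)],
                sequence=random_dna(rng, length),
            )
        )
    return lib


@dataclass
class Pangenome:
    base: dict[str, str]                  # contig -> sequence
    donors: dict[str, dict[str, str]]     # accession -> contig -> sequence
    truth: SyntheticTruth
    sv_truth: list[tuple[str, str, int, str, str]]  # (donor, contig, position, te_id, sequence)


def _draw_positions(rng: np.random.Generator, n: int, genome_length: int, spacing: int) -> list[int]:
    lo, hi = FLANK_MIN, genome_length - FLANK_MIN
    if hi - lo < n * spacing:
        raise ValueError(
            f"cannot place {n} loci with {spacing} bp spacing in a {genome_length} bp genome"
        )
    # draw gaps, then positions: deterministic and spacing-respecting
    slack = (hi - lo) - n * spacing
    cuts = np.sort(rng.integers(0, slack + 1, size=n))
    return [int(lo + cuts[i] + i * spacing + spacing // 2) for i in range(n)]


def simulate_pangenome(
    cfg: SimConfig,
    library: list[TESequence] | None = None,
    base_genome: dict[str, str] | None = None,
    positions: list[int] | None = None,
) -> Pangenome:
    """Plant TE insertions into donor genomes at known loci.

    Each donor genome equals the base genome with its carried TE copies
    spliced in; an optional per-locus divergence rate point-mutates the
    planted copy (one mutated copy per locus, shared by all carriers, as for
    a single historical insertion event).  Explicitly supplied positions are
    validated against overlap of the planted flank regions.
    """
    rng_lib, rng_pos, rng_carry, rng_div = spawn_rngs(cfg.seed, 4)
    if library is None:
        library = simulate_te_library(cfg.te_count, cfg.te_length_range, seed=cfg.seed + 1)
    if base_genome is None:
        base_genome = {"chr1": random_dna(rng_lib, cfg.genome_length)}
    if len(base_genome) != 1 and positions is None:
        raise ValueError("automatic locus placement supports single-contig bases; pass positions")
    contig = next(iter(base_genome))
    base_seq = base_genome[contig]

    n_loci = cfg.insertion_rate
    if positions is None:
        positions = _draw_positions(rng_pos, n_loci, len(base_seq), cfg.min_locus_spacing)
    else:
        positions = sorted(int(p) for p in positions)
        n_loci = len(positions)
        if any(b - a < 1 for a, b in zip(positions, positions[1:])):
            raise ValueError("overlapping planted insertions: rejecting design")
        if positions[0] < FLANK_MIN or positions[-1] > len(base_seq) - FLANK_MIN:
            raise ValueError(f"insertion points must lie >= {FLANK_MIN} bp from contig ends")

    loci: dict[str, tuple[str, int, str, int]] = {}
    locus_seq: dict[str, str] = {}
    for i, pos in enumerate(positions):
        te = library[i % len(library)]
        seq = mutate_substitutions(rng_div, te.sequence, cfg.divergence)
        lid = f"L{i + 1:04d}"
        loci[lid] = (contig, pos, te.te_id, len(seq))
        locus_seq[lid] = seq

    accessions = [f"acc{i + 1:03d}" for i in range(cfg.n_accessions)]
    carry = rng_carry.random((len(positions), cfg.n_accessions)) < cfg.carrier_frequency
    carriers = {
        acc: {lid for j, lid in enumerate(loci) if carry[j, i]} for i, acc in enumerate(accessions)
    }

    donors: dict[str, dict[str, str]] = {}
    sv_truth = []
    for acc in accessions:
        parts = []
        prev = 0
        for lid, (ctg, pos, te_id, te_len) in loci.items():
            if lid not in carriers[acc]:
                continue
            parts.append(base_seq[prev:pos])
            parts.append(locus_seq[lid])
            sv_truth.append((acc, ctg, pos, te_id, locus_seq[lid]))
            prev = pos
        parts.append(base_seq[prev:])
        donors[acc] = {contig: "".join(parts)}

    truth = SyntheticTruth(loci=loci, carriers=carriers)
    return Pangenome(base=base_genome, donors=donors, truth=truth, sv_truth=sv_truth)


@dataclass
class ReadPair:
    name: str
    seq1: str
    seq2: str


def simulate_reads(genome: str, cfg: SimConfig, seed: int | None = None, prefix: str = "rd") -> list[ReadPair]:
    """Paired-end reads from one (haploid) genome sequence.

    Fragment lengths are Normal(insert_mean, insert_sd) truncated below at
    read_length; mate 2 is the reverse complement of the fragment end; each
    base is substituted independently at error_rate.  The pair count is
    round(coverage * genome_length / (2 * read_length)).
    """
    if cfg.coverage <= 0:
        raise ValueError("coverage must be > 0")
    glen = len(genome)
    if glen < cfg.insert_mean + 6 * cfg.insert_sd:
        raise ValueError("genome too short for the configured insert size distribution")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n_pairs = round(cfg.coverage * glen / (2 * cfg.read_length))
    inserts = np.maximum(
        np.rint(rng.normal(cfg.insert_mean, cfg.insert_sd, size=n_pairs)).astype(np.int64),
        cfg.read_length,
    )
    inserts = np.minimum(inserts, glen)
    starts = rng.integers(0, glen - inserts + 1)
    L = cfg.read_length
    pairs = []
    for i in range(n_pairs):
        s, ins = int(starts[i]), int(inserts[i])
        frag = genome[s : s + ins]
        r1 = frag[:L]
        r2 = revcomp(frag[-L:]) if ins >= L else revcomp(frag)
        pairs.append(ReadPair(f"{prefix}{i + 1}", r1, r2))
    if cfg.error_rate > 0:
        for p in pairs:
            p.seq1 = mutate_substitutions(rng, p.seq1, cfg.error_rate)
            p.seq2 = mutate_substitutions(rng, p.seq2, cfg.error_rate)
    return pairs


def simulate_population_matrix(
    n_loci: int,
    groups: list[tuple[str, int]],
    enriched: dict[int, tuple[float, float]] | None = None,
    *,
    neutral_freq_range: tuple[float, float] = (0.1, 0.9),
    nn_rate: float = 0.0,
    cg_rate: float = 0.0,
    seed: int = 0,
    n_accessions: int | None = None,
):
    """Genotype-code matrix for a structured population with planted enrichment.

    ``groups`` lists (label, size) in order; ``enriched`` maps locus index ->
    (frequency in first group, frequency in remaining groups).  Neutral loci
    share one frequency, drawn uniformly from ``neutral_freq_range``, across
    all groups.  Returns (codes DataFrame loci x accessions, group Series,
    list of enriched locus_ids).
    """
    import pandas as pd

    if enriched is None:
        enriched = {}
    if n_accessions is not None and sum(s for _, s in groups) != n_accessions:
        raise ValueError("group sizes do not sum to n_accessions")
    rng = np.random.default_rng(seed)
    labels = []
    acc = []
    for gi, (label, size) in enumerate(groups):
        for k in range(size):
            acc.append(f"{label}_{k + 1:03d}")
            labels.append(label)
    n_acc = len(acc)
    group_of = pd.Series(labels, index=acc, name="group")
    first = groups[0][0]

    freqs = np.empty((n_loci, n_acc))
    neutral = rng.uniform(*neutral_freq_range, size=n_loci)
    in_first = np.array([g == first for g in labels])
    for i in range(n_loci):
        if i in enriched:
            f1, f0 = enriched[i]
            freqs[i] = np.where(in_first, f1, f0)
        else:
            freqs[i] = neutral[i]
    carrier = rng.random((n_loci, n_acc)) < freqs
    codes = np.where(carrier, "CC", "GG").astype(object)
    if cg_rate > 0:
        codes[rng.random(codes.shape) < cg_rate] = "CG"
    if nn_rate > 0:
        codes[rng.random(codes.shape) < nn_rate] = "NN"
    locus_ids = [f"L{i + 1:04d}" for i in range(n_loci)]
    df = pd.DataFrame(codes, index=locus_ids, columns=acc)
    enriched_ids = [locus_ids[i] for i in sorted(enriched)]
    return df, group_of, enriched_ids
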