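"""End-to-end orchestration: reproducible runs, fixtures, and the stage
sequence classify -> collate -> genotype -> scan.

Every run echoes its effective configuration and input checksums into a
manifest so any output file is attributable to a logged configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import pandas as pd
import yaml

from . import io as tio
from .classify import classify_te
from .discovery import collate_insertions, partition_regions, tag_region
from .genotyping import GenotypeParams, build_locus_construct, genotype_population
from .popgen import enrichment_scan, maf_filter, nj_tree, pairwise_distance, pca
from .synthetic import SimConfig, simulate_pangenome, simulate_reads, simulate_te_library, simulate_population_matrix

log = logging.getLogger("tipscan")

STAGES = ("classify", "collate", "genotype", "scan")


@dataclass
class RunConfig:
    """All pipeline parameters; unknown keys are rejected on load."""

    stages: list[str] = field(default_factory=lambda: list(STAGES))
    out_dir: str = "tipscan_out"
    seed: int = 0
    # inputs
    te_library: str | None = None
    sv_table: str | None = None
    anchor_fasta: str | None = None
    gff3: str | None = None
    aligned_bed: str | None = None
    reads_manifest: str | None = None   # TSV: accession, fastq1, fastq2
    classified_svs: str | None = None   # output of a previous classify stage
    loci: str | None = None             # output of a previous collate stage
    matrix: str | None = None
    groups: str | None = None
    derived_group: str | None = None
    control_group: str | None = None
    # stage parameters
    id_min: float = 80.0
    cov_min: float = 80.0
    flank: int = 1000
    genic_flank: int = 2000
    min_aln: int = 20
    maf: float = 0.05
    merge_window: int = 100
    merge_similarity: float = 80.0
    keep_intergenic: bool = False

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the selected stages in order; returns the output manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "outputs": {}, "inputs": {}, "started": time.strftime("%Y-%m-%dT%H:%M:%S")}
    for key in ("te_library", "sv_table", "anchor_fasta", "gff3", "aligned_bed", "matrix", "groups", "reads_manifest"):
        p = getattr(config, key)
        if p:
            manifest["inputs"][key] = {"path": str(p), "sha256": _sha256(Path(p))}

    unknown = set(config.stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    stages = [s for s in STAGES if s in config.stages]
    classified = None
    loci = None
    codes = None

    if "classify" in stages:
        if not (config.te_library and config.sv_table):
            raise ValueError("classify stage requires te_library and sv_table inputs")
        library = tio.read_te_library(config.te_library)
        svs = tio.read_sv_tsv(config.sv_table)
        classified = []
        for sv in svs:
            cls = classify_te(sv, library, config.id_min, config.cov_min)
            if cls is not None:
                classified.append((sv, cls))
        path = out / "classified_svs.tsv"
        pd.DataFrame(
            [
                (s.source_genome, s.contig, s.position, s.sv_type, c.te_id, c.superfamily,
                 round(c.stats.identity_pct, 4), round(c.stats.coverage_pct, 4), s.sequence)
                for s, c in classified
            ],
            columns=["source_genome", "contig", "position", "sv_type", "te_id",
                     "superfamily", "identity_pct", "coverage_pct", "sequence"],
        ).to_csv(path, sep="\t", index=False)
        manifest["outputs"]["classified_svs"] = str(path)
        log.info("classify: %d/%d SVs classified as TE insertions", len(classified), len(svs))

    if "collate" in stages:
        if classified is None and config.classified_svs:
            from .align import AlignmentStats
            from .classify import Classification, SVRecord

            df = pd.read_csv(config.classified_svs, sep="\t")
            classified = [
                (
                    SVRecord(r.source_genome, r.contig, int(r.position), r.sv_type, r.sequence),
                    Classification(
                        r.te_id, r.superfamily,
                        AlignmentStats(float(r.identity_pct), float(r.coverage_pct), 0, 0.0),
                    ),
                )
                for r in df.itertuples()
            ]
        if classified is None:
            raise ValueError(
                "collate stage requires the classify stage upstream or a classified_svs input"
            )
        loci = collate_insertions(
            classified,
            anchor_genome=Path(config.anchor_fasta).stem if config.anchor_fasta else "anchor",
            merge_window=config.merge_window,
            merge_similarity=config.merge_similarity,
        )
        if config.gff3:
            from .classify import assign_genic_context

            genes = tio.read_gff3(config.gff3)
            for locus in loci:
                locus.context, locus.gene_id = assign_genic_context(
                    locus.contig, locus.position, genes, config.genic_flank
                )
            if not config.keep_intergenic:
                loci = [l for l in loci if l.context != "intergenic"]
        if config.aligned_bed:
            with open(config.aligned_bed) as fh:
                region_map = partition_regions(fh)
            for locus in loci:
                tag_region(locus, region_map)
        path = out / "tip_loci.tsv"
        tio.write_locus_tsv(path, loci)
        manifest["outputs"]["tip_loci"] = str(path)
        log.info("collate: %d nonredundant TIP loci", len(loci))

    if "genotype" in stages:
        if loci is None and config.loci:
            loci = tio.read_locus_tsv(config.loci)
        if loci is None or not config.anchor_fasta or not config.reads_manifest:
            raise ValueError("genotype stage requires collate output, anchor_fasta and reads_manifest")
        genome = tio.read_fasta(config.anchor_fasta)
        constructs = [
            build_locus_construct(l.locus_id, genome[l.contig], l.position, l.sequence, config.flank)
            for l in loci
        ]
        mf = pd.read_csv(config.reads_manifest, sep="\t")
        accession_reads = {}
        for r in mf.itertuples():
            try:
                accession_reads[r.accession] = tio.read_fastq_pairs(r.fastq1, r.fastq2)
            except FileNotFoundError:
                log.warning("accession %s listed without reads; all calls NN", r.accession)
                accession_reads[r.accession] = []
        codes, evidence = genotype_population(
            constructs, accession_reads, GenotypeParams(min_aln=config.min_aln)
        )
        tio.write_genotype_tsv(out / "genotypes.tsv", codes)
        tio.write_genotype_vcf(out / "genotypes.vcf", codes, loci)
        evidence.to_csv(out / "genotype_evidence.tsv", sep="\t", index=False)
        from .genotyping import locus_summary

        locus_summary(codes).to_csv(out / "locus_summary.tsv", sep="\t",
                                    index_label="locus_id", float_format="%.6g")
        manifest["outputs"]["genotypes"] = str(out / "genotypes.tsv")
        log.info("genotype: %d loci x %d accessions", *codes.shape)

    if "scan" in stages:
        if codes is None:
            if not config.matrix:
                raise ValueError("scan stage requires the genotype stage or a matrix input")
            codes = tio.read_genotype_tsv(config.matrix)
        if not config.groups:
            raise ValueError("scan stage requires a group manifest")
        groups = tio.read_groups_tsv(config.groups)
        filtered = maf_filter(codes, config.maf)
        derived = [a for a in filtered.columns if groups.get(a) == config.derived_group]
        control = [a for a in filtered.columns if groups.get(a) == config.control_group]
        scan = enrichment_scan(filtered, derived, control)
        scan.to_csv(out / "selection_scan.tsv", sep="\t", index=False, float_format="%.6g")
        manifest["outputs"]["selection_scan"] = str(out / "selection_scan.tsv")
        # companion population-structure outputs
        try:
            dist = pairwise_distance(filtered)
            (out / "nj_tree.nwk").write_text(nj_tree(dist) + "\n")
            manifest["outputs"]["nj_tree"] = str(out / "nj_tree.nwk")
            res = pca(filtered, k=min(20, filtered.shape[1] - 1))
            res.coordinates.to_csv(out / "pca_coordinates.tsv", sep="\t", float_format="%.6g")
            manifest["outputs"]["pca"] = str(out / "pca_coordinates.tsv")
        except ValueError as exc:
            log.warning("population-structure outputs skipped: %s", exc)
        log.info("scan: %d loci scanned", len(scan))

    manifest_path = out / "manifest.json"
    manifest["outputs"]["manifest"] = str(manifest_path)
    for name, p in list(manifest["outputs"].items()):
        if name != "manifest":
            manifest["outputs"][name] = {"path": p, "sha256": _sha256(Path(p))}
    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


# ---------------------------------------------------------------------------
# fixtures

PRESETS = {
    # 3 loci x 6 accessions: smoke-test scale
    "tiny": SimConfig(
        genome_length=12_000, n_accessions=6, te_count=3, insertion_rate=3,
        te_length_range=(1000, 2000), error_rate=0.0, min_locus_spacing=2600,
    ),
    # 50 loci x 60 accessions, error-free 20x reads: genotyping validation scale
    "demo": SimConfig(
        genome_length=140_000, n_accessions=60, te_count=50, insertion_rate=50,
        te_length_range=(3000, 6000), error_rate=0.0, min_locus_spacing=2600,
    ),
    # matrix-level only: two-group selection-scan design (329 vs 195 accessions,
    # five loci enriched at 0.80 vs 0.02 carrier frequency)
    "scan_only": SimConfig(
        n_accessions=524, genome_length=100_000,
        group_design=(("derived", 329, (0, 1, 2, 3, 4)), ("control", 195, ())),
    ),
}

SCAN_ONLY_N_LOCI = 500
SCAN_ONLY_ENRICHED = {i: (0.80, 0.02) for i in range(5)}


def make_fixture(preset: str, seed: int, out_dir, write_reads: bool | None = None) -> dict:
    """Write an on-disk synthetic dataset for one of the named presets.

    tiny/demo write genomes, TE library, SV truth and (for tiny, or on
    request) paired FASTQ; scan_only writes only the genotype matrix and
    group manifest of the two-group selection design.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = PRESETS[preset]
    cfg = SimConfig(**{**asdict(cfg), "seed": seed})
    manifest: dict = {"preset": preset, "seed": seed, "config": asdict(cfg), "files": {}}

    if preset == "scan_only":
        codes, groups, enriched_ids = simulate_population_matrix(
            SCAN_ONLY_N_LOCI,
            [(g, n) for g, n, _ in cfg.group_design],
            SCAN_ONLY_ENRICHED,
            seed=seed,
        )
        tio.write_genotype_tsv(out / "genotypes.tsv", codes)
        groups.rename_axis("accession").reset_index().to_csv(out / "groups.tsv", sep="\t", index=False)
        (out / "enriched_truth.txt").write_text("\n".join(enriched_ids) + "\n")
        manifest["files"] = {
            "genotypes": "genotypes.tsv", "groups": "groups.tsv", "enriched_truth": "enriched_truth.txt",
        }
    else:
        library = simulate_te_library(cfg.te_count, cfg.te_length_range, seed=cfg.seed + 1)
        pg = simulate_pangenome(cfg, library=library)
        tio.write_te_library(out / "te_library.fasta", library)
        tio.write_fasta(out / "base_genome.fasta", pg.base)
        from .classify import SVRecord

        svs = [SVRecord(acc, ctg, pos, "insertion", seq) for acc, ctg, pos, te_id, seq in pg.sv_truth]
        tio.write_sv_tsv(out / "sv_truth.tsv", svs)
        truth_rows = [
            (lid, ctg, pos, te_id, te_len) for lid, (ctg, pos, te_id, te_len) in pg.truth.loci.items()
        ]
        pd.DataFrame(truth_rows, columns=["locus_id", "contig", "position", "te_id", "te_length"]).to_csv(
            out / "locus_truth.tsv", sep="\t", index=False
        )
        pd.DataFrame(
            [(acc, ",".join(sorted(s)) or ".") for acc, s in pg.truth.carriers.items()],
            columns=["accession", "carried_loci"],
        ).to_csv(out / "carrier_truth.tsv", sep="\t", index=False)
        manifest["files"] = {
            "te_library": "te_library.fasta", "base_genome": "base_genome.fasta",
            "sv_truth": "sv_truth.tsv", "locus_truth": "locus_truth.tsv",
            "carrier_truth": "carrier_truth.tsv",
        }
        if write_reads is None:
            write_reads = preset == "tiny"
        if write_reads:
            reads_dir = out / "reads"
            reads_dir.mkdir(exist_ok=True)
            rows = []
            for i, (acc, donor) in enumerate(pg.donors.items()):
                pairs = simulate_reads(donor["chr1"], cfg, seed=cfg.seed * 100_003 + i, prefix=f"{acc}_")
                f1, f2 = reads_dir / f"{acc}_1.fastq", reads_dir / f"{acc}_2.fastq"
                tio.write_fastq_pairs(f1, f2, pairs)
                rows.append((acc, str(f1), str(f2)))
            pd.DataFrame(rows, columns=["accession", "fastq1", "fastq2"]).to_csv(
                out / "reads_manifest.tsv", sep="\t", index=False
            )
            manifest["files"]["reads_manifest"] = "reads_manifest.tsv"
    (out / "fixture_manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
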