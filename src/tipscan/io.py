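"""Readers and writers for the pipeline's on-disk formats.

FASTA/FASTQ go through Biopython; gene models come from GFF3; SV calls are
accepted as 5-column TSV or sequence-resolved VCF; genotype matrices are
written as TSV (loci rows x accession columns) and as a minimal VCF with the
presence allele as ALT <INS:ME>.

TE library FASTA headers carry the superfamily as ``>te_id#superfamily``
(RepeatMasker convention, regex ``^(?P<te_id>[^#\\s]+)#(?P<superfamily>\\S+)``);
a bare ``>te_id`` falls back to superfamily "unknown".
"""

from __future__ import annotations

import re
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .classify import GeneModel, SVRecord, TESequence
from .discovery import TIPLocus
from .synthetic import ReadPair

_LIB_HEADER = re.compile(r"^(?P<te_id>[^#\s]+)(#(?P<superfamily>\S+))?")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, sequences: dict[str, str]) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_te_library(path) -> list[TESequence]:
    lib = []
    for rec in SeqIO.parse(str(path), "fasta"):
        m = _LIB_HEADER.match(rec.id)
        lib.append(
            TESequence(
                te_id=m.group("te_id"),
                superfamily=m.group("superfamily") or "unknown",
                sequence=str(rec.seq).upper(),
            )
        )
    return lib


def write_te_library(path, library: list[TESequence]) -> None:
    write_fasta(path, {f"{te.te_id}#{te.superfamily}": te.sequence for te in library})


# -- FASTQ ------------------------------------------------------------------


def write_fastq_pairs(path1, path2, pairs) -> None:
    """Paired FASTQ with the /1 /2 read-name suffix convention."""
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for p in pairs:
            q1 = "I" * len(p.seq1)
            q2 = "I" * len(p.seq2)
            f1.write(f"@{p.name}/1\n{p.seq1}\n+\n{q1}\n")
            f2.write(f"@{p.name}/2\n{p.seq2}\n+\n{q2}\n")


def read_fastq_pairs(path1, path2) -> list[ReadPair]:
    pairs = []
    for r1, r2 in zip(SeqIO.parse(str(path1), "fastq"), SeqIO.parse(str(path2), "fastq")):
        name = r1.id.rsplit("/", 1)[0]
        if len(r1.seq) == 0 or len(r2.seq) == 0:
            raise ValueError(f"empty read in pair {name}")
        pairs.append(ReadPair(name, str(r1.seq), str(r2.seq)))
    return pairs


# -- SV calls ---------------------------------------------------------------

SV_COLUMNS = ["source_genome", "contig", "position", "sv_type", "sequence"]


def read_sv_tsv(path) -> list[SVRecord]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"position": int})
    missing = set(SV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"SV TSV missing columns: {sorted(missing)}")
    return [
        SVRecord(r.source_genome, r.contig, int(r.position), r.sv_type, r.sequence.upper())
        for r in df.itertuples()
    ]


def write_sv_tsv(path, svs: list[SVRecord]) -> None:
    pd.DataFrame(
        [(s.source_genome, s.contig, s.position, s.sv_type, s.sequence) for s in svs],
        columns=SV_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def read_sv_vcf(path, source_genome: str = "vcf") -> list[SVRecord]:
    """Sequence-resolved insertions/deletions from a VCF.

    An ALT longer than REF is an insertion (inserted bases = ALT minus the
    shared leading REF base); REF longer than ALT is a deletion.
    """
    import pysam

    out = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            for alt in rec.alts or ():
                if alt.startswith("<"):
                    continue  # symbolic allele without sequence: skip
                ref = rec.ref
                if len(alt) > len(ref):
                    out.append(SVRecord(source_genome, rec.chrom, rec.pos, "insertion", alt[len(ref):].upper()))
                elif len(ref) > len(alt):
                    out.append(SVRecord(source_genome, rec.chrom, rec.pos, "deletion", ref[len(alt):].upper()))
    return out


# -- gene models ------------------------------------------------------------


def read_gff3(path) -> list[GeneModel]:
    """Parse gene/exon/CDS features from a GFF3 file (coordinates converted
    to 0-based half-open)."""
    genes: dict[str, dict] = {}
    children: list[tuple[str, str, int, int]] = []
    mrna_parent: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise ValueError(f"malformed GFF3 line: {line.strip()!r}")
            contig, _, ftype, start, end, _, strand, _, attrs = parts[:9]
            attr = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            start, end = int(start) - 1, int(end)
            if ftype == "gene":
                gid = attr.get("ID", f"gene:{contig}:{start}")
                genes[gid] = {"contig": contig, "strand": strand, "start": start, "end": end,
                              "exons": [], "cds": []}
            elif ftype == "mRNA":
                mrna_parent[attr.get("ID", "")] = attr.get("Parent", "")
            elif ftype in ("exon", "CDS"):
                children.append((ftype, attr.get("Parent", ""), start, end))
    for ftype, parent, start, end in children:
        gid = mrna_parent.get(parent, parent)
        if gid in genes:
            genes[gid]["exons" if ftype == "exon" else "cds"].append((start, end))
    out = []
    for gid, g in genes.items():
        out.append(
            GeneModel(
                gene_id=gid,
                contig=g["contig"],
                strand=g["strand"],
                start=g["start"],
                end=g["end"],
                exons=tuple(sorted(set(g["exons"]))),
                cds=tuple(sorted(set(g["cds"]))),
            )
        )
    return out


# -- TIP locus tables -------------------------------------------------------

LOCUS_COLUMNS = [
    "locus_id", "anchor_genome", "contig", "position", "te_id", "superfamily",
    "te_length", "identity_pct", "coverage_pct", "context", "gene_id",
    "region_class", "n_support", "sequence",
]


def write_locus_tsv(path, loci: list[TIPLocus]) -> None:
    rows = [
        (l.locus_id, l.anchor_genome, l.contig, l.position, l.te_id, l.superfamily,
         l.te_length, round(l.identity_pct, 4), round(l.coverage_pct, 4), l.context,
         l.gene_id or ".", l.region_class, len(l.support), l.sequence)
        for l in loci
    ]
    pd.DataFrame(rows, columns=LOCUS_COLUMNS).to_csv(path, sep="\t", index=False)


def read_locus_tsv(path) -> list[TIPLocus]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for r in df.itertuples():
        out.append(
            TIPLocus(
                locus_id=r.locus_id, anchor_genome=r.anchor_genome, contig=r.contig,
                position=int(r.position), te_id=r.te_id, superfamily=r.superfamily,
                sequence=r.sequence, context=r.context,
                gene_id=None if r.gene_id == "." else r.gene_id,
                region_class=r.region_class,
                identity_pct=float(r.identity_pct), coverage_pct=float(r.coverage_pct),
                support=[("unknown", "insertion")] * int(r.n_support),
            )
        )
    return out


# -- genotype matrix --------------------------------------------------------


def write_genotype_tsv(path, codes: pd.DataFrame) -> None:
    codes.to_csv(path, sep="\t", index_label="locus_id")


def read_genotype_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="locus_id")


_GT = {"CC": "1/1", "GG": "0/0", "CG": "0/1", "NN": "./."}


def write_genotype_vcf(path, codes: pd.DataFrame, loci: list[TIPLocus] | None = None) -> None:
    """Minimal VCF: presence allele as symbolic ALT <INS:ME>."""
    meta = {l.locus_id: l for l in loci or []}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##ALT=<ID=INS:ME,Description="Mobile element insertion">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(codes.columns) + "\n")
        for lid in codes.index:
            l = meta.get(lid)
            chrom = l.contig if l else "."
            pos = l.position if l else 0
            info = f"SVTYPE=INS;TEID={l.te_id};SVLEN={l.te_length}" if l else "SVTYPE=INS"
            gts = "\t".join(_GT[g] for g in codes.loc[lid])
            fh.write(f"{chrom}\t{pos + 1}\t{lid}\tN\t<INS:ME>\t.\tPASS\t{info}\tGT\t{gts}\n")


def read_groups_tsv(path) -> pd.Series:
    """Accession -> group label manifest (two columns: accession, group)."""
    df = pd.read_csv(path, sep="\t")
    if not {"accession", "group"} <= set(df.columns):
        raise ValueError("group manifest needs 'accession' and 'group' columns")
    return df.set_index("accession")["group"]
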