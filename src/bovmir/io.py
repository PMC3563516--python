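"""Readers and writers for the pipeline's on-disk formats.

FASTA/FASTQ go through Biopython; the locus annotation is GFF3 with the
RNA class in the type column; tag matrices and summary tables are TSV;
the family file follows the miFam.dat stanza layout.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .mapping import Locus
from .util import normalize_seq

#: GFF3 class annotation written for these locus classes only; planted
#: novel hairpins stay out of the annotation on purpose.
ANNOTATION_CLASSES = (
    "miRNA",
    "rRNA",
    "tRNA",
    "snRNA",
    "snoRNA",
    "scRNA",
    "srpRNA",
    "repeat",
    "exon",
    "intron",
)


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fastq_seqs(path) -> list[str]:
    with open(path) as fh:
        return [seq for _, seq, _ in FastqGeneralIterator(fh)]


def write_fastq(reads: Iterable[str], path, prefix: str = "read") -> None:
    """Phred+33 FASTQ with constant high quality (quality is not modelled)."""
    with open(path, "w") as fh:
        for i, seq in enumerate(reads, start=1):
            fh.write(f"@{prefix}{i}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_collapsed_fasta(path) -> Counter:
    """Pre-collapsed FASTA with `>id_xCOUNT` headers -> tag Counter."""
    tags: Counter = Counter()
    for rec in SeqIO.parse(str(path), "fasta"):
        count = 1
        if "_x" in rec.id:
            try:
                count = int(rec.id.rsplit("_x", 1)[1])
            except ValueError:
                pass
        tags[normalize_seq(str(rec.seq))] += count
    return tags


def write_collapsed_fasta(tags: Mapping[str, int], path) -> None:
    ordered = sorted(tags.items(), key=lambda kv: (-kv[1], kv[0]))
    write_fasta({f"t{i}_x{count}": seq for i, (seq, count) in enumerate(ordered, 1)}, path)


def write_loci_gff3(loci: Iterable[Locus], path, classes=ANNOTATION_CLASSES) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for locus in loci:
            if locus.klass not in classes:
                continue
            fh.write(
                "\t".join(
                    [
                        locus.chrom,
                        "bovmir_sim",
                        locus.klass,
                        str(locus.start),
                        str(locus.end),
                        ".",
                        locus.strand,
                        ".",
                        f"ID={locus.locus_id}",
                    ]
                )
                + "\n"
            )


def read_loci_gff3(path) -> list[Locus]:
    loci = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            chrom, _, klass, start, end, _, strand, _, attrs = line.rstrip("\n").split("\t")
            locus_id = ""
            for part in attrs.split(";"):
                if part.startswith("ID="):
                    locus_id = part[3:]
            loci.append(Locus(locus_id, chrom, klass, strand, int(start), int(end)))
    return loci


def write_family_file(families: Mapping[str, str], path) -> None:
    """miFam.dat-like stanzas from a precursor -> family mapping."""
    by_family: dict[str, list[str]] = {}
    for precursor, family in families.items():
        by_family.setdefault(family, []).append(precursor)
    with open(path, "w") as fh:
        for i, family in enumerate(sorted(by_family), start=1):
            fh.write(f"AC   MIPF{i:07d}\n")
            fh.write(f"ID   {family}\n")
            for j, precursor in enumerate(sorted(by_family[family]), start=1):
                fh.write(f"MI   MI{i:05d}{j:02d}  {precursor}\n")
            fh.write("//\n")


def read_family_file(path) -> dict[str, str]:
    from .known import parse_family_file

    with open(path) as fh:
        return parse_family_file(fh.read())


def write_tags_tsv(tags: pd.DataFrame, path) -> None:
    tags.to_csv(path, sep="\t")


def read_tags_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_table(df: pd.DataFrame, path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)
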