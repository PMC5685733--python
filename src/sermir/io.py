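"""Readers and writers for the standard formats the pipeline touches.

FASTA and FASTQ go through Biopython; GFF3 through gffutils (miRBase
convention: 1-based inclusive coordinates, converted to 0-based
half-open in memory). Count matrices and metadata tables are plain TSV
via pandas.
"""

from __future__ import annotations

import os
from typing import Iterable, Iterator

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.SeqIO.QualityIO import FastqGeneralIterator


def read_fasta(path) -> dict[str, str]:
    """Return id -> sequence (uppercase, as stored) for a FASTA file."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, records: Iterable[tuple[str, str]], descriptions=None) -> None:
    descriptions = descriptions or {}
    recs = [
        SeqRecord(Seq(seq), id=name, description=descriptions.get(name, ""))
        for name, seq in records
    ]
    SeqIO.write(recs, str(path), "fasta")


def iter_fastq(path) -> Iterator[tuple[str, str]]:
    """Yield (read id, sequence) pairs; qualities are ignored downstream."""
    with open(path) as fh:
        for title, seq, _qual in FastqGeneralIterator(fh):
            yield title.split()[0], seq


def write_fastq(path, reads: Iterable[tuple[str, str]], quality_char: str = "I") -> None:
    """Write reads with a constant Phred+33 quality string."""
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{quality_char * len(seq)}\n")


def write_mirna_gff3(path, loci) -> None:
    """Write mature-miRNA loci as GFF3 (1-based inclusive, strand honored)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for loc in loci:
            attrs = f"ID={loc.name};Name={loc.mature_name}"
            fh.write(
                f"{loc.contig}\tsermir\tmiRNA\t{loc.start + 1}\t{loc.end}\t.\t"
                f"{loc.strand}\t.\t{attrs}\n"
            )


def read_mirna_gff3(path):
    """Parse a miRBase-style GFF3 of mature loci into MirnaLocus records."""
    from .synthetic_data import MirnaLocus

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    loci = []
    for feat in db.features_of_type("miRNA"):
        loci.append(
            MirnaLocus(
                name=feat.attributes["ID"][0],
                mature_name=feat.attributes.get("Name", [feat.id])[0],
                contig=feat.seqid,
                start=feat.start - 1,
                end=feat.end,
                strand=feat.strand,
            )
        )
    return loci


def write_tsv(df: pd.DataFrame, path, index: bool = True) -> None:
    os.makedirs(os.path.dirname(str(path)) or ".", exist_ok=True)
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)
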