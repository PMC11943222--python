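"""Readers and writers for the text formats the pipeline exchanges."""

from __future__ import annotations

import tempfile

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = ["read_fasta", "write_fasta", "write_gff3", "read_gff3_features"]


def read_fasta(path) -> dict[str, str]:
    """FASTA file -> ordered {id: sequence}."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="")
               for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def write_gff3(features: pd.DataFrame, path) -> None:
    """Write features (contig, source, type, start, end, strand, ID) as GFF3.

    Coordinates are 1-based inclusive per the GFF3 convention.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, row in features.iterrows():
            attrs = f"ID={row['ID']}"
            fh.write("\t".join([
                str(row["contig"]), str(row.get("source", "ncrip")),
                str(row["type"]), str(int(row["start"])), str(int(row["end"])),
                ".", str(row.get("strand", "+")), ".", attrs]) + "\n")


def read_gff3_features(path, feature_type: str | None = None) -> pd.DataFrame:
    """Parse a GFF3 file into a frame of (ID, contig, type, start, end, strand)."""
    db = gffutils.create_db(str(path), ":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    rows = []
    for feat in db.all_features():
        if feature_type is not None and feat.featuretype != feature_type:
            continue
        rows.append({"gene_id": feat.id, "contig": feat.seqid,
                     "type": feat.featuretype, "start": feat.start,
                     "end": feat.end, "strand": feat.strand})
    return pd.DataFrame(rows)
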