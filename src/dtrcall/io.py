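"""File-format adapters: FASTA, FASTQ, GFF3, BLAST outfmt-6, truth tables.

Standard formats go through the standard libraries (Biopython, gffutils,
pandas); this module only adapts them to the package's internal types.
"""

from __future__ import annotations

import os
from typing import Iterable, List, Sequence, Tuple

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .genome import GeneFeature, GenomeInterval

BLAST6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_fasta(path: str) -> List[Tuple[str, str]]:
    """Read a FASTA file into ``[(name, sequence), ...]``."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(path, "fasta")]


def write_fasta(path: str, records: Iterable[Tuple[str, str]], width: int = 70) -> None:
    """Write ``(name, sequence)`` pairs as FASTA wrapped at ``width`` columns."""
    seq_records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(seq_records)


def read_fastq(path: str) -> List[Tuple[str, str, str]]:
    """Read FASTQ into ``[(read_id, sequence, quality), ...]`` (Phred+33 text)."""
    with open(path) as handle:
        return [(title.split()[0], seq.upper(), qual)
                for title, seq, qual in FastqGeneralIterator(handle)]


def write_fastq(path: str, reads: Iterable[Tuple[str, str, str]]) -> None:
    with open(path, "w") as handle:
        for read_id, seq, qual in reads:
            handle.write(f"@{read_id}\n{seq}\n+\n{qual}\n")


def read_gff3(path: str) -> List[GeneFeature]:
    """Read CDS and tRNA features from a GFF3 file.

    Only CDS and tRNA rows are consumed; coordinates are converted from
    GFF3 1-based inclusive to internal 0-based half-open.
    """
    import gffutils

    db = gffutils.create_db(
        path, ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    features: List[GeneFeature] = []
    for kind in ("CDS", "tRNA"):
        for f in db.features_of_type(kind, order_by="start"):
            attrs = {k: v[0] for k, v in f.attributes.items() if v}
            frame = int(f.frame) if f.frame not in (None, ".", "") else 0
            features.append(
                GeneFeature(
                    interval=GenomeInterval(f.start - 1, f.end, f.strand or "."),
                    kind=kind,
                    frame=frame,
                    attributes=attrs,
                )
            )
    features.sort(key=lambda g: (g.interval.start, g.interval.end))
    return features


def write_gff3(path: str, seqid: str, seq_length: int,
               features: Sequence[GeneFeature]) -> None:
    """Write features as GFF3 (1-based inclusive coordinates)."""
    with open(path, "w") as handle:
        handle.write("##gff-version 3\n")
        handle.write(f"##sequence-region {seqid} 1 {seq_length}\n")
        for f in features:
            kind = f.kind if f.kind != "other" else f.attributes.get("type", "region")
            attrs = ";".join(f"{k}={v}" for k, v in f.attributes.items()) or "."
            frame = str(f.frame) if f.kind == "CDS" else "."
            handle.write(
                "\t".join([
                    seqid, "dtrcall", kind,
                    str(f.interval.start + 1), str(f.interval.end),
                    ".", f.interval.strand, frame, attrs,
                ]) + "\n"
            )


def read_blast6(path: str) -> pd.DataFrame:
    """Read a tabular BLAST (outfmt 6) file with the default 12 columns."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 12:
        raise ValueError(
            f"expected >= 12 outfmt-6 columns, found {df.shape[1]} in {path}"
        )
    df = df.iloc[:, :12]
    df.columns = BLAST6_COLUMNS
    return df


def write_truth_tsv(path: str, reads) -> None:
    """Write per-read ground truth (simulator output) as TSV."""
    rows = []
    for r in reads:
        t = r.truth
        rows.append({
            "read_id": r.id,
            "molecule": t.molecule,
            "offset": t.offset,
            "strand": t.strand,
            "tagged": int(t.tagged),
            "tag_end": t.tag_end or ".",
            "junction_pos": -1 if t.junction is None else t.junction,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_truth_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_depth_tsv(path: str, depths) -> None:
    pd.DataFrame({"pos": range(1, len(depths) + 1), "depth": depths}).to_csv(
        path, sep="\t", index=False
    )


def write_bedgraph(path: str, chrom: str, depths) -> None:
    """Write per-base depth as a run-length-compressed bedGraph."""
    with open(path, "w") as handle:
        start = 0
        current = depths[0] if len(depths) else 0
        for i in range(1, len(depths)):
            if depths[i] != current:
                handle.write(f"{chrom}\t{start}\t{i}\t{current}\n")
                start, current = i, depths[i]
        if len(depths):
            handle.write(f"{chrom}\t{start}\t{len(depths)}\t{current}\n")


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
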