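"""Reading and writing the pipeline's on-disk formats.

FASTA via Biopython; mature-arm annotations as miRBase-dialect GFF3 (type
``miRNA`` nested under ``miRNA_primary_transcript``, 1-based inclusive
coordinates, each hairpin on its own sequence region); presence/absence and
count tables as TSV; trees as Newick with quoted ``name|rank=K`` node
labels.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from mirevol.divergence import RegionAnnotation


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper().replace("U", "T")
            for rec in SeqIO.parse(str(path), "fasta")}


def read_reads(path) -> list[str]:
    """Read sequences from FASTA or FASTQ (by extension)."""
    p = str(path)
    fmt = "fastq" if p.endswith((".fastq", ".fq")) else "fasta"
    return [str(rec.seq).upper().replace("U", "T") for rec in SeqIO.parse(p, fmt)]


def write_gff3(arms: dict[str, RegionAnnotation], path) -> None:
    """miRBase-dialect GFF3: one primary transcript + nested miRNA per arm."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for lid, ann in arms.items():
            fh.write(f"{lid}\t.\tmiRNA_primary_transcript\t1\t{ann.hairpin_length}"
                     f"\t.\t+\t.\tID={lid};Name={lid}\n")
            for arm, start, end in ann.arms:
                fh.write(f"{lid}\t.\tmiRNA\t{start}\t{end}\t.\t+\t.\t"
                         f"ID={lid}-{arm};Name={lid}-{arm};Derives_from={lid}\n")


def read_gff3(path) -> dict[str, RegionAnnotation]:
    """Parse the miRBase-dialect GFF3 written by :func:`write_gff3`."""
    lengths: dict[str, int] = {}
    arms: dict[str, list[tuple[str, int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            seqid, _, ftype, start, end, _, _, _, attrs = fields[:9]
            attr = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            if ftype == "miRNA_primary_transcript":
                lengths[seqid] = int(end)
            elif ftype == "miRNA":
                parent = attr.get("Derives_from", seqid)
                name = attr.get("ID", "")
                arm = name.rsplit("-", 1)[-1] if "-" in name else "5p"
                arms.setdefault(parent, []).append((arm, int(start), int(end)))
    out = {}
    for lid, length in lengths.items():
        out[lid] = RegionAnnotation(hairpin_length=length,
                                    arms=tuple(arms.get(lid, ())))
    return out


def write_tsv(df: pd.DataFrame, path, index_label: str | None = None) -> None:
    df.to_csv(path, sep="\t", index_label=index_label or df.index.name or "id")


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_newick(newick: str, path) -> None:
    Path(path).write_text(newick if newick.endswith("\n") else newick + "\n")


def write_reads_fasta(reads: list[str], path, prefix: str = "read") -> None:
    with open(path, "w") as fh:
        for i, seq in enumerate(reads):
            fh.write(f">{prefix}{i + 1}\n{seq}\n")
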