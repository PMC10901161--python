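"""File loading helpers (FASTA/FASTQ via Biopython, feature tables, configs)."""
from __future__ import annotations

from pathlib import Path

from Bio import SeqIO

from .simulate import Feature, ReadSet, VectorMap


def load_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def load_reads(path: str | Path) -> ReadSet:
    """FASTQ (or FASTA, with placeholder qualities) into a ReadSet."""
    path = Path(path)
    fmt = "fasta" if path.suffix.lower() in (".fa", ".fasta", ".fna") else "fastq"
    reads: list[tuple[str, str, str]] = []
    for rec in SeqIO.parse(str(path), fmt):
        seq = str(rec.seq).upper()
        if fmt == "fastq":
            qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        else:
            qual = "I" * len(seq)
        reads.append((rec.id, seq, qual))
    read_length = max((len(s) for _, s, _ in reads), default=0)
    return ReadSet(reads, read_length, source_name=path.stem)


def load_feature_table(path: str | Path) -> list[Feature]:
    feats: list[Feature] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("label"):
            raise ValueError("feature table must start with a 'label' header line")
        for line in fh:
            if not line.strip():
                continue
            label, start, end, strand = line.rstrip("\n").split("\t")
            feats.append(Feature(label, int(start), int(end), strand))
    return feats


def load_vector(
    fasta: str | Path,
    feature_table: str | Path | None = None,
    topology: str = "circular",
) -> VectorMap:
    seqs = load_fasta(fasta)
    if len(seqs) != 1:
        raise ValueError("vector FASTA must contain exactly one record")
    (name, seq), = seqs.items()
    feats = load_feature_table(feature_table) if feature_table else []
    return VectorMap(seq, topology, feats, name=name)
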