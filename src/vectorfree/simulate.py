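"""Synthetic data generator: host genomes, annotated binary vectors,
integration events and shotgun reads with known ground truth.

The generator emulates the inputs of a transgene-freedom verification
study: a large host genome (stand-in for a plant genome), a circular
binary vector partitioned into a T-DNA region and a backbone, an optional
integration of a (possibly truncated) vector segment into the host, and
optional host-vector homologous tracts that produce the background k-mer
signal a wild-type genome shows against a vector built from plant-derived
elements. Reads are single-end with i.i.d. substitution errors; every
operation is a pure function of its arguments including the seed.

Coordinates are 1-based inclusive throughout.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._encode import decode, encode, revcomp_codes

FEATURE_LABELS = {"tdna", "backbone", "marker", "nuclease_cassette", "probe", "other"}


@dataclass
class Feature:
    label: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    strand: str = "+"


@dataclass
class HostGenome:
    sequence: str
    name: str = "host"
    ploidy_note: str = "copies identical unless an edit is applied"

    def __post_init__(self) -> None:
        if set(self.sequence) - set("ACGT"):
            raise ValueError("host genome alphabet restricted to A/C/G/T")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class VectorMap:
    """Circular (or linear) vector sequence with labelled intervals."""

    sequence: str
    topology: str = "circular"
    features: list[Feature] = field(default_factory=list)
    homology_tracts: list[tuple[int, int]] = field(default_factory=list)
    name: str = "vector"

    def __post_init__(self) -> None:
        if self.topology not in ("circular", "linear"):
            raise ValueError(f"unknown topology {self.topology!r}")
        L = len(self.sequence)
        for f in self.features:
            if f.label not in FEATURE_LABELS:
                raise ValueError(f"unknown feature label {f.label!r}")
            if not (1 <= f.start <= f.end <= L):
                raise ValueError(f"feature {f.label} interval outside [1, {L}]")
        tdna = self.feature("tdna")
        backbone = self.feature("backbone")
        if tdna and backbone:
            if not (tdna.end < backbone.start or backbone.end < tdna.start):
                raise ValueError("tdna and backbone must be disjoint")
            if (tdna.end - tdna.start + 1) + (backbone.end - backbone.start + 1) != L:
                raise ValueError("tdna and backbone must jointly cover the vector")
        probe = self.feature("probe")
        if probe and tdna and backbone:
            in_tdna = tdna.start <= probe.start and probe.end <= tdna.end
            in_bb = backbone.start <= probe.start and probe.end <= backbone.end
            if in_tdna == in_bb:
                raise ValueError("probe must lie within exactly one compartment")

    def __len__(self) -> int:
        return len(self.sequence)

    def feature(self, label: str) -> Feature | None:
        for f in self.features:
            if f.label == label:
                return f
        return None

    def segment(self, start: int, end: int) -> str:
        """Sequence of [start, end]; start > end wraps the origin (circular)."""
        L = len(self.sequence)
        if not (1 <= start <= L and 1 <= end <= L):
            raise ValueError("interval outside vector")
        if start <= end:
            return self.sequence[start - 1:end]
        if self.topology != "circular":
            raise ValueError("wrap-around interval on a linear vector")
        return self.sequence[start - 1:] + self.sequence[:end]


@dataclass
class TruthRecord:
    """Simulation ground truth for parameter-recovery tests."""

    integrated: bool = False
    vector_interval: tuple[int, int] | None = None
    host_locus: int | None = None
    homology_tracts: list[tuple[tuple[int, int], tuple[int, int]]] = field(
        default_factory=list
    )
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.integrated and (
            self.vector_interval is not None or self.host_locus is not None
        ):
            raise ValueError("non-integrated record cannot carry coordinates")


@dataclass
class ReadSet:
    """Single-end reads of one declared length with placeholder qualities."""

    reads: list[tuple[str, str, str]]
    read_length: int
    source_name: str = "reads"

    def __len__(self) -> int:
        return len(self.reads)

    def sequences(self) -> list[str]:
        return [seq for _, seq, _ in self.reads]


def make_host_genome(length: int, gc: float, seed: int, name: str = "host") -> HostGenome:
    """Random host genome with i.i.d. bases and P(G)+P(C)=gc."""
    if length < 1000:
        raise ValueError("host genome length must be >= 1000")
    if not 0.0 < gc < 1.0:
        raise ValueError("gc must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=length, p=p).astype(np.uint8)
    return HostGenome(decode(codes), name=name)


def make_vector(
    tdna_len: int,
    backbone_len: int,
    seed: int,
    homology: list[int] | None = None,
    probe_len: int = 500,
    gc: float = 0.5,
    name: str = "vector",
) -> VectorMap:
    """Random circular binary vector: T-DNA [1, tdna_len] then backbone.

    A selectable-marker feature and a nuclease-expression cassette are
    nested inside the T-DNA, and a probe feature of ``probe_len`` bp sits
    inside the cassette (mirroring a hybridisation probe within the
    nuclease structural gene). Optional ``homology`` tract lengths are
    reserved on the vector, alternating T-DNA/backbone, for later
    verbatim embedding into a host genome.
    """
    if tdna_len < 500 or backbone_len < 500:
        raise ValueError("tdna_len and backbone_len must both be >= 500")
    rng = np.random.default_rng(seed)
    total = tdna_len + backbone_len
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = decode(rng.choice(4, size=total, p=p).astype(np.uint8))

    features = [
        Feature("tdna", 1, tdna_len),
        Feature("backbone", tdna_len + 1, total),
    ]
    cas_len = min(1000, max(tdna_len // 2, probe_len))
    cas_len = min(cas_len, tdna_len)
    cas_start = 1 + (tdna_len - cas_len) // 2
    if cas_len >= probe_len + 2:
        features.append(Feature("nuclease_cassette", cas_start, cas_start + cas_len - 1))
        pr_start = cas_start + (cas_len - probe_len) // 2
    else:
        pr_start = 1 + (tdna_len - probe_len) // 2
    if probe_len > tdna_len:
        raise ValueError("probe_len larger than T-DNA")
    features.append(Feature("probe", pr_start, pr_start + probe_len - 1))
    if tdna_len >= 400:
        features.append(Feature("marker", 51, 350))

    tracts: list[tuple[int, int]] = []
    if homology:
        compartments = [(1, tdna_len), (tdna_len + 1, total)]
        for i, tlen in enumerate(homology):
            lo, hi = compartments[i % 2]
            if hi - lo + 1 < tlen:
                raise ValueError("homology tract longer than compartment")
            start = int(rng.integers(lo, hi - tlen + 2))
            tracts.append((start, start + tlen - 1))

    return VectorMap(seq, "circular", features, tracts, name=name)


def integrate(
    host: HostGenome,
    vector: VectorMap,
    vector_interval: tuple[int, int] | None,
    host_locus: int | None,
    seed: int | None = None,
) -> tuple[HostGenome, TruthRecord]:
    """Insert the vector segment [start, end] into the host after host_locus.

    Passing ``vector_interval=None`` is the identity: the host is returned
    unchanged with ``TruthRecord.integrated=False``. The returned genome
    length is exactly host length + segment length; no other base changes.
    """
    if vector_interval is None:
        return host, TruthRecord(integrated=False, seed=seed)
    if host_locus is None or not (1 <= host_locus <= len(host)):
        raise ValueError("host_locus outside host genome")
    start, end = vector_interval
    segment = vector.segment(start, end)
    seq = host.sequence[:host_locus] + segment + host.sequence[host_locus:]
    truth = TruthRecord(
        integrated=True,
        vector_interval=(start, end),
        host_locus=host_locus,
        seed=seed,
    )
    return HostGenome(seq, name=f"{host.name}+{vector.name}[{start}-{end}]"), truth


def embed_homology(
    host: HostGenome, vector: VectorMap, seed: int
) -> tuple[HostGenome, list[tuple[tuple[int, int], tuple[int, int]]]]:
    """Copy the vector's homology tracts verbatim into the host.

    Each tract overwrites a host window of equal length at a
    generator-chosen locus (host length is conserved), emulating
    plant-derived vector elements that share sequence with the host
    genome. Loci are non-overlapping and at least one read length from
    the sequence ends.
    """
    rng = np.random.default_rng(seed)
    seq = list(host.sequence)
    placed: list[tuple[int, int]] = []
    pairs: list[tuple[tuple[int, int], tuple[int, int]]] = []
    margin = 200
    for (vs, ve) in vector.homology_tracts:
        tlen = ve - vs + 1
        for _ in range(1000):
            start = int(rng.integers(margin + 1, len(host) - tlen - margin))
            if all(start + tlen < s - margin or start > e + margin for s, e in placed):
                break
        else:  # pragma: no cover - would need a pathologically full host
            raise ValueError("could not place homology tracts without overlap")
        seq[start - 1:start - 1 + tlen] = vector.sequence[vs - 1:ve]
        placed.append((start, start + tlen - 1))
        pairs.append(((start, start + tlen - 1), (vs, ve)))
    return HostGenome("".join(seq), name=host.name), pairs


def simulate_reads(
    genome: HostGenome,
    depth: float,
    read_length: int,
    error_rate: float = 0.0,
    seed: int = 0,
    source_name: str | None = None,
) -> ReadSet:
    """Uniform single-end shotgun reads at the requested fold-coverage.

    Read count is round(genome_length * depth / read_length); start
    positions are uniform, strands equiprobable, and errors are i.i.d.
    substitutions to a different base. Qualities are a constant
    placeholder ('I'); no quality model is used downstream.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    if read_length > len(genome):
        raise ValueError("read_length exceeds genome length")
    if not 0.0 <= error_rate < 0.1:
        raise ValueError("error_rate must lie in [0, 0.1)")
    rng = np.random.default_rng(seed)
    L = len(genome)
    n = int(round(L * depth / read_length))
    codes = encode(genome.sequence)
    starts = rng.integers(0, L - read_length + 1, size=n)
    mat = codes[starts[:, None] + np.arange(read_length)]
    minus = rng.random(n) < 0.5
    mat[minus] = revcomp_codes(mat[minus])
    if error_rate > 0:
        err = rng.random((n, read_length)) < error_rate
        shift = rng.integers(1, 4, size=int(err.sum()), dtype=np.uint8)
        mat[err] = (mat[err] + shift) % 4
    blob = decode(mat.reshape(-1))
    qual = "I" * read_length
    name = source_name or genome.name
    reads = [
        (f"{name}_r{i}", blob[i * read_length:(i + 1) * read_length], qual)
        for i in range(n)
    ]
    return ReadSet(reads, read_length, source_name=name)


# ---------------------------------------------------------------------------
# plain-text writers

def write_fasta(path: str | Path, records: list[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


def write_fastq(path: str | Path, reads: ReadSet) -> None:
    with open(path, "w") as fh:
        for rid, seq, qual in reads.reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def write_feature_table(path: str | Path, vector: VectorMap) -> None:
    with open(path, "w") as fh:
        fh.write("label\tstart\tend\tstrand\n")
        for f in vector.features:
            fh.write(f"{f.label}\t{f.start}\t{f.end}\t{f.strand}\n")


def write_truth(path: str | Path, truth: TruthRecord) -> None:
    with open(path, "w") as fh:
        json.dump(dataclasses.asdict(truth), fh, indent=2)
        fh.write("\n")


def read_truth(path: str | Path) -> TruthRecord:
    with open(path) as fh:
        d = json.load(fh)
    if d.get("vector_interval") is not None:
        d["vector_interval"] = tuple(d["vector_interval"])
    d["homology_tracts"] = [
        (tuple(h), tuple(v)) for h, v in d.get("homology_tracts", [])
    ]
    return TruthRecord(**d)
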