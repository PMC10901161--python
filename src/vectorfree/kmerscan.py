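"""Per-position k-mer profiling of sequencing reads against a vector.

The vector contributes one canonical k-mer per position (positions
1..L on a circular vector, wrap-around k-mers included; 1..L-k+1 on a
linear one). Scanning counts, for every vector position, how many reads
contain that position's k-mer — read-level presence, so a read
increments a position at most once and the library size is a clean
margin for the downstream 2x2 G-test. Canonical k-mers (the
lexicographic minimum of a k-mer and its reverse complement) make the
profile invariant to read strand.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._encode import SENTINEL, encode, revcomp, revcomp_codes
from .simulate import ReadSet, VectorMap

_INVALID = np.uint64(0xFFFFFFFFFFFFFFFF)


def canonical(kmer: str) -> str:
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


@dataclass
class PositionIndex:
    """Maps each canonical vector k-mer to the 1-based positions holding it."""

    k: int
    topology: str
    kmer_to_positions: dict[str, list[int]]
    vector_length: int
    n_positions: int
    # packed lookup tables (k <= 31 only): sorted 2-bit codes + CSR positions
    _codes: np.ndarray | None = field(default=None, repr=False)
    _offsets: np.ndarray | None = field(default=None, repr=False)
    _pos_flat: np.ndarray | None = field(default=None, repr=False)


@dataclass
class KmerHitProfile:
    """Read-level hit counts per vector position for one read set."""

    counts: np.ndarray
    library_size: int
    k: int
    sample_name: str
    topology: str = "circular"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.size and (
            self.counts.min() < 0 or self.counts.max() > self.library_size
        ):
            raise ValueError("counts must lie in [0, library_size]")

    @property
    def n_positions(self) -> int:
        return int(self.counts.size)


def _kmer_code(kmer: str) -> int:
    code = 0
    for c in encode(kmer):
        code = (code << 2) | int(c)
    return code


def build_index(
    vector: VectorMap | str, k: int, topology: str | None = None
) -> PositionIndex:
    """One canonical k-mer per vector position.

    k-mers containing non-ACGT characters are skipped (their position is
    simply absent from the mapping).
    """
    if isinstance(vector, VectorMap):
        seq = vector.sequence
        topo = topology or vector.topology
    else:
        seq = vector
        topo = topology or "circular"
    L = len(seq)
    if not 4 <= k <= 63:
        raise ValueError("k must lie in [4, 63]")
    if k > L:
        raise ValueError("k exceeds vector length")

    if topo == "circular":
        padded = seq + seq[:k - 1]
        n_positions = L
    else:
        padded = seq
        n_positions = L - k + 1

    mapping: dict[str, list[int]] = {}
    for i in range(n_positions):
        kmer = padded[i:i + k]
        if set(kmer) - set("ACGT"):
            continue
        mapping.setdefault(canonical(kmer), []).append(i + 1)

    codes = offsets = pos_flat = None
    if k <= 31:
        items = sorted((_kmer_code(km), pos) for km, pos in mapping.items())
        codes = np.array([c for c, _ in items], dtype=np.uint64)
        degree = np.array([len(p) for _, p in items], dtype=np.int64)
        offsets = np.concatenate([[0], np.cumsum(degree)])
        pos_flat = np.array(
            [p for _, plist in items for p in plist], dtype=np.int64
        )
    return PositionIndex(k, topo, mapping, L, n_positions, codes, offsets, pos_flat)


def _rolling_codes(mat: np.ndarray, k: int) -> np.ndarray:
    """Canonical 2-bit k-mer codes for each window of each row.

    Returns an (n_reads, L-k+1) uint64 array; windows containing a
    non-ACGT base are set to the invalid marker.
    """
    n, L = mat.shape
    P = L - k + 1
    invalid = mat >= SENTINEL
    base = np.where(invalid, 0, mat).astype(np.uint64)
    rc = revcomp_codes(mat)
    base_rc = np.where(rc >= SENTINEL, 0, rc).astype(np.uint64)

    mask = np.uint64((1 << (2 * k)) - 1) if 2 * k < 64 else _INVALID

    def roll(b: np.ndarray) -> np.ndarray:
        out = np.empty((n, P), dtype=np.uint64)
        code = np.zeros(n, dtype=np.uint64)
        for j in range(k):
            code = (code << np.uint64(2)) | b[:, j]
        out[:, 0] = code
        for i in range(1, P):
            code = ((code << np.uint64(2)) | b[:, i + k - 1]) & mask
            out[:, i] = code
        return out

    fwd = roll(base)
    rev = roll(base_rc)[:, ::-1]
    canon = np.minimum(fwd, rev)

    cs = np.zeros((n, L + 1), dtype=np.int32)
    np.cumsum(invalid, axis=1, out=cs[:, 1:])
    bad = (cs[:, k:] - cs[:, :-k]) > 0
    canon[bad] = _INVALID
    return canon


def _scan_packed(seqs: list[str], read_length: int, index: PositionIndex) -> np.ndarray:
    counts = np.zeros(index.n_positions, dtype=np.int64)
    if not seqs:
        return counts
    blob = "".join(seqs)
    mat = encode(blob).reshape(len(seqs), read_length)
    canon = _rolling_codes(mat, index.k)
    # read-level presence: dedupe codes within each row
    srt = np.sort(canon, axis=1)
    first = np.ones_like(srt, dtype=bool)
    first[:, 1:] = srt[:, 1:] != srt[:, :-1]
    sel = first & (srt != _INVALID)
    flat = srt[sel]
    pos = np.searchsorted(index._codes, flat)
    pos[pos >= index._codes.size] = 0
    hit = index._codes[pos] == flat
    if not hit.any():
        return counts
    per_code = np.bincount(pos[hit], minlength=index._codes.size)
    nz = np.nonzero(per_code)[0]
    degree = (index._offsets[nz + 1] - index._offsets[nz]).astype(np.int64)
    pos_idx = np.concatenate(
        [index._pos_flat[index._offsets[i]:index._offsets[i + 1]] for i in nz]
    )
    weights = np.repeat(per_code[nz], degree)
    counts += np.bincount(pos_idx - 1, weights=weights, minlength=index.n_positions).astype(np.int64)
    return counts


def _scan_generic(seqs: list[str], index: PositionIndex) -> np.ndarray:
    counts = np.zeros(index.n_positions, dtype=np.int64)
    k = index.k
    for seq in seqs:
        if len(seq) < k:
            continue
        seen: set[str] = set()
        for i in range(len(seq) - k + 1):
            seen.add(canonical(seq[i:i + k]))
        for km in seen:
            for p in index.kmer_to_positions.get(km, ()):
                counts[p - 1] += 1
    return counts


def scan_reads(reads: ReadSet, index: PositionIndex, sample_name: str | None = None) -> KmerHitProfile:
    """Count, per vector position, the reads containing that position's k-mer.

    Reads shorter than k contribute nothing but are counted in the
    library size (sequencing effort is the margin of the downstream
    test). An empty read set is degenerate: an all-zero profile with
    library_size 0 is returned with a warning.
    """
    name = sample_name or reads.source_name
    if len(reads) == 0:
        warnings.warn("empty read set: returning all-zero profile")
        return KmerHitProfile(
            np.zeros(index.n_positions, dtype=np.int64), 0, index.k, name, index.topology
        )
    seqs = reads.sequences()
    uniform = all(len(s) == reads.read_length for s in seqs)
    if index._codes is not None and uniform and reads.read_length >= index.k:
        counts = _scan_packed(seqs, reads.read_length, index)
    else:
        counts = _scan_generic(seqs, index)
    return KmerHitProfile(counts, len(reads), index.k, name, index.topology)


def write_profile(path: str | Path, profile: KmerHitProfile) -> None:
    """Two-column TSV (position, count) plus a JSON sidecar of the margins."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("position\tcount\n")
        for i, c in enumerate(profile.counts, start=1):
            fh.write(f"{i}\t{int(c)}\n")
    sidecar = {
        "k": profile.k,
        "library_size": profile.library_size,
        "topology": profile.topology,
        "sample_name": profile.sample_name,
    }
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(sidecar, fh, indent=2)
        fh.write("\n")


def read_profile(path: str | Path) -> KmerHitProfile:
    path = Path(path)
    counts = np.loadtxt(path, delimiter="\t", skiprows=1, dtype=np.int64, ndmin=2)[:, 1]
    with open(path.with_suffix(path.suffix + ".json")) as fh:
        meta = json.load(fh)
    return KmerHitProfile(
        counts, meta["library_size"], meta["k"], meta["sample_name"], meta["topology"]
    )
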