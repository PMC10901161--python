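"""Reference study designs run at desk scale.

Every quantitative claim the package makes about its own behaviour is
computed by one of these routines: type-I calibration of the
per-position G-test under a split-library null, the replicate-
intersection false-positive control, power/breakpoint recovery for a
simulated T-DNA integration, agreement of the scanner and the
G-statistic with naive independent oracles, and exact truth-matrix
agreement for the in-silico PCR and allele-classification channels.

Study conditions (sizes, depth, error rate) are fixed here as the
package's defaults; see docs/methods.md for the rationale.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._encode import revcomp
from .gtest import call_segments, g_statistic, intersect_replicates, per_position_g
from .kmerscan import build_index, scan_reads
from .orthogonal import PrimerPair, classify_alleles, line_status, presence_matrix
from .pipeline import kmer_stage, pcr_stage
from .simulate import (
    HostGenome,
    ReadSet,
    embed_homology,
    integrate,
    make_host_genome,
    make_vector,
    simulate_reads,
)

# default study conditions
READ_LENGTH = 100       # bp, single-end
DEPTH = 30.0            # fold-coverage per library
ERROR_RATE = 0.001      # per-base substitution probability (power runs use 0)
K_LIST = (20, 25)
ALPHA = 0.01
HOST_GC = 0.36          # plant-genome-like GC content
TDNA_LEN = 2000
BACKBONE_LEN = 3000
HOMOLOGY_TRACTS = [300, 300]  # promoter/terminator-scale plant-derived elements
CAL_HOST_LEN = 10_000   # calibration genome host (full vector copy embedded)
NULL_HOST_LEN = 20_000  # wild-type background for the replicate null study
POWER_HOST_LEN = 50_000


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


def _split_reads(reads: ReadSet) -> tuple[ReadSet, ReadSet]:
    """Deterministic even/odd split of one library into sample/control."""
    return (
        ReadSet(reads.reads[0::2], reads.read_length, reads.source_name + "_a"),
        ReadSet(reads.reads[1::2], reads.read_length, reads.source_name + "_b"),
    )


# ---------------------------------------------------------------------------
# null calibration

def null_calibration(
    seed: int,
    n_runs: int = 50,
    spacing: int = 150,
    k_list: tuple[int, ...] = K_LIST,
) -> dict:
    """Type-I calibration of the per-position G-test.

    The calibration genome carries one full copy of the vector so every
    vector position is testable; each run splits one shotgun library
    into sample/control halves, so the null of equal hit proportions
    holds at every position by construction. The significant fraction
    is measured over positions thinned to ``spacing`` bp (beyond the
    read length, so the selected positions share no reads and the
    binomial error model for the fraction is valid).
    """
    seeds = _child_seeds(seed, n_runs + 2)
    vector = make_vector(TDNA_LEN, BACKBONE_LEN, int(seeds[-1]))
    host = make_host_genome(CAL_HOST_LEN, HOST_GC, int(seeds[-2]))
    genome, _ = integrate(host, vector, (1, len(vector)), CAL_HOST_LEN // 2)

    indexes = {k: build_index(vector, k) for k in k_list}
    sig = {k: 0 for k in k_list}
    tested = {k: 0 for k in k_list}
    for r in range(n_runs):
        reads = simulate_reads(genome, DEPTH, READ_LENGTH, ERROR_RATE, int(seeds[r]))
        sample, control = _split_reads(reads)
        for k in k_list:
            prof_s = scan_reads(sample, indexes[k])
            prof_c = scan_reads(control, indexes[k])
            track = per_position_g(prof_s, prof_c, alpha=ALPHA)
            pick = np.arange(0, track.n_positions, spacing)
            covered = (prof_s.counts[pick] + prof_c.counts[pick]) > 0
            sig[k] += int(track.significant[pick][covered].sum())
            tested[k] += int(covered.sum())
    out = {}
    for k in k_list:
        n = tested[k]
        frac = sig[k] / n if n else float("nan")
        band = 3.0 * math.sqrt(ALPHA * (1 - ALPHA) / n) if n else float("nan")
        out[k] = {
            "fraction_significant": frac,
            "n_positions": n,
            "alpha": ALPHA,
            "band_3sd": band,
            "within_band": abs(frac - ALPHA) <= band,
        }
    return out


# ---------------------------------------------------------------------------
# replicate-intersection null

def _wt_background(seed: int, host_len: int) -> tuple:
    seeds = _child_seeds(seed, 3)
    vector = make_vector(
        TDNA_LEN, BACKBONE_LEN, int(seeds[0]), homology=HOMOLOGY_TRACTS
    )
    host = make_host_genome(host_len, HOST_GC, int(seeds[1]))
    host, tracts = embed_homology(host, vector, int(seeds[2]))
    return vector, host, tracts


def replicate_null_study(
    seed: int, n_pairs: int = 100, k_list: tuple[int, ...] = K_LIST
) -> dict:
    """False-positive control: independent replicate pairs under the null.

    The wild-type background shares two 300 bp tracts with the vector
    (plant-derived elements), so isolated significant positions appear
    at roughly the alpha rate. Each pair runs two independent
    experiments (independent sample and control libraries from the same
    integration-free genome); a pair is clean when replicate
    intersection leaves no peak at any k.
    """
    vector, host, _ = _wt_background(seed, NULL_HOST_LEN)
    indexes = {k: build_index(vector, k) for k in k_list}
    seeds = _child_seeds(seed + 1, 4 * n_pairs)
    clean = 0
    total_peaks = 0
    total_replicated = 0
    for p in range(n_pairs):
        s = seeds[4 * p:4 * p + 4]
        calls_by_run: list[dict[int, list]] = []
        for run in range(2):
            sample = simulate_reads(
                host, DEPTH, READ_LENGTH, ERROR_RATE, int(s[2 * run])
            )
            control = simulate_reads(
                host, DEPTH, READ_LENGTH, ERROR_RATE, int(s[2 * run + 1])
            )
            per_k = {}
            for k in k_list:
                track = per_position_g(
                    scan_reads(sample, indexes[k]),
                    scan_reads(control, indexes[k]),
                    alpha=ALPHA,
                )
                per_k[k] = call_segments(track, k)
                total_peaks += len(per_k[k])
            calls_by_run.append(per_k)
        replicated = [
            intersect_replicates(calls_by_run[0][k], calls_by_run[1][k])
            for k in k_list
        ]
        n_rep = sum(len(r) for r in replicated)
        total_replicated += n_rep
        if n_rep == 0:
            clean += 1
    return {
        "n_pairs": n_pairs,
        "fraction_pairs_clean": clean / n_pairs,
        "mean_peaks_per_run_per_k": total_peaks / (2 * n_pairs * len(k_list)),
        "total_replicated_peaks": total_replicated,
    }


# ---------------------------------------------------------------------------
# power / recovery

def power_study(
    seed: int,
    k: int = 20,
    vector_interval: tuple[int, int] = (1, TDNA_LEN),
    error_rate: float = 0.0,
) -> dict:
    """Recovery of a simulated T-DNA integration at default depth.

    Error-free 100 bp reads at 30x from the edited genome against an
    integration-free control; measures the fraction of integrated-
    segment positions flagged significant and the breakpoint error of
    the strongest called peak against the simulation ground truth.
    The host shares no sequence with the vector: power is defined for
    segments that are actually foreign (a plant-derived element inside
    the T-DNA is by construction invisible to a host-vs-vector test).
    """
    seeds0 = _child_seeds(seed, 2)
    vector = make_vector(TDNA_LEN, BACKBONE_LEN, int(seeds0[0]))
    host = make_host_genome(POWER_HOST_LEN, HOST_GC, int(seeds0[1]))
    edited, truth = integrate(host, vector, vector_interval, POWER_HOST_LEN // 2)
    seeds = _child_seeds(seed + 2, 2)
    sample = simulate_reads(edited, DEPTH, READ_LENGTH, error_rate, int(seeds[0]))
    control = simulate_reads(host, DEPTH, READ_LENGTH, error_rate, int(seeds[1]))
    index = build_index(vector, k)
    track = per_position_g(
        scan_reads(sample, index), scan_reads(control, index), alpha=ALPHA
    )
    vs, ve = truth.vector_interval
    seg = track.significant[vs - 1:ve]
    calls = call_segments(track, k)
    best = max(calls, key=lambda c: c.n_significant) if calls else None
    return {
        "truth_interval": (vs, ve),
        "fraction_segment_significant": float(seg.mean()),
        "n_calls": len(calls),
        "best_call": (best.vector_start, best.vector_end) if best else None,
        "breakpoint_error": (
            max(abs(best.vector_start - vs), abs(best.vector_end - ve))
            if best
            else None
        ),
        "track": track,
    }


def k_sensitivity_study(seed: int, error_rate: float = 0.01) -> dict:
    """With sequencing errors, longer k-mers are never more sensitive."""
    seeds0 = _child_seeds(seed, 2)
    vector = make_vector(TDNA_LEN, BACKBONE_LEN, int(seeds0[0]))
    host = make_host_genome(POWER_HOST_LEN, HOST_GC, int(seeds0[1]))
    edited, truth = integrate(host, vector, (1, TDNA_LEN), POWER_HOST_LEN // 2)
    seeds = _child_seeds(seed + 3, 2)
    sample = simulate_reads(edited, DEPTH, READ_LENGTH, error_rate, int(seeds[0]))
    control = simulate_reads(host, DEPTH, READ_LENGTH, error_rate, int(seeds[1]))
    out = {}
    vs, ve = truth.vector_interval
    for k in (20, 25):
        index = build_index(vector, k)
        track = per_position_g(
            scan_reads(sample, index), scan_reads(control, index), alpha=ALPHA
        )
        out[k] = float(track.significant[vs - 1:ve].mean())
    return out


# ---------------------------------------------------------------------------
# end-to-end verdicts

def end_to_end_verdicts(seed: int) -> dict:
    """Full verification (k-mer channel with replicates + PCR channel)
    on a clean line and on a line carrying a 2 kb T-DNA integration."""
    seeds = _child_seeds(seed + 4, 10)
    vector = make_vector(TDNA_LEN, BACKBONE_LEN, int(seeds[0]))
    host = make_host_genome(POWER_HOST_LEN, HOST_GC, int(seeds[1]))
    edited, truth = integrate(host, vector, (1, TDNA_LEN), POWER_HOST_LEN // 2)
    panel = tiled_panel(vector, host)

    def channel(genome: HostGenome, base: int) -> dict:
        sample = simulate_reads(genome, DEPTH, READ_LENGTH, 0.0, int(seeds[base]))
        control = simulate_reads(host, DEPTH, READ_LENGTH, 0.0, int(seeds[base + 1]))
        sample2 = simulate_reads(genome, DEPTH, READ_LENGTH, 0.0, int(seeds[base + 2]))
        control2 = simulate_reads(host, DEPTH, READ_LENGTH, 0.0, int(seeds[base + 3]))
        kmer = kmer_stage(vector, sample, control, (sample2, control2), k_list=K_LIST)
        kmer.pop("_tracks")
        pcr = pcr_stage(genome.sequence, vector, panel)
        return {
            "kmer": kmer,
            "pcr": pcr,
            "transgene_free": kmer["free"] and pcr["free"],
        }

    clean = channel(host, 2)
    contaminated = channel(edited, 6)
    # the replicated peak must overlap the true integrated interval
    vs, ve = truth.vector_interval
    overlap_truth = any(
        c["vector_start"] <= ve and vs <= c["vector_end"]
        for k in K_LIST
        for c in contaminated["kmer"]["k"][k]["replicated_peaks"]
    )
    return {
        "clean": clean,
        "contaminated": contaminated,
        "truth_interval": (vs, ve),
        "replicated_peak_overlaps_truth": overlap_truth,
    }


# ---------------------------------------------------------------------------
# oracle agreement

def g_oracle_direct(a: float, b: float, c: float, d: float) -> float:
    """Independent direct evaluation of 2*sum(O*ln(O/E)) (plain Python)."""
    n = a + b + c + d
    rows = (a + b, a + b, c + d, c + d)
    cols = (a + c, b + d, a + c, b + d)
    total = 0.0
    for o, r, col in zip((a, b, c, d), rows, cols):
        if o > 0:
            total += o * math.log(o / (r * col / n))
    return 2.0 * total


def g_oracle_study(seed: int, n_tables: int = 1000) -> dict:
    """Max |G - direct formula| over random tables with positive row sums."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_tables):
        a, b, c, d = (int(x) for x in rng.integers(0, 1000, size=4))
        if a + b == 0 or c + d == 0:
            b, d = b + 1, d + 1
        diff = abs(g_statistic(a, b, c, d) - g_oracle_direct(a, b, c, d))
        worst = max(worst, diff)
    return {"n_tables": n_tables, "max_abs_diff": worst}


def naive_scan(reads: ReadSet, vector_seq: str, k: int, topology: str = "circular") -> np.ndarray:
    """Brute-force O(reads x positions) substring-scan oracle.

    A read hits a position when the position's k-mer occurs in the read
    or in its reverse complement.
    """
    padded = vector_seq + vector_seq[:k - 1] if topology == "circular" else vector_seq
    n_positions = len(vector_seq) if topology == "circular" else len(vector_seq) - k + 1
    counts = np.zeros(n_positions, dtype=np.int64)
    kmers = [padded[i:i + k] for i in range(n_positions)]
    for _, seq, _ in reads.reads:
        rc = revcomp(seq)
        for i, km in enumerate(kmers):
            if km in seq or km in rc:
                counts[i] += 1
    return counts


def scan_oracle_study(seed: int, k_list: tuple[int, ...] = K_LIST) -> dict:
    """Exact agreement of the production scanner with the naive oracle
    on a small (<10 kb of reads) simulated input."""
    seeds = _child_seeds(seed + 5, 3)
    vector = make_vector(500, 500, int(seeds[0]))
    host = make_host_genome(2000, 0.5, int(seeds[1]))
    genome, _ = integrate(host, vector, (200, 700), 1000)
    reads = simulate_reads(genome, 3.0, 50, 0.01, int(seeds[2]))
    mismatches = 0
    n_positions = 0
    for k in k_list:
        index = build_index(vector, k)
        prof = scan_reads(reads, index)
        oracle = naive_scan(reads, vector.sequence, k, vector.topology)
        mismatches += int((prof.counts != oracle).sum())
        n_positions += oracle.size
    return {
        "n_reads": len(reads),
        "n_positions": n_positions,
        "mismatching_positions": mismatches,
    }


# ---------------------------------------------------------------------------
# PCR truth matrix

@dataclass
class _Tile:
    set_id: str
    amp_start: int  # on vector, 1-based
    amp_end: int


def tiled_panel(
    vector,
    host: HostGenome,
    amp_len: int = 400,
    tile_step: int = 500,
    primer_len: int = 20,
    control_locus: int = 1000,
) -> list[PrimerPair]:
    """Primer pairs tiled across the vector plus a genomic control set PCR0.

    The control set targets a host locus, playing the role of the
    endogenous-gene control that every template must amplify.
    """
    seq = vector.sequence
    panel = [
        PrimerPair(
            "PCR0",
            host.sequence[control_locus - 1:control_locus - 1 + primer_len],
            revcomp(
                host.sequence[control_locus - 1 + amp_len - primer_len:control_locus - 1 + amp_len]
            ),
        )
    ]
    i = 1
    for s in range(1, len(seq) - amp_len + 2, tile_step):
        fwd = seq[s - 1:s - 1 + primer_len]
        rev = revcomp(seq[s - 1 + amp_len - primer_len:s - 1 + amp_len])
        panel.append(PrimerPair(f"PCR{i}", fwd, rev))
        i += 1
    return panel


def panel_tiles(vector, amp_len: int = 400, tile_step: int = 500) -> list[_Tile]:
    return [
        _Tile(f"PCR{i + 1}", s, s + amp_len - 1)
        for i, s in enumerate(range(1, len(vector.sequence) - amp_len + 2, tile_step))
    ]


def pcr_truth_study(seed: int, vector_interval: tuple[int, int] = (501, 2500)) -> dict:
    """Exact truth-matrix agreement for the PCR presence/absence channel.

    A vector segment is integrated into the host; a tiled primer set
    produces a band on the edited genome exactly when its whole
    amplicon lies inside the integrated interval. The observed
    presence matrix must equal this truth matrix cell for cell, and
    the genomic control must amplify on every host template.
    """
    seeds = _child_seeds(seed + 6, 2)
    vector = make_vector(TDNA_LEN, BACKBONE_LEN, int(seeds[0]))
    host = make_host_genome(30_000, HOST_GC, int(seeds[1]))
    edited, truth = integrate(host, vector, vector_interval, 15_000)
    panel = tiled_panel(vector, host)
    tiles = panel_tiles(vector)
    matrix = presence_matrix(
        {
            "vector": (vector.sequence, "circular"),
            "wild_type": host.sequence,
            "edited": edited.sequence,
        },
        panel,
    )
    vs, ve = truth.vector_interval
    agree = 0
    total = 0
    for tile in tiles:
        inside = vs <= tile.amp_start and tile.amp_end <= ve
        expected = {"vector": True, "wild_type": False, "edited": inside}
        for col, want in expected.items():
            got = bool(matrix.loc[tile.set_id, col])
            agree += int(got == want)
            total += 1
    for col, want in {"vector": False, "wild_type": True, "edited": True}.items():
        got = bool(matrix.loc["PCR0", col])
        agree += int(got == want)
        total += 1
    return {
        "n_cells": total,
        "agreement": agree / total,
        "matrix": matrix,
        "truth_interval": (vs, ve),
    }


# ---------------------------------------------------------------------------
# allele classification truth

def allele_truth_study(seed: int = 0) -> dict:
    """Constructed clones with known edits must classify exactly.

    6 bp deletion -> in-frame loss, 1 bp insertion -> frameshift,
    unmodified clone -> intact; complete-disruptant status iff no clone
    is intact.
    """
    rng = np.random.default_rng(seed)
    ref = "".join("ACGT"[i] for i in rng.integers(0, 4, size=300))
    target = (141, 160)
    cut = 150
    clones = {
        "intact": ref,
        "del6": ref[:cut] + ref[cut + 6:],
        "ins1": ref[:cut] + "A" + ref[cut:],
        "del5": ref[:cut] + ref[cut + 5:],
    }
    calls = {c.clone_id: c for c in classify_alleles(clones, ref, target)}
    expected = {
        "intact": ("intact", True),
        "del6": ("in_frame", False),
        "ins1": ("frameshift", False),
        "del5": ("frameshift", False),
    }
    agree = sum(
        int((calls[cid].frame, calls[cid].intact) == want)
        for cid, want in expected.items()
    )
    disrupted = line_status(
        [calls["del6"], calls["ins1"], calls["del5"]], "line_all_mutated"
    )
    partial = line_status([calls["intact"], calls["del6"]], "line_mixed")
    unedited = line_status([calls["intact"]], "line_unedited")
    status_ok = (
        disrupted.status == "complete_disruptant"
        and partial.status == "partial"
        and unedited.status == "unedited"
    )
    return {
        "n_clones": len(expected),
        "classification_agreement": agree / len(expected),
        "status_rules_hold": status_ok,
        "calls": calls,
    }
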