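"""Orthogonal verification computations.

Three sequence-level surrogates for the wet-lab checks used alongside
k-mer screening when certifying a transgene-free edited line:

* in-silico PCR across a tiled primer panel (the presence/absence band
  matrix over templates),
* restriction-digest fragment prediction with a probe overlap test (the
  expected-fragment logic of a Southern hybridisation),
* target-site allele classification of cloned amplicon sequences
  (indel events, reading-frame consequence, complete-disruptant status)
  plus the same classification on an off-target homolog.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import Align

from ._encode import encode, revcomp

#: recognition motif and cut offset (bases left of the cut within the motif)
ENZYMES: dict[str, tuple[str, int]] = {
    "BamHI": ("GGATCC", 1),
    "HindIII": ("AAGCTT", 1),
    "EcoRI": ("GAATTC", 1),
}


@dataclass
class PrimerPair:
    set_id: str
    forward: str
    reverse: str
    annealing_note: str = ""
    expected_products: list[int] | None = None

    def __post_init__(self) -> None:
        for p in (self.forward, self.reverse):
            if set(p) - set("ACGT"):
                raise ValueError(f"primer {p!r} has non-ACGT characters")
            if not 15 <= len(p) <= 35:
                raise ValueError("primer length must be 15-35 nt")


@dataclass
class AmpliconHit:
    template_name: str
    start: int  # 1-based inclusive; end may exceed the template length
    end: int    # when a circular product spans the origin
    length: int
    orientation: str  # "F+/R-" or "R+/F-"


@dataclass
class FragmentPrediction:
    fragment_sizes_all: list[int]
    fragments_hit_by_probe: list[int]
    enzymes: list[str]


@dataclass
class AlleleCall:
    clone_id: str
    indel_events: list[tuple[int, int, str]]  # (ref position, length, kind)
    net_indel: int
    frame: str  # intact | in_frame | frameshift
    intact: bool


@dataclass
class LineStatus:
    line_id: str
    n_clones: int
    n_intact: int
    status: str  # complete_disruptant | partial | unedited


# ---------------------------------------------------------------------------
# in-silico PCR

def _primer_sites(
    text_codes: np.ndarray,
    primer: str,
    minus: bool,
    max_mismatch: int,
    three_prime_exact: int,
) -> np.ndarray:
    """0-based window starts where the primer anneals.

    ``minus=False``: the primer matches the given strand, 3' end at the
    window's right edge (rightward extension). ``minus=True``: the primer
    anneals to the opposite strand, so its reverse complement matches the
    given strand with the primer's 3' end at the window's left edge.
    """
    query = revcomp(primer) if minus else primer
    q = encode(query)
    m = len(q)
    if text_codes.size < m:
        return np.empty(0, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(text_codes, m)
    mm = (win != q).sum(axis=1)
    ok = mm <= max_mismatch
    tpe = min(three_prime_exact, m)
    if tpe > 0:
        if minus:
            ok &= (win[:, :tpe] == q[:tpe]).all(axis=1)
        else:
            ok &= (win[:, m - tpe:] == q[m - tpe:]).all(axis=1)
    return np.nonzero(ok)[0]


def insilico_pcr(
    template: str,
    pair: PrimerPair,
    topology: str = "linear",
    max_mismatch: int = 2,
    three_prime_exact: int = 3,
    max_amplicon_length: int = 5000,
    template_name: str = "template",
) -> list[AmpliconHit]:
    """All products the primer pair would amplify from the template.

    A product requires one primer annealing on each strand, facing each
    other, with at most ``max_mismatch`` mismatches per primer and none
    in the 3'-terminal ``three_prime_exact`` bases, and a length of at
    most ``max_amplicon_length``. Circular templates allow
    origin-spanning products (reported with end > template length).
    """
    if not template:
        raise ValueError("empty template")
    L = len(template)
    if topology == "circular":
        ext = min(L, max_amplicon_length - 1)
        text = template + template[:ext]
    else:
        text = template
    codes = encode(text)

    hits: list[AmpliconHit] = []
    combos = [
        (pair.forward, pair.reverse, "F+/R-"),
        (pair.reverse, pair.forward, "R+/F-"),
    ]
    for plus_primer, minus_primer, orient in combos:
        plus_sites = _primer_sites(codes, plus_primer, False, max_mismatch, three_prime_exact)
        minus_sites = _primer_sites(codes, minus_primer, True, max_mismatch, three_prime_exact)
        plus_sites = plus_sites[plus_sites < L]  # products start on the first copy
        if plus_sites.size == 0 or minus_sites.size == 0:
            continue
        m2 = len(minus_primer)
        ends = minus_sites + m2 - 1  # 0-based product right edge
        for s in plus_sites:
            lo = np.searchsorted(minus_sites, s)
            for e in ends[lo:]:
                length = int(e - s + 1)
                if length > max_amplicon_length:
                    break
                hits.append(
                    AmpliconHit(template_name, int(s) + 1, int(e) + 1, length, orient)
                )
    hits.sort(key=lambda h: (h.start, h.length, h.orientation))
    # a palindromic-overlap edge: identical span found in both orientations
    dedup: list[AmpliconHit] = []
    seen: set[tuple[int, int]] = set()
    for h in hits:
        if (h.start, h.end) not in seen:
            seen.add((h.start, h.end))
            dedup.append(h)
    return dedup


def presence_matrix(
    templates: dict[str, str | tuple[str, str]],
    panel: list[PrimerPair],
    **pcr_kwargs,
) -> pd.DataFrame:
    """Band matrix: rows = primer sets, columns = templates.

    Each cell holds the tuple of predicted product sizes (empty tuple =
    no band). Vector-freedom by PCR requires every vector-panel cell of
    a genome column to be empty while the genomic control set amplifies.
    """
    if not panel:
        raise ValueError("empty primer panel")
    data = {}
    for name, tpl in templates.items():
        seq, topo = tpl if isinstance(tpl, tuple) else (tpl, "linear")
        col = []
        for pair in panel:
            prods = insilico_pcr(seq, pair, topology=topo, template_name=name, **pcr_kwargs)
            col.append(tuple(sorted(h.length for h in prods)))
        data[name] = col
    return pd.DataFrame(data, index=[p.set_id for p in panel])


# ---------------------------------------------------------------------------
# restriction digest + probe

def _cut_positions(seq: str, motif: str, offset: int) -> set[int]:
    """Cuts as 'number of bases to the left'; both strands if non-palindromic."""
    cuts: set[int] = set()
    L = len(seq)
    start = 0
    while True:
        i = seq.find(motif, start)
        if i < 0:
            break
        cuts.add(i + offset)
        start = i + 1
    rc = revcomp(motif)
    if rc != motif:
        start = 0
        while True:
            i = seq.find(rc, start)
            if i < 0:
                break
            cuts.add(i + len(motif) - offset)
            start = i + 1
    return {c for c in cuts if 0 < c < L}


def digest_and_probe(
    genome: str,
    topology: str,
    enzymes: list[str] | list[tuple[str, str, int]],
    vector,
    truth,
    probe_interval: tuple[int, int] | None = None,
    min_overlap: int = 50,
) -> FragmentPrediction:
    """Predict digest fragments and which of them a vector probe lights up.

    ``enzymes`` may be names from the built-in table or explicit
    (name, motif, cut_offset) triples. The probe interval defaults to the
    vector's ``probe`` feature; its integrated copy is located through
    the simulation ground truth, and fragments sharing at least
    ``min_overlap`` bp with that copy are reported. An integration-free
    genome yields an empty probe-hit list.
    """
    names: list[str] = []
    cuts: set[int] = set()
    for e in enzymes:
        if isinstance(e, str):
            motif, off = ENZYMES[e]
            names.append(e)
        else:
            e_name, motif, off = e
            names.append(e_name)
        if set(motif) - set("ACGT"):
            raise ValueError("degenerate recognition motifs not supported")
        cuts |= _cut_positions(genome, motif, off)

    L = len(genome)
    order = sorted(cuts)
    if topology == "circular":
        if not order:
            frags = [(1, L)]
        else:
            frags = [
                (order[i] + 1, order[i + 1]) for i in range(len(order) - 1)
            ] + [(order[-1] + 1, L + order[0])]  # wraps the origin
    else:
        bounds = [0] + order + [L]
        frags = [(bounds[i] + 1, bounds[i + 1]) for i in range(len(bounds) - 1)]
    sizes = [e - s + 1 for s, e in frags]

    if probe_interval is None:
        pf = vector.feature("probe")
        if pf is None:
            raise ValueError("vector has no probe feature and no interval given")
        probe_interval = (pf.start, pf.end)

    hit_sizes: list[int] = []
    probe_host = _integrated_probe_interval(truth, probe_interval)
    if probe_host is not None:
        ps, pe = probe_host
        vs, ve = truth.vector_interval
        covered = (max(probe_interval[0], vs), min(probe_interval[1], ve))
        if genome[ps - 1:pe] != vector.segment(*covered):
            raise ValueError("integration claimed but probe sequence absent from genome")
        for (fs, fe), size in zip(frags, sizes):
            if _overlap_len(fs, fe, ps, pe, L, topology) >= min_overlap:
                hit_sizes.append(size)
    return FragmentPrediction(sizes, hit_sizes, names)


def _integrated_probe_interval(truth, probe_interval) -> tuple[int, int] | None:
    """Host coordinates of the integrated copy of the probe, if any."""
    if truth is None or not truth.integrated:
        return None
    vs, ve = truth.vector_interval
    ps, pe = probe_interval
    s = max(ps, vs)
    e = min(pe, ve)
    if s > e:
        return None  # truncated segment misses the probe
    return truth.host_locus + (s - vs) + 1, truth.host_locus + (e - vs) + 1


def _overlap_len(fs: int, fe: int, ps: int, pe: int, L: int, topology: str) -> int:
    spans = [(fs, fe)]
    if topology == "circular" and fe > L:  # origin-spanning fragment
        spans = [(fs, L), (1, fe - L)]
    return max(0, max(min(e, pe) - max(s, ps) + 1 for s, e in spans))


# ---------------------------------------------------------------------------
# target-site allele classification

def _aligner(match: float = 2, mismatch: float = -3, gap_open: float = -5, gap_extend: float = -2) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = match
    al.mismatch_score = mismatch
    al.open_gap_score = gap_open
    al.extend_gap_score = gap_extend
    return al


def _events_from_alignment(aln, ref: str, clone: str) -> list[tuple[int, int, str]]:
    events: list[tuple[int, int, str]] = []
    ref_blocks = [(int(s), int(e)) for s, e in aln.aligned[0]]
    q_blocks = [(int(s), int(e)) for s, e in aln.aligned[1]]
    prev_r, prev_q = 0, 0
    first = True
    for (rs, re_), (qs, qe) in zip(ref_blocks, q_blocks):
        dr, dq = rs - prev_r, qs - prev_q
        if not first or dr or dq:
            if dr > 0:
                events.append((prev_r + 1, int(dr), "deletion"))
            if dq > 0:
                events.append((int(prev_r), int(dq), "insertion"))
        # substitutions inside the block, merged into runs
        run_start = None
        for off in range(re_ - rs):
            if ref[rs + off] != clone[qs + off]:
                if run_start is None:
                    run_start = rs + off
            elif run_start is not None:
                events.append((run_start + 1, rs + off - run_start, "substitution"))
                run_start = None
        if run_start is not None:
            events.append((run_start + 1, re_ - run_start, "substitution"))
        prev_r, prev_q = re_, qe
        first = False
    # trailing unaligned tails (global alignment end gaps)
    if len(ref) - prev_r > 0:
        events.append((prev_r + 1, len(ref) - prev_r, "deletion"))
    if len(clone) - prev_q > 0:
        events.append((prev_r, len(clone) - prev_q, "insertion"))
    return events


def _event_overlaps(event: tuple[int, int, str], start: int, end: int) -> bool:
    pos, length, kind = event
    if kind == "insertion":
        return start - 1 <= pos <= end
    return pos <= end and pos + length - 1 >= start


def classify_alleles(
    clone_seqs: list[str] | dict[str, str],
    reference: str,
    target_interval: tuple[int, int],
    min_identity: float = 0.7,
    scoring: tuple[float, float, float, float] = (2, -3, -5, -2),
) -> list[AlleleCall]:
    """Classify cloned amplicon sequences against the target reference.

    Each clone is globally aligned (affine gaps); indel/substitution
    events overlapping the target interval break the ``intact`` flag,
    and the net indel across the amplicon determines the reading-frame
    consequence (net 0 -> intact frame, multiple of 3 -> in_frame,
    otherwise frameshift). Clones aligning below ``min_identity`` are
    excluded with a warning.
    """
    if not clone_seqs:
        raise ValueError("no clone sequences given")
    if isinstance(clone_seqs, dict):
        items = list(clone_seqs.items())
    else:
        items = [(f"clone_{i + 1}", s) for i, s in enumerate(clone_seqs)]
    s, e = target_interval
    if not (1 <= s <= e <= len(reference)):
        raise ValueError("target interval outside reference")
    al = _aligner(*scoring)
    calls: list[AlleleCall] = []
    for cid, seq in items:
        aln = al.align(reference, seq)[0]
        matches = sum(
            1
            for (rs, re_), (qs, _) in zip(*aln.aligned)
            for off in range(re_ - rs)
            if reference[rs + off] == seq[qs + off]
        )
        identity = matches / max(len(reference), len(seq))
        if identity < min_identity:
            warnings.warn(f"clone {cid} unalignable (identity {identity:.2f}); excluded")
            continue
        events = _events_from_alignment(aln, reference, seq)
        net = sum(
            ln if kind == "insertion" else -ln
            for _, ln, kind in events
            if kind in ("insertion", "deletion")
        )
        overlapping = [ev for ev in events if _event_overlaps(ev, s, e)]
        if net == 0:
            frame = "intact"
        elif net % 3 == 0:
            frame = "in_frame"
        else:
            frame = "frameshift"
        calls.append(AlleleCall(cid, events, net, frame, intact=not overlapping))
    return calls


def line_status(calls: list[AlleleCall], line_id: str = "line") -> LineStatus:
    """Complete disruptant iff no sequenced clone retains an intact target."""
    if not calls:
        raise ValueError("no allele calls for line")
    n_intact = sum(1 for c in calls if c.intact)
    n = len(calls)
    if n_intact == 0:
        status = "complete_disruptant"
    elif n_intact == n:
        status = "unedited"
    else:
        status = "partial"
    return LineStatus(line_id, n, n_intact, status)


def offtarget_check(
    clone_seqs: list[str] | dict[str, str],
    homolog_reference: str,
    target_interval: tuple[int, int] | None = None,
    **kwargs,
) -> list[AlleleCall]:
    """Allele classification at a potential off-target homolog locus."""
    if target_interval is None:
        target_interval = (1, len(homolog_reference))
    return classify_alleles(clone_seqs, homolog_reference, target_interval, **kwargs)


def editing_efficiency(n_candidates: int, n_regenerated: int) -> float:
    """Percent of regenerated shoots that are transgene-free edited candidates."""
    if n_regenerated <= 0:
        raise ValueError("n_regenerated must be positive")
    if not 0 <= n_candidates <= n_regenerated:
        raise ValueError("n_candidates must lie in [0, n_regenerated]")
    return round(100.0 * n_candidates / n_regenerated, 1)


# ---------------------------------------------------------------------------
# plain-text I/O

def read_primer_panel(path: str | Path) -> list[PrimerPair]:
    """TSV with columns set_id, forward, reverse (header required)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [
        PrimerPair(r.set_id, r.forward, r.reverse)
        for r in df.itertuples(index=False)
    ]


def write_primer_panel(path: str | Path, panel: list[PrimerPair]) -> None:
    with open(path, "w") as fh:
        fh.write("set_id\tforward\treverse\n")
        for p in panel:
            fh.write(f"{p.set_id}\t{p.forward}\t{p.reverse}\n")


def write_matrix(path: str | Path, matrix: pd.DataFrame) -> None:
    out = matrix.map(lambda cell: ";".join(str(x) for x in cell) if cell else "")
    out.to_csv(path)
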