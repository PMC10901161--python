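"""Per-position G-test of an edited line against a wild-type control.

Each vector position yields a 2x2 contingency table
(hits, library_size - hits) for sample vs. control; the G-statistic
2*sum(O*ln(O/E)) is chi-square distributed with 1 df under the null of
equal hit proportions, so positions with G above the upper-alpha
chi-square quantile (6.635 at alpha=0.01) are flagged. Runs of
significant positions become candidate integration segments, and
replicate intersection — the false-positive control of the screening
design — keeps only peaks reproduced in an independent sequencing run.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .kmerscan import KmerHitProfile


@dataclass
class ContingencyTable2x2:
    """a = sample hits, b = sample misses, c = control hits, d = control misses."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")


@dataclass
class GTrack:
    g_values: np.ndarray
    alpha: float
    critical_value: float
    significant: np.ndarray
    sample_name: str
    control_name: str
    counts_sample: np.ndarray | None = None
    counts_control: np.ndarray | None = None
    sample_excess: np.ndarray | None = None
    k: int | None = None
    library_sizes: tuple[int, int] | None = None

    @property
    def n_positions(self) -> int:
        return int(self.g_values.size)


@dataclass
class IntegrationCall:
    """A called peak: run of significant positions, end extended by k-1."""

    vector_start: int
    vector_end: int
    n_significant: int
    max_g: float
    replicated: bool = False

    def overlaps(self, other: "IntegrationCall") -> bool:
        return self.vector_start <= other.vector_end and other.vector_start <= self.vector_end


def _g_array(
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    d: np.ndarray,
    williams: bool = False,
    yates: bool = False,
) -> np.ndarray:
    """Vectorised 2*sum(O*ln(O/E)) with the 0*ln0 = 0 convention.

    Tables with a zero row sum are undefined and return NaN.
    """
    a, b, c, d = (np.asarray(x, dtype=np.float64) for x in (a, b, c, d))
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    n = r1 + r2
    with np.errstate(divide="ignore", invalid="ignore"):
        if yates:
            # shrink each observed count 0.5 toward its expectation
            ea = r1 * c1 / n
            adj = np.minimum(0.5, np.abs(a - ea))
            sgn = np.sign(a - ea)
            a = a - sgn * adj
            b = b + sgn * adj
            c = c + sgn * adj
            d = d - sgn * adj
            c1, c2 = a + c, b + d

        def term(o: np.ndarray, e: np.ndarray) -> np.ndarray:
            return np.where(o > 0, o * np.log(o / e), 0.0)

        g = 2.0 * (
            term(a, r1 * c1 / n)
            + term(b, r1 * c2 / n)
            + term(c, r2 * c1 / n)
            + term(d, r2 * c2 / n)
        )
        if williams:
            q = 1.0 + ((n / r1 + n / r2 - 1.0) * (n / c1 + n / c2 - 1.0)) / (6.0 * n)
            g = g / q
    g = np.where((r1 <= 0) | (r2 <= 0), np.nan, g)
    # clip tiny negative rounding noise; G is non-negative by construction
    return np.where(np.isnan(g), np.nan, np.maximum(g, 0.0))


def g_statistic(
    t: ContingencyTable2x2 | int,
    b: int | None = None,
    c: int | None = None,
    d: int | None = None,
    williams: bool = False,
    yates: bool = False,
) -> float:
    """G for one 2x2 table; accepts a ContingencyTable2x2 or four counts.

    Returns NaN (the undefined marker, treated downstream as
    non-significant) when a row sum is zero.
    """
    if isinstance(t, ContingencyTable2x2):
        a_, b_, c_, d_ = t.a, t.b, t.c, t.d
    else:
        a_, b_, c_, d_ = t, b, c, d
    return float(_g_array(a_, b_, c_, d_, williams=williams, yates=yates))


def critical_value(alpha: float, df: int = 1) -> float:
    """Upper-alpha quantile of the chi-square distribution with df dof."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(stats.chi2.ppf(1.0 - alpha, df))


def per_position_g(
    sample: KmerHitProfile,
    control: KmerHitProfile,
    alpha: float = 0.01,
    williams: bool = False,
) -> GTrack:
    """G track of an edited-line profile against a wild-type control.

    For each position the 2x2 table is (hits, library_size - hits) in
    sample vs. control; the library-size margins are the depth
    normalisation. Significance is strict: G must exceed the critical
    value. ``sample_excess`` records where the sample hit proportion
    exceeds the control's (the direction relevant to integration).
    """
    if sample.k != control.k:
        raise ValueError("profiles built with different k")
    if sample.n_positions != control.n_positions:
        raise ValueError("profiles cover different position sets")
    a = sample.counts
    c = control.counts
    n1, n2 = sample.library_size, control.library_size
    g = _g_array(a, n1 - a, c, n2 - c, williams=williams)
    crit = critical_value(alpha, 1)
    with np.errstate(invalid="ignore"):
        significant = np.nan_to_num(g, nan=0.0) > crit
        excess = a * np.int64(n2) > c * np.int64(n1)
    return GTrack(
        g_values=g,
        alpha=alpha,
        critical_value=crit,
        significant=significant,
        sample_name=sample.sample_name,
        control_name=control.sample_name,
        counts_sample=a,
        counts_control=c,
        sample_excess=excess,
        k=sample.k,
        library_sizes=(n1, n2),
    )


def call_segments(
    track: GTrack,
    k: int,
    max_gap: int | None = None,
    require_excess: bool = True,
) -> list[IntegrationCall]:
    """Maximal runs of significant positions, merged across small gaps.

    Runs separated by <= max_gap (default k-1) non-significant positions
    are merged; each call's end is extended by k-1 because a hit at a
    starting position implies shared sequence through start+k-1. With
    ``require_excess`` only sample-excess positions seed peaks (the
    verdict concerns presence in the edited line, not depletion).
    """
    if max_gap is None:
        max_gap = k - 1
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    sig = track.significant
    if require_excess and track.sample_excess is not None:
        sig = sig & track.sample_excess
    positions = np.nonzero(sig)[0] + 1
    if positions.size == 0:
        return []
    calls: list[IntegrationCall] = []
    run = [int(positions[0])]
    for p in positions[1:]:
        if p - run[-1] - 1 <= max_gap:
            run.append(int(p))
        else:
            calls.append(_make_call(run, track, k))
            run = [int(p)]
    calls.append(_make_call(run, track, k))
    return calls


def _make_call(run: list[int], track: GTrack, k: int) -> IntegrationCall:
    end = min(run[-1] + k - 1, track.n_positions)
    g = track.g_values[np.array(run) - 1]
    return IntegrationCall(
        vector_start=run[0],
        vector_end=end,
        n_significant=len(run),
        max_g=float(np.nanmax(g)),
    )


def intersect_replicates(
    calls_run1: list[IntegrationCall], calls_run2: list[IntegrationCall]
) -> list[IntegrationCall]:
    """Calls from run 1 whose span overlaps any call in run 2.

    An empty result is the replicate-level evidence that detected peaks
    were not reproducible — the transgene-free verdict requires it.
    """
    out = []
    for c1 in calls_run1:
        if any(c1.overlaps(c2) for c2 in calls_run2):
            out.append(
                IntegrationCall(
                    c1.vector_start, c1.vector_end, c1.n_significant, c1.max_g, True
                )
            )
    return out


def write_track(path: str | Path, track: GTrack) -> None:
    """Per-position TSV: position, count_sample, count_control, G, significant."""
    with open(path, "w") as fh:
        fh.write("position\tcount_sample\tcount_control\tG\tsignificant\n")
        for i in range(track.n_positions):
            g = track.g_values[i]
            fh.write(
                f"{i + 1}\t{int(track.counts_sample[i])}\t{int(track.counts_control[i])}"
                f"\t{'' if np.isnan(g) else f'{g:.6g}'}\t{int(track.significant[i])}\n"
            )


def plot_track(path: str | Path, track: GTrack, title: str | None = None) -> None:
    """Two-panel figure: hit counts on top, G values with the alpha line below."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.arange(1, track.n_positions + 1)
    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(10, 5), sharex=True)
    ax1.vlines(x, 0, track.counts_sample, color="steelblue", lw=0.5)
    ax1.set_ylabel("read hits")
    g = np.nan_to_num(track.g_values, nan=0.0)
    colors = np.where(track.significant, "red", "grey")
    ax2.vlines(x, 0, g, colors=colors, lw=0.5)
    ax2.axhline(track.critical_value, color="red", lw=1)
    ax2.set_ylabel("G")
    ax2.set_xlabel("vector position (bp)")
    if title:
        ax1.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
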