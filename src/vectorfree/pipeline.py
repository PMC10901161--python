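"""End-to-end orchestration: simulate/load -> scan -> G-test -> orthogonal
checks -> machine-readable verdict.

The verdict is fail-closed: a line is called ``transgene_free`` only if
every detection channel that actually ran came back clean — no
replicated k-mer peak at any configured k, and no vector-panel PCR band
on the genome while the genomic control set amplifies. A failed or
disabled stage can never silently contribute a clean channel.
"""
from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .gtest import (
    GTrack,
    IntegrationCall,
    call_segments,
    intersect_replicates,
    per_position_g,
    plot_track,
    write_track,
)
from .io import load_fasta, load_reads, load_vector
from .kmerscan import build_index, scan_reads, write_profile
from .orthogonal import (
    classify_alleles,
    line_status,
    presence_matrix,
    read_primer_panel,
    write_matrix,
)
from .simulate import ReadSet, VectorMap


class StageError(RuntimeError):
    """A pipeline stage failed; the verdict is aborted, never defaulted."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Inputs, parameters and stage toggles for one verification run."""

    vector_fasta: str | None = None
    vector_features: str | None = None
    vector_topology: str = "circular"
    sample_fastq: str | None = None
    control_fastq: str | None = None
    sample_fastq_rep2: str | None = None
    control_fastq_rep2: str | None = None
    pcr_genome_fasta: str | None = None
    primer_panel_tsv: str | None = None
    pcr_control_set: str = "PCR0"
    clones_fasta: str | None = None
    target_reference_fasta: str | None = None
    target_interval: tuple[int, int] | None = None
    k_list: list[int] = field(default_factory=lambda: [20, 25])
    alpha: float = 0.01
    max_gap: int | None = None
    require_excess: bool = True
    run_kmer: bool | None = None
    run_pcr: bool | None = None
    run_alleles: bool | None = None
    seed: int = 0
    out_dir: str = "vectorfree_out"
    make_plots: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        for k in self.k_list:
            if not 4 <= k <= 63:
                raise ValueError("every k must lie in [4, 63]")
        if self.run_kmer is None:
            self.run_kmer = bool(self.sample_fastq and self.control_fastq)
        if self.run_pcr is None:
            self.run_pcr = bool(self.pcr_genome_fasta and self.primer_panel_tsv)
        if self.run_alleles is None:
            self.run_alleles = bool(self.clones_fasta and self.target_reference_fasta)
        if not (self.run_kmer or self.run_pcr or self.run_alleles):
            raise ValueError("at least one stage must be enabled")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "target_interval" in raw and raw["target_interval"] is not None:
            raw["target_interval"] = tuple(raw["target_interval"])
        return cls(**raw)


@dataclass
class Verdict:
    transgene_free: bool
    kmer: dict | None
    pcr: dict | None
    alleles: dict | None
    provenance: dict

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _call_to_dict(c: IntegrationCall) -> dict:
    return {
        "vector_start": c.vector_start,
        "vector_end": c.vector_end,
        "n_significant": c.n_significant,
        "max_g": round(c.max_g, 4),
        "replicated": c.replicated,
    }


def kmer_stage(
    vector: VectorMap,
    sample: ReadSet,
    control: ReadSet,
    replicate: tuple[ReadSet, ReadSet] | None = None,
    k_list: list[int] = (20, 25),
    alpha: float = 0.01,
    max_gap: int | None = None,
    require_excess: bool = True,
) -> dict:
    """k-mer/G-test channel over all configured k, with replicate intersection.

    Returns per-k peak lists, the replicated peaks (when a replicate
    run is provided) and the channel verdict ``free``: with replicates,
    no replicated peak at any k; without, no peak at all at any k (a
    single run cannot de-noise itself, so the bar is stricter).
    """
    result: dict = {"k": {}, "replicates_used": replicate is not None}
    tracks: dict[int, GTrack] = {}
    free = True
    for k in k_list:
        index = build_index(vector, k)
        prof_s = scan_reads(sample, index)
        prof_c = scan_reads(control, index)
        track = per_position_g(prof_s, prof_c, alpha=alpha)
        calls1 = call_segments(track, k, max_gap=max_gap, require_excess=require_excess)
        entry = {"peaks_run1": [_call_to_dict(c) for c in calls1]}
        if replicate is not None:
            prof_s2 = scan_reads(replicate[0], index)
            prof_c2 = scan_reads(replicate[1], index)
            track2 = per_position_g(prof_s2, prof_c2, alpha=alpha)
            calls2 = call_segments(track2, k, max_gap=max_gap, require_excess=require_excess)
            rep = intersect_replicates(calls1, calls2)
            entry["peaks_run2"] = [_call_to_dict(c) for c in calls2]
            entry["replicated_peaks"] = [_call_to_dict(c) for c in rep]
            free = free and not rep
        else:
            free = free and not calls1
        result["k"][k] = entry
        tracks[k] = track
    result["free"] = free
    result["_tracks"] = tracks  # not serialised; for plotting/inspection
    return result


def pcr_stage(
    genome: str,
    vector: VectorMap,
    panel,
    control_set: str = "PCR0",
    **pcr_kwargs,
) -> dict:
    """Vector-panel PCR channel on the line's genome.

    ``free`` requires every vector-panel band on the genome to be absent
    while the genomic control set amplifies (template-quality control);
    the vector template column documents that the panel works.
    """
    templates = {
        "vector": (vector.sequence, vector.topology),
        "genome": (genome, "linear"),
    }
    matrix = presence_matrix(templates, panel, **pcr_kwargs)
    vector_sets = [p.set_id for p in panel if p.set_id != control_set]
    control_ok = control_set in matrix.index and bool(
        matrix.loc[control_set, "genome"]
    )
    vector_clean = all(not matrix.loc[s, "genome"] for s in vector_sets)
    return {
        "matrix": {
            col: {s: list(matrix.loc[s, col]) for s in matrix.index}
            for col in matrix.columns
        },
        "control_amplified": control_ok,
        "vector_bands_on_genome": not vector_clean,
        "free": vector_clean and control_ok,
    }


def allele_stage(
    clones: dict[str, str],
    reference: str,
    target_interval: tuple[int, int],
    line_id: str = "line",
) -> dict:
    calls = classify_alleles(clones, reference, target_interval)
    status = line_status(calls, line_id=line_id)
    return {
        "calls": [dataclasses.asdict(c) for c in calls],
        "n_clones": status.n_clones,
        "n_intact": status.n_intact,
        "status": status.status,
    }


def run_verification(config: RunConfig) -> Verdict:
    """Execute the enabled stages and write all outputs plus a JSON verdict.

    Identical config + seeds produce identical verdict bodies (no
    timestamps enter the report). A failed stage raises StageError and
    aborts the verdict rather than passing silently.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    vector = None
    if config.vector_fasta:
        try:
            vector = load_vector(
                config.vector_fasta, config.vector_features, config.vector_topology
            )
        except Exception as exc:
            raise StageError("load", str(exc)) from exc

    kmer_result = pcr_result = allele_result = None

    if config.run_kmer:
        if vector is None:
            raise StageError("kmer", "vector FASTA required for the k-mer stage")
        try:
            sample = load_reads(config.sample_fastq)
            control = load_reads(config.control_fastq)
            replicate = None
            if config.sample_fastq_rep2 and config.control_fastq_rep2:
                replicate = (
                    load_reads(config.sample_fastq_rep2),
                    load_reads(config.control_fastq_rep2),
                )
            kmer_result = kmer_stage(
                vector,
                sample,
                control,
                replicate,
                k_list=config.k_list,
                alpha=config.alpha,
                max_gap=config.max_gap,
                require_excess=config.require_excess,
            )
            tracks = kmer_result.pop("_tracks")
            for k, track in tracks.items():
                write_track(out / f"gtrack_k{k}.tsv", track)
                if config.make_plots:
                    plot_track(out / f"gtrack_k{k}.png", track, title=f"k={k}")
                index = build_index(vector, k)
                write_profile(out / f"profile_sample_k{k}.tsv", scan_reads(sample, index))
        except StageError:
            raise
        except Exception as exc:
            raise StageError("kmer", str(exc)) from exc

    if config.run_pcr:
        if vector is None:
            raise StageError("pcr", "vector FASTA required for the PCR stage")
        try:
            genome = "".join(load_fasta(config.pcr_genome_fasta).values())
            panel = read_primer_panel(config.primer_panel_tsv)
            pcr_result = pcr_stage(genome, vector, panel, config.pcr_control_set)
            import pandas as pd

            write_matrix(
                out / "pcr_matrix.csv",
                pd.DataFrame(
                    {
                        col: [tuple(v) for v in colmap.values()]
                        for col, colmap in pcr_result["matrix"].items()
                    },
                    index=list(next(iter(pcr_result["matrix"].values())).keys()),
                ),
            )
        except Exception as exc:
            raise StageError("pcr", str(exc)) from exc

    if config.run_alleles:
        try:
            clones = load_fasta(config.clones_fasta)
            ref = "".join(load_fasta(config.target_reference_fasta).values())
            if config.target_interval is None:
                raise ValueError("target_interval required for the allele stage")
            allele_result = allele_stage(clones, ref, config.target_interval)
        except Exception as exc:
            raise StageError("alleles", str(exc)) from exc

    channels = [r["free"] for r in (kmer_result, pcr_result) if r is not None]
    transgene_free = bool(channels) and all(channels)
    if not channels:
        warnings.warn("no detection stage ran; transgene_free is fail-closed False")

    verdict = Verdict(
        transgene_free=transgene_free,
        kmer=kmer_result,
        pcr=pcr_result,
        alleles=allele_result,
        provenance={
            "package": "vectorfree",
            "version": __version__,
            "alpha": config.alpha,
            "k_list": list(config.k_list),
            "seed": config.seed,
            "require_excess": config.require_excess,
        },
    )
    verdict.write(out / "verdict.json")
    return verdict
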