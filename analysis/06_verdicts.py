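#!/usr/bin/env python
"""End-to-end file-based verification of the simulated lines.

Consumes the material written by 01_simulate_lines.py through the same
config-driven entry point the CLI uses: k-mer/G-test channel with a
replicate pair plus the tiled PCR panel, for the clean line and the
line with the 2 kb T-DNA integration. Copies the two verdicts into
results/.
"""
import json
import shutil
from pathlib import Path

from vectorfree._encode import revcomp
from vectorfree.io import load_fasta, load_vector
from vectorfree.orthogonal import PrimerPair, write_primer_panel
from vectorfree.pipeline import RunConfig, run_verification

SEED = 1
ROOT = Path(__file__).resolve().parents[1]
SIM = ROOT / "scratch" / "sim"
RESULTS = ROOT / "results"


def main() -> None:
    if not (SIM / "vector.fasta").exists():
        raise SystemExit("run analysis/01_simulate_lines.py first")
    RESULTS.mkdir(exist_ok=True)

    vector = load_vector(SIM / "vector.fasta", SIM / "vector.features.tsv")
    host_seq = next(iter(load_fasta(SIM / "wild_type.fasta").values()))
    panel = [PrimerPair("PCR0", host_seq[999:1019],
                        revcomp(host_seq[1379:1399]))]
    seq = vector.sequence
    for i, s in enumerate(range(0, len(seq) - 400 + 1, 500), start=1):
        panel.append(PrimerPair(f"PCR{i}", seq[s:s + 20],
                                revcomp(seq[s + 380:s + 400])))
    write_primer_panel(SIM / "panel.tsv", panel)

    for label, sample_prefix, genome_fasta in [
        ("clean", "clean", SIM / "wild_type.fasta"),
        ("integrated", "integrated", SIM / "edited_integrated.fasta"),
    ]:
        cfg = RunConfig(
            vector_fasta=str(SIM / "vector.fasta"),
            vector_features=str(SIM / "vector.features.tsv"),
            sample_fastq=str(SIM / f"{sample_prefix}_run1.fastq"),
            control_fastq=str(SIM / "wt_run1.fastq"),
            sample_fastq_rep2=str(SIM / f"{sample_prefix}_run2.fastq"),
            control_fastq_rep2=str(SIM / "wt_run2.fastq"),
            pcr_genome_fasta=str(genome_fasta),
            primer_panel_tsv=str(SIM / "panel.tsv"),
            out_dir=str(ROOT / "scratch" / f"verdict_{label}"),
            seed=SEED,
        )
        verdict = run_verification(cfg)
        shutil.copy(Path(cfg.out_dir) / "verdict.json",
                    RESULTS / f"verdict_{label}.json")
        reps = sum(
            len(verdict.kmer["k"][k]["replicated_peaks"]) for k in cfg.k_list
        )
        print(f"{label}: transgene_free={verdict.transgene_free} "
              f"(replicated k-mer peaks: {reps}; "
              f"PCR vector bands: {verdict.pcr['vector_bands_on_genome']})")
    print(f"verdicts copied to {RESULTS}")


if __name__ == "__main__":
    main()
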