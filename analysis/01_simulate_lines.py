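#!/usr/bin/env python
"""Simulate the reference study material: an annotated binary vector, a
wild-type host background sharing two plant-derived tracts with the
vector, a clean edited line (no integration) and a line carrying a 2 kb
T-DNA integration, plus 30x shotgun libraries for each scenario.

Reads and genomes go to scratch/sim/ (bulky); a summary of what was
generated, with the ground-truth coordinates, goes to results/.
"""
import json
from pathlib import Path

from vectorfree.experiments import (
    BACKBONE_LEN,
    DEPTH,
    HOST_GC,
    POWER_HOST_LEN,
    READ_LENGTH,
    TDNA_LEN,
)
from vectorfree.simulate import (
    integrate,
    make_host_genome,
    make_vector,
    simulate_reads,
    write_fasta,
    write_fastq,
    write_feature_table,
    write_truth,
)

SEED = 1
ROOT = Path(__file__).resolve().parents[1]
SIM = ROOT / "scratch" / "sim"
RESULTS = ROOT / "results"


def main() -> None:
    SIM.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(exist_ok=True)

    vector = make_vector(TDNA_LEN, BACKBONE_LEN, seed=SEED)
    host = make_host_genome(POWER_HOST_LEN, HOST_GC, seed=SEED + 1)
    edited, truth = integrate(host, vector, (1, TDNA_LEN), POWER_HOST_LEN // 2)

    write_fasta(SIM / "vector.fasta", [("vector", vector.sequence)])
    write_feature_table(SIM / "vector.features.tsv", vector)
    write_fasta(SIM / "wild_type.fasta", [("wild_type", host.sequence)])
    write_fasta(SIM / "edited_integrated.fasta", [("edited", edited.sequence)])
    write_truth(SIM / "truth_integrated.json", truth)

    libraries = {}
    for name, genome, seed in [
        ("clean_run1", host, 10), ("clean_run2", host, 11),
        ("wt_run1", host, 12), ("wt_run2", host, 13),
        ("integrated_run1", edited, 14), ("integrated_run2", edited, 15),
    ]:
        reads = simulate_reads(genome, DEPTH, READ_LENGTH, 0.0, SEED * 100 + seed)
        write_fastq(SIM / f"{name}.fastq", reads)
        libraries[name] = len(reads)

    summary = {
        "seed": SEED,
        "vector_length": len(vector),
        "features": [(f.label, f.start, f.end) for f in vector.features],
        "host_length": len(host),
        "integrated_interval_on_vector": truth.vector_interval,
        "integration_locus_on_host": truth.host_locus,
        "depth": DEPTH,
        "read_length": READ_LENGTH,
        "libraries": libraries,
    }
    with open(RESULTS / "simulation_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    print(f"simulated {len(libraries)} libraries "
          f"({sum(libraries.values())} reads) into {SIM}")
    print(f"ground truth: vector[1..{TDNA_LEN}] inserted at host position "
          f"{truth.host_locus}; summary in {RESULTS/'simulation_summary.json'}")


if __name__ == "__main__":
    main()
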