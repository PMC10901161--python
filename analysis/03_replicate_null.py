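#!/usr/bin/env python
"""Replicate intersection as the false-positive control.

One hundred null seed pairs on a wild-type background that shares two
300 bp tracts with the vector: isolated significant peaks appear at
roughly the alpha rate, but requiring a peak to recur in an independent
sequencing run should leave essentially none.
"""
import json
from pathlib import Path

from vectorfree.experiments import replicate_null_study

SEED = 1
RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    rep = replicate_null_study(SEED, n_pairs=100)
    with open(RESULTS / "replicate_null.json", "w") as fh:
        json.dump(rep, fh, indent=2)
    print(f"{rep['fraction_pairs_clean']:.0%} of {rep['n_pairs']} null pairs "
          f"have zero replicated peaks "
          f"(mean {rep['mean_peaks_per_run_per_k']:.2f} raw peaks per run/k; "
          f"{rep['total_replicated_peaks']} replicated in total)")
    print(f"summary written to {RESULTS/'replicate_null.json'}")


if __name__ == "__main__":
    main()
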