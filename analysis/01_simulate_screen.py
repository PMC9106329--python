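#!/usr/bin/env python
"""Generate the synthetic pooled screen used by the downstream analyses.

Builds a scaled-down guide library (450 RBP genes x 10 guides + 500
non-targeting controls), plants 20 accumulation-promoting (4-fold CD138+
depletion on knockout) and 30 accumulation-limiting genes at 0.8 guide
penetrance, simulates negative-binomial counts for the four screen
populations at 500x depth, and writes a binomially down-sampled day4
read set (~100k reads) so the read-counting step can be exercised end to
end without a multi-million-read FASTQ.

Outputs: results/screen/{library.tsv, counts_true.tsv, truth.tsv,
day4_sample_counts.tsv, day4_sample.fastq.gz}
"""

from pathlib import Path

import numpy as np
import pandas as pd

import plasmascreen as ps

OUT = Path(__file__).resolve().parents[1] / "results" / "screen"
SEED = 11

PROMOTE = [f"RBP{i:04d}" for i in range(1, 21)]
LIMIT = [f"RBP{i:04d}" for i in range(21, 51)]


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = ps.SimConfig(n_genes=450, n_pos_controls=0, n_nt=500, depth=500, seed=SEED)
    lib = ps.make_library(cfg)
    lib.to_tsv(OUT / "library.tsv")

    effects = ps.EffectSpec(
        {g: (0.0, -2.0) for g in PROMOTE} | {g: (0.0, 2.0) for g in LIMIT},
        guide_penetrance=0.8,
    )
    counts = ps.simulate_screen_counts(lib, effects, cfg)
    ps.quantify.write_count_matrix(counts, OUT / "counts_true.tsv")

    truth = pd.DataFrame(
        {"gene": PROMOTE + LIMIT,
         "planted_class": ["accumulation_promote"] * len(PROMOTE)
         + ["accumulation_limit"] * len(LIMIT)}
    )
    truth.to_csv(OUT / "truth.tsv", sep="\t", index=False)

    rng = np.random.default_rng(SEED + 1)
    sampled = pd.Series(
        rng.binomial(counts["day4"].to_numpy(), 0.04), index=counts.index, name="day4"
    )
    sampled.to_csv(OUT / "day4_sample_counts.tsv", sep="\t", header=True)
    fq = ps.simulate_fastq(
        dict(sampled), lib, OUT / "day4_sample.fastq.gz", seed=SEED + 2
    )
    print(f"library: {len(lib)} guides ({lib.category_counts()})")
    print(f"planted: {len(PROMOTE)} promote, {len(LIMIT)} limit genes")
    print(f"counts:  {counts.shape[0]} x {counts.shape[1]} -> {OUT/'counts_true.tsv'}")
    print(f"reads:   {int(sampled.sum())} down-sampled day4 reads -> {fq}")


if __name__ == "__main__":
    main()
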