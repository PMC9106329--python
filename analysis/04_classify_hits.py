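#!/usr/bin/env python
"""Intersect the two screens and compare classes with the planted truth.

A gene hitting only the accumulation screen is an accumulation regulator
(promote if z <= -2, limit if z >= +2); a gene hitting only the expansion
screen regulates B-cell expansion; hits in both are pleiotropic.

Outputs: results/screen/{classification.tsv, class_summary.tsv}
"""

from pathlib import Path

import pandas as pd

import plasmascreen as ps

OUT = Path(__file__).resolve().parents[1] / "results" / "screen"


def main() -> None:
    exp = pd.read_csv(OUT / "expansion.gene.tsv", sep="\t")
    acc = pd.read_csv(OUT / "accumulation.gene.tsv", sep="\t")
    classes = ps.classify_genes(exp, acc)
    classes.to_csv(OUT / "classification.tsv", sep="\t", index=False)
    summary = ps.summarize_classes(classes)
    summary.to_csv(OUT / "class_summary.tsv", sep="\t", header=True)
    print(summary.to_string())

    truth = pd.read_csv(OUT / "truth.tsv", sep="\t").set_index("gene")
    merged = classes.set_index("gene").join(truth, how="left")
    planted = merged[merged.planted_class.notna()]
    agree = (planted["class"] == planted["planted_class"]).mean()
    print(f"\nplanted genes recovered with the correct class: {100 * agree:.1f}%")


if __name__ == "__main__":
    main()
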