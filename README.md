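# plasmascreen

Analysis pipeline for pooled CRISPR knockout screens of RNA-binding
proteins (RBPs) in plasma-cell differentiation, with a companion
m6A-eCLIP crosslink-site analysis. It is written for researchers who run
guide-level dropout/enrichment screens read out by sorting (here: CD138+
plasmablast accumulation vs B-cell expansion) and who map N6-
methyladenosine (m6A) sites from eCLIP data.

The pipeline covers, end to end:

* **Guide quantification** — protospacer extraction from reads anchored
  on the sgRNA scaffold (`GTTTAAGAGCTAT`; the 19 bases preceding it),
  zero-mismatch assignment, guide × sample count matrices.
* **Screen statistics** — median-of-ratios normalization anchored on
  non-targeting (NT) controls; an NT mean–variance null
  `var(mu) = mu + k·mu^b`; negative-binomial sgRNA tail tests; gene
  scores by alpha robust rank aggregation,
  `rho = min_k P(Beta(k, m−k+1) ≤ u_(k))` over the gene's selected guide
  ranks; permutation p-values from randomized guide-to-gene allocation;
  Benjamini–Hochberg FDR; gene LFC (median same-direction guide LFC) and
  z-scores in NT-LFC standard deviations; hits at |z| ≥ 2 and FDR < 0.05.
* **Two-screen classification** — intersecting an expansion screen
  (day 8 vs day 4) with an accumulation screen (CD138+ vs CD138−) to
  separate promoters and limiters of plasma-cell accumulation from
  expansion regulators.
* **m6A site annotation** — hierarchical gene/feature assignment of
  single-nucleotide crosslink sites against an Ensembl-dialect GTF
  (coding first; TSL < 4 first; CDS > 3'UTR > 5'UTR > intron > nc exon >
  nc intron; then TSL/CCDS confidence), and grouping of transcripts by
  methylation location (3'UTR / CDS / both).
* **Motif enrichment** — per-5-mer z-scores of crosslink-site k-mers
  against 100 feature-matched randomized control-site sets,
  `z = (obs − ctrl_mean) / ctrl_sd`.
* **Metagene profiles** — mean cluster occupancy over each gene's scaled
  CDS ± 1 kb flanks (binary per-bin indicator, averaged over genes).
* **Synthetic data** — generators for every input above (library, screen
  counts with planted effects, FASTQ reads, toy annotated genomes with
  motif-planted stop-biased sites), used by the tests and the analysis
  scripts.

See `docs/methods.md` for the models, defaults and limitations.

## Worked example

The numbered scripts under `analysis/` run the whole pipeline on
synthetic data and write their tables under `results/`:

```bash
python analysis/01_simulate_screen.py      # library + counts + reads
python analysis/02_quantify_reads.py       # FASTQ -> counts, verified
python analysis/03_screen_inference.py     # both screen comparisons
python analysis/04_classify_hits.py        # two-screen intersection
python analysis/05_simulate_eclip.py       # toy genome + planted sites
python analysis/06_annotate_motif_metagene.py
```

The simulated screen has 5,000 guides (450 genes × 10 + 500 NT controls)
at 500× depth with 20 planted promoters (4-fold CD138+ depletion on
knockout) and 30 planted limiters at 0.8 guide penetrance. Script 03
prints:

```
expansion (day4 -> day8): 0 hit genes of 450; strongest:
accumulation (cd138neg -> cd138pos): 50 hit genes of 450; strongest: RBP0017 (z=-4.8), RBP0008 (z=-4.3), RBP0018 (z=-3.6)
```

— the null expansion screen calls nothing, and the accumulation screen
calls exactly the 50 planted genes. Script 04 then recovers the planted
classes perfectly:

```
accumulation_promote     20
accumulation_limit       30
expansion_only            0
both                      0
none                    400
total                   450

planted genes recovered with the correct class: 100.0%
```

On the eCLIP side, script 06 annotates 200 planted sites (118 CDS,
60 3'UTR, 17 nc exon, 5 5'UTR), and the planted DRACH 5-mer dominates
the motif table while all other 5-mers stay near the null:

```
top 5-mers by z:
       obs_count  ctrl_mean           z
GGACT        130       1.74  105.892625
GTAGT          2       0.14    4.620919
...
metagene peak at bin 198 (body spans bins 100-199; stop codon at bin 199)
```

The metagene peak in the last body bins reflects the stop-codon bias of
the planted sites — the hallmark positional signature of m6A.

A `plasmascreen` CLI exposes the same steps for real inputs
(`plasmascreen count | test | classify | annotate-sites | motif-z |
metagene | simulate`); run any subcommand with `--help`.

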