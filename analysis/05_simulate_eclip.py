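#!/usr/bin/env python
"""Generate the toy m6A-eCLIP inputs: genome, annotation, sites, clusters.

Builds a 20-gene toy transcriptome (multi-exon coding and non-coding
genes on both strands with TSL/CCDS flags) and plants 200 crosslink
sites: 60% carry the DRACH-consensus 5-mer GGACT edited into the genome
at the site, and 50% fall within 100 nt of a stop codon — the two
signatures real m6A-eCLIP data shows. Clusters are +/-20 nt windows
around sites.

Outputs: results/eclip/{genome.fa, annotation.gtf, sites.bed, clusters.bed}
"""

from pathlib import Path

import plasmascreen as ps

OUT = Path(__file__).resolve().parents[1] / "results" / "eclip"
SEED = 21


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    ann = ps.make_toy_annotation(20, seed=SEED)
    sites, clusters = ps.plant_crosslink_sites(
        ann, 200, motif="GGACT", motif_fraction=0.6, stop_bias=0.5, seed=SEED + 1
    )
    ann.write_fasta(OUT / "genome.fa")
    ann.write_gtf(OUT / "annotation.gtf")
    ps.annotation.write_sites_bed(sites, OUT / "sites.bed")
    ps.annotation.write_clusters_bed(clusters, OUT / "clusters.bed")
    n_coding = sum(m.coding for m in ann.models)
    print(
        f"{len(ann.models)} genes ({n_coding} coding) on "
        f"{len(ann.chrom_seqs)} chromosomes; {len(sites)} sites, "
        f"{len(clusters)} clusters -> {OUT}"
    )


if __name__ == "__main__":
    main()
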