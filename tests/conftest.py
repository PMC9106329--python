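import numpy as np
import pytest

import plasmascreen as ps
from plasmascreen.library import GuideLibrary, GuideRecord


def make_small_library(n_genes=3, per_gene=2, n_nt=4, seed=0) -> GuideLibrary:
    """Deterministic toy library with readable ids."""
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    seen, records = set(), []

    def proto():
        while True:
            s = "".join(bases[rng.integers(0, 4, 19)])
            if s not in seen:
                seen.add(s)
                return s

    for i in range(n_genes):
        gene = f"GENE{i + 1}"
        for j in range(per_gene):
            records.append(GuideRecord(f"{gene}_sg{j + 1}", proto(), gene, "rbp_target"))
    for i in range(n_nt):
        records.append(GuideRecord(f"NT{i + 1}", proto(), None, "non_targeting"))
    return GuideLibrary(records)


@pytest.fixture
def small_library() -> GuideLibrary:
    return make_small_library()


@pytest.fixture(scope="session")
def toy_eclip():
    """Toy genome + annotation with planted, stop-biased, motif-rich sites."""
    ann = ps.make_toy_annotation(12, seed=5)
    sites, clusters = ps.plant_crosslink_sites(
        ann, 150, motif_fraction=0.6, stop_bias=0.5, seed=6
    )
    return ann, sites, clusters


@pytest.fixture(scope="session")
def toy_eclip_files(toy_eclip, tmp_path_factory):
    ann, sites, clusters = toy_eclip
    d = tmp_path_factory.mktemp("eclip")
    fasta = ann.write_fasta(d / "genome.fa")
    gtf = ann.write_gtf(d / "annotation.gtf")
    ps.annotation.write_sites_bed(sites, d / "sites.bed")
    ps.annotation.write_clusters_bed(clusters, d / "clusters.bed")
    return {
        "fasta": fasta,
        "gtf": gtf,
        "sites": d / "sites.bed",
        "clusters": d / "clusters.bed",
    }
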