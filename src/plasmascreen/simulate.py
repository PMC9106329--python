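"""Synthetic inputs with the statistical structure the analysis assumes.

The generators emulate the screen and m6A-eCLIP study design end to end:

* a guide library of 10 sgRNAs per RBP gene plus positive-control genes
  and 500 non-targeting guides (13,350 guides at full scale), with random
  unique 19-nt protospacers;
* a log-normal plasmid representation whose spread keeps >=98.8% of
  guides within a 16-fold abundance range, as in the real library QC;
* negative-binomial screen counts for the four populations (day4, day8,
  CD138-, CD138+) with planted per-gene expansion/accumulation effects of
  configurable penetrance;
* FASTQ reads of the form prefix + protospacer + scaffold + suffix, the
  exact inverse of the read-counting step;
* a toy annotated transcriptome (random chromosomes, multi-exon coding
  and non-coding genes on both strands, TSL/CCDS flags) with
  motif-planted, stop-codon-biased crosslink sites and +/-20 nt clusters.

Every generator is a pure function of its configuration and seed.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import ClusterInterval, CrosslinkSite, TranscriptModel
from .library import GuideLibrary, GuideRecord, PROTOSPACER_LEN
from .quantify import SCAFFOLD_ANCHOR, SampleCounts

_BASES = np.array(list("ACGT"))
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

SCREEN_SAMPLES = ("day4", "day8", "cd138neg", "cd138pos")


@dataclass
class SimConfig:
    """Screen simulation settings.

    plasmid_sigma is the SD of log2 plasmid abundance; 0.78 keeps the
    expected fraction of guides within a central 16-fold (+/-2 log2)
    abundance window at 99.0%, comfortably above the library's >=98.8% QC
    line at finite library size. depth is the mean sequenced reads per
    guide; nb_dispersion is the negative-binomial dispersion phi in
    var = mu + phi * mu^2 (0 = Poisson).
    """

    n_genes: int = 1213
    sgrnas_per_gene: int = 10
    n_pos_controls: int = 72
    n_nt: int = 500
    plasmid_sigma: float = 0.78
    depth: float = 500.0
    nb_dispersion: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.sgrnas_per_gene) < 1 or self.n_nt < 0:
            raise ValueError("library composition must be positive")
        if self.depth <= 0 or self.plasmid_sigma <= 0 or self.nb_dispersion < 0:
            raise ValueError("depth and noise parameters must be positive")

    @property
    def n_guides(self) -> int:
        return (self.n_genes + self.n_pos_controls) * self.sgrnas_per_gene + self.n_nt


@dataclass
class EffectSpec:
    """Planted per-gene effects, as log2 multipliers on guide abundance.

    effects maps gene -> (expansion_effect, accumulation_effect);
    guide_penetrance is the fraction of a gene's guides carrying its
    effect. Non-targeting guides never carry an effect.
    """

    effects: dict[str, tuple[float, float]] = field(default_factory=dict)
    guide_penetrance: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.guide_penetrance <= 1):
            raise ValueError("guide_penetrance must be in (0, 1]")


def _random_kmers(rng: np.random.Generator, n: int, k: int) -> list[str]:
    """n distinct random k-mers."""
    if n > 4**k / 2:
        raise ValueError(f"cannot draw {n} distinct {k}-mers safely")
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        block = rng.integers(0, 4, size=(n - len(out) + 16, k))
        for row in block:
            s = "".join(_BASES[row])
            if s not in seen:
                seen.add(s)
                out.append(s)
                if len(out) == n:
                    break
    return out


def make_library(config: SimConfig) -> GuideLibrary:
    """Random guide library with the configured composition."""
    rng = np.random.default_rng(config.seed)
    protospacers = _random_kmers(rng, config.n_guides, PROTOSPACER_LEN)
    records: list[GuideRecord] = []
    it = iter(protospacers)
    for i in range(config.n_genes):
        gene = f"RBP{i + 1:04d}"
        for j in range(config.sgrnas_per_gene):
            records.append(
                GuideRecord(f"{gene}_sg{j + 1}", next(it), gene, "rbp_target")
            )
    for i in range(config.n_pos_controls):
        gene = f"POS{i + 1:03d}"
        for j in range(config.sgrnas_per_gene):
            records.append(
                GuideRecord(f"{gene}_sg{j + 1}", next(it), gene, "positive_control")
            )
    for i in range(config.n_nt):
        records.append(
            GuideRecord(f"NT{i + 1:04d}", next(it), None, "non_targeting")
        )
    return GuideLibrary(records)


def plasmid_abundance(library: GuideLibrary, config: SimConfig) -> pd.Series:
    """Relative plasmid abundance per guide (log-normal, mean-normalized)."""
    rng = np.random.default_rng(config.seed + 1)
    log2_ab = rng.normal(0.0, config.plasmid_sigma, size=len(library))
    ab = np.exp2(log2_ab)
    return pd.Series(ab / ab.mean(), index=pd.Index(library.guide_ids, name="guide_id"))


def fraction_within_fold_range(abundance, fold: float = 16.0) -> float:
    """Fraction of guides inside a ``fold``-range window centred on the
    median in log space (the library QC statistic: e.g. >=98.8% within a
    16-fold range)."""
    a = np.log2(np.asarray(abundance, dtype=float))
    half = np.log2(fold) / 2
    return float(np.mean(np.abs(a - np.median(a)) <= half))


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    mean = np.asarray(mean, float)
    if phi <= 0:
        return rng.poisson(mean)
    n = 1.0 / phi
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


def simulate_screen_counts(
    library: GuideLibrary, effects: EffectSpec, config: SimConfig
) -> pd.DataFrame:
    """Guide x sample counts for day4, day8, cd138neg, cd138pos.

    Expected day4 count = depth x plasmid abundance. Planted expansion
    effects multiply effect-carrying guides' day8 (and downstream sorted
    populations') means by 2^effect; accumulation effects multiply only
    the CD138+ mean, so the CD138+/CD138- guide LFC recovers the planted
    accumulation effect.
    """
    unknown = set(effects.effects) - set(library.gene_map())
    if unknown:
        raise ValueError(f"effects reference unknown genes, e.g. {sorted(unknown)[:3]}")
    rng = np.random.default_rng(config.seed + 2)
    ab = plasmid_abundance(library, config)
    idx = {g: i for i, g in enumerate(library.guide_ids)}

    exp_eff = np.zeros(len(library))
    acc_eff = np.zeros(len(library))
    gene_map = library.gene_map()
    for gene, (e_exp, e_acc) in sorted(effects.effects.items()):
        gids = gene_map[gene]
        n_carry = int(round(effects.guide_penetrance * len(gids)))
        carriers = rng.choice(len(gids), size=n_carry, replace=False)
        for ci in carriers:
            gi = idx[gids[ci]]
            exp_eff[gi] = e_exp
            acc_eff[gi] = e_acc

    mu_day4 = config.depth * ab.to_numpy()
    mu_day8 = mu_day4 * np.exp2(exp_eff)
    mu_neg = mu_day8
    mu_pos = mu_day8 * np.exp2(acc_eff)

    data = {
        "day4": _nb_draw(rng, mu_day4, config.nb_dispersion),
        "day8": _nb_draw(rng, mu_day8, config.nb_dispersion),
        "cd138neg": _nb_draw(rng, mu_neg, config.nb_dispersion),
        "cd138pos": _nb_draw(rng, mu_pos, config.nb_dispersion),
    }
    return pd.DataFrame(data, index=ab.index).astype(int)


def simulate_fastq(
    counts: SampleCounts | dict[str, int],
    library: GuideLibrary,
    path: str | Path,
    seed: int = 0,
    read_len: int = 60,
) -> Path:
    """Write FASTQ reads realising the given per-guide counts.

    Each read is random-prefix(0-6 nt) + protospacer + scaffold anchor +
    random suffix, padded to ``read_len``; read order is shuffled.
    Gzip output when the path ends in .gz.
    """
    if isinstance(counts, SampleCounts):
        counts = counts.counts
    unknown = set(counts) - set(library.guide_ids)
    if unknown:
        raise ValueError(f"counts reference unknown guides, e.g. {sorted(unknown)[:3]}")
    rng = np.random.default_rng(seed)
    proto = {r.guide_id: r.protospacer for r in library}
    reads: list[str] = []
    for gid in sorted(counts):
        for _ in range(counts[gid]):
            prefix_len = int(rng.integers(0, 7))
            prefix = "".join(_BASES[rng.integers(0, 4, size=prefix_len)])
            core = prefix + proto[gid] + SCAFFOLD_ANCHOR
            pad = max(read_len - len(core), 0)
            suffix = "".join(_BASES[rng.integers(0, 4, size=pad)])
            reads.append(core + suffix)
    rng.shuffle(reads)
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for i, seq in enumerate(reads):
            fh.write(f"@read{i + 1}\n{seq}\n+\n{'I' * len(seq)}\n")
    return path


# --- toy annotated transcriptome -----------------------------------------


@dataclass
class ToyAnnotation:
    """A small random genome with Ensembl-style gene models.

    Chromosome sequences are kept mutable (lists of bases) so that motif
    planting can edit them before serialisation.
    """

    chrom_seqs: dict[str, list[str]]
    models: list[TranscriptModel]

    def sequences(self) -> dict[str, str]:
        return {c: "".join(s) for c, s in self.chrom_seqs.items()}

    def write_fasta(self, path: str | Path, width: int = 70) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            for chrom, seq in self.sequences().items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")
        return path

    def write_gtf(self, path: str | Path) -> Path:
        path = Path(path)
        lines = []
        for m in self.models:
            attrs = [f'gene_id "{m.gene_id}"', f'transcript_id "{m.transcript_id}"']
            attrs.append(f'gene_biotype "{m.biotype}"')
            attrs.append(f'transcript_biotype "{m.biotype}"')
            if m.tsl is not None:
                attrs.append(f'transcript_support_level "{m.tsl}"')
            if m.has_ccds:
                attrs.append(f'ccds_id "CCDS_{m.transcript_id}"')
            attr_str = "; ".join(attrs) + ";"
            span = (m.exons[0][0] + 1, m.exons[-1][1])
            for feat, ivs in (
                ("gene", [span]),
                ("transcript", [span]),
                ("exon", [(s + 1, e) for s, e in m.exons]),
                ("CDS", [(s + 1, e) for s, e in m.cds]),
            ):
                for s, e in ivs:
                    lines.append(
                        f"{m.chrom}\ttoy\t{feat}\t{s}\t{e}\t.\t{m.strand}\t.\t{attr_str}"
                    )
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")
        return path


def _tx_to_genomic(
    exons: list[tuple[int, int]], strand: str, t_start: int, t_end: int
) -> list[tuple[int, int]]:
    """Map a transcript-coordinate interval to genomic intervals."""
    walk = exons if strand == "+" else exons[::-1]
    out = []
    t = 0
    for s, e in walk:
        length = e - s
        lo, hi = max(t_start - t, 0), min(t_end - t, length)
        if lo < hi:
            if strand == "+":
                out.append((s + lo, s + hi))
            else:
                out.append((e - hi, e - lo))
        t += length
    return sorted(out)


def make_toy_annotation(n_genes: int, seed: int = 0) -> ToyAnnotation:
    """Random annotated toy genome: multi-exon genes on both strands.

    About 80% of genes are coding (the first always is), with 2-5 exons,
    derivable UTRs, in-frame CDS lengths and varying TSL/CCDS flags; the
    rest are non-coding. Strands alternate so both are always represented.
    """
    if n_genes < 1:
        raise ValueError("need at least one gene")
    rng = np.random.default_rng(seed)
    genes_per_chrom = 10
    chrom_seqs: dict[str, list[str]] = {}
    models: list[TranscriptModel] = []
    margin = 1500  # room for metagene flanks and k-mer windows

    cursor: dict[str, int] = {}
    for gi in range(n_genes):
        chrom = f"chr{gi // genes_per_chrom + 1}"
        start = cursor.get(chrom, margin)
        strand = "+" if gi % 2 == 0 else "-"
        coding = gi == 0 or rng.random() < 0.8

        n_exons = int(rng.integers(2, 6))
        exon_lens = rng.integers(150, 401, size=n_exons)
        intron_lens = rng.integers(80, 301, size=n_exons - 1)
        exons = []
        pos = start
        for i, el in enumerate(exon_lens):
            exons.append((pos, pos + int(el)))
            pos += int(el)
            if i < n_exons - 1:
                pos += int(intron_lens[i])
        exonic = int(exon_lens.sum())

        cds: list[tuple[int, int]] = []
        biotype = "lncRNA"
        tsl = int(rng.integers(1, 6)) if rng.random() < 0.8 else None
        has_ccds = False
        if coding:
            biotype = "protein_coding"
            utr5 = int(rng.integers(30, 80))
            utr3 = int(rng.integers(100, 200))
            cds_len = exonic - utr5 - utr3
            cds_len -= cds_len % 3
            if cds_len < 60:
                utr5, utr3 = 30, 100
                cds_len = exonic - 130 - (exonic - 130) % 3
            cds = _tx_to_genomic(exons, strand, utr5, utr5 + cds_len)
            has_ccds = bool(rng.random() < 0.5)

        models.append(
            TranscriptModel(
                transcript_id=f"TX{gi + 1:04d}",
                gene_id=f"G{gi + 1:04d}",
                chrom=chrom,
                strand=strand,
                biotype=biotype,
                tsl=tsl,
                has_ccds=has_ccds,
                exons=exons,
                cds=cds,
            )
        )
        cursor[chrom] = pos + 500 + margin

    for chrom, end in cursor.items():
        length = end + margin
        chrom_seqs[chrom] = list("".join(_BASES[rng.integers(0, 4, size=length)]))
    return ToyAnnotation(chrom_seqs=chrom_seqs, models=models)


def plant_crosslink_sites(
    ann: ToyAnnotation,
    n_sites: int,
    motif: str = "GGACT",
    motif_fraction: float = 0.6,
    stop_bias: float = 0.5,
    seed: int = 0,
    cluster_halfwidth: int = 20,
) -> tuple[list[CrosslinkSite], list[ClusterInterval]]:
    """Plant crosslink sites (and +/-20 nt clusters) in a toy genome.

    A ``motif_fraction`` of sites gets the genome edited so the 5-mer
    centred on the site, read on the transcript strand, equals ``motif``;
    a ``stop_bias`` fraction is placed within 100 nt of a stop codon, the
    rest uniformly over exonic territory. Edits are written in place into
    ``ann.chrom_seqs``.
    """
    if not (0 <= motif_fraction <= 1 and 0 <= stop_bias <= 1):
        raise ValueError("fractions must lie in [0, 1]")
    if len(motif) != 5:
        raise ValueError("motif must be a 5-mer")
    rng = np.random.default_rng(seed)
    coding = [m for m in ann.models if m.coding]
    if not coding:
        raise ValueError("toy annotation has no coding transcripts")

    def _pool(intervals: list[tuple[TranscriptModel, int, int]]):
        lens = np.array([e - s for _, s, e in intervals])
        return np.cumsum(lens), intervals

    exonic_pool = _pool(
        [(m, s, e) for m in ann.models for s, e in m.exons]
    )
    stop_ivs = []
    for m in coding:
        sp = m.stop_codon_pos()
        for s, e in m.exons:
            lo, hi = max(s, sp - 100), min(e, sp + 101)
            if lo < hi:
                stop_ivs.append((m, lo, hi))
    stop_pool = _pool(stop_ivs)

    def _draw(pool) -> tuple[TranscriptModel, int]:
        cum, ivs = pool
        off = int(rng.integers(0, cum[-1]))
        wi = int(np.searchsorted(cum, off, side="right"))
        m, s, e = ivs[wi]
        base = off - (int(cum[wi - 1]) if wi > 0 else 0)
        return m, s + base

    sites: list[CrosslinkSite] = []
    clusters: list[ClusterInterval] = []
    taken: dict[str, set[int]] = {}  # 5-mer windows must not overlap
    for i in range(n_sites):
        for _ in range(200):  # resample on bound/window collisions
            pool = stop_pool if rng.random() < stop_bias else exonic_pool
            m, pos = _draw(pool)
            seq = ann.chrom_seqs[m.chrom]
            occupied = taken.setdefault(m.chrom, set())
            if 2 <= pos <= len(seq) - 3 and not (
                occupied & set(range(pos - 4, pos + 5))
            ):
                occupied.add(pos)
                break
        else:
            raise RuntimeError("could not place a site within chromosome bounds")
        if rng.random() < motif_fraction:
            planted = motif if m.strand == "+" else motif.translate(_COMPLEMENT)[::-1]
            seq[pos - 2 : pos + 3] = list(planted)
        score = float(np.round(rng.uniform(1, 5), 3))
        sites.append(CrosslinkSite(m.chrom, pos, m.strand, f"site{i + 1}", score))
        clusters.append(
            ClusterInterval(
                m.chrom,
                max(pos - cluster_halfwidth, 0),
                pos + cluster_halfwidth + 1,
                m.strand,
                f"cluster{i + 1}",
                score,
            )
        )
    return sites, clusters
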