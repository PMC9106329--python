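"""5-mer enrichment at crosslink sites against randomized control sites.

m6A deposition occurs at DRACH motifs (D = A/G/U, R = A/G, H = A/C/U), so
genuine m6A crosslink sites are strongly enriched for DRACH-matching
5-mers such as GGACT. Enrichment is quantified as a z-score per 5-mer:

    z = (occurrence at crosslink sites - mean occurrence at control sites)
        / sd of occurrence at control sites

where control sites are drawn in ``n_sets`` (default 100) randomized sets.
Control positions are randomized across all genes that contain at least
one crosslink site, preserving the observed distribution across feature
types (a site assigned to a CDS is re-drawn uniformly from the pooled CDS
territory of site-containing genes, and so on).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import CrosslinkSite, FeatureAssignment, TranscriptModel

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_VALID = frozenset("ACGT")

DRACH_D = set("AGT")
DRACH_R = set("AG")
DRACH_H = set("ACT")


def is_drach(kmer: str) -> bool:
    """True if a 5-mer matches the DRACH consensus (DNA alphabet)."""
    return (
        len(kmer) == 5
        and kmer[0] in DRACH_D
        and kmer[1] in DRACH_R
        and kmer[2] == "A"
        and kmer[3] == "C"
        and kmer[4] in DRACH_H
    )


def extract_kmer(site: CrosslinkSite, genome, k: int = 5) -> str | None:
    """The k bases centred on a site, read on the site's strand.

    ``genome`` is a mapping chrom -> sequence (e.g. a pyfaidx.Fasta).
    Returns None when the window runs off the chromosome or contains
    non-ACGT characters.
    """
    if k % 2 != 1:
        raise ValueError("k must be odd to centre on the site")
    if site.chrom not in genome:
        raise ValueError(f"unknown chromosome {site.chrom!r}")
    half = k // 2
    chrom_seq = genome[site.chrom]
    start, end = site.pos - half, site.pos + half + 1
    if start < 0 or end > len(chrom_seq):
        return None
    window = str(chrom_seq[start:end]).upper()
    if not set(window) <= _VALID:
        return None
    if site.strand == "-":
        window = window.translate(_COMPLEMENT)[::-1]
    return window


@dataclass
class ControlSiteSet:
    set_index: int
    sites: list[CrosslinkSite]
    feature_tally: dict[str, int]


def _gene_feature_territory(
    models: list[TranscriptModel],
) -> dict[tuple[str, str], list[tuple[str, int, int, str]]]:
    """Merged (chrom, start, end, strand) intervals per (gene, feature)."""
    raw: dict[tuple[str, str], list[tuple[str, int, int, str]]] = {}
    for m in models:
        for s, e, feat in m.feature_intervals():
            raw.setdefault((m.gene_id, feat), []).append((m.chrom, s, e, m.strand))
    merged = {}
    for key, ivs in raw.items():
        ivs = sorted(ivs)
        out: list[tuple[str, int, int, str]] = []
        for chrom, s, e, strand in ivs:
            if out and out[-1][0] == chrom and s <= out[-1][2]:
                prev = out[-1]
                out[-1] = (chrom, prev[1], max(prev[2], e), strand)
            else:
                out.append((chrom, s, e, strand))
        merged[key] = out
    return merged


def randomize_control_sites(
    observed: list[FeatureAssignment],
    models: list[TranscriptModel],
    n_sets: int = 100,
    seed: int | np.random.Generator = 0,
) -> list[ControlSiteSet]:
    """Draw ``n_sets`` feature-matched randomized control site sets.

    For every observed genic site with feature F, each control set gets one
    position drawn uniformly from the pooled feature-F territory of genes
    that contain at least one observed site (so a gene's chance is
    proportional to its feature-F length). Intergenic observed sites have
    no gene territory and are skipped with a warning. Fully deterministic
    under the seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    genic = [a for a in observed if a.gene_id is not None]
    n_skipped = len(observed) - len(genic)
    if n_skipped:
        logger.warning("skipping %d intergenic observed sites", n_skipped)
    if not genic:
        raise ValueError("no genic observed sites to randomize")
    eligible = {a.gene_id for a in genic}
    territory = _gene_feature_territory(models)

    tally: dict[str, int] = {}
    for a in genic:
        tally[a.feature] = tally.get(a.feature, 0) + 1

    # pooled territory per feature, restricted to eligible genes
    pooled: dict[str, tuple[np.ndarray, list[tuple[str, int, int, str]]]] = {}
    for feat in tally:
        ivs = [
            iv
            for (gene, f), iv_list in territory.items()
            if f == feat and gene in eligible
            for iv in iv_list
        ]
        if not ivs:
            logger.warning(
                "no %s territory among site-containing genes; "
                "falling back to all genes",
                feat,
            )
            ivs = [
                iv
                for (gene, f), iv_list in territory.items()
                if f == feat
                for iv in iv_list
            ]
        if not ivs:
            raise ValueError(f"no {feat} territory anywhere in the annotation")
        lengths = np.array([e - s for _, s, e, _ in ivs])
        pooled[feat] = (np.cumsum(lengths), ivs)

    sets: list[ControlSiteSet] = []
    for set_index in range(1, n_sets + 1):
        sites: list[CrosslinkSite] = []
        for feat, count in sorted(tally.items()):
            cum, ivs = pooled[feat]
            total = int(cum[-1])
            offsets = rng.integers(0, total, size=count)
            which = np.searchsorted(cum, offsets, side="right")
            for off, wi in zip(offsets, which):
                chrom, s, e, strand = ivs[wi]
                base = off - (cum[wi - 1] if wi > 0 else 0)
                sites.append(
                    CrosslinkSite(
                        chrom, int(s + base), strand,
                        name=f"ctrl{set_index}_{feat}_{len(sites)}",
                    )
                )
        sets.append(ControlSiteSet(set_index, sites, dict(tally)))
    return sets


def count_kmers(kmers: list[str]) -> dict[str, int]:
    out: dict[str, int] = {}
    for km in kmers:
        out[km] = out.get(km, 0) + 1
    return out


def motif_zscores(
    observed_kmers: list[str],
    control_sets: list[ControlSiteSet],
    genome,
    k: int = 5,
) -> pd.DataFrame:
    """Per-5-mer z-scores of observed counts against control-set counts.

    Returns a table indexed by 5-mer with obs_count, ctrl_mean, ctrl_sd
    (sample sd over sets), z and a ``sd_zero`` flag; z is 0 when the
    control sd is zero and the observed count equals the control mean,
    +/-inf otherwise. Sorted by z descending.
    """
    if not observed_kmers:
        raise ValueError("no observed k-mers to score")
    if len(control_sets) < 2:
        raise ValueError("need at least two control sets for a standard deviation")
    obs = count_kmers(observed_kmers)
    ctrl_counts: list[dict[str, int]] = []
    for cs in control_sets:
        kms = [extract_kmer(s, genome, k) for s in cs.sites]
        ctrl_counts.append(count_kmers([km for km in kms if km is not None]))
    universe = sorted(set(obs) | {km for c in ctrl_counts for km in c})
    mat = np.array([[c.get(km, 0) for km in universe] for c in ctrl_counts], float)
    ctrl_mean = mat.mean(axis=0)
    ctrl_sd = mat.std(axis=0, ddof=1)
    obs_vec = np.array([obs.get(km, 0) for km in universe], float)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (obs_vec - ctrl_mean) / ctrl_sd
    sd_zero = ctrl_sd == 0
    diff = obs_vec[sd_zero] - ctrl_mean[sd_zero]
    z[sd_zero] = np.where(diff == 0, 0.0, np.where(diff > 0, np.inf, -np.inf))
    df = pd.DataFrame(
        {
            "obs_count": obs_vec.astype(int),
            "ctrl_mean": ctrl_mean,
            "ctrl_sd": ctrl_sd,
            "z": z,
            "sd_zero": sd_zero,
            "is_drach": [is_drach(km) for km in universe],
        },
        index=pd.Index(universe, name="kmer"),
    )
    return df.sort_values("z", ascending=False)


def observed_site_kmers(
    sites: list[CrosslinkSite], genome, k: int = 5
) -> list[str]:
    """k-mers at the scorable observed sites (windows fully in-bounds, ACGT)."""
    kms = [extract_kmer(s, genome, k) for s in sites]
    return [km for km in kms if km is not None]
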