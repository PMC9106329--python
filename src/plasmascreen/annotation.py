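"""Transcript models and hierarchical feature assignment of crosslink sites.

Single-nucleotide m6A-eCLIP crosslink sites (and cluster intervals) are
assigned to genes and feature types from an Ensembl-dialect GTF. When a
site overlaps several transcripts or feature types, one is chosen by a
fixed priority:

1. protein-coding isoforms before non-coding;
2. isoforms with transcript support level (TSL) < 4 before the rest;
3. feature type: CDS > 3'UTR > 5'UTR > intron > non-coding exon >
   non-coding intron;
4. confidence: lower TSL first (absent TSL last), then CCDS-flagged
   transcripts first;
5. transcript_id, as a final deterministic tie-break.

All coordinates are 0-based half-open internally; GTF's 1-based closed
intervals are converted on read. eCLIP is strand-specific, so a site is
only a candidate for transcripts on its own strand.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
import pandas as pd
from intervaltree import IntervalTree

FEATURES = ("CDS", "UTR3", "UTR5", "intron", "nc_exon", "nc_intron", "intergenic")
_FEATURE_RANK = {f: i for i, f in enumerate(FEATURES[:-1])}


@dataclass
class TranscriptModel:
    """One transcript: exon/CDS structure plus annotation confidence flags."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    biotype: str = "protein_coding"
    tsl: int | None = None
    has_ccds: bool = False
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        self.cds = sorted(self.cds)
        for iv in self.exons + self.cds:
            if iv[0] >= iv[1]:
                raise ValueError(f"{self.transcript_id}: empty interval {iv}")
        for a, b in zip(self.exons, self.exons[1:]):
            if a[1] > b[0]:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
        if not _contained(self.cds, self.exons):
            raise ValueError(
                f"transcript {self.transcript_id}: CDS extends outside exons"
            )

    @property
    def coding(self) -> bool:
        return bool(self.cds)

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [
            (a[1], b[0]) for a, b in zip(self.exons, self.exons[1:]) if a[1] < b[0]
        ]

    @property
    def cds_span(self) -> tuple[int, int] | None:
        """Genomic span from first to last CDS base (introns included)."""
        if not self.cds:
            return None
        return self.cds[0][0], self.cds[-1][1]

    def utrs(self) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
        """(UTR5, UTR3) exonic intervals; empty for non-coding transcripts."""
        if not self.cds:
            return [], []
        cs, ce = self.cds_span
        left = _clip(self.exons, None, cs)
        right = _clip(self.exons, ce, None)
        return (left, right) if self.strand == "+" else (right, left)

    def feature_intervals(self) -> list[tuple[int, int, str]]:
        """All (start, end, feature) intervals of this transcript."""
        out: list[tuple[int, int, str]] = []
        if self.coding:
            utr5, utr3 = self.utrs()
            out += [(s, e, "CDS") for s, e in self.cds]
            out += [(s, e, "UTR5") for s, e in utr5]
            out += [(s, e, "UTR3") for s, e in utr3]
            out += [(s, e, "intron") for s, e in self.introns]
        else:
            out += [(s, e, "nc_exon") for s, e in self.exons]
            out += [(s, e, "nc_intron") for s, e in self.introns]
        return out

    def stop_codon_pos(self) -> int | None:
        """Genomic 0-based position of the last CDS base (stop-proximal anchor)."""
        if not self.cds:
            return None
        return self.cds[-1][1] - 1 if self.strand == "+" else self.cds[0][0]


def _contained(inner: list[tuple[int, int]], outer: list[tuple[int, int]]) -> bool:
    for s, e in inner:
        if not any(os <= s and e <= oe for os, oe in outer):
            return False
    return True


def _clip(
    intervals: list[tuple[int, int]], lo: int | None, hi: int | None
) -> list[tuple[int, int]]:
    """Parts of each interval inside [lo, hi); None means unbounded."""
    out = []
    for s, e in intervals:
        s2 = s if lo is None else max(s, lo)
        e2 = e if hi is None else min(e, hi)
        if s2 < e2:
            out.append((s2, e2))
    return out


@dataclass(frozen=True)
class CrosslinkSite:
    chrom: str
    pos: int  # 0-based single-nucleotide coordinate
    strand: str
    name: str = "."
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.pos < 0 or self.strand not in "+-":
            raise ValueError(f"invalid site {self}")


@dataclass(frozen=True)
class ClusterInterval:
    chrom: str
    start: int
    end: int  # 0-based half-open
    strand: str
    name: str = "."
    lfc: float = 0.0

    def __post_init__(self) -> None:
        if self.start >= self.end or self.strand not in "+-":
            raise ValueError(f"invalid cluster {self}")


@dataclass(frozen=True)
class FeatureAssignment:
    name: str
    gene_id: str | None
    transcript_id: str | None
    feature: str

    def __post_init__(self) -> None:
        if (self.feature == "intergenic") != (self.gene_id is None):
            raise ValueError("gene_id must be absent exactly for intergenic")


_TSL_RE = re.compile(r"^(\d)")


def _parse_tsl(raw: str | None) -> int | None:
    # Ensembl writes e.g. "1 (assigned to previous version 5)" or "NA"
    if raw is None:
        return None
    m = _TSL_RE.match(raw.strip())
    return int(m.group(1)) if m else None


def parse_annotation(gtf_path: str | Path) -> list[TranscriptModel]:
    """Read an Ensembl-dialect GTF into transcript models.

    Uses transcript/exon/CDS features; transcript_biotype,
    transcript_support_level and ccds_id attributes are optional
    (defaults: biotype from gene_biotype or protein_coding, TSL absent,
    no CCDS).
    """
    db = gffutils.create_db(
        str(gtf_path),
        ":memory:",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        keep_order=True,
    )
    models = []
    for tx in db.features_of_type("transcript"):
        exons = [(f.start - 1, f.end) for f in db.children(tx, featuretype="exon")]
        cds = [(f.start - 1, f.end) for f in db.children(tx, featuretype="CDS")]
        attrs = tx.attributes
        biotype = (
            attrs.get("transcript_biotype", attrs.get("gene_biotype", ["protein_coding"]))
        )[0]
        tsl = _parse_tsl(attrs.get("transcript_support_level", [None])[0])
        has_ccds = "ccds_id" in attrs
        models.append(
            TranscriptModel(
                transcript_id=tx.id,
                gene_id=attrs["gene_id"][0],
                chrom=tx.seqid,
                strand=tx.strand,
                biotype=biotype,
                tsl=tsl,
                has_ccds=has_ccds,
                exons=exons,
                cds=cds,
            )
        )
    return models


def candidate_sort_key(model: TranscriptModel, feature: str):
    """Total order over (transcript, feature) candidates; lower wins."""
    return (
        0 if model.coding else 1,
        0 if (model.tsl is not None and model.tsl < 4) else 1,
        _FEATURE_RANK[feature],
        model.tsl if model.tsl is not None else 99,
        0 if model.has_ccds else 1,
        model.transcript_id,
    )


class FeatureIndex:
    """Interval index over all transcripts' feature intervals, per strand."""

    def __init__(self, models: list[TranscriptModel]):
        self.models = list(models)
        self._trees: dict[tuple[str, str], IntervalTree] = {}
        for m in models:
            tree = self._trees.setdefault((m.chrom, m.strand), IntervalTree())
            for s, e, feat in m.feature_intervals():
                tree.addi(s, e, (m, feat))

    def candidates(
        self, chrom: str, start: int, end: int, strand: str
    ) -> list[tuple[TranscriptModel, str]]:
        tree = self._trees.get((chrom, strand))
        if tree is None:
            return []
        return [iv.data for iv in tree.overlap(start, end)]

    def assign(self, site: CrosslinkSite | ClusterInterval) -> FeatureAssignment:
        if isinstance(site, CrosslinkSite):
            start, end = site.pos, site.pos + 1
        else:
            start, end = site.start, site.end
        cands = self.candidates(site.chrom, start, end, site.strand)
        if not cands:
            return FeatureAssignment(site.name, None, None, "intergenic")
        best = min(cands, key=lambda c: candidate_sort_key(*c))
        model, feature = best
        return FeatureAssignment(site.name, model.gene_id, model.transcript_id, feature)


def assign_feature(
    site: CrosslinkSite | ClusterInterval,
    models: list[TranscriptModel] | FeatureIndex,
) -> FeatureAssignment:
    """Assign one site/cluster to its highest-priority (gene, feature)."""
    index = models if isinstance(models, FeatureIndex) else FeatureIndex(models)
    return index.assign(site)


def assign_all(
    sites: list[CrosslinkSite | ClusterInterval],
    models: list[TranscriptModel] | FeatureIndex,
) -> list[FeatureAssignment]:
    index = models if isinstance(models, FeatureIndex) else FeatureIndex(models)
    return [index.assign(s) for s in sites]


def classify_transcript_methylation(
    assignments: list[FeatureAssignment],
) -> dict[str, str]:
    """Group methylated transcripts by where their sites fall.

    'utr3' (only 3'UTR sites), 'cds' (only CDS sites), 'both' (at least
    one of each) or 'other'. Transcripts without any assignment are absent
    (unmethylated).
    """
    feats: dict[str, set[str]] = {}
    for a in assignments:
        if a.transcript_id is not None:
            feats.setdefault(a.transcript_id, set()).add(a.feature)
    out = {}
    for tid, fs in feats.items():
        if "UTR3" in fs and "CDS" in fs:
            out[tid] = "both"
        elif fs == {"UTR3"}:
            out[tid] = "utr3"
        elif fs == {"CDS"}:
            out[tid] = "cds"
        else:
            out[tid] = "other"
    return out


# --- BED I/O (6-column: chrom start end name score strand) ---------------

_BED_COLS = ["chrom", "start", "end", "name", "score", "strand"]


def read_sites_bed(path: str | Path) -> list[CrosslinkSite]:
    df = pd.read_csv(path, sep="\t", header=None, names=_BED_COLS, comment="#")
    return [
        CrosslinkSite(r.chrom, int(r.start), r.strand, str(r.name), float(r.score))
        for r in df.itertuples()
    ]


def read_clusters_bed(path: str | Path) -> list[ClusterInterval]:
    df = pd.read_csv(path, sep="\t", header=None, names=_BED_COLS, comment="#")
    return [
        ClusterInterval(
            r.chrom, int(r.start), int(r.end), r.strand, str(r.name), float(r.score)
        )
        for r in df.itertuples()
    ]


def write_sites_bed(sites: list[CrosslinkSite], path: str | Path) -> None:
    pd.DataFrame(
        [(s.chrom, s.pos, s.pos + 1, s.name, s.score, s.strand) for s in sites]
    ).to_csv(path, sep="\t", header=False, index=False)


def write_clusters_bed(clusters: list[ClusterInterval], path: str | Path) -> None:
    pd.DataFrame(
        [(c.chrom, c.start, c.end, c.name, c.lfc, c.strand) for c in clusters]
    ).to_csv(path, sep="\t", header=False, index=False)


def assignments_to_frame(assignments: list[FeatureAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [(a.name, a.gene_id or "", a.transcript_id or "", a.feature) for a in assignments],
        columns=["site_id", "gene_id", "transcript_id", "feature"],
    )
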