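"""Metagene profiles of cluster occupancy over scaled CDS regions.

Each gene's genomic CDS span (first to last coding base of a
representative transcript) is scaled to a fixed number of body bins, with
1 kb of genomic flank on each side split into fixed-width bins. A bin's
value is 1 if any same-strand cluster overlaps its genomic interval and 0
otherwise (the maximum of an indicator, zeros kept); the profile is the
per-bin mean over genes, so values lie in [0, 1]. Profiles are oriented
5' -> 3', which places the stop codon at the end of the body — where m6A
clusters concentrate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from intervaltree import IntervalTree

from .annotation import ClusterInterval, TranscriptModel


@dataclass
class MetageneProfile:
    n_bins_body: int
    flank_bp: int
    bin_bp: int
    values: np.ndarray  # mean occupancy per bin, 5'->3'
    n_genes: int = 0

    @property
    def n_bins_flank(self) -> int:
        return self.flank_bp // self.bin_bp

    def __post_init__(self) -> None:
        expected = self.n_bins_body + 2 * self.n_bins_flank
        if len(self.values) != expected:
            raise ValueError(
                f"profile length {len(self.values)} != expected {expected}"
            )
        if ((self.values < 0) | (self.values > 1)).any():
            raise ValueError("profile values must lie in [0, 1]")


def representative_transcripts(
    models: list[TranscriptModel],
) -> list[TranscriptModel]:
    """One coding transcript per gene: longest CDS, ties by transcript_id."""
    best: dict[str, TranscriptModel] = {}
    for m in models:
        if not m.coding:
            continue
        cur = best.get(m.gene_id)
        if (
            cur is None
            or m.cds_length > cur.cds_length
            or (m.cds_length == cur.cds_length and m.transcript_id < cur.transcript_id)
        ):
            best[m.gene_id] = m
    return [best[g] for g in sorted(best)]


def _cluster_trees(
    clusters: list[ClusterInterval],
) -> dict[tuple[str, str], IntervalTree]:
    trees: dict[tuple[str, str], IntervalTree] = {}
    for c in clusters:
        trees.setdefault((c.chrom, c.strand), IntervalTree()).addi(c.start, c.end)
    return trees


def gene_occupancy_row(
    model: TranscriptModel,
    trees: dict[tuple[str, str], IntervalTree],
    n_bins_body: int,
    flank_bp: int,
    bin_bp: int,
) -> np.ndarray:
    """Binary occupancy vector for one gene, oriented 5'->3'."""
    span = model.cds_span
    if span is None:
        raise ValueError(f"{model.transcript_id} is non-coding")
    cs, ce = span
    n_flank = flank_bp // bin_bp
    edges = []
    # upstream-genomic flank, body, downstream-genomic flank (genomic order)
    for i in range(n_flank):
        edges.append((cs - flank_bp + i * bin_bp, cs - flank_bp + (i + 1) * bin_bp))
    body = np.linspace(cs, ce, n_bins_body + 1)
    for i in range(n_bins_body):
        edges.append((body[i], body[i + 1]))
    for i in range(n_flank):
        edges.append((ce + i * bin_bp, ce + (i + 1) * bin_bp))

    tree = trees.get((model.chrom, model.strand))
    row = np.zeros(len(edges))
    if tree is not None:
        for j, (s, e) in enumerate(edges):
            lo, hi = int(np.floor(s)), int(np.ceil(e))
            if hi > max(lo, 0) and tree.overlap(max(lo, 0), hi):
                row[j] = 1.0
    if model.strand == "-":
        row = row[::-1]
    return row


def compute_metagene(
    clusters: list[ClusterInterval],
    models: list[TranscriptModel],
    n_bins_body: int = 100,
    flank_bp: int = 1000,
    bin_bp: int = 10,
) -> MetageneProfile:
    """Average cluster occupancy over scaled CDS +/- flank, across genes."""
    reps = representative_transcripts(models)
    if not reps:
        raise ValueError("no coding transcripts in the annotation")
    if flank_bp % bin_bp != 0:
        raise ValueError("flank_bp must be a multiple of bin_bp")
    trees = _cluster_trees(clusters)
    rows = np.array(
        [gene_occupancy_row(m, trees, n_bins_body, flank_bp, bin_bp) for m in reps]
    )
    return MetageneProfile(
        n_bins_body=n_bins_body,
        flank_bp=flank_bp,
        bin_bp=bin_bp,
        values=rows.mean(axis=0),
        n_genes=len(reps),
    )
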