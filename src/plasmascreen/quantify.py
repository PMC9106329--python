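"""Guide quantification from screen sequencing reads.

Screen reads contain the 19-nt protospacer immediately followed by the
constant sgRNA scaffold. Each read is searched for the scaffold anchor
(GTTTAAGAGCTAT); the 19 bases immediately preceding its first occurrence
are extracted and assigned to a library guide by exact (zero-mismatch)
string match. Reads with no anchor, fewer than 19 preceding bases, an
extracted 19-mer containing N, or no exact library match are left
unassigned.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .library import GuideLibrary, PROTOSPACER_LEN

logger = logging.getLogger(__name__)

SCAFFOLD_ANCHOR = "GTTTAAGAGCTAT"


def extract_protospacer(read: str) -> str | None:
    """Return the 19 bases immediately preceding the first scaffold anchor.

    Returns None when the anchor is absent or fewer than 19 bases precede
    it. The first anchor occurrence is used when there are several.
    """
    idx = read.find(SCAFFOLD_ANCHOR)
    if idx < PROTOSPACER_LEN:
        return None
    return read[idx - PROTOSPACER_LEN : idx]


@dataclass
class SampleCounts:
    """Per-sample guide counts plus read-fate tallies."""

    sample_id: str
    counts: dict[str, int]
    n_reads_total: int = 0
    n_reads_with_scaffold: int = 0
    n_reads_assigned: int = 0

    def __post_init__(self) -> None:
        assigned = sum(self.counts.values())
        if assigned != self.n_reads_assigned:
            raise ValueError(
                f"sample {self.sample_id!r}: counts sum to {assigned} but "
                f"n_reads_assigned={self.n_reads_assigned}"
            )
        if not (
            self.n_reads_assigned
            <= self.n_reads_with_scaffold
            <= self.n_reads_total
        ):
            raise ValueError(
                f"sample {self.sample_id!r}: inconsistent read tallies"
            )


def _open_maybe_gzip(path: str | Path):
    """Open a possibly gzip-compressed text file, detected by magic bytes."""
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def count_reads(
    fastq_path: str | Path, library: GuideLibrary, sample_id: str
) -> SampleCounts:
    """Count guide occurrences in one FASTQ file (plain or gzip).

    Each read contributes to at most one guide; assignment is exact
    equality of the extracted 19-mer to a library protospacer.
    """
    if len(library) == 0:
        raise ValueError("cannot count against an empty library")
    counts = {gid: 0 for gid in library.guide_ids}
    n_total = n_scaffold = n_assigned = 0
    record_no = 0
    with _open_maybe_gzip(fastq_path) as fh:
        try:
            for rec in SeqIO.parse(fh, "fastq"):
                record_no += 1
                n_total += 1
                seq = str(rec.seq).upper()
                proto = extract_protospacer(seq)
                if seq.find(SCAFFOLD_ANCHOR) != -1:
                    n_scaffold += 1
                if proto is None:
                    continue
                gid = library.index.get(proto)
                if gid is not None:
                    counts[gid] += 1
                    n_assigned += 1
        except ValueError as exc:
            raise IOError(
                f"malformed FASTQ {fastq_path} near record {record_no + 1}: {exc}"
            ) from exc
    logger.info(
        "sample %s: %d reads, %d with scaffold, %d assigned",
        sample_id,
        n_total,
        n_scaffold,
        n_assigned,
    )
    return SampleCounts(
        sample_id=sample_id,
        counts=counts,
        n_reads_total=n_total,
        n_reads_with_scaffold=n_scaffold,
        n_reads_assigned=n_assigned,
    )


def build_count_matrix(
    samples: list[SampleCounts], library: GuideLibrary
) -> pd.DataFrame:
    """Assemble a guide x sample integer count matrix.

    Rows follow library order; every library guide appears (zero-filled
    where unseen). Samples counted against a different library (unknown
    guide ids) are rejected.
    """
    if not samples:
        raise ValueError("need at least one sample")
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate sample_id among {ids}")
    guide_ids = library.guide_ids
    known = set(guide_ids)
    data = {}
    for s in samples:
        unknown = set(s.counts) - known
        if unknown:
            raise ValueError(
                f"sample {s.sample_id!r} has guides not in the library, "
                f"e.g. {sorted(unknown)[:3]}"
            )
        data[s.sample_id] = [s.counts.get(g, 0) for g in guide_ids]
    df = pd.DataFrame(data, index=pd.Index(guide_ids, name="guide_id"))
    return df.astype(int)


def read_count_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="guide_id")
    if (df.values < 0).any():
        raise ValueError("count matrix contains negative values")
    return df.astype(int)


def write_count_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="guide_id")
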