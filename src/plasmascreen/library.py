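"""sgRNA library handling.

A pooled screen library is a table of guides: each guide carries a 19-nt
protospacer (the programmable targeting sequence that precedes the constant
scaffold in sequencing reads), a target gene (or none, for non-targeting
controls) and a category. The library studied here targets RNA-binding
proteins with 10 guides per gene, plus positive-control genes and 500
non-targeting guides.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

PROTOSPACER_LEN = 19
CATEGORIES = ("rbp_target", "positive_control", "non_targeting")
_VALID_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class GuideRecord:
    """One guide: id, 19-nt protospacer, target gene (None = non-targeting)."""

    guide_id: str
    protospacer: str
    gene: str | None
    category: str

    def __post_init__(self) -> None:
        if len(self.protospacer) != PROTOSPACER_LEN:
            raise ValueError(
                f"guide {self.guide_id!r}: protospacer must be "
                f"{PROTOSPACER_LEN} nt, got {len(self.protospacer)}"
            )
        if not set(self.protospacer) <= _VALID_BASES:
            raise ValueError(
                f"guide {self.guide_id!r}: protospacer contains non-ACGT characters"
            )
        if self.category not in CATEGORIES:
            raise ValueError(
                f"guide {self.guide_id!r}: unknown category {self.category!r}"
            )
        # non_targeting iff gene is null
        if (self.category == "non_targeting") != (self.gene is None):
            raise ValueError(
                f"guide {self.guide_id!r}: gene must be empty exactly for "
                f"non_targeting guides"
            )


class GuideLibrary:
    """Ordered collection of guides with a protospacer -> guide_id index.

    Protospacers must be unique across the library: with zero-mismatch
    assignment a collision would make read assignment ambiguous, so it is
    treated as a load error.
    """

    def __init__(self, records: list[GuideRecord]):
        if not records:
            raise ValueError("library is empty")
        seen_ids: set[str] = set()
        index: dict[str, str] = {}
        for rec in records:
            if rec.guide_id in seen_ids:
                raise ValueError(f"duplicate guide_id {rec.guide_id!r}")
            seen_ids.add(rec.guide_id)
            if rec.protospacer in index:
                raise ValueError(
                    f"protospacer collision between {index[rec.protospacer]!r} "
                    f"and {rec.guide_id!r}"
                )
            index[rec.protospacer] = rec.guide_id
        self.records: list[GuideRecord] = list(records)
        self.index: dict[str, str] = index

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def guide_ids(self) -> list[str]:
        return [r.guide_id for r in self.records]

    def category_counts(self) -> dict[str, int]:
        out = {c: 0 for c in CATEGORIES}
        for r in self.records:
            out[r.category] += 1
        return out

    def guides_by_category(self, category: str) -> list[str]:
        return [r.guide_id for r in self.records if r.category == category]

    @property
    def nt_guide_ids(self) -> list[str]:
        """Non-targeting control guides (the null set for screen statistics)."""
        return self.guides_by_category("non_targeting")

    @property
    def targeting_guide_ids(self) -> list[str]:
        return [r.guide_id for r in self.records if r.gene is not None]

    def gene_map(self) -> dict[str, list[str]]:
        """Map gene -> guide_ids, targeting guides only."""
        out: dict[str, list[str]] = {}
        for r in self.records:
            if r.gene is not None:
                out.setdefault(r.gene, []).append(r.guide_id)
        return out

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GuideLibrary":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        required = ["guide_id", "protospacer", "gene", "category"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"library TSV missing columns: {missing}")
        records = [
            GuideRecord(
                guide_id=row.guide_id,
                protospacer=row.protospacer,
                gene=row.gene or None,
                category=row.category,
            )
            for row in df.itertuples()
        ]
        return cls(records)

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "guide_id": [r.guide_id for r in self.records],
                "protospacer": [r.protospacer for r in self.records],
                "gene": [r.gene or "" for r in self.records],
                "category": [r.category for r in self.records],
            }
        )
        df.to_csv(path, sep="\t", index=False)
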