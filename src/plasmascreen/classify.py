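"""Two-screen intersection: expansion vs CD138+ accumulation regulators.

Two screens are run from the same library: an expansion screen (day 8 vs
day 4 of culture, capturing proliferation/survival effects) and an
accumulation screen (CD138+ vs CD138- sorted cells, capturing effects on
plasma-cell abundance). Intersecting the two separates genes that regulate
CD138+ accumulation specifically from genes that act through B-cell
expansion.

Sign convention: accumulation LFC is CD138+ over CD138-. Knocking out a
differentiation promoter depletes its guides from CD138+ cells, so a
*promoter* of accumulation shows z <= -z_cut and a *limiter* z >= +z_cut.
A ``flip_sign`` flag inverts this if the comparison was run the other way
around.
"""

from __future__ import annotations

import pandas as pd

from .screen_stats import ScreenConfig

CLASSES = ("accumulation_promote", "accumulation_limit", "expansion_only", "both", "none")


def _as_gene_table(df: pd.DataFrame, label: str) -> pd.DataFrame:
    if df["gene"].duplicated().any():
        dups = df.loc[df["gene"].duplicated(), "gene"].tolist()[:3]
        raise ValueError(f"{label} results contain duplicated genes, e.g. {dups}")
    return df.set_index("gene")[["z", "fdr", "is_hit"]]


def classify_genes(
    expansion: pd.DataFrame,
    accumulation: pd.DataFrame,
    config: ScreenConfig | None = None,
    flip_sign: bool = False,
) -> pd.DataFrame:
    """Classify every gene from either screen into one of five classes.

    accumulation hit only -> accumulation_promote / accumulation_limit by
    the sign of its accumulation z; expansion hit only -> expansion_only;
    hit in both -> both; otherwise none. Genes absent from one screen are
    treated as non-hits there.
    """
    config = config or ScreenConfig()
    exp = _as_gene_table(expansion, "expansion")
    acc = _as_gene_table(accumulation, "accumulation")
    genes = exp.index.union(acc.index)
    exp = exp.reindex(genes)
    acc = acc.reindex(genes)
    # genes absent from one screen (NaN) are non-hits there
    exp_hit = exp["is_hit"].eq(True)
    acc_hit = acc["is_hit"].eq(True)

    z_acc = acc["z"]
    promote_sign = z_acc >= config.z_cut if flip_sign else z_acc <= -config.z_cut

    cls = pd.Series("none", index=genes, dtype=object)
    cls[acc_hit & ~exp_hit & promote_sign] = "accumulation_promote"
    cls[acc_hit & ~exp_hit & ~promote_sign] = "accumulation_limit"
    cls[exp_hit & ~acc_hit] = "expansion_only"
    cls[exp_hit & acc_hit] = "both"

    return pd.DataFrame(
        {
            "z_expansion": exp["z"],
            "z_accumulation": acc["z"],
            "fdr_expansion": exp["fdr"],
            "fdr_accumulation": acc["fdr"],
            "class": cls,
        }
    ).rename_axis("gene").reset_index()


def summarize_classes(classifications: pd.DataFrame) -> pd.Series:
    """Tally genes per class (zero-filled) plus a total."""
    if classifications.empty:
        raise ValueError("no classifications to summarize")
    counts = classifications["class"].value_counts()
    out = pd.Series({c: int(counts.get(c, 0)) for c in CLASSES}, name="count")
    out["total"] = int(len(classifications))
    return out
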