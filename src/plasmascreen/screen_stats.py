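"""Screen inference: negative-control-anchored statistics for pooled screens.

The procedure mirrors the standard pooled-screen workflow anchored on
non-targeting (NT) control guides:

1. normalization by median-of-ratios size factors computed over NT guides;
2. a mean-variance null model ``var(mu) = mu + k * mu**b`` fitted to NT
   guides of the tested sample pair;
3. per-guide negative-binomial tail tests for enrichment and depletion,
   each direction ranked independently;
4. gene scores by alpha-robust-rank-aggregation (alpha-RRA): the minimum,
   over a gene's significantly selected guides, of the Beta order-statistic
   probability of seeing ranks that extreme;
5. gene p-values by permuting the guide-to-gene allocation, then
   Benjamini-Hochberg FDR within each direction;
6. a gene effect size (median log2 fold change of same-direction guides)
   expressed as a z-score in units of the NT-control LFC distribution.

A gene is called a hit when ``|z| >= z_cut`` and ``fdr < fdr_cut``
(defaults 2 and 0.05).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .library import GuideLibrary

logger = logging.getLogger(__name__)

DIRECTIONS = ("positive", "negative")


@dataclass
class ScreenConfig:
    """Tunable thresholds and seeds for screen inference.

    pseudocount : added to normalized counts for LFCs (symmetric, 0.5).
    alpha_select : per-guide p-value cutoff for alpha-RRA guide selection.
    n_permutations : guide-to-gene allocation permutations per gene size.
    z_cut, fdr_cut : the hit rule |z| >= z_cut and fdr < fdr_cut.
    nt_reference : "guide" references gene z-scores to individual NT guide
        LFCs; "pseudo" references them to median LFCs of random NT
        pseudo-genes of matching size.
    """

    pseudocount: float = 0.5
    alpha_select: float = 0.05
    n_permutations: int = 10_000
    z_cut: float = 2.0
    fdr_cut: float = 0.05
    seed: int = 0
    nt_reference: str = "guide"
    min_nt_guides: int = 20
    normalization: str = "nt_median_ratio"  # or "total"

    def __post_init__(self) -> None:
        if not (0 < self.alpha_select < 1 and 0 < self.fdr_cut < 1):
            raise ValueError("alpha_select and fdr_cut must be in (0,1)")
        if self.pseudocount <= 0 or self.z_cut < 0:
            raise ValueError("invalid pseudocount or z_cut")
        if self.n_permutations < 100:
            logger.warning(
                "n_permutations=%d is very low; p-value floor is %.3g",
                self.n_permutations,
                1 / (self.n_permutations + 1),
            )
        if self.nt_reference not in ("guide", "pseudo"):
            raise ValueError("nt_reference must be 'guide' or 'pseudo'")


@dataclass
class NormalizedCounts:
    matrix: pd.DataFrame
    size_factors: pd.Series
    pseudocount: float


@dataclass
class MeanVarModel:
    """NT-guide mean-variance null: predicted var(mu) = mu + k * mu**b."""

    k: float
    b: float
    fit_n: int
    floor_variance: float = 1e-2

    def predict(self, mu: np.ndarray) -> np.ndarray:
        mu = np.asarray(mu, dtype=float)
        return mu + self.k * np.power(mu, self.b)


def normalize_counts(
    matrix: pd.DataFrame, library: GuideLibrary, config: ScreenConfig
) -> NormalizedCounts:
    """Median-of-ratios normalization restricted to NT control guides.

    The size factor of a sample is the median, over NT guides with nonzero
    geometric mean across samples, of count / geometric-mean; normalized
    value = count / size factor. NT guides are the designated null set, so
    anchoring size factors on them keeps the null centred even when many
    targeting guides shift. ``config.normalization='total'`` falls back to
    total-count scaling.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least two samples to normalize")
    if config.normalization == "total":
        totals = matrix.sum(axis=0).astype(float)
        sf = totals / totals.mean()
    else:
        nt = matrix.loc[matrix.index.intersection(library.nt_guide_ids)]
        usable = nt[(nt > 0).all(axis=1)]
        if len(usable) < config.min_nt_guides:
            raise ValueError(
                f"only {len(usable)} NT guides with nonzero geometric mean "
                f"(need {config.min_nt_guides}); consider "
                f"ScreenConfig(normalization='total')"
            )
        logmean = np.log(usable.astype(float)).mean(axis=1)
        ratios = usable.astype(float).div(np.exp(logmean), axis=0)
        sf = ratios.median(axis=0)
    if (sf <= 0).any():
        raise ValueError("non-positive size factor estimated")
    norm = matrix.astype(float).div(sf, axis=1)
    return NormalizedCounts(matrix=norm, size_factors=sf, pseudocount=config.pseudocount)


def fit_mean_variance(
    norm: NormalizedCounts,
    library: GuideLibrary,
    pair: tuple[str, str],
    min_nt_guides: int = 20,
    floor_variance: float = 1e-2,
    min_per_bin: int = 5,
) -> MeanVarModel:
    """Fit var(mu) = mu + k * mu**b to NT guides of a sample pair.

    Per NT guide, mu is the pair mean and (x1-x2)^2 / 2 the variance proxy
    (the unbiased two-point variance estimate under a shared mean). Guides
    are split into equal-occupancy mean bins; the super-Poisson excess
    variance of bin averages is regressed in log2 space to give the power
    law's exponent b and coefficient k = 2**intercept.
    """
    a, b_ = pair
    for s in pair:
        if s not in norm.matrix.columns:
            raise KeyError(f"sample {s!r} not in matrix")
    nt = norm.matrix.loc[norm.matrix.index.intersection(library.nt_guide_ids), [a, b_]]
    x1 = nt[a].to_numpy(float)
    x2 = nt[b_].to_numpy(float)
    mu = (x1 + x2) / 2
    keep = mu > 0
    mu, v = mu[keep], ((x1 - x2) ** 2 / 2)[keep]
    n = mu.size
    if n < min_nt_guides:
        raise ValueError(f"only {n} usable NT guides for mean-variance fit")
    order = np.argsort(mu)
    n_bins = int(np.clip(n // min_per_bin, 1, 20))
    mu_bar, excess = [], []
    for idx in np.array_split(order, n_bins):
        m = mu[idx].mean()
        e = max(v[idx].mean() - m, floor_variance)
        mu_bar.append(m)
        excess.append(e)
    slope, intercept = np.polyfit(np.log2(mu_bar), np.log2(excess), 1)
    k = max(float(2.0**intercept), 0.0)
    return MeanVarModel(k=k, b=float(slope), fit_n=n, floor_variance=floor_variance)


def _nb_tail_probs(
    t_round: np.ndarray, mu: np.ndarray, var: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """P(X >= t) and P(X <= t) under NB(mean mu, variance var).

    Falls back to Poisson tails where var <= mu (the NB parameterisation
    degenerates there).
    """
    p_enrich = np.empty_like(mu)
    p_deplete = np.empty_like(mu)
    over = var > mu
    if over.any():
        # NB with mean mu, var: size r = mu^2/(var-mu), prob p = mu/var
        r = mu[over] ** 2 / (var[over] - mu[over])
        p = mu[over] / var[over]
        t = t_round[over]
        p_enrich[over] = stats.nbinom.sf(t - 1, r, p)
        p_deplete[over] = stats.nbinom.cdf(t, r, p)
    if (~over).any():
        t = t_round[~over]
        m = mu[~over]
        p_enrich[~over] = stats.poisson.sf(t - 1, m)
        p_deplete[~over] = stats.poisson.cdf(t, m)
    return np.clip(p_enrich, 0, 1), np.clip(p_deplete, 0, 1)


def sgrna_test(
    norm: NormalizedCounts,
    model: MeanVarModel,
    control_sample: str,
    treatment_sample: str,
    config: ScreenConfig,
) -> pd.DataFrame:
    """Per-guide enrichment/depletion tests for one comparison.

    Null: treatment count ~ NB(mean = control value, variance from the NT
    model). Both one-sided tail probabilities are reported and each
    direction is ranked independently (ascending p; ties broken by |LFC|
    descending, then guide_id).
    """
    c = norm.matrix[control_sample].to_numpy(float)
    t = norm.matrix[treatment_sample].to_numpy(float)
    ps = config.pseudocount
    lfc = np.log2((t + ps) / (c + ps))
    mu = np.maximum(c, ps)
    var = model.predict(mu)
    t_round = np.round(t)
    p_enrich, p_deplete = _nb_tail_probs(t_round, mu, var)

    guide_ids = norm.matrix.index.to_numpy()

    def ranks_for(p: np.ndarray) -> np.ndarray:
        order = np.lexsort((guide_ids, -np.abs(lfc), p))
        r = np.empty(len(p), dtype=int)
        r[order] = np.arange(1, len(p) + 1)
        return r

    rank_enrich = ranks_for(p_enrich)
    rank_deplete = ranks_for(p_deplete)
    return pd.DataFrame(
        {
            "lfc": lfc,
            "p_enrich": p_enrich,
            "p_deplete": p_deplete,
            "rank_enrich": rank_enrich,
            "rank_deplete": rank_deplete,
            "selected_enrich": p_enrich < config.alpha_select,
            "selected_deplete": p_deplete < config.alpha_select,
        },
        index=norm.matrix.index,
    )


def alpha_rra_score(
    u_selected: np.ndarray | list[float], m: int
) -> float:
    """Alpha-RRA gene score from the normalized ranks of selected guides.

    ``u_selected`` holds rank/N_total for the guides that passed the
    per-guide selection threshold; ``m`` is the gene's total guide count.
    The score is min over k of P(Beta(k, m-k+1) <= u_(k)) where u_(k) is
    the k-th smallest selected normalized rank — the probability that the
    k-th best of m uniform ranks would be that extreme. With no selected
    guide the score is 1.
    """
    if m < 1:
        raise ValueError("gene must have at least one guide")
    u = np.sort(np.asarray(u_selected, dtype=float))
    j = u.size
    if j == 0:
        return 1.0
    if j > m:
        raise ValueError("more selected guides than guides")
    k = np.arange(1, j + 1)
    return float(np.min(special.betainc(k, m - k + 1, u)))


def _score_sets(
    u_mat: np.ndarray, sel_mat: np.ndarray
) -> np.ndarray:
    """Vectorised alpha-RRA over many guide sets of identical size m.

    u_mat: (n_sets, m) normalized ranks; sel_mat: matching selection flags.
    """
    m = u_mat.shape[1]
    u = np.where(sel_mat, u_mat, 2.0)  # push unselected past the valid range
    u.sort(axis=1)
    k = np.arange(1, m + 1)
    probs = special.betainc(k, m - k + 1, np.minimum(u, 1.0))
    probs = np.where(u > 1.0, np.inf, probs)
    scores = probs.min(axis=1)
    return np.where(np.isfinite(scores), scores, 1.0)


def permute_gene_pvalues(
    stats_df: pd.DataFrame,
    gene_map: dict[str, list[str]],
    direction: str,
    config: ScreenConfig,
    rng: np.random.Generator,
) -> dict[str, tuple[float, float]]:
    """Gene alpha-RRA scores and permutation p-values for one direction.

    Null scores are generated by randomizing the guide-to-gene allocation:
    for each gene size m, ``n_permutations`` random m-guide sets are drawn
    from all targeting guides and scored; draws are pooled across genes of
    identical size. p = (1 + #{null <= observed}) / (1 + n_permutations).
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    col = "enrich" if direction == "positive" else "deplete"
    n_total = len(stats_df)
    u_all = stats_df[f"rank_{col}"].to_numpy(float) / n_total
    sel_all = stats_df[f"selected_{col}"].to_numpy(bool)
    pos = {g: i for i, g in enumerate(stats_df.index)}

    targeting = sorted(gid for gids in gene_map.values() for gid in gids)
    t_idx = np.array([pos[g] for g in targeting])

    observed: dict[str, float] = {}
    sizes: dict[int, list[str]] = {}
    for gene, gids in gene_map.items():
        idx = np.array([pos[g] for g in gids])
        m = len(idx)
        observed[gene] = alpha_rra_score(u_all[idx][sel_all[idx]], m)
        sizes.setdefault(m, []).append(gene)

    out: dict[str, tuple[float, float]] = {}
    n_perm = config.n_permutations
    for m, genes in sizes.items():
        null = np.empty(n_perm)
        chunk = max(1, min(n_perm, 2_000_000 // max(len(t_idx), 1)))
        done = 0
        while done < n_perm:
            c = min(chunk, n_perm - done)
            # without-replacement draws via per-row argpartition of noise
            noise = rng.random((c, len(t_idx)))
            draws = t_idx[np.argpartition(noise, m - 1, axis=1)[:, :m]]
            null[done : done + c] = _score_sets(u_all[draws], sel_all[draws])
            done += c
        null.sort()
        for gene in genes:
            obs = observed[gene]
            n_le = int(np.searchsorted(null, obs, side="right"))
            out[gene] = (obs, (1 + n_le) / (1 + n_perm))
    return out


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, order-preserving."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def gene_lfc_and_z(
    guide_lfcs: np.ndarray | list[float],
    direction: str,
    nt_lfcs: np.ndarray | list[float],
) -> tuple[float, float, bool]:
    """Gene LFC (median of same-direction guide LFCs) and NT-referenced z.

    Returns (gene_lfc, z, flagged); flagged is True when no guide LFC has
    the direction's sign, in which case both values are 0.
    """
    lfcs = np.asarray(guide_lfcs, dtype=float)
    nt = np.asarray(nt_lfcs, dtype=float)
    sd = nt.std(ddof=1)
    if sd == 0 or np.isnan(sd):
        raise ValueError("NT LFC reference has zero spread")
    same = lfcs[lfcs > 0] if direction == "positive" else lfcs[lfcs < 0]
    if same.size == 0:
        return 0.0, 0.0, True
    gene_lfc = float(np.median(same))
    z = (gene_lfc - nt.mean()) / sd
    return gene_lfc, float(z), False


def _nt_reference_lfcs(
    sgrna: pd.DataFrame,
    library: GuideLibrary,
    config: ScreenConfig,
    rng: np.random.Generator,
    pseudo_size: int = 10,
    n_pseudo: int = 1000,
) -> np.ndarray:
    """LFC reference distribution from NT guides.

    "guide": the NT guide LFCs themselves. "pseudo": median LFCs of random
    NT pseudo-genes of ``pseudo_size`` guides.
    """
    nt_ids = sgrna.index.intersection(library.nt_guide_ids)
    nt_lfcs = sgrna.loc[nt_ids, "lfc"].to_numpy(float)
    if config.nt_reference == "guide":
        return nt_lfcs
    draws = np.array(
        [rng.choice(nt_lfcs.size, size=min(pseudo_size, nt_lfcs.size), replace=False)
         for _ in range(n_pseudo)]
    )
    return np.median(nt_lfcs[draws], axis=1)


def run_screen(
    matrix: pd.DataFrame,
    library: GuideLibrary,
    control_sample: str,
    treatment_sample: str,
    config: ScreenConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full screen inference for one comparison.

    Returns (per-sgRNA table, per-gene table). Positive and negative
    enrichment are scored and FDR-adjusted independently; each gene is
    reported in its better direction (smaller permutation p, ties by
    smaller RRA score, then direction name).
    """
    config = config or ScreenConfig()
    rng = np.random.default_rng(config.seed)
    norm = normalize_counts(matrix, library, config)
    model = fit_mean_variance(
        norm, library, (control_sample, treatment_sample),
        min_nt_guides=config.min_nt_guides,
    )
    sgrna = sgrna_test(norm, model, control_sample, treatment_sample, config)
    gene_map = library.gene_map()
    nt_ref = _nt_reference_lfcs(sgrna, library, config, rng)

    per_direction: dict[str, pd.DataFrame] = {}
    for direction in DIRECTIONS:
        scored = permute_gene_pvalues(sgrna, gene_map, direction, config, rng)
        genes = sorted(scored)
        rra = np.array([scored[g][0] for g in genes])
        p_perm = np.array([scored[g][1] for g in genes])
        fdr = bh_fdr(p_perm)
        rows = []
        for g, r, p, q in zip(genes, rra, p_perm, fdr):
            lfcs = sgrna.loc[gene_map[g], "lfc"].to_numpy(float)
            gl, z, flagged = gene_lfc_and_z(lfcs, direction, nt_ref)
            rows.append((g, direction, r, p, q, gl, z, flagged))
        per_direction[direction] = pd.DataFrame(
            rows,
            columns=["gene", "direction", "rra_score", "p_perm", "fdr",
                     "gene_lfc", "z", "flagged"],
        ).set_index("gene")

    # merge: each gene keeps its better direction
    pos, neg = per_direction["positive"], per_direction["negative"]
    take_pos = (pos["p_perm"] < neg["p_perm"]) | (
        (pos["p_perm"] == neg["p_perm"]) & (pos["rra_score"] < neg["rra_score"])
    ) | (
        (pos["p_perm"] == neg["p_perm"]) & (pos["rra_score"] == neg["rra_score"])
    )
    gene_df = pos.where(take_pos, neg).copy()
    gene_df["n_guides"] = [len(gene_map[g]) for g in gene_df.index]
    gene_df = call_hits(gene_df, config)
    gene_df = gene_df.sort_values(["p_perm", "rra_score"]).reset_index()
    return sgrna, gene_df


def call_hits(gene_df: pd.DataFrame, config: ScreenConfig) -> pd.DataFrame:
    """Apply the hit rule: |z| >= z_cut and fdr < fdr_cut."""
    out = gene_df.copy()
    out["is_hit"] = (out["z"].abs() >= config.z_cut) & (out["fdr"] < config.fdr_cut)
    return out
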