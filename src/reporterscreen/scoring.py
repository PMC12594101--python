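"""alpha-robust-rank-aggregation scoring of sorted-bin sgRNA counts.

The per-guide statistic is the replicate-mean log2 ratio of normalized
low-bin to high-bin counts (pseudocount 0.5).  Each guide gets a
one-sided empirical p-value against the non-targeting control guides in
each direction, and a percentile rank within each direction's ordering
of all guides.  Per gene and direction, guides with empirical p below
``alpha`` are "selected" and the gene statistic is

    rho = min_{k=1..s} P( Beta(k, m-k+1) <= r_(k) )

over the gene's sorted guide percentile ranks r_(1) <= ... <= r_(m),
where s is the number of selected guides (rho = 1 when s = 0).  The
gene p-value comes from a permutation null that redraws m guides
without replacement from the full guide pool and reapplies the same
alpha selection; genes are BH-adjusted per direction.

The ``pos`` direction (low-bin enrichment) identifies activators and
the ``neg`` direction (high-bin enrichment) identifies repressors.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .counting import CountTable
from .library import CONTROL, SgRNALibrary

__all__ = [
    "NormalizedCounts",
    "RraConfig",
    "normalize",
    "default_design",
    "sgrna_scores",
    "gene_rra",
    "export_scores",
    "read_scores",
]


# ---------------------------------------------------------------------------
# normalization


@dataclass
class NormalizedCounts:
    """Size-factor-normalized counts (sgRNA x sample) with gene mapping."""

    matrix: pd.DataFrame
    size_factors: pd.Series
    gene_of: pd.Series
    method: str  # "median_ratio" or "total"


def normalize(table: CountTable, min_common: int = 100) -> NormalizedCounts:
    """Median-of-ratios size-factor normalization.

    size_factor_j = median over guides with all-positive counts of
    count_ij / geomean_i(counts).  Falls back to total-count scaling
    when fewer than ``min_common`` guides are positive in every sample.
    """
    matrix = table.to_matrix().astype(float)
    if matrix.shape[1] < 2:
        raise ValueError("normalization needs at least two samples")
    totals = matrix.sum(axis=0)
    if (totals == 0).any():
        bad = list(totals.index[totals == 0])
        raise ValueError(f"samples with zero total counts: {bad}")
    positive = (matrix > 0).all(axis=1)
    if int(positive.sum()) >= min_common:
        sub = matrix.loc[positive]
        geomean = np.exp(np.log(sub).mean(axis=1))
        factors = sub.div(geomean, axis=0).median(axis=0)
        method = "median_ratio"
    else:
        factors = totals / totals.mean()
        method = "total"
    gene_of = table.counts.drop_duplicates("sgrna").set_index("sgrna")["gene"]
    return NormalizedCounts(
        matrix.div(factors, axis=1), factors, gene_of.reindex(matrix.index), method
    )


def default_design(table: CountTable) -> list[tuple[str, str]]:
    """Pair repK_low with repK_high sample names."""
    names = set(table.sample_names)
    pairs = []
    for name in sorted(names):
        if name.endswith("_low"):
            high = name[: -len("_low")] + "_high"
            if high in names:
                pairs.append((name, high))
    if not pairs:
        raise ValueError("no low/high sample pairs found")
    return pairs


# ---------------------------------------------------------------------------
# per-guide scores


def sgrna_scores(
    norm: NormalizedCounts,
    design: list[tuple[str, str]],
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-guide enrichment statistic, control-based empirical p-values
    and percentile ranks in each direction.

    ``design`` lists (low_sample, high_sample) pairs, one per replicate.
    Returns columns ``sgrna, gene, score, pos_p, neg_p, pos_rank,
    neg_rank`` where ranks are percentile ranks in (0, 1], pos sorted by
    descending score (most low-enriched first) and neg ascending, ties
    broken by sgRNA id.
    """
    if not design:
        raise ValueError("empty design")
    matrix = norm.matrix
    ratios = [
        np.log2((matrix[lo] + pseudocount) / (matrix[hi] + pseudocount))
        for lo, hi in design
    ]
    score = pd.concat(ratios, axis=1).mean(axis=1)
    df = pd.DataFrame(
        {"sgrna": matrix.index, "gene": norm.gene_of.to_numpy(), "score": score.to_numpy()}
    )
    controls = df.loc[df["gene"] == CONTROL, "score"].to_numpy()
    if controls.size == 0:
        raise ValueError("no control sgRNAs: the empirical null requires them")
    ctrl_sorted = np.sort(controls)
    n_ctrl = controls.size
    s = df["score"].to_numpy()
    # pos: one-sided p vs controls, extreme = large score (low-bin enriched)
    ge = n_ctrl - np.searchsorted(ctrl_sorted, s, side="left")
    le = np.searchsorted(ctrl_sorted, s, side="right")
    df["pos_p"] = (1.0 + ge) / (1.0 + n_ctrl)
    df["neg_p"] = (1.0 + le) / (1.0 + n_ctrl)

    n = len(df)
    order_pos = df.sort_values(["score", "sgrna"], ascending=[False, True]).index
    order_neg = df.sort_values(["score", "sgrna"], ascending=[True, True]).index
    pos_rank = pd.Series(np.arange(1, n + 1) / n, index=order_pos)
    neg_rank = pd.Series(np.arange(1, n + 1) / n, index=order_neg)
    df["pos_rank"] = pos_rank.reindex(df.index)
    df["neg_rank"] = neg_rank.reindex(df.index)
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# gene-level alpha-RRA


@dataclass
class RraConfig:
    alpha: float = 0.05
    n_permutations: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if self.n_permutations < 100:
            raise ValueError("need at least 100 permutations")


def _rho(ranks: np.ndarray, n_selected: np.ndarray) -> np.ndarray:
    """Vectorized rho over rows of sorted percentile ranks.

    ``ranks``: (N, m) row-sorted ascending; ``n_selected``: (N,) number
    of alpha-selected guides per row.
    """
    n, m = ranks.shape
    k = np.arange(1, m + 1)
    cdf = stats.beta.cdf(ranks, k[None, :], (m - k + 1)[None, :])
    mask = k[None, :] <= n_selected[:, None]
    vals = np.where(mask, cdf, np.inf)
    rho = vals.min(axis=1)
    rho[n_selected == 0] = 1.0
    return np.minimum(rho, 1.0)


def _sample_distinct(
    rng: np.random.Generator, n: int, m: int, size: int
) -> np.ndarray:
    """(size, m) index rows sampled without replacement from range(n)."""
    idx = rng.integers(0, n, size=(size, m))
    if m > 1:
        while True:
            srt = np.sort(idx, axis=1)
            dup = (srt[:, 1:] == srt[:, :-1]).any(axis=1)
            if not dup.any():
                break
            idx[dup] = rng.integers(0, n, size=(int(dup.sum()), m))
    return idx


_EXHAUSTIVE_LIMIT = 500_000


def gene_rra(
    scores: pd.DataFrame,
    library: SgRNALibrary,
    config: RraConfig | None = None,
    exhaustive: bool = False,
) -> pd.DataFrame:
    """Aggregate per-guide ranks into per-gene rho statistics with
    permutation p-values and BH FDR, separately per direction.

    With ``exhaustive=True`` the permutation null enumerates every
    combination of m guides from the pool (small pools only) and the
    p-value is the exact fraction of null rho values <= the observed.

    Returns columns ``gene, n_guides, pos_score, pos_p, pos_fdr,
    pos_good, neg_score, neg_p, neg_fdr, neg_good``.
    """
    config = config or RraConfig()
    rng = np.random.default_rng(config.seed)
    targeting = scores[scores["gene"] != CONTROL]
    genes = sorted(targeting["gene"].unique())
    if not genes:
        return pd.DataFrame(
            columns=[
                "gene", "n_guides",
                "pos_score", "pos_p", "pos_fdr", "pos_good",
                "neg_score", "neg_p", "neg_fdr", "neg_good",
            ]
        )
    out = pd.DataFrame({"gene": genes}).set_index("gene")
    for direction in ("pos", "neg"):
        rank_col, p_col = f"{direction}_rank", f"{direction}_p"
        pool_ranks = scores[rank_col].to_numpy()
        pool_pvals = scores[p_col].to_numpy()
        n_pool = pool_ranks.size

        grouped = targeting.groupby("gene")
        gene_names = []
        by_m: dict[int, list] = {}
        for gene, sub in grouped:
            r = np.sort(sub[rank_col].to_numpy())
            s = int((sub[p_col].to_numpy() < config.alpha).sum())
            by_m.setdefault(len(r), []).append((gene, r, s))

        rho_map, p_map, good_map, m_map = {}, {}, {}, {}
        for m, items in by_m.items():
            ranks = np.vstack([r for _, r, _ in items])
            sel = np.array([s for _, _, s in items])
            rho_obs = _rho(ranks, sel)
            null = _null_distribution(
                pool_ranks, pool_pvals, m, config, rng, exhaustive
            )
            n_null = null.size
            counts = np.searchsorted(null, rho_obs, side="right")
            if exhaustive:
                pvals = counts / n_null
            else:
                pvals = (1.0 + counts) / (1.0 + n_null)
            for (gene, _, s), rho_g, p_g in zip(items, rho_obs, pvals):
                rho_map[gene] = rho_g
                p_map[gene] = p_g
                good_map[gene] = s
                m_map[gene] = m

        out[f"{direction}_score"] = pd.Series(rho_map)
        out[f"{direction}_p"] = pd.Series(p_map)
        out[f"{direction}_good"] = pd.Series(good_map)
        out["n_guides"] = pd.Series(m_map)
        out[f"{direction}_fdr"] = stats.false_discovery_control(
            out[f"{direction}_p"].to_numpy(), method="bh"
        )
    out = out.reset_index()
    return out[
        [
            "gene", "n_guides",
            "pos_score", "pos_p", "pos_fdr", "pos_good",
            "neg_score", "neg_p", "neg_fdr", "neg_good",
        ]
    ]


def _null_distribution(
    pool_ranks: np.ndarray,
    pool_pvals: np.ndarray,
    m: int,
    config: RraConfig,
    rng: np.random.Generator,
    exhaustive: bool,
) -> np.ndarray:
    """Sorted null rho values for genes with m guides."""
    n_pool = pool_ranks.size
    if exhaustive:
        if comb(n_pool, m) > _EXHAUSTIVE_LIMIT:
            raise ValueError(
                f"exhaustive enumeration infeasible: C({n_pool},{m}) combinations"
            )
        idx = np.array(list(combinations(range(n_pool), m)))
    else:
        idx = _sample_distinct(rng, n_pool, m, config.n_permutations)
    ranks = np.sort(pool_ranks[idx], axis=1)
    sel = (pool_pvals[idx] < config.alpha).sum(axis=1)
    return np.sort(_rho(ranks, sel))


# ---------------------------------------------------------------------------
# export

_EXPORT_COLS = [
    "gene",
    "pos.score",
    "neg.score",
    "pos.fdr",
    "neg.fdr",
    "pos.goodsgrna",
    "neg.goodsgrna",
]


def export_scores(gene_scores: pd.DataFrame, path: str | Path) -> None:
    """Write the gene score table as TSV, sorted by min(pos, neg) score."""
    df = gene_scores.rename(
        columns={
            "pos_score": "pos.score",
            "neg_score": "neg.score",
            "pos_fdr": "pos.fdr",
            "neg_fdr": "neg.fdr",
            "pos_good": "pos.goodsgrna",
            "neg_good": "neg.goodsgrna",
        }
    )
    if len(df):
        df = df.iloc[
            np.argsort(np.minimum(df["pos.score"], df["neg.score"]), kind="stable")
        ]
    df[_EXPORT_COLS].to_csv(path, sep="\t", index=False)


def read_scores(path: str | Path) -> pd.DataFrame:
    """Read a TSV written by :func:`export_scores` back into the internal
    column naming."""
    df = pd.read_csv(path, sep="\t")
    return df.rename(
        columns={
            "pos.score": "pos_score",
            "neg.score": "neg_score",
            "pos.fdr": "pos_fdr",
            "neg.fdr": "neg_fdr",
            "pos.goodsgrna": "pos_good",
            "neg.goodsgrna": "neg_good",
        }
    )
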