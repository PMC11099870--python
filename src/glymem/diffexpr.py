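"""Count normalization, NB Wald differential expression, and over-representation.

The differential test is a deliberately transparent negative-binomial
moment/Wald procedure: median-of-ratios size factors, a pooled moment
estimate of the NB dispersion (variance = mu + alpha * mu^2), a pseudo-count
log2 fold change, and a two-sided normal Wald p-value with BH adjustment.
A gene is called differential at adjusted p < 0.05 and |log2FC| > 0.5
(strict inequalities).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

#: default call thresholds
PADJ_CUTOFF = 0.05
LFC_CUTOFF = 0.5
#: pseudo-count in the fold-change so log2FC stays bounded for zero groups
PSEUDOCOUNT = 0.5

LN2 = np.log(2.0)


@dataclass
class CountMatrix:
    """Integer counts, features x samples, with a condition label per sample.

    ``counts`` rows are features, columns are samples; ``conditions`` maps
    each sample id to its condition label; ``replicates`` gives the replicate
    index within the condition (defaults to order of appearance).
    """

    counts: pd.DataFrame
    conditions: pd.Series
    replicates: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if not self.counts.index.is_unique:
            raise ValueError("feature ids must be unique")
        self.conditions = pd.Series(self.conditions)
        missing = [s for s in self.counts.columns if s not in self.conditions.index]
        if missing:
            raise ValueError(f"samples without a condition label: {missing}")
        self.conditions = self.conditions.loc[self.counts.columns]
        if self.replicates is None:
            rep = self.conditions.groupby(self.conditions).cumcount() + 1
            self.replicates = rep
        self.replicates = pd.Series(self.replicates).loc[self.counts.columns]

    @property
    def features(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    def subset_conditions(self, labels: list[str]) -> "CountMatrix":
        keep = self.conditions.isin(labels)
        cols = self.counts.columns[keep.to_numpy()]
        return CountMatrix(self.counts[cols], self.conditions.loc[cols],
                           self.replicates.loc[cols])


def estimate_size_factors(counts: CountMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    For each feature with all-positive counts, form the ratio of each
    sample's count to the feature's geometric mean across samples; a
    sample's factor is the median of its ratios. Raises if no feature has
    all-positive counts (no silent pseudo-reference fallback).
    """
    mat = counts.counts if isinstance(counts, CountMatrix) else counts
    arr = mat.to_numpy(dtype=float)
    eligible = (arr > 0).all(axis=1)
    if not eligible.any():
        raise ValueError(
            "no feature with all-positive counts: cannot form the "
            "median-of-ratios reference; filter samples or supply factors"
        )
    sub = arr[eligible]
    log_geomean = np.mean(np.log(sub), axis=1, keepdims=True)
    ratios = sub / np.exp(log_geomean)
    factors = np.median(ratios, axis=0)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=mat.columns, name="size_factor")


def pooled_dispersion(y_a: np.ndarray, y_b: np.ndarray) -> float:
    """Pooled NB dispersion alpha with Var = mu + alpha * mu^2 (moment fit).

    Per feature: pooled within-group variance (n_A + n_B - 2 df) and the
    mean of normalized counts give alpha_g = (v - ybar) / ybar^2; the global
    estimate is the mean over features of max(0, alpha_g). The mean (rather
    than a quantile) of the per-feature moment statistic keeps the Wald test
    calibrated at small replicate numbers, where quantiles of the skewed
    per-feature sampling distribution sit well below the target.
    """
    n_a, n_b = y_a.shape[1], y_b.shape[1]
    if n_a < 2 or n_b < 2:
        raise ValueError("need >= 2 replicates per group to estimate dispersion")
    ss = (y_a.var(axis=1, ddof=1) * (n_a - 1) + y_b.var(axis=1, ddof=1) * (n_b - 1))
    v = ss / (n_a + n_b - 2)
    ybar = np.concatenate([y_a, y_b], axis=1).mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_g = (v - ybar) / ybar**2
    alpha_g = np.where(np.isfinite(alpha_g), alpha_g, 0.0)
    usable = ybar > 0
    if not usable.any():
        return 0.0
    return float(np.mean(np.maximum(0.0, alpha_g[usable])))


def nb_wald_contrast(
    counts: CountMatrix,
    reference: str,
    treatment: str,
    padj_cutoff: float = PADJ_CUTOFF,
    lfc_cutoff: float = LFC_CUTOFF,
) -> pd.DataFrame:
    """Differential test of ``treatment`` over ``reference``.

    Counts are normalized by size factors estimated within the two groups'
    samples. log2FC = log2((mu_B + 0.5) / (mu_A + 0.5)); the Wald statistic
    uses the delta-method standard error
    SE^2 = (1/ln2)^2 * [(1/mu_A + alpha)/n_A + (1/mu_B + alpha)/n_B]
    with group means floored at the pseudo-count. Features with zero counts
    in every sample get p = 1, log2FC = 0 and are excluded from the BH
    adjustment (their padj is reported as 1).

    Returns a DataFrame indexed by feature with columns ``baseMeanA``,
    ``baseMeanB``, ``log2FC``, ``p``, ``padj``, ``is_deg``, ``direction``.
    """
    for label in (reference, treatment):
        if (counts.conditions == label).sum() == 0:
            raise ValueError(f"condition {label!r} has no samples")
    sub = counts.subset_conditions([reference, treatment])
    factors = estimate_size_factors(sub)
    y = sub.counts.to_numpy(dtype=float) / factors.to_numpy()
    in_a = (sub.conditions == reference).to_numpy()
    in_b = (sub.conditions == treatment).to_numpy()
    y_a, y_b = y[:, in_a], y[:, in_b]
    n_a, n_b = int(in_a.sum()), int(in_b.sum())

    mu_a = y_a.mean(axis=1)
    mu_b = y_b.mean(axis=1)
    lfc = np.log2((mu_b + PSEUDOCOUNT) / (mu_a + PSEUDOCOUNT))

    alpha = pooled_dispersion(y_a, y_b)
    mu_a_f = np.maximum(mu_a, PSEUDOCOUNT)
    mu_b_f = np.maximum(mu_b, PSEUDOCOUNT)
    se2 = (1.0 / LN2) ** 2 * ((1.0 / mu_a_f + alpha) / n_a
                              + (1.0 / mu_b_f + alpha) / n_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = lfc / np.sqrt(se2)
    p = 2.0 * stats.norm.sf(np.abs(z))

    all_zero = sub.counts.sum(axis=1).to_numpy() == 0
    p = np.where(all_zero, 1.0, p)
    lfc = np.where(all_zero, 0.0, lfc)

    padj = np.ones_like(p)
    tested = ~all_zero
    if tested.any():
        padj[tested] = multipletests(p[tested], method="fdr_bh")[1]

    is_deg = (padj < padj_cutoff) & (np.abs(lfc) > lfc_cutoff)
    direction = np.where(~is_deg, "none", np.where(lfc > 0, "up", "down"))

    return pd.DataFrame(
        {
            "baseMeanA": mu_a,
            "baseMeanB": mu_b,
            "log2FC": lfc,
            "p": p,
            "padj": padj,
            "is_deg": is_deg,
            "direction": direction,
        },
        index=sub.counts.index.rename("feature_id"),
    )


def deg_set(result: pd.DataFrame, direction: str | None = None) -> set[str]:
    """Feature ids called differential, optionally restricted to a direction."""
    mask = result["is_deg"]
    if direction is not None:
        mask = mask & (result["direction"] == direction)
    return set(result.index[mask])


def overrepresentation_test(
    query: set[str],
    universe: set[str],
    gene_sets: dict[str, set[str]],
    p_cutoff: float = 0.05,
) -> pd.DataFrame:
    """One-sided Fisher exact (hypergeometric upper tail) per gene set.

    Each gene set is intersected with the universe before testing; the
    2x2 table is (in query / not) x (in set / not). ``enriched`` uses the
    raw-p cutoff (default 0.05); BH-adjusted p is also reported.
    """
    if not universe:
        raise ValueError("empty universe")
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    rows = []
    for name in sorted(gene_sets):
        members = gene_sets[name] & universe
        k = len(query & members)
        n_universe, n_set, n_query = len(universe), len(members), len(query)
        # P(X >= k) for X ~ Hypergeom(N, K, n)
        p = float(stats.hypergeom.sf(k - 1, n_universe, n_set, n_query))
        rows.append((name, n_set, k, p))
    df = pd.DataFrame(rows, columns=["gene_set", "set_size", "overlap", "p"]
                      ).set_index("gene_set")
    if len(df):
        df["padj"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    else:
        df["padj"] = []
    df["enriched"] = df["p"] < p_cutoff
    return df
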