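"""Consensus peaks and the Poisson differential-accessibility test.

Replicate peak sets are reduced to a consensus (peaks reproducible in every
replicate); region tag counts are pooled within condition, normalized to
tags per 10 million, and compared with an exact Poisson tail test. A region
is a differentially accessible region (DAR) at fold change > 1.5 (either
direction) and Poisson tail p < 1e-4.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import CountMatrix
from .intervals import GenomicInterval, build_trees

logger = logging.getLogger(__name__)

FOLD_CUTOFF = 1.5
POISSON_P_CUTOFF = 1e-4
#: normalization scale: tags per 10 million
NORM_SCALE = 1e7
#: floor on the normalized reference rate, avoids a zero-lambda tail
LAMBDA_FLOOR = 1.0


@dataclass
class RegionCounts:
    """Per-region tag counts with genomic coordinates.

    ``regions`` maps region id -> interval; ``counts`` is a CountMatrix
    indexed by the same ids. Regions must be non-overlapping within the
    table (one tag pile-up belongs to one region).
    """

    regions: dict[str, GenomicInterval]
    counts: CountMatrix

    def __post_init__(self) -> None:
        missing = [fid for fid in self.counts.features if fid not in self.regions]
        if missing:
            raise ValueError(f"regions missing coordinates: {missing[:5]} ...")
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for iv in self.regions.values():
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            for (s1, e1), (s2, _e2) in zip(ivs, ivs[1:]):
                if s2 < e1:
                    raise ValueError(f"overlapping regions on {chrom}: "
                                     f"[{s1},{e1}) and [{s2},...)")


def consensus_peaks(
    replicate_peaks: list[list[GenomicInterval]],
) -> list[GenomicInterval]:
    """Peaks reproducible across all replicates of one condition.

    A peak from the first replicate is retained iff it overlaps (>= 1 bp)
    at least one peak in every other replicate; the retained interval is
    the merged span of the seed peak and all its overlapping partners.
    Overlapping consensus spans are merged afterwards so the result is a
    non-overlapping set.
    """
    if len(replicate_peaks) < 2:
        raise ValueError("need >= 2 replicate peak sets")
    if any(len(peaks) == 0 for peaks in replicate_peaks):
        logger.warning("empty replicate peak set: consensus is empty")
        return []
    other_trees = [build_trees(peaks) for peaks in replicate_peaks[1:]]
    spans: list[tuple[str, int, int]] = []
    for seed in replicate_peaks[0]:
        lo, hi = seed.start, seed.end
        ok = True
        for trees in other_trees:
            tree = trees.get(seed.chrom)
            hits = tree.overlap(seed.start, seed.end) if tree is not None else set()
            if not hits:
                ok = False
                break
            lo = min(lo, min(h.begin for h in hits))
            hi = max(hi, max(h.end for h in hits))
        if ok:
            spans.append((seed.chrom, lo, hi))
    return _merge_spans(spans)


def _merge_spans(spans: list[tuple[str, int, int]]) -> list[GenomicInterval]:
    merged: list[GenomicInterval] = []
    for chrom in sorted({c for c, _, _ in spans}):
        ivs = sorted((s, e) for c, s, e in spans if c == chrom)
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                merged.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        merged.append(GenomicInterval(chrom, cur_s, cur_e))
    return merged


def poisson_differential(
    regions: RegionCounts,
    reference: str,
    treatment: str,
    fold_cutoff: float = FOLD_CUTOFF,
    p_cutoff: float = POISSON_P_CUTOFF,
) -> pd.DataFrame:
    """Poisson differential-accessibility test, treatment versus reference.

    Replicates are pooled within each condition; pooled counts are scaled
    to tags per 10 million using the condition's pooled library total. With
    normalized counts floored at 1.0 tag, fold = treat / ref, the
    more-accessible tail is P(X >= ceil(treat) | lambda = ref) and the
    less-accessible tail swaps the roles. A region is a DAR iff its fold
    passes the cutoff in one direction and that direction's exact tail
    probability is below ``p_cutoff``.

    Returns a DataFrame indexed by region id with columns ``norm_ref``,
    ``norm_treat``, ``fold``, ``p``, ``is_dar``, ``direction``
    (``more_accessible`` / ``less_accessible`` / ``none``).
    """
    cm = regions.counts
    pooled = {}
    for label in (reference, treatment):
        cols = cm.samples[(cm.conditions == label).to_numpy()]
        if len(cols) == 0:
            raise ValueError(f"condition {label!r} has no replicates")
        pooled[label] = cm.counts[cols].sum(axis=1).to_numpy(dtype=float)
        total = pooled[label].sum()
        if total == 0:
            raise ValueError(f"zero total library count in condition {label!r}")
        pooled[label] *= NORM_SCALE / total

    norm_ref = np.maximum(pooled[reference], LAMBDA_FLOOR)
    norm_treat = np.maximum(pooled[treatment], LAMBDA_FLOOR)
    fold = norm_treat / norm_ref

    p_up = poisson_upper_tail(norm_treat, norm_ref)
    p_down = poisson_upper_tail(norm_ref, norm_treat)
    p = np.where(fold >= 1.0, p_up, p_down)

    more = (fold > fold_cutoff) & (p_up < p_cutoff)
    less = (fold < 1.0 / fold_cutoff) & (p_down < p_cutoff)
    is_dar = more | less
    direction = np.where(more, "more_accessible",
                         np.where(less, "less_accessible", "none"))

    return pd.DataFrame(
        {
            "norm_ref": pooled[reference],
            "norm_treat": pooled[treatment],
            "fold": fold,
            "p": p,
            "is_dar": is_dar,
            "direction": direction,
        },
        index=cm.features.rename("region_id"),
    )


def poisson_upper_tail(observed: np.ndarray | float,
                       lam: np.ndarray | float) -> np.ndarray:
    """Exact Poisson tail P(X >= ceil(observed) | lam).

    The observed normalized count is ceiled to the integer support;
    P(X >= 0) = 1 by convention.
    """
    k = np.ceil(np.asarray(observed, dtype=float))
    return np.asarray(stats.poisson.sf(k - 1.0, np.asarray(lam, dtype=float)))


def dar_intervals(result: pd.DataFrame,
                  regions: dict[str, GenomicInterval]) -> list[GenomicInterval]:
    """DARs as intervals carrying their direction in ``name`` metadata."""
    out = []
    for rid in result.index[result["is_dar"]]:
        iv = regions[rid]
        out.append(GenomicInterval(iv.chrom, iv.start, iv.end,
                                   name=f"{rid}|{result.at[rid, 'direction']}",
                                   score=float(result.at[rid, 'fold']),
                                   strand="."))
    return out
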