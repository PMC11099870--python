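"""TAD-constrained enhancer-to-gene assignment and direction concordance.

Topologically associating domains (TADs) delimit the candidate regulatory
domain of each differentially accessible enhancer (DAE): only differential
genes whose TSS lies in the same TAD as the enhancer are considered
candidate targets. A DAE-gene link is concordant when the accessibility
change and the expression change share a sign.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from intervaltree import IntervalTree

from .intervals import GeneModel, GenomicInterval
from .report import int_percent


@dataclass(frozen=True)
class TadDomain:
    domain_id: str
    interval: GenomicInterval


def validate_tads(tads: Sequence[TadDomain]) -> None:
    """Raise if two domains on one chromosome overlap."""
    by_chrom: dict[str, list[TadDomain]] = {}
    for t in tads:
        by_chrom.setdefault(t.interval.chrom, []).append(t)
    for chrom, ts in by_chrom.items():
        ts.sort(key=lambda t: t.interval.start)
        for a, b in zip(ts, ts[1:]):
            if b.interval.start < a.interval.end:
                raise ValueError(f"overlapping TADs on {chrom}: "
                                 f"{a.domain_id}, {b.domain_id}")


def _tad_trees(tads: Sequence[TadDomain]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for t in tads:
        trees.setdefault(t.interval.chrom, IntervalTree()
                         ).addi(t.interval.start, t.interval.end, t)
    return trees


def assign_tad(
    feature: GenomicInterval | tuple[str, int],
    tads: Sequence[TadDomain],
    _trees: dict[str, IntervalTree] | None = None,
) -> TadDomain | None:
    """The TAD containing the feature's midpoint (half-open), or None.

    An interval is assigned by its midpoint; a point feature may be passed
    as ``(chrom, position)``. TADs must be non-overlapping, so at most one
    domain contains any point.
    """
    if isinstance(feature, GenomicInterval):
        chrom, point = feature.chrom, feature.midpoint
    else:
        chrom, point = feature
    trees = _trees if _trees is not None else _tad_trees(tads)
    tree = trees.get(chrom)
    if tree is None:
        return None
    hits = tree.at(point)
    if not hits:
        return None
    return next(iter(hits)).data


@dataclass(frozen=True)
class EnhancerGeneLink:
    dae_id: str
    dae: GenomicInterval
    acc_direction: str  # more_accessible | less_accessible
    gene_id: str
    log2fc: float
    deg_direction: str  # up | down
    tad_id: str

    @property
    def concordant(self) -> bool:
        """Accessibility and expression change share a sign."""
        acc_up = self.acc_direction == "more_accessible"
        expr_up = self.deg_direction == "up"
        return acc_up == expr_up


def link_daes_to_degs(
    daes: Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
    deg_table: pd.DataFrame,
    tads: Sequence[TadDomain],
    deg_filter: set[str] | None = None,
) -> list[EnhancerGeneLink]:
    """All DAE-gene candidate links inside shared TADs.

    ``daes`` carry ``<region_id>|<direction>`` in their name (as produced by
    the accessibility stage). ``deg_table`` is a contrast result indexed by
    gene id with ``log2FC``/``direction``/``is_deg``; ``deg_filter`` further
    restricts the candidate gene set (e.g., to genes differential in both the
    high-glucose and memory arms). A DAE whose TAD holds no candidate gene
    yields no links but still counts in the DAE total.
    """
    validate_tads(tads)
    trees = _tad_trees(tads)
    candidates = set(deg_table.index[deg_table["is_deg"]])
    if deg_filter is not None:
        candidates &= deg_filter

    genes_by_tad: dict[str, list[GeneModel]] = {}
    for g in genes:
        if g.gene_id not in candidates:
            continue
        tad = assign_tad((g.chrom, g.tss), tads, _trees=trees)
        if tad is not None:
            genes_by_tad.setdefault(tad.domain_id, []).append(g)

    links: list[EnhancerGeneLink] = []
    for dae in daes:
        dae_id, _, acc_dir = dae.name.partition("|")
        tad = assign_tad(dae, tads, _trees=trees)
        if tad is None:
            continue
        for g in genes_by_tad.get(tad.domain_id, []):
            links.append(EnhancerGeneLink(
                dae_id=dae_id,
                dae=dae,
                acc_direction=acc_dir,
                gene_id=g.gene_id,
                log2fc=float(deg_table.at[g.gene_id, "log2FC"]),
                deg_direction=str(deg_table.at[g.gene_id, "direction"]),
                tad_id=tad.domain_id,
            ))
    return links


def concordance_summary(links: Sequence[EnhancerGeneLink]) -> dict:
    """Per-DAE concordance: a DAE with >= 1 candidate target is concordant
    if any of its links is concordant; the percentage is over DAEs with at
    least one target (integer, round half away from zero; None if no DAE
    has a target)."""
    by_dae: dict[str, bool] = {}
    for link in links:
        by_dae[link.dae_id] = by_dae.get(link.dae_id, False) or link.concordant
    n_with_target = len(by_dae)
    n_concordant = sum(by_dae.values())
    return {
        "n_daes_with_target": n_with_target,
        "n_concordant": n_concordant,
        "percent_concordant": int_percent(n_concordant, n_with_target),
    }


def links_table(links: Sequence[EnhancerGeneLink]) -> pd.DataFrame:
    rows = [
        (l.dae_id, l.gene_id, l.tad_id, l.acc_direction, l.log2fc,
         l.deg_direction, l.concordant)
        for l in links
    ]
    return pd.DataFrame(rows, columns=["dae_id", "gene_id", "tad_id",
                                       "acc_direction", "log2FC",
                                       "deg_direction", "concordant"])
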