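"""End-to-end orchestration of the memory analysis on a synthetic study.

Stage order: differential expression -> differential accessibility ->
consensus peaks / annotation -> enhancer (DAE) calling -> TAD linkage ->
set algebra and restoration -> motif enrichment -> report. Each stage is
also callable on its own through the library (or the CLI subcommands).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .accessibility import (FOLD_CUTOFF, POISSON_P_CUTOFF, consensus_peaks,
                            dar_intervals, poisson_differential)
from .diffexpr import (LFC_CUTOFF, PADJ_CUTOFF, deg_set, nb_wald_contrast,
                       overrepresentation_test)
from .intervals import annotate_regions, annotation_counts, call_daes
from .linkage import concordance_summary, link_daes_to_degs, links_table
from .motifs import DEFAULT_THRESHOLD_FRAC, extract_windows, motif_enrichment
from .report import (build_report, dar_direction_summary, restoration,
                     set_algebra)
from .simulate import SyntheticStudy

logger = logging.getLogger(__name__)

EXPRESSION_CONTRASTS = ("HG", "memory", "memory_SF", "HG_SF", "OE_HG", "OE_memory")
ACCESSIBILITY_CONTRASTS = ("HG", "memory", "memory_SF")


@dataclass
class RunConfig:
    """Thresholds, mode flags and seed for one pipeline run."""

    padj_cutoff: float = PADJ_CUTOFF
    lfc_cutoff: float = LFC_CUTOFF
    fold_cutoff: float = FOLD_CUTOFF
    poisson_p_cutoff: float = POISSON_P_CUTOFF
    ora_p_cutoff: float = 0.05
    motif_threshold_frac: float = DEFAULT_THRESHOLD_FRAC
    reference: str = "control"
    expression_contrasts: tuple[str, ...] = EXPRESSION_CONTRASTS
    accessibility_contrasts: tuple[str, ...] = ACCESSIBILITY_CONTRASTS
    #: "intersection" keeps genes differential in both HG and memory
    deg_filter: str = "intersection"
    #: require the intervention contrast to keep the baseline direction
    direction_aware_restoration: bool = False
    strict: bool = True
    run_motifs: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("padj_cutoff", "lfc_cutoff", "fold_cutoff",
                     "poisson_p_cutoff", "ora_p_cutoff", "motif_threshold_frac"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.deg_filter not in {"intersection", "union"}:
            raise ValueError("deg_filter must be 'intersection' or 'union'")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["expression_contrasts"] = list(self.expression_contrasts)
        d["accessibility_contrasts"] = list(self.accessibility_contrasts)
        return d


@dataclass
class PipelineResult:
    report: dict
    de_tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    da_tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    links: dict[str, pd.DataFrame] = field(default_factory=dict)
    motif_tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    ora_table: pd.DataFrame | None = None


def _restoration_sets(de_tables: dict[str, pd.DataFrame], baseline: str,
                      intervention: str, direction_aware: bool) -> dict:
    base = deg_set(de_tables[baseline])
    inter = deg_set(de_tables[intervention])
    if direction_aware:
        bdir = de_tables[baseline]["direction"]
        idir = de_tables[intervention]["direction"]
        inter = {g for g in inter if g in base and idir[g] == bdir[g]}
    return restoration(base, inter)


def run_pipeline(study: SyntheticStudy, config: RunConfig | None = None
                 ) -> PipelineResult:
    """Run every analysis stage on a study and assemble the report.

    Validates contrast labels up front; with ``strict`` (default) any stage
    failure aborts with the failing stage named, otherwise the section is
    marked absent in the report.
    """
    config = RunConfig() if config is None else config
    known_expr = set(study.expression.conditions)
    known_acc = set(study.accessibility.counts.conditions)
    unknown = ([c for c in config.expression_contrasts if c not in known_expr]
               + [c for c in config.accessibility_contrasts if c not in known_acc])
    if config.reference not in known_expr or unknown:
        raise ValueError(f"unknown condition labels in config: "
                         f"{unknown or [config.reference]}")

    result = PipelineResult(report={})
    sections: dict[str, dict | None] = {"expression": None, "accessibility": None,
                                        "linkage": None, "motifs": None}

    def run_stage(name, fn):
        try:
            sections[name] = fn()
        except Exception:
            if config.strict:
                logger.error("stage %s failed in strict mode", name)
                raise
            logger.warning("stage %s failed; section marked absent", name)

    # ---- expression ------------------------------------------------
    def expression_stage() -> dict:
        for label in config.expression_contrasts:
            result.de_tables[label] = nb_wald_contrast(
                study.expression, config.reference, label,
                padj_cutoff=config.padj_cutoff, lfc_cutoff=config.lfc_cutoff)
        hg, mem = deg_set(result.de_tables["HG"]), deg_set(result.de_tables["memory"])
        shared = set_algebra(hg, mem)
        hg_dir = result.de_tables["HG"]["direction"]
        mem_dir = result.de_tables["memory"]["direction"]
        same_dir = {g for g in shared["shared"] if hg_dir[g] == mem_dir[g]}
        section = {
            "contrasts": {
                label: {
                    "n_deg": int(result.de_tables[label]["is_deg"].sum()),
                    "n_up": int((result.de_tables[label]["direction"] == "up").sum()),
                    "n_down": int((result.de_tables[label]["direction"] == "down").sum()),
                } for label in config.expression_contrasts
            },
            "shared_hg_memory": shared,
            "n_shared_same_direction": len(same_dir),
            "restoration": {
                "sf_on_memory": _restoration_sets(
                    result.de_tables, "memory", "memory_SF",
                    config.direction_aware_restoration),
                "sf_on_hg": _restoration_sets(
                    result.de_tables, "HG", "HG_SF",
                    config.direction_aware_restoration),
                "oe_on_memory": _restoration_sets(
                    result.de_tables, "memory", "OE_memory",
                    config.direction_aware_restoration),
                "oe_on_hg": _restoration_sets(
                    result.de_tables, "HG", "OE_HG",
                    config.direction_aware_restoration),
            },
        }
        if study.gene_sets:
            universe = set(study.expression.features)
            result.ora_table = overrepresentation_test(
                hg, universe, study.gene_sets, p_cutoff=config.ora_p_cutoff)
            top = result.ora_table.sort_values("p").head(1)
            section["ora_top_set"] = str(top.index[0]) if len(top) else None
            section["n_enriched_sets"] = int(result.ora_table["enriched"].sum())
        return section

    run_stage("expression", expression_stage)

    # ---- accessibility ---------------------------------------------
    def accessibility_stage() -> dict:
        for label in config.accessibility_contrasts:
            result.da_tables[label] = poisson_differential(
                study.accessibility, config.reference, label,
                fold_cutoff=config.fold_cutoff, p_cutoff=config.poisson_p_cutoff)
        consensus = {cond: consensus_peaks(reps)
                     for cond, reps in study.replicate_peaks.items()}
        hg_dars = dar_intervals(result.da_tables["HG"], study.accessibility.regions)
        annot = annotate_regions(hg_dars, study.genes)
        dar_sets = {
            label: set(result.da_tables[label].index[result.da_tables[label]["is_dar"]])
            for label in config.accessibility_contrasts
        }
        return {
            "direction": {label: dar_direction_summary(result.da_tables[label])
                          for label in config.accessibility_contrasts},
            "consensus_peak_counts": {cond: len(p) for cond, p in consensus.items()},
            "hg_dar_annotation": annotation_counts(annot),
            "dar_restoration": {
                "sf_on_memory": restoration(dar_sets["memory"],
                                            dar_sets["memory_SF"]),
            },
        }

    run_stage("accessibility", accessibility_stage)

    # ---- linkage ----------------------------------------------------
    def linkage_stage() -> dict:
        hg = deg_set(result.de_tables["HG"])
        mem = deg_set(result.de_tables["memory"])
        deg_filter = hg & mem if config.deg_filter == "intersection" else hg | mem
        out: dict = {"deg_filter": config.deg_filter,
                     "n_deg_filter": len(deg_filter)}
        for label in ("HG", "memory"):
            dars = dar_intervals(result.da_tables[label],
                                 study.accessibility.regions)
            daes = call_daes(dars, study.k4me1, study.k27ac)
            links = link_daes_to_degs(
                daes, study.genes, result.de_tables[label], study.tads,
                deg_filter=deg_filter)
            result.links[label] = links_table(links)
            out[label] = {"n_dar": len(dars), "n_dae": len(daes),
                          "n_links": len(links),
                          **concordance_summary(links)}
        return out

    run_stage("linkage", linkage_stage)

    # ---- motifs ------------------------------------------------------
    def motif_stage() -> dict | None:
        if not config.run_motifs or not study.genome:
            return None
        rng = np.random.default_rng(config.seed)
        hg_tab, mem_tab = result.de_tables["HG"], result.de_tables["memory"]
        down_shared = (deg_set(hg_tab, "down") & deg_set(mem_tab, "down"))
        down_genes = [g for g in study.genes if g.gene_id in down_shared]
        out: dict = {}
        promoters = extract_windows("promoter", down_genes, study.genome)
        if promoters:
            enr = motif_enrichment(promoters, None, study.pwms,
                                   threshold_frac=config.motif_threshold_frac,
                                   rng=rng)
            result.motif_tables["promoter_down_shared"] = enr
            out["promoter_down_shared"] = _motif_summary(enr)
        daes = call_daes(
            dar_intervals(result.da_tables["HG"], study.accessibility.regions)
            + dar_intervals(result.da_tables["memory"],
                            study.accessibility.regions),
            study.k4me1, study.k27ac)
        seen, uniq = set(), []
        for d in daes:
            if d.name not in seen:
                seen.add(d.name)
                uniq.append(d)
        windows = extract_windows("dae_center", uniq, study.genome)
        if windows:
            enr = motif_enrichment(windows, None, study.pwms,
                                   threshold_frac=config.motif_threshold_frac,
                                   rng=rng)
            result.motif_tables["dae_centers"] = enr
            out["dae_centers"] = _motif_summary(enr)
        return out or None

    run_stage("motifs", motif_stage)

    result.report = build_report(
        config={"run": config.to_dict(), "study": study.config.to_dict()},
        expression=sections["expression"],
        accessibility=sections["accessibility"],
        linkage=sections["linkage"],
        motifs=sections["motifs"],
        strict=False,
    )
    return result


def _motif_summary(enr: pd.DataFrame) -> dict:
    top = enr.index[0]
    return {
        "top_motif": str(top),
        "top_padj": float(enr.at[top, "padj"]),
        "n_significant": int((enr["padj"] < 0.05).sum()),
        "n_targets": int(enr["n_targets"].iloc[0]),
    }
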