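"""Synthetic glucose-memory study generator with known ground truth.

Emulates the design of the experiment this package analyses: HUVEC-style
bulk RNA-seq over seven arms (control, high glucose HG, memory,
memory + sulforaphane, HG + sulforaphane, NRF2-overexpression HG/memory)
and ATAC-style region counts over four arms, on a small synthetic genome
tiled by TADs. Ground truth plants differential-gene classes (HG-unique,
memory-unique, HG/M-shared, sulforaphane-restored, overexpression-restored),
differential-accessibility classes concentrated outside promoters, putative
enhancers co-marked by H3K4me1/H3K27ac, enhancer-gene pairs sharing a TAD
with concordant directions, and bZIP-core motif occurrences in the
promoters of down-regulated genes and in enhancer centers.

Counts are negative binomial with Var = mu + alpha * mu^2. A fixed seed
makes every artifact byte-identical across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from . import io as gio
from .accessibility import RegionCounts
from .diffexpr import CountMatrix
from .intervals import GeneModel, GenomicInterval, build_trees
from .linkage import TadDomain, assign_tad, _tad_trees
from .motifs import PWM, _IUPAC

EXPRESSION_CONDITIONS = ("control", "HG", "memory", "memory_SF", "HG_SF",
                         "OE_HG", "OE_memory")
ACCESSIBILITY_CONDITIONS = ("control", "HG", "memory", "memory_SF")

DEG_CLASSES = ("shared_deg_up", "shared_deg_down", "hg_unique_deg_up",
               "hg_unique_deg_down", "memory_unique_deg_up",
               "memory_unique_deg_down", "none")
DAR_CLASSES = ("dar_hg_up", "dar_hg_down", "dar_memory_up",
               "dar_sf_restored", "none")


@dataclass
class SyntheticConfig:
    """Study-design parameters of the synthetic experiment.

    Defaults mirror the analysed design: 3 RNA replicates per arm across 7
    arms (21 samples), 2 ATAC replicates per arm, planted effect sizes of
    |log2FC| = 2 for genes and 1 (fold 2) for regions, and near-Poisson
    region counts.
    """

    n_chroms: int = 2
    chrom_length: int = 4_000_000
    n_tads_per_chrom: int = 100
    n_genes: int = 2000
    n_regions: int = 2000
    n_expr_replicates: int = 3
    n_acc_replicates: int = 2

    deg_class_sizes: dict = field(default_factory=lambda: {
        "shared_deg_up": 120, "shared_deg_down": 80,
        "hg_unique_deg_up": 40, "hg_unique_deg_down": 20,
        "memory_unique_deg_up": 30, "memory_unique_deg_down": 20,
    })
    deg_lfc: float = 2.0
    sf_restored_frac: float = 0.5
    oe_restored_frac: float = 0.75

    dar_class_sizes: dict = field(default_factory=lambda: {
        "dar_hg_up": 60, "dar_hg_down": 20,
        "dar_memory_up": 30, "dar_sf_restored": 90,
    })
    dar_lfc: float = 1.0
    enhancer_frac: float = 0.5
    concordant_frac: float = 0.8
    n_chance_comarked: int = 20

    nb_dispersion_expression: float = 0.05
    nb_dispersion_accessibility: float = 0.003
    gene_mean_range: tuple[float, float] = (100.0, 1000.0)
    region_mean_range: tuple[float, float] = (200.0, 600.0)
    size_factor_range: tuple[float, float] = (0.8, 1.25)

    gene_length_range: tuple[int, int] = (1000, 6000)
    region_length: int = 400
    consensus: str = "TGACTCA"
    p_target: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tads_per_chrom < 1:
            raise ValueError("need at least one TAD per chromosome")
        if self.nb_dispersion_expression <= 0 or self.nb_dispersion_accessibility <= 0:
            raise ValueError("NB dispersion must be positive")
        if sum(self.deg_class_sizes.values()) > self.n_genes:
            raise ValueError("planted DEG class sizes exceed n_genes")
        if sum(self.dar_class_sizes.values()) > self.n_regions:
            raise ValueError("planted DAR class sizes exceed n_regions")
        for ch in self.consensus.upper():
            if ch not in _IUPAC:
                raise ValueError(f"consensus character {ch!r} outside ACGT/IUPAC")

    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d


def nb_counts(mean: np.ndarray, dispersion: float,
              rng: np.random.Generator) -> np.ndarray:
    """NB draws with Var = mu + dispersion * mu^2 (gamma-Poisson mixture)."""
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    mean = np.asarray(mean, dtype=float)
    n = 1.0 / dispersion
    p = n / (n + np.maximum(mean, 1e-12))
    out = rng.negative_binomial(n, p)
    return np.where(mean <= 0, 0, out)


# ------------------------------------------------------------------ genome

def simulate_genome(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, list[TadDomain], list[GeneModel], list[GenomicInterval]]:
    """Chromosome table, TAD tiling, gene models, candidate enhancer regions.

    TADs tile each chromosome back-to-back (half-open, no gaps), so every
    TSS and region midpoint falls in exactly one TAD. Candidate enhancer
    regions avoid every promoter window (TSS-1000..TSS+100, strand-aware)
    and do not overlap each other.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    chroms = [f"chr{i + 1}" for i in range(config.n_chroms)]
    chrom_table = pd.DataFrame({"chrom": chroms,
                                "length": [config.chrom_length] * len(chroms)})

    tads: list[TadDomain] = []
    for chrom in chroms:
        bounds = [round(i * config.chrom_length / config.n_tads_per_chrom)
                  for i in range(config.n_tads_per_chrom + 1)]
        for i, (lo, hi) in enumerate(zip(bounds, bounds[1:])):
            tads.append(TadDomain(f"{chrom}_tad{i:03d}",
                                  GenomicInterval(chrom, lo, hi)))

    genes: list[GeneModel] = []
    width = len(str(config.n_genes))
    for g in range(config.n_genes):
        chrom = chroms[int(rng.integers(len(chroms)))]
        length = int(rng.integers(*config.gene_length_range))
        if length + 2 >= config.chrom_length:
            raise ValueError("gene longer than chromosome: increase chrom_length")
        start = int(rng.integers(1, config.chrom_length - length - 1))
        end = start + length
        strand = "+" if rng.random() < 0.5 else "-"
        tss = start if strand == "+" else end - 1
        genes.append(GeneModel(f"gene_{g:0{width}d}", chrom, strand, tss,
                               start, end, exons=_random_exons(start, end, rng)))

    promoter_trees = build_trees([g.promoter_window() for g in genes])
    regions: list[GenomicInterval] = []
    placed = build_trees([])
    rwidth = len(str(config.n_regions))
    for r in range(config.n_regions):
        for attempt in range(3000):
            chrom = chroms[int(rng.integers(len(chroms)))]
            start = int(rng.integers(0, config.chrom_length - config.region_length))
            end = start + config.region_length
            ptree = promoter_trees.get(chrom)
            if ptree is not None and ptree.overlap(start, end):
                continue
            dtree = placed.get(chrom)
            if dtree is not None and dtree.overlap(start, end):
                continue
            iv = GenomicInterval(chrom, start, end, name=f"region_{r:0{rwidth}d}")
            regions.append(iv)
            placed.setdefault(chrom, IntervalTree()).addi(start, end, iv)
            break
        else:
            raise ValueError(
                "infeasible packing: could not place candidate regions outside "
                "promoter windows; increase chrom_length or reduce n_regions/n_genes"
            )
    return chrom_table, tads, genes, regions


def _random_exons(start: int, end: int,
                  rng: np.random.Generator) -> tuple[tuple[int, int], ...]:
    """Short exons (100-300 bp) at random positions, so most of a gene body
    is intronic as in real gene models."""
    n_exons = int(rng.integers(2, 8))
    exons = []
    prev_end = start
    for _ in range(n_exons):
        length = int(rng.integers(100, 301))
        if prev_end + length >= end:
            break
        s = int(rng.integers(prev_end, end - length))
        exons.append((s, s + length))
        prev_end = s + length
    return tuple(exons) if exons else ((start, min(start + 200, end)),)


# ------------------------------------------------------------------ truth

def assign_gene_truth(config: SyntheticConfig, genes: list[GeneModel],
                      rng: np.random.Generator) -> pd.DataFrame:
    """Assign planted DEG classes and restoration flags to genes.

    Returns one row per gene: class label, sf/oe restoration flags, and
    the planted log2FC per expression condition. Labels exactly determine
    the nonzero planted fold changes.
    """
    ids = [g.gene_id for g in genes]
    order = rng.permutation(len(ids))
    truth = pd.DataFrame({"feature_id": ids}).set_index("feature_id")
    truth["class"] = "none"
    truth["sf_restored"] = False
    truth["oe_restored"] = False
    for cond in EXPRESSION_CONDITIONS:
        truth[f"lfc_{cond}"] = 0.0

    pos = 0
    for cls, size in config.deg_class_sizes.items():
        if cls not in DEG_CLASSES:
            raise ValueError(f"unknown DEG class {cls!r}")
        chosen = [ids[i] for i in order[pos:pos + size]]
        pos += size
        lfc = config.deg_lfc if cls.endswith("_up") else -config.deg_lfc
        truth.loc[chosen, "class"] = cls
        n_sf = int(round(config.sf_restored_frac * size))
        n_oe = int(round(config.oe_restored_frac * size))
        truth.loc[chosen[:n_sf], "sf_restored"] = True
        truth.loc[chosen[:n_oe], "oe_restored"] = True

        in_hg = cls.startswith(("shared", "hg_unique"))
        in_mem = cls.startswith(("shared", "memory_unique"))
        if in_hg:
            truth.loc[chosen, "lfc_HG"] = lfc
            keep = ~truth.loc[chosen, "sf_restored"]
            truth.loc[np.array(chosen)[keep.to_numpy()], "lfc_HG_SF"] = lfc
            keep = ~truth.loc[chosen, "oe_restored"]
            truth.loc[np.array(chosen)[keep.to_numpy()], "lfc_OE_HG"] = lfc
        if in_mem:
            truth.loc[chosen, "lfc_memory"] = lfc
            keep = ~truth.loc[chosen, "sf_restored"]
            truth.loc[np.array(chosen)[keep.to_numpy()], "lfc_memory_SF"] = lfc
            keep = ~truth.loc[chosen, "oe_restored"]
            truth.loc[np.array(chosen)[keep.to_numpy()], "lfc_OE_memory"] = lfc
    return truth


def assign_region_truth(config: SyntheticConfig,
                        regions: list[GenomicInterval],
                        tads: list[TadDomain],
                        genes: list[GeneModel],
                        gene_truth: pd.DataFrame,
                        rng: np.random.Generator) -> pd.DataFrame:
    """Assign planted DAR classes, enhancer flags and histone marks.

    Enhancer-flagged planted regions are preferentially drawn from the TAD
    of a same-direction HG/M-shared planted gene (probability
    ``concordant_frac``), wiring in the enhancer-target concordance the
    linkage stage is meant to recover. A small set of unplanted regions is
    chance co-marked by both histone marks.
    """
    truth = pd.DataFrame({"feature_id": [r.name for r in regions]}
                         ).set_index("feature_id")
    truth["class"] = "none"
    truth["is_enhancer"] = False
    truth["has_k4me1"] = False
    truth["has_k27ac"] = False
    for cond in ACCESSIBILITY_CONDITIONS:
        truth[f"lfc_{cond}"] = 0.0

    trees = _tad_trees(tads)
    regions_by_tad: dict[str, list[str]] = {}
    for r in regions:
        tad = assign_tad(r, tads, _trees=trees)
        if tad is not None:
            regions_by_tad.setdefault(tad.domain_id, []).append(r.name)
    shared_genes = {
        "up": [g for g in genes
               if gene_truth.at[g.gene_id, "class"] == "shared_deg_up"],
        "down": [g for g in genes
                 if gene_truth.at[g.gene_id, "class"] == "shared_deg_down"],
    }
    available = {r.name for r in regions}

    def draw_in_tad_of(direction: str) -> str | None:
        pool = shared_genes[direction]
        if not pool:
            return None
        for _ in range(20):
            g = pool[int(rng.integers(len(pool)))]
            tad = assign_tad((g.chrom, g.tss), tads, _trees=trees)
            if tad is None:
                continue
            cands = [rid for rid in regions_by_tad.get(tad.domain_id, [])
                     if rid in available]
            if cands:
                return cands[int(rng.integers(len(cands)))]
        return None

    def draw_any() -> str:
        rid = sorted(available)[int(rng.integers(len(available)))]
        return rid

    for cls, size in config.dar_class_sizes.items():
        if cls not in DAR_CLASSES:
            raise ValueError(f"unknown DAR class {cls!r}")
        direction = "down" if cls == "dar_hg_down" else "up"
        n_enh = int(round(config.enhancer_frac * size))
        for i in range(size):
            rid = None
            if i < n_enh and rng.random() < config.concordant_frac:
                rid = draw_in_tad_of(direction)
            if rid is None:
                rid = draw_any()
            available.discard(rid)
            truth.at[rid, "class"] = cls
            if i < n_enh:
                truth.loc[rid, ["is_enhancer", "has_k4me1", "has_k27ac"]] = True
            lfc = config.dar_lfc if direction == "up" else -config.dar_lfc
            truth.at[rid, "lfc_HG"] = lfc
            if cls in ("dar_memory_up", "dar_sf_restored"):
                truth.at[rid, "lfc_memory"] = lfc
            if cls == "dar_memory_up":
                truth.at[rid, "lfc_memory_SF"] = lfc

    # chance co-marking of unplanted regions plus singly marked regions
    rest = sorted(available)
    picks = rng.permutation(len(rest))
    n_cm = min(config.n_chance_comarked, len(rest))
    for i in picks[:n_cm]:
        truth.loc[rest[i], ["has_k4me1", "has_k27ac"]] = True
    for i in picks[n_cm:n_cm + n_cm]:
        truth.at[rest[i], "has_k4me1"] = True
    for i in picks[2 * n_cm:3 * n_cm]:
        truth.at[rest[i], "has_k27ac"] = True
    return truth


# ------------------------------------------------------------------ counts

def simulate_expression_counts(
    config: SyntheticConfig, genes: list[GeneModel], truth: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[CountMatrix, pd.DataFrame]:
    """NB gene counts for every expression arm and replicate.

    Counts for gene g in condition c, replicate r are
    NB(mean = s_r * mu_g * 2^lfc(g, c), dispersion alpha) with per-sample
    size factors s_r and baseline means mu_g ~ U(gene_mean_range). Returns
    the counts and the truth table augmented with ``baseline_mean``.
    """
    ids = [g.gene_id for g in genes]
    mu = rng.uniform(*config.gene_mean_range, size=len(ids))
    truth = truth.copy()
    truth["baseline_mean"] = pd.Series(mu, index=ids)
    samples, conditions = [], {}
    cols = {}
    for cond in EXPRESSION_CONDITIONS:
        lfc = truth.loc[ids, f"lfc_{cond}"].to_numpy()
        for rep in range(1, config.n_expr_replicates + 1):
            s = rng.uniform(*config.size_factor_range)
            name = f"{cond}_r{rep}"
            cols[name] = nb_counts(s * mu * 2.0 ** lfc,
                                   config.nb_dispersion_expression, rng)
            samples.append(name)
            conditions[name] = cond
    counts = pd.DataFrame(cols, index=pd.Index(ids, name="feature_id"))
    return CountMatrix(counts, pd.Series(conditions)), truth


def simulate_accessibility(
    config: SyntheticConfig, regions: list[GenomicInterval], truth: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[RegionCounts, pd.DataFrame, dict[str, list[list[GenomicInterval]]],
           list[GenomicInterval], list[GenomicInterval]]:
    """Region counts, per-replicate peak sets, and histone-mark intervals.

    Region counts are NB with planted fold changes (fold >= 2 for "up"
    classes, exactly 1 for stable regions). Each condition gets
    ``n_acc_replicates`` peak BED-style sets: every region appears as a
    slightly jittered peak in every replicate, and each replicate adds its
    own non-reproducible noise peaks (which a consensus over replicates
    removes). Every truth-labelled enhancer region is covered by one
    H3K4me1 and one H3K27ac interval.
    """
    if not regions:
        raise ValueError("region list is empty")
    ids = [r.name for r in regions]
    mu = rng.uniform(*config.region_mean_range, size=len(ids))
    truth = truth.copy()
    truth["baseline_mean"] = pd.Series(mu, index=ids)
    cols, conditions = {}, {}
    for cond in ACCESSIBILITY_CONDITIONS:
        lfc = truth.loc[ids, f"lfc_{cond}"].to_numpy()
        for rep in range(1, config.n_acc_replicates + 1):
            s = rng.uniform(*config.size_factor_range)
            name = f"{cond}_r{rep}"
            cols[name] = nb_counts(s * mu * 2.0 ** lfc,
                                   config.nb_dispersion_accessibility, rng)
            conditions[name] = cond
    counts = pd.DataFrame(cols, index=pd.Index(ids, name="feature_id"))
    region_counts = RegionCounts({r.name: r for r in regions},
                                 CountMatrix(counts, pd.Series(conditions)))

    replicate_peaks: dict[str, list[list[GenomicInterval]]] = {}
    chrom_len = config.chrom_length
    for cond in ACCESSIBILITY_CONDITIONS:
        reps = []
        for rep in range(config.n_acc_replicates):
            peaks = []
            for r in regions:
                j1 = int(rng.integers(-30, 31))
                j2 = int(rng.integers(-30, 31))
                start = max(0, r.start + j1)
                end = min(chrom_len, max(start + 50, r.end + j2))
                peaks.append(GenomicInterval(r.chrom, start, end,
                                             name=f"{r.name}_{cond}_r{rep + 1}"))
            n_noise = max(1, len(regions) // 20)
            for k in range(n_noise):
                chrom = f"chr{int(rng.integers(config.n_chroms)) + 1}"
                start = int(rng.integers(0, chrom_len - 300))
                peaks.append(GenomicInterval(chrom, start, start + 300,
                                             name=f"noise_{cond}_r{rep + 1}_{k}"))
            reps.append(peaks)
        replicate_peaks[cond] = reps

    k4me1, k27ac = [], []
    for r in regions:
        if truth.at[r.name, "has_k4me1"]:
            pad = int(rng.integers(50, 400))
            k4me1.append(GenomicInterval(r.chrom, max(0, r.start - pad),
                                         min(chrom_len, r.end + pad),
                                         name=f"k4me1_{r.name}"))
        if truth.at[r.name, "has_k27ac"]:
            pad = int(rng.integers(50, 400))
            k27ac.append(GenomicInterval(r.chrom, max(0, r.start - pad),
                                         min(chrom_len, r.end + pad),
                                         name=f"k27ac_{r.name}"))
    # background marks away from any candidate region
    region_trees = build_trees(regions)
    for mark_list, mark in ((k4me1, "k4me1"), (k27ac, "k27ac")):
        for k in range(len(regions) // 10):
            chrom = f"chr{int(rng.integers(config.n_chroms)) + 1}"
            start = int(rng.integers(0, chrom_len - 800))
            tree = region_trees.get(chrom)
            if tree is not None and tree.overlap(start, start + 800):
                continue
            mark_list.append(GenomicInterval(chrom, start, start + 800,
                                             name=f"{mark}_bg{k}"))
    return region_counts, truth, replicate_peaks, k4me1, k27ac


# ------------------------------------------------------------------ sequences

def simulate_sequences(
    config: SyntheticConfig,
    genes: list[GeneModel],
    regions: list[GenomicInterval],
    gene_truth: pd.DataFrame,
    region_truth: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[dict[str, str], list[PWM]]:
    """Genome sequences with planted motif occurrences, and a PFM library.

    The configured consensus (default the bZIP core) is embedded at rate
    ``p_target`` in the promoter window of every planted down-regulated
    gene and in the +/-50 bp center of every truth enhancer region, on a
    random strand with IUPAC degeneracies resolved at random. The returned
    PWM library holds the planted motif plus decoys; the first entry is
    the planted one.
    """
    genome = {}
    for c in range(config.n_chroms):
        codes = rng.integers(0, 4, size=config.chrom_length, dtype=np.uint8)
        genome[f"chr{c + 1}"] = codes  # keep numeric until all edits are done

    base_arr = np.frombuffer(b"ACGT", dtype=np.uint8)

    def embed(chrom: str, lo: int, hi: int) -> None:
        word = _resolve_consensus(config.consensus, rng)
        if rng.random() < 0.5:
            word = word.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        w = len(word)
        if hi - lo < w:
            return
        pos = int(rng.integers(lo, hi - w + 1))
        genome[chrom][pos:pos + w] = np.frombuffer(word.encode(), dtype=np.uint8)

    down_classes = {c for c in DEG_CLASSES if c.endswith("_down")}
    for g in genes:
        if gene_truth.at[g.gene_id, "class"] in down_classes:
            if rng.random() < config.p_target:
                win = g.promoter_window()
                embed(g.chrom, win.start, min(win.end, config.chrom_length))
    for r in regions:
        if region_truth.at[r.name, "is_enhancer"]:
            if rng.random() < config.p_target:
                center = r.midpoint
                embed(r.chrom, max(0, center - 50),
                      min(config.chrom_length, center + 50))

    # indices 0..3 -> ACGT; embedded words were written as ASCII, map back
    out = {}
    for chrom, codes in genome.items():
        arr = codes.copy()
        for i, b in enumerate(base_arr):
            arr[codes == b] = i
        arr = np.minimum(arr, 3)
        out[chrom] = base_arr[arr].tobytes().decode("ascii")

    pwms = [
        PWM.from_consensus("BZIP_CORE", config.consensus),
        PWM.from_consensus("GC_BOX", "GGGGCGGGG"),
        PWM.from_consensus("EBOX", "CACGTG"),
        PWM.from_consensus("GATA_MOTIF", "AGATAAGA"),
        PWM.from_consensus("CCAAT_BOX", "CCAATCAG"),
    ]
    return out, pwms


def _resolve_consensus(consensus: str, rng: np.random.Generator) -> str:
    out = []
    for ch in consensus.upper():
        allowed = _IUPAC[ch]
        out.append(allowed[int(rng.integers(len(allowed)))])
    return "".join(out)


def simulate_gene_sets(config: SyntheticConfig, gene_truth: pd.DataFrame,
                       rng: np.random.Generator) -> dict[str, set[str]]:
    """A small GMT-style collection: one set enriched for planted shared
    DEGs plus random decoy sets."""
    ids = list(gene_truth.index)
    shared = [g for g in ids if gene_truth.at[g, "class"].startswith("shared")]
    n_pick = max(1, int(0.6 * len(shared)))
    picked = [shared[i] for i in rng.permutation(len(shared))[:n_pick]]
    filler = [ids[i] for i in rng.permutation(len(ids))[:max(1, n_pick // 4)]]
    sets = {"HYPERGLYCEMIA_RESPONSE": set(picked) | set(filler)}
    for k in range(10):
        members = [ids[i] for i in rng.permutation(len(ids))[:50]]
        sets[f"RANDOM_SET_{k:02d}"] = set(members)
    return sets


# ------------------------------------------------------------------ bundle

@dataclass
class SyntheticStudy:
    config: SyntheticConfig
    chrom_table: pd.DataFrame
    tads: list[TadDomain]
    genes: list[GeneModel]
    regions: list[GenomicInterval]
    gene_truth: pd.DataFrame
    region_truth: pd.DataFrame
    expression: CountMatrix
    accessibility: RegionCounts
    replicate_peaks: dict[str, list[list[GenomicInterval]]]
    k4me1: list[GenomicInterval]
    k27ac: list[GenomicInterval]
    genome: dict[str, str]
    pwms: list[PWM]
    gene_sets: dict[str, set[str]]


def simulate_study(config: SyntheticConfig | None = None,
                   with_sequences: bool = True) -> SyntheticStudy:
    """Run every generator stage in a fixed order under one seeded RNG."""
    config = SyntheticConfig() if config is None else config
    rng = np.random.default_rng(config.seed)
    chrom_table, tads, genes, regions = simulate_genome(config, rng)
    gene_truth = assign_gene_truth(config, genes, rng)
    region_truth = assign_region_truth(config, regions, tads, genes,
                                       gene_truth, rng)
    expression, gene_truth = simulate_expression_counts(config, genes,
                                                        gene_truth, rng)
    accessibility, region_truth, replicate_peaks, k4me1, k27ac = \
        simulate_accessibility(config, regions, region_truth, rng)
    if with_sequences:
        genome, pwms = simulate_sequences(config, genes, regions, gene_truth,
                                          region_truth, rng)
    else:
        genome, pwms = {}, [PWM.from_consensus("BZIP_CORE", config.consensus)]
    gene_sets = simulate_gene_sets(config, gene_truth, rng)
    return SyntheticStudy(config, chrom_table, tads, genes, regions,
                          gene_truth, region_truth, expression, accessibility,
                          replicate_peaks, k4me1, k27ac, genome, pwms,
                          gene_sets)


def write_study(study: SyntheticStudy, outdir: str | Path) -> None:
    """Dump every artifact of the study as plain-text files."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    gio.write_yaml(study.config.to_dict(), out / "config.yaml")
    study.chrom_table.to_csv(out / "chroms.tsv", sep="\t", index=False)
    gio.write_bed([GenomicInterval(t.interval.chrom, t.interval.start,
                                   t.interval.end, name=t.domain_id)
                   for t in study.tads], out / "tads.bed")
    gio.write_gene_table(study.genes, out / "genes.tsv", out / "exons.tsv")
    gio.write_bed(study.regions, out / "regions.bed")
    study.gene_truth.to_csv(out / "gene_truth.tsv", sep="\t")
    study.region_truth.to_csv(out / "region_truth.tsv", sep="\t")
    gio.write_counts_tsv(study.expression.counts, out / "expression_counts.tsv")
    gio.write_counts_tsv(study.accessibility.counts.counts,
                         out / "region_counts.tsv")
    for cond, reps in study.replicate_peaks.items():
        for i, peaks in enumerate(reps):
            gio.write_bed(peaks, out / f"peaks_{cond}_rep{i + 1}.bed")
    gio.write_bed(study.k4me1, out / "k4me1.bed")
    gio.write_bed(study.k27ac, out / "k27ac.bed")
    if study.genome:
        gio.write_fasta(study.genome, out / "genome.fa")
    _write_pfm_library(study.pwms, out / "motifs.pfm")
    gio.write_gmt({k: sorted(v) for k, v in study.gene_sets.items()},
                  out / "gene_sets.gmt")


def read_study(indir: str | Path) -> SyntheticStudy:
    """Reload a study directory written by :func:`write_study`."""
    ind = Path(indir)
    cfg_dict = gio.read_yaml(ind / "config.yaml")
    for k, v in cfg_dict.items():
        if isinstance(v, list) and k.endswith("_range"):
            cfg_dict[k] = tuple(v)
    config = SyntheticConfig(**cfg_dict)
    chrom_table = pd.read_csv(ind / "chroms.tsv", sep="\t")
    tads = [TadDomain(iv.name, iv) for iv in gio.read_bed(ind / "tads.bed")]
    genes = gio.read_gene_table(ind / "genes.tsv", ind / "exons.tsv")
    regions = gio.read_bed(ind / "regions.bed")
    gene_truth = pd.read_csv(ind / "gene_truth.tsv", sep="\t", index_col=0)
    region_truth = pd.read_csv(ind / "region_truth.tsv", sep="\t", index_col=0)
    expr_counts = gio.read_counts_tsv(ind / "expression_counts.tsv")
    expression = CountMatrix(expr_counts, _conditions_from_names(expr_counts.columns))
    acc_counts = gio.read_counts_tsv(ind / "region_counts.tsv")
    accessibility = RegionCounts(
        {r.name: r for r in regions},
        CountMatrix(acc_counts, _conditions_from_names(acc_counts.columns)))
    replicate_peaks: dict[str, list[list[GenomicInterval]]] = {}
    for cond in ACCESSIBILITY_CONDITIONS:
        reps = []
        for i in range(1, config.n_acc_replicates + 1):
            p = ind / f"peaks_{cond}_rep{i}.bed"
            if p.exists():
                reps.append(gio.read_bed(p))
        if reps:
            replicate_peaks[cond] = reps
    k4me1 = gio.read_bed(ind / "k4me1.bed")
    k27ac = gio.read_bed(ind / "k27ac.bed")
    fasta = ind / "genome.fa"
    genome = gio.read_fasta(fasta) if fasta.exists() else {}
    pfm = ind / "motifs.pfm"
    pwms = ([PWM.from_biopython(m) for m in gio.read_jaspar(pfm)]
            if pfm.exists() else [])
    gmt = ind / "gene_sets.gmt"
    gene_sets = gio.read_gmt(gmt) if gmt.exists() else {}
    return SyntheticStudy(config, chrom_table, tads, genes, regions,
                          gene_truth, region_truth, expression, accessibility,
                          replicate_peaks, k4me1, k27ac, genome, pwms,
                          gene_sets)


def _conditions_from_names(columns) -> pd.Series:
    """Condition labels from ``<condition>_r<k>`` sample names."""
    return pd.Series({c: c.rsplit("_r", 1)[0] for c in columns})


def _write_pfm_library(pwms: list[PWM], path: Path) -> None:
    """JASPAR-style PFM text: counts scaled back from probabilities."""
    with open(path, "w") as fh:
        for p in pwms:
            fh.write(f">{p.motif_id}\t{p.motif_id}\n")
            counts = np.round(p.probs * 100, 2)
            for i, base in enumerate("ACGT"):
                row = "  ".join(f"{c:7.2f}" for c in counts[:, i])
                fh.write(f"{base}  [ {row} ]\n")
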