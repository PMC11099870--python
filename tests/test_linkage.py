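"""TAD assignment, enhancer-gene linkage, and concordance summaries."""

import numpy as np
import pandas as pd
import pytest

from glymem import (GeneModel, GenomicInterval, TadDomain, assign_tad,
                    concordance_summary, link_daes_to_degs)
from glymem.linkage import links_table, validate_tads


def tad(domain_id, chrom, start, end):
    return TadDomain(domain_id, GenomicInterval(chrom, start, end))


def deg_table(rows: dict[str, tuple[float, str]]) -> pd.DataFrame:
    return pd.DataFrame(
        {"log2FC": {g: v[0] for g, v in rows.items()},
         "direction": {g: v[1] for g, v in rows.items()},
         "is_deg": {g: v[1] != "none" for g, v in rows.items()}})


class TestAssignTad:
    TADS = [tad("t0", "chr1", 0, 25_000), tad("t1", "chr1", 25_000, 50_000)]

    def test_midpoint_on_last_base_of_domain(self):
        hit = assign_tad(("chr1", 24_999), self.TADS)
        assert hit.domain_id == "t0"

    def test_half_open_boundary_goes_to_next_domain(self):
        hit = assign_tad(("chr1", 25_000), self.TADS)
        assert hit.domain_id == "t1"

    def test_interval_assigned_by_midpoint(self):
        # [24000, 27000) has midpoint 25500, inside t1
        hit = assign_tad(GenomicInterval("chr1", 24_000, 27_000), self.TADS)
        assert hit.domain_id == "t1"

    def test_outside_all_tads_is_none(self):
        assert assign_tad(("chr1", 60_000), self.TADS) is None
        assert assign_tad(("chr2", 10), self.TADS) is None

    def test_overlapping_tads_rejected(self):
        with pytest.raises(ValueError, match="overlapping"):
            validate_tads([tad("a", "chr1", 0, 100), tad("b", "chr1", 50, 200)])

    def test_matches_brute_force_on_random_tiling(self):
        rng = np.random.default_rng(31)
        bounds = np.sort(rng.choice(np.arange(1, 100_000), 40, replace=False))
        edges = [0, *bounds.tolist(), 100_000]
        tads = [tad(f"t{i}", "chr1", a, b)
                for i, (a, b) in enumerate(zip(edges, edges[1:]))]
        for point in rng.integers(0, 100_000, size=500):
            got = assign_tad(("chr1", int(point)), tads)
            expected = [t for t in tads
                        if t.interval.start <= point < t.interval.end]
            assert got.domain_id == expected[0].domain_id


class TestLinkage:
    TADS = [tad("t0", "chr1", 0, 50_000), tad("t1", "chr1", 50_000, 100_000)]

    def gene(self, gid, tss, strand="+"):
        return GeneModel(gid, "chr1", strand, tss, max(0, tss - 100), tss + 2000)

    def dae(self, name, start, direction="more_accessible"):
        return GenomicInterval("chr1", start, start + 400,
                               name=f"{name}|{direction}")

    def test_same_tad_same_direction_is_concordant(self):
        links = link_daes_to_degs(
            [self.dae("d1", 10_000)], [self.gene("gU", 20_000)],
            deg_table({"gU": (1.2, "up")}), self.TADS)
        assert len(links) == 1
        assert links[0].tad_id == "t0"
        assert links[0].concordant

    def test_opposite_direction_is_discordant(self):
        links = link_daes_to_degs(
            [self.dae("d1", 10_000)], [self.gene("gD", 20_000)],
            deg_table({"gD": (-0.8, "down")}), self.TADS)
        assert len(links) == 1 and not links[0].concordant

    def test_gene_in_other_tad_is_not_linked(self):
        links = link_daes_to_degs(
            [self.dae("d1", 10_000)], [self.gene("g2", 60_000)],
            deg_table({"g2": (1.0, "up")}), self.TADS)
        assert links == []

    def test_deg_filter_restricts_candidates(self):
        table = deg_table({"gA": (1.0, "up"), "gB": (1.0, "up")})
        genes = [self.gene("gA", 20_000), self.gene("gB", 30_000)]
        links = link_daes_to_degs([self.dae("d1", 10_000)], genes, table,
                                  self.TADS, deg_filter={"gA"})
        assert [l.gene_id for l in links] == ["gA"]

    def test_links_match_brute_force_on_study(self, small_study):
        from glymem import nb_wald_contrast, deg_set, poisson_differential
        from glymem.accessibility import dar_intervals
        from glymem.intervals import call_daes
        de = nb_wald_contrast(small_study.expression, "control", "HG")
        da = poisson_differential(small_study.accessibility, "control", "HG")
        daes = call_daes(dar_intervals(da, small_study.accessibility.regions),
                         small_study.k4me1, small_study.k27ac)
        links = link_daes_to_degs(daes, small_study.genes, de,
                                  small_study.tads)
        got = {(l.dae_id, l.gene_id) for l in links}
        # brute force: scan every DAE x DEG pair for shared-TAD membership
        degs = deg_set(de)
        expected = set()
        for d in daes:
            for t in small_study.tads:
                if (t.interval.chrom == d.chrom
                        and t.interval.start <= d.midpoint < t.interval.end):
                    for g in small_study.genes:
                        if (g.gene_id in degs and g.chrom == t.interval.chrom
                                and t.interval.start <= g.tss < t.interval.end):
                            expected.add((d.name.split("|")[0], g.gene_id))
        assert got == expected
        tab = links_table(links)
        assert set(tab.columns) >= {"dae_id", "gene_id", "tad_id", "concordant"}


class TestConcordanceSummary:
    def links_with(self, n_daes, n_concordant):
        out = []
        for i in range(n_daes):
            direction = "up" if i < n_concordant else "down"
            out.append(next(iter(link_daes_to_degs(
                [GenomicInterval("chr1", 1000, 1400,
                                 name=f"d{i}|more_accessible")],
                [GeneModel(f"g{i}", "chr1", "+", 2000, 1900, 4000)],
                deg_table({f"g{i}": (1.0 if direction == "up" else -1.0,
                                     direction)}),
                [tad("t0", "chr1", 0, 50_000)]))))
        return out

    def test_zero_concordant_is_zero_percent(self):
        s = concordance_summary(self.links_with(10, 0))
        assert (s["n_daes_with_target"], s["n_concordant"],
                s["percent_concordant"]) == (10, 0, 0)

    def test_dae_counts_once_if_any_link_concordant(self):
        genes = [GeneModel("gU", "chr1", "+", 2000, 1900, 4000),
                 GeneModel("gD", "chr1", "+", 3000, 2900, 5000)]
        links = link_daes_to_degs(
            [GenomicInterval("chr1", 10_000, 10_400, name="d|more_accessible")],
            genes, deg_table({"gU": (1.0, "up"), "gD": (-1.0, "down")}),
            [tad("t0", "chr1", 0, 50_000)])
        assert len(links) == 2
        s = concordance_summary(links)
        assert (s["n_daes_with_target"], s["n_concordant"]) == (1, 1)

    def test_no_targets_gives_na_percent(self):
        s = concordance_summary([])
        assert s["n_daes_with_target"] == 0
        assert s["percent_concordant"] is None

    def test_shuffled_balanced_directions_near_half(self):
        """With one balanced up/down gene per TAD and shuffled labels,
        concordance falls to ~50%."""
        rng = np.random.default_rng(37)
        tads = [tad(f"t{i}", "chr1", i * 10_000, (i + 1) * 10_000)
                for i in range(400)]
        genes, rows, daes = [], {}, []
        for i in range(400):
            gid = f"g{i}"
            tss = i * 10_000 + 6000
            genes.append(GeneModel(gid, "chr1", "+", tss, tss - 100, tss + 1000))
            direction = "up" if rng.random() < 0.5 else "down"
            rows[gid] = (1.0 if direction == "up" else -1.0, direction)
            daes.append(GenomicInterval("chr1", i * 10_000 + 1000,
                                        i * 10_000 + 1400,
                                        name=f"d{i}|more_accessible"))
        links = link_daes_to_degs(daes, genes, deg_table(rows), tads)
        s = concordance_summary(links)
        frac = s["n_concordant"] / s["n_daes_with_target"]
        assert abs(frac - 0.5) <= 3 * np.sqrt(0.25 / 400)

    def test_counts_are_nested(self, small_study):
        from glymem import nb_wald_contrast, poisson_differential
        from glymem.accessibility import dar_intervals
        from glymem.intervals import call_daes
        de = nb_wald_contrast(small_study.expression, "control", "HG")
        da = poisson_differential(small_study.accessibility, "control", "HG")
        daes = call_daes(dar_intervals(da, small_study.accessibility.regions),
                         small_study.k4me1, small_study.k27ac)
        links = link_daes_to_degs(daes, small_study.genes, de, small_study.tads)
        s = concordance_summary(links)
        assert s["n_concordant"] <= s["n_daes_with_target"] <= len(daes)
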