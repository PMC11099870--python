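"""Synthetic study generator: determinism, containment, planted effects."""

import numpy as np
import pandas as pd
import pytest

from glymem import SyntheticConfig, simulate_genome, simulate_study
from glymem.simulate import (assign_gene_truth, nb_counts,
                             simulate_expression_counts, write_study)

from conftest import small_config


class TestGenome:
    def test_uniform_tad_tiling_is_forced(self):
        cfg = SyntheticConfig(n_chroms=1, chrom_length=100_000,
                              n_tads_per_chrom=4, n_genes=10, n_regions=5,
                              deg_class_sizes={}, dar_class_sizes={})
        _, tads, _, _ = simulate_genome(cfg)
        spans = [(t.interval.start, t.interval.end) for t in tads]
        assert spans == [(0, 25000), (25000, 50000), (50000, 75000),
                         (75000, 100000)]

    def test_same_seed_identical_coordinates(self):
        a = simulate_genome(small_config())
        b = simulate_genome(small_config())
        assert [(g.chrom, g.tss, g.start, g.end) for g in a[2]] == \
               [(g.chrom, g.tss, g.start, g.end) for g in b[2]]
        assert [(r.chrom, r.start, r.end) for r in a[3]] == \
               [(r.chrom, r.start, r.end) for r in b[3]]

    def test_every_feature_in_exactly_one_tad(self, small_study):
        tads = small_study.tads
        def containing(chrom, point):
            return [t for t in tads if t.interval.chrom == chrom
                    and t.interval.start <= point < t.interval.end]
        for g in small_study.genes:
            assert len(containing(g.chrom, g.tss)) == 1
        for r in small_study.regions:
            assert len(containing(r.chrom, r.midpoint)) == 1

    def test_regions_avoid_promoters_and_each_other(self, small_study):
        windows = [g.promoter_window() for g in small_study.genes]
        for r in small_study.regions:
            assert all(r.overlap_bp(w) == 0 for w in windows)
        by_chrom = {}
        for r in small_study.regions:
            by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
        for ivs in by_chrom.values():
            ivs.sort()
            assert all(b[0] >= a[1] for a, b in zip(ivs, ivs[1:]))

    def test_infeasible_packing_raises(self):
        with pytest.raises(ValueError, match="packing|chrom_length"):
            cfg = small_config(chrom_length=60_000, n_genes=50, n_regions=400,
                              n_tads_per_chrom=2, deg_class_sizes={},
                              dar_class_sizes={"dar_hg_up": 10})
            simulate_genome(cfg)


class TestCounts:
    def test_null_means_match_baseline(self):
        """With no planted effects and unit size factors, per-gene sample
        means across all 21 samples sit within 4 SE of the baseline."""
        cfg = small_config(deg_class_sizes={}, dar_class_sizes={},
                          size_factor_range=(1.0, 1.0),
                          n_genes=300, n_regions=20)
        _, _, genes, _ = simulate_genome(cfg)
        rng = np.random.default_rng(cfg.seed)
        truth = assign_gene_truth(cfg, genes, rng)
        cm, truth = simulate_expression_counts(cfg, genes, truth, rng)
        assert cm.counts.shape[1] == 21
        mu = truth["baseline_mean"]
        mean = cm.counts.mean(axis=1)
        alpha = cfg.nb_dispersion_expression
        se = np.sqrt((mu + alpha * mu**2) / cm.counts.shape[1])
        frac_inside = (np.abs(mean - mu) <= 4 * se).mean()
        assert frac_inside > 0.99

    def test_planted_shared_up_fold_change(self):
        cfg = small_config(size_factor_range=(1.0, 1.0))
        _, _, genes, _ = simulate_genome(cfg)
        rng = np.random.default_rng(cfg.seed)
        truth = assign_gene_truth(cfg, genes, rng)
        cm, truth = simulate_expression_counts(cfg, genes, truth, rng)
        hg = cm.counts.loc[:, (cm.conditions == "HG").to_numpy()].mean(axis=1)
        ctl = cm.counts.loc[:, (cm.conditions == "control").to_numpy()].mean(axis=1)
        planted = truth.index[(truth["class"] == "shared_deg_up")
                              & (truth["baseline_mean"] >= 100)]
        ratios = (hg[planted] / ctl[planted]).to_numpy()
        assert ((ratios >= 2**1.5) & (ratios <= 2**2.5)).mean() > 0.9

    def test_identical_seed_identical_matrix(self):
        a = simulate_study(small_config()).expression.counts
        b = simulate_study(small_config()).expression.counts
        pd.testing.assert_frame_equal(a, b)

    def test_nb_poisson_limit(self):
        """As dispersion -> 0 the variance/mean ratio approaches 1."""
        rng = np.random.default_rng(5)
        mu = np.full(20_000, 200.0)
        x = nb_counts(mu, 1e-8, rng)
        assert x.var() / x.mean() == pytest.approx(1.0, rel=0.05)
        y = nb_counts(mu, 0.05, rng)
        assert y.var() / y.mean() == pytest.approx(1 + 0.05 * 200, rel=0.15)

    def test_invalid_dispersion_rejected(self):
        with pytest.raises(ValueError):
            nb_counts(np.array([10.0]), 0.0, np.random.default_rng(0))
        with pytest.raises(ValueError):
            SyntheticConfig(nb_dispersion_expression=-1.0)

    def test_class_sizes_validated(self):
        with pytest.raises(ValueError, match="exceed"):
            small_config(n_genes=10)


class TestTruthConsistency:
    def test_labels_determine_nonzero_lfcs(self, small_study):
        truth = small_study.gene_truth
        lfc_cols = [c for c in truth.columns if c.startswith("lfc_")]
        for _, row in truth.iterrows():
            nonzero = {c for c in lfc_cols if row[c] != 0}
            cls = row["class"]
            if cls == "none":
                assert not nonzero
            if cls.startswith("shared"):
                assert {"lfc_HG", "lfc_memory"} <= nonzero
            if cls.startswith("hg_unique"):
                assert "lfc_HG" in nonzero and "lfc_memory" not in nonzero
            if cls.startswith("memory_unique"):
                assert "lfc_memory" in nonzero and "lfc_HG" not in nonzero
            if cls != "none" and row["sf_restored"]:
                assert row["lfc_memory_SF"] == 0 and row["lfc_HG_SF"] == 0

    def test_sf_restored_regions_have_memory_fold_but_not_after_sf(self, small_study):
        truth = small_study.region_truth
        sf = truth[truth["class"] == "dar_sf_restored"]
        assert (2.0 ** sf["lfc_memory"] >= 2).all()
        assert (sf["lfc_memory_SF"] == 0).all()
        stable = truth[truth["class"] == "none"]
        lfc_cols = [c for c in truth.columns if c.startswith("lfc_")]
        assert (stable[lfc_cols] == 0).all().all()

    def test_enhancers_carry_both_marks(self, small_study):
        truth = small_study.region_truth
        enh = truth[truth["is_enhancer"]]
        assert bool(enh["has_k4me1"].all()) and bool(enh["has_k27ac"].all())


class TestAccessibilityCounts:
    def test_stable_region_fold_near_one(self, small_study):
        cm = small_study.accessibility.counts
        truth = small_study.region_truth
        hg = cm.counts.loc[:, (cm.conditions == "HG").to_numpy()].sum(axis=1)
        ctl = cm.counts.loc[:, (cm.conditions == "control").to_numpy()].sum(axis=1)
        stable = truth.index[(truth["class"] == "none")
                             & (truth["baseline_mean"] >= 200)]
        ratio = (hg[stable] / ctl[stable]).to_numpy()
        assert ((ratio > 1 / 1.5) & (ratio < 1.5)).all()

    def test_empty_region_list_raises(self):
        from glymem.simulate import simulate_accessibility
        cfg = small_config()
        with pytest.raises(ValueError, match="empty"):
            simulate_accessibility(cfg, [], pd.DataFrame(),
                                   np.random.default_rng(0))


class TestSequences:
    def test_p_target_one_embeds_literal_consensus(self):
        cfg = small_config(p_target=1.0, n_genes=100, n_regions=60,
                          deg_class_sizes={"shared_deg_down": 20},
                          dar_class_sizes={"dar_hg_up": 10})
        study = simulate_study(cfg)
        word = cfg.consensus
        rc = word.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        for g in study.genes:
            if study.gene_truth.at[g.gene_id, "class"] == "shared_deg_down":
                w = g.promoter_window()
                seq = study.genome[g.chrom][w.start:w.end]
                assert word in seq or rc in seq

    def test_p_target_zero_leaves_only_chance_hits(self):
        cfg = small_config(p_target=0.0, n_genes=200, n_regions=60)
        study = simulate_study(cfg)
        word, rc = cfg.consensus, "TGAGTCA"
        down = [g for g in study.genes
                if study.gene_truth.at[g.gene_id, "class"].endswith("down")]
        hits = 0
        for g in down:
            w = g.promoter_window()
            seq = study.genome[g.chrom][w.start:w.end]
            hits += (word in seq) or (rc in seq)
        # chance rate for a 7-mer in 1100 bp is ~13% per window
        assert hits / max(1, len(down)) < 0.4

    def test_chance_hit_rate_matches_binomial_expectation(self):
        """Uniform random 500-mers: both-strand occurrences of a 7-bp word
        arrive at rate ~2*(500-6)/4^7 per sequence."""
        rng = np.random.default_rng(11)
        word, rc = "TGACTCA", "TGAGTCA"
        n_seq, length = 400, 500
        bases = np.array(list("ACGT"))
        total = 0
        for _ in range(n_seq):
            seq = "".join(bases[rng.integers(0, 4, size=length)])
            total += seq.count(word) + seq.count(rc)
        expected = n_seq * 2 * (length - 6) / 4**7
        sd = np.sqrt(expected)
        assert abs(total - expected) <= 3 * sd

    def test_bad_consensus_rejected(self):
        with pytest.raises(ValueError, match="consensus"):
            small_config(consensus="TGAXTCA")


class TestStudyDeterminism:
    def test_written_study_is_byte_identical(self, tmp_path):
        cfg = small_config()
        for sub in ("a", "b"):
            write_study(simulate_study(cfg), tmp_path / sub)
        files_a = sorted((tmp_path / "a").iterdir())
        assert files_a
        for fa in files_a:
            fb = tmp_path / "b" / fa.name
            assert fa.read_bytes() == fb.read_bytes(), fa.name

    def test_study_roundtrip_through_files(self, tmp_path):
        from glymem.simulate import read_study
        study = simulate_study(small_config())
        write_study(study, tmp_path / "s")
        loaded = read_study(tmp_path / "s")
        pd.testing.assert_frame_equal(study.expression.counts,
                                      loaded.expression.counts)
        assert len(loaded.tads) == len(study.tads)
        assert loaded.genome.keys() == study.genome.keys()
        assert [p.motif_id for p in loaded.pwms] == \
               [p.motif_id for p in study.pwms]
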