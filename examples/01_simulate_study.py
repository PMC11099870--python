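"""Generate the synthetic glucose-memory study and inspect its ground truth.

The generator builds a small genome tiled by TADs, places genes and
candidate enhancer regions, and draws NB counts for seven expression arms
(3 replicates each) and four accessibility arms (2 replicates each), with
planted differential classes recorded in truth tables.
"""

from glymem import SyntheticConfig, simulate_study

study = simulate_study(SyntheticConfig(seed=0))

print(f"genome: {len(study.genome)} chromosomes, "
      f"{sum(len(s) for s in study.genome.values()):,} bp")
print(f"TADs: {len(study.tads)}  genes: {len(study.genes)}  "
      f"candidate regions: {len(study.regions)}")
print(f"expression matrix: {study.expression.counts.shape} "
      f"(genes x samples)")
print(f"accessibility matrix: {study.accessibility.counts.counts.shape}")

print("\nplanted gene classes (ground truth):")
print(study.gene_truth["class"].value_counts().to_string())
print("\nplanted region classes:")
print(study.region_truth["class"].value_counts().to_string())
# 'shared' genes are differential in both the high-glucose and memory arms;
# 'dar_sf_restored' regions lose their accessibility gain under sulforaphane.
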