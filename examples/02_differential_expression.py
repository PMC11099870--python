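"""Differential expression and the shared-DEG set algebra.

The NB Wald contrast calls a gene differential at adjusted p < 0.05 and
|log2FC| > 0.5. Genes shared between the high-glucose (HG) and memory
contrasts are the transcriptional-memory signature.
"""

from glymem import (SyntheticConfig, deg_set, nb_wald_contrast, set_algebra,
                    simulate_study)

study = simulate_study(SyntheticConfig(seed=0), with_sequences=False)

hg = nb_wald_contrast(study.expression, "control", "HG")
mem = nb_wald_contrast(study.expression, "control", "memory")
print(hg[hg["is_deg"]].head().round(3).to_string())

out = set_algebra(deg_set(hg), deg_set(mem))
print(f"\nHG DEGs: {out['n_a']}   memory DEGs: {out['n_b']}")
print(f"shared: {len(out['shared'])} "
      f"({out['percent_shared_of_a']}% of HG, "
      f"{out['percent_shared_of_b']}% of memory)")
# A large shared fraction means most glucose-induced expression changes
# persist after glucose normalisation - the transcriptional memory.
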