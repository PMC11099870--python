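"""Restoration of differential calls by NRF2-activating interventions.

A baseline differential feature (vs control) is "restored" when the
intervention arm (sulforaphane SF, or NRF2 overexpression OE) no longer
calls it differential vs the same control.
"""

from glymem import (SyntheticConfig, deg_set, nb_wald_contrast,
                    poisson_differential, restoration, simulate_study)

study = simulate_study(SyntheticConfig(seed=0), with_sequences=False)

contrast = {c: nb_wald_contrast(study.expression, "control", c)
            for c in ("memory", "memory_SF", "OE_memory")}

for label, arm in (("sulforaphane", "memory_SF"),
                   ("NRF2 overexpression", "OE_memory")):
    out = restoration(deg_set(contrast["memory"]), deg_set(contrast[arm]))
    print(f"{label}: {len(out['remaining'])} of {out['n_baseline']} memory "
          f"DEGs remain ({out['percent_remaining']}%), "
          f"{out['percent_restored']}% restored")

da_mem = poisson_differential(study.accessibility, "control", "memory")
da_sf = poisson_differential(study.accessibility, "control", "memory_SF")
dars = lambda t: set(t.index[t["is_dar"]])
out = restoration(dars(da_mem), dars(da_sf))
print(f"chromatin: {out['percent_restored']}% of memory DARs restored by SF")
# Both interventions erase most of the memory signature; the generator
# plants a larger restored fraction for overexpression than for SF.
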