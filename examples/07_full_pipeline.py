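"""End-to-end run: simulate, analyse every stage, print the report.

Equivalent to `glymem run --outdir <dir> --seed 0` from the shell. The
report is deterministic: the same seed always yields the same hash.
"""

from glymem import RunConfig, SyntheticConfig, report_hash, run_pipeline, simulate_study
from glymem.report import summary_lines

study = simulate_study(SyntheticConfig(seed=0))
result = run_pipeline(study, RunConfig(seed=0))

for line in summary_lines(result.report):
    print(line)
print(f"\nreport hash: {report_hash(result.report)}")
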