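"""The full synthetic pipeline: simulate -> adjust -> rank -> test.

Plants the strongest adjusted binding on the cognate anticodon-middle base
for ten amino acids, runs the whole chain, and prints the headline
statistics. Identical configs give byte-identical reports.
"""

from codonaffinity.pipeline import RunConfig, human_summary, run_pipeline

config = RunConfig(seed=1, out_path="pipeline_report.json")
report = run_pipeline(config)
print(human_summary(report))
print("\nplanted amino acids:", ", ".join(config.planted_amino_acids))
print("report written to pipeline_report.json")
# With ten planted cognates among 23 allocations the exact binomial
# enrichment p-value is 0.0408, below the 5% level.
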