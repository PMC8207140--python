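"""Run the complete analysis end to end and list the written reports.

simulate -> cluster -> discover -> scan -> select -> classify ->
profile -> flowchart, all on the default study conditions.
"""

from ferrocre import run_pipeline

result = run_pipeline(outdir="example_out/pipeline", seed=1)

print(f"regulon sizes:\n{result.regulons.labels.value_counts().to_string()}")
print(f"\ndiscovered motifs: {len(result.discovered)}")
print(f"confirmed features: {result.selection.confirmed}")
print(f"balanced accuracy: {result.report.balanced_accuracy:.3f}")
print("\nreport files:")
for key, path in sorted(result.files.items()):
    print(f"  {key}: {path}")
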