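"""Full three-tier pipeline: study-shaped report and cross-level view.

Runs every condition of the shipped reference tables through the
synthetic-bundle pipeline at a reduced problem size (2 runs x 1500
frames per trajectory condition) and prints the cross-level summary:
per ligand, whether the wild-type phosphorylation response is restored
at the trajectory, motility and myocyte tiers, and how well the tiers
agree.
"""

from tncoupling.pipeline import RunConfig, cross_level_summary, run_pipeline

config = RunConfig(seed=5, out_dir="scratch/report")
report = run_pipeline(config)
summary = cross_level_summary(report)

print(f"report tables : {sorted(report.tables)}  (config hash {report.config_hash})")
print(summary.to_string(index=False))
print("The three recouplers (EGCG, RVL, silybin B) restore the response at")
print("most tiers; silybin A and ECG at none.  EGCG's anomalous hinge shift")
print("shows up as an agreement score below 1.")
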