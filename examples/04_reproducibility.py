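"""Scan-to-scan reproducibility of a painted hot sphere.

Acquires the 36 mm hot sphere in a 48 mm cube (3:1 dwell ratio) five
times with independent Poisson noise and reports the COV across repeats
of the compartment statistics.
"""

from paintpet.experiments import ExperimentConfig, run_reproducibility

cfg = ExperimentConfig(study="reproducibility", seed=1, n_repeats=5)
report = run_reproducibility(cfg)
row = report.table.loc["cov_across_repeats"]
for stat in ("mean_hot", "mean_bg", "max_hot", "max_bg", "min_hot", "min_bg"):
    print(f"COV({stat:8s}) = {row[f'cov_{stat}_percent']:.3f} %")
print(f"COV(total positioning time) = {row['cov_total_time_s_percent']:.3f} %")
print()
print("Compartment means average thousands of voxels and are far more")
print("repeatable than single-voxel extremes; with a deterministic stage")
print("(no timing jitter configured) the total time COV is exactly zero.")
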