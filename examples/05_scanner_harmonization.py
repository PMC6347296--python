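"""Inter-scanner texture comparison and voxel-size harmonization.

Paints the identical heterogeneous lesion DTM on the 4 mm PMT and
2.73 mm SiPM clinical presets, extracts the nine texture indices from the
40% isocontour VOI, and compares them before and after spline resampling
to a common 4 mm grid.
"""

from paintpet.experiments import ExperimentConfig, run_scanner_comparison
from paintpet.radiomics import FEATURE_COLUMNS

cfg = ExperimentConfig(
    study="scanner_comparison",
    seed=1,
    noiseless=True,
    scanners=["clinical_pmt_4mm", "clinical_sipm_273mm"],
    harmonize_to_mm=4.0,
)
report = run_scanner_comparison(cfg)
print(report.table[list(FEATURE_COLUMNS)].to_string(float_format=lambda v: f"{v:.4g}"))
print()
print("per-feature symmetric percent differences (PMT vs SiPM):")
print(report.percent_diff.to_string(float_format=lambda v: f"{v:.1f}"))
print()
print("Voxel size drives much of the apparent texture difference between")
print("devices: resampling both images to a common 4 mm grid shrinks the")
print("summed percent difference across the nine texture indices.")
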