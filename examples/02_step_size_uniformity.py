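"""Step-size optimization: how uniform is a painted line?

Paints constant-dwell lines at 4, 6, 8 and 10 mm step sizes, simulates
them with a 4.58 mm FWHM PSF on a fine analysis grid, and reports the
plateau coefficient of variation of each line profile, plus the COV of a
20 ml spherical VOI inside a painted homogeneous cube.
"""

from paintpet.experiments import ExperimentConfig, run_uniformity

report = run_uniformity(ExperimentConfig(study="uniformity", seed=1))
print(report.table.to_string(float_format=lambda v: f"{v:.2f}"))
print()
print("The plateau COV grows with step size: stops spaced well below the")
print("PSF width merge into a uniform line, wider spacing leaves ripple.")
print("The noisy-cube VOI COV (~2%) is the whole-chain uniformity of a")
print("painted homogeneous 48 mm cube at the default noise level.")
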