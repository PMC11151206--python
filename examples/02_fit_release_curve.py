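"""Recover permeability and partition coefficient from a release trace.

Runs the full analysis chain on a synthetic probe-alone trace with
realistic instrument noise: calibration inversion, stage segmentation,
exponential regression from the inflection point, then
P = b*V_in*V_out/(A*(V_in+V_out)) and K = (c_triton-c_fin)/c_fin * V_aq/V_lip.
"""

import numpy as np

import lipoperm as lp

pop, protocol, calib = lp.LiposomePopulation(), lp.MixingProtocol(), lp.CalibrationCurve()
geom = lp.assay_geometry(pop, protocol)
kin = lp.reference_kinetics()

recipe = lp.ExperimentRecipe("CF alone", seed=7)   # default 0.5% noise
trace = lp.generate_trace(recipe, kin, pop, protocol, calib)
fit = lp.fit_release(trace, calib, geom)

print(f"rate constant b        : {fit.b:.3e} 1/s")
print(f"permeability P         : {fit.P:.3e} cm/s   (truth {trace.true_P:.3e})")
print(f"partition coefficient K: {fit.K:.3e}        (truth {trace.true_K:.3e})")
print(f"log10 K                : {np.log10(fit.K):.2f}")
print("P within a few percent of truth shows the chain is unbiased at the")
print("assay's working noise level; log10 K near 4.5 reproduces the")
print("unexpectedly strong membrane association of the probe.")
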