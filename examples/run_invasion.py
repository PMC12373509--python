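"""Simulate a ballistic-wave invasion and quantify its front kinetics.

Runs the reaction-diffusion model at the canonical ballistic-wave preset
(arrested condensate, 1 mM barcode, 1 uM invader bath, 1e4 diffusivity
contrast), then tracks the front through the kymograph and fits its
velocity, displacement exponent and peak ratio.
"""

import numpy as np

import balwave as bw

params = bw.load_preset("ballistic_wave")
result = bw.simulate_invasion(params)

trace = bw.front_trace(
    result.kymograph,
    convention="peak",
    fit_window=(0.35 * params.t_end, 0.85 * params.t_end),
)
ratios = trace.I_p_over_I0[np.isfinite(trace.I_p_over_I0)]

print(f"front velocity v        : {trace.v:.3e} um/s")
print(f"displacement exponent   : {trace.alpha:.3f}   (1 = ballistic)")
print(f"median peak ratio Ip/I0 : {np.median(ratios):.2f}   (>1 marks the wave)")
print(f"transport regime        : {bw.classify_regime(trace)}")
print(f"barcode conservation    : {result.diagnostics['max_barcode_drift']:.1e} relative drift")

# The front moves at constant speed carrying a bound-invader peak ~3x the
# intensity of the swollen plateau behind it: ballistic wave diffusion.
# The kymograph and its metadata can be written as plain text:
result.kymograph.write_text("scratch_wave_kymograph")
print("kymograph written to scratch_wave_kymograph.{tsv,json}")
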