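# balwave — ballistic diffusion fronts in biomolecular condensates

`balwave` models and quantifies a non-Fickian transport mode observed when a
short "invader" oligonucleotide is taken up by an *arrested* (solid-like) DNA
condensate whose chains carry complementary barcode domains.  Binding at the
invasion front converts the local material from arrested to dynamic and
swollen, switching the invader diffusivity from a very small value `D0` to a
much larger `D1`.  The interplay of molecular recognition, swelling kinetics
and this threshold-gated diffusivity produces an ultrasharp front that
propagates *linearly in time* (ballistic), optionally carrying a
high-intensity invader peak — in contrast to classical Fickian invasion with
its blurry erfc profile and ΔX ∝ t¹ᐟ² law.

The package is aimed at soft-matter biophysicists who simulate such invasion
experiments or quantify them from microscopy: it bundles

* **`rd_core`** — a conservative finite-volume reaction–diffusion simulator:
  free invader u binds free barcode m irreversibly (`k_bind`), the bound
  complex converts first-order from arrested `M_arr` to swollen `M_sw`
  (`k_swell`), a cell's width dilates with its swollen fraction φ up to the
  volumetric factor `f_swell` (≈4), and the diffusivity switches D0 → D1 once
  φ ≥ θ.  Cartesian slab or radially symmetric geometry;
* **`front_kinetics`** — kymograph front tracking: front position, width W,
  peak ratio I_p/I_0, fitted velocity v, displacement exponent α of
  ΔX ∝ t^α, and the regime taxonomy {`fickian`, `ballistic_front`,
  `ballistic_wave`};
* **`frap`** — FRAP double normalization
  I_norm(t) = [I_ROI(t)/I_ROI(t₀)]·[I_ref(t₀)/I_ref(t)], half-recovery times
  with the 6000 s arrested convention, and point-bleach diffusivities from
  the Gaussian-spreading law σ²(t) = σ₀² + 2Dt;
* **`phasor`** — FLIM phasor transform
  g = ∫I cos(nωt)dt / ∫I dt, s = ∫I sin(nωt)dt / ∫I dt, the universal
  semicircle, mono-exponential lifetime readout τ = s/(g·n·ω), and cursor
  segmentation;
* **`synthetic`** — generators for every input (kymographs, FRAP series,
  point-bleach stacks, photon decays) with known ground truth and recorded
  seeds, so the full pipeline is testable as closed loops.

## Worked example

```python
import numpy as np
import balwave as bw

params = bw.load_preset("ballistic_wave")   # YAML preset shipped with the package
result = bw.simulate_invasion(params)
trace = bw.front_trace(result.kymograph, convention="peak",
                       fit_window=(0.35 * params.t_end, 0.85 * params.t_end))
print(trace.v, trace.alpha, bw.classify_regime(trace))
```

Running `python examples/run_invasion.py` prints:

```
front velocity v        : 5.004e-06 um/s
displacement exponent   : 1.047   (1 = ballistic)
median peak ratio Ip/I0 : 3.17   (>1 marks the wave)
transport regime        : ballistic_wave
barcode conservation    : 1.1e-14 relative drift
```

The displacement exponent ≈1 says the front advances at constant velocity;
the peak ratio ≈3 is the transient accumulation of bound invader in the
compact, not-yet-swollen layer at the front — the "wave".  The other
examples cover the regime taxonomy (`transport_regimes.py`), the scaling
laws v ∝ [m*]⁰·⁵ and v ∝ W across an invader-concentration sweep
(`concentration_sweep.py`), FRAP/point-bleach quantification
(`frap_and_pointbleach.py`) and FLIM phasor segmentation of the 2.9 ns vs
3.4 ns lifetime populations (`flim_phasor.py`).

Model parameters live in YAML config files (`src/balwave/presets/*.yaml`);
`ModelParams.from_yaml`/`to_yaml` read and write the same format, and
kymographs serialize to a TSV matrix plus JSON sidecar (`Kymograph.
write_text`/`read_text`) or a multi-page TIFF (`write_tiff`).

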