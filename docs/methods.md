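# Methods

## The invasion model

A 1D material grid represents a slab (or radial section) of an arrested
condensate with uniform barcode concentration `m_total` (default 1 mM, the
order of magnitude inside such condensates).  A reservoir of free invader at
concentration `u_res` (µM scale) is held at the outer boundary; the centre
is a zero-flux boundary.  Four processes act on the per-cell species
amounts:

1. **Transport.** Free invader `u` diffuses; bound species are immobile
   (each bound invader is part of a high-molecular-weight chain).  The
   local diffusivity is `D0` while the cell is arrested and `D1` once its
   swollen fraction φ = M_sw/(m + M_arr + M_sw) reaches the threshold θ
   (hard step by default; an optional logistic width smooths the switch).
   Interface diffusivities are harmonic means of the adjacent cells.
2. **Binding.** `u + m → M_arr` with bimolecular rate `k_bind`; unbinding
   is neglected (the duplex is far too stable on the experimental time
   scale).
3. **Swelling conversion.** `M_arr → M_sw` first-order with rate `k_swell`,
   modelling the slow relaxation/disentanglement that dynamizes bound
   material.
4. **Grid expansion.** A cell's lab width is `w = w0·(1 + (g_f − 1)·φ)`.
   In the cartesian slab a 1D volume is a length, so the linear factor is
   the full volumetric one, `g_f = f_swell` (default 4): complete invasion
   quadruples the domain length and dilutes the conserved barcode fourfold,
   matching the observed fourfold intensity drop.  In radial geometry
   `g_f = f_swell^(1/3)`, reproducing the ≈4^(1/3) radius growth.

Because species are stored as amounts per material cell, the per-cell
barcode total `m + M_arr + M_sw` is conserved exactly by construction
(measured drift ~1e-14 relative), and the domain-total invader equals the
time-integrated boundary influx to ~1e-11 relative.

### Why the front is ballistic, and the scaling laws

With `D1 ≫ D0`, the swollen region behind the front is effectively
gradient-free, so the reservoir concentration is delivered to the front.
The rate-limiting step is diffusion (still at `D0`) across the
*bound-but-not-yet-swollen gap layer* whose material width self-adjusts to
Δ = v·τ_θ, with τ_θ = −ln(1−θ)/k_swell the time for a freshly bound cell to
cross the switch threshold.  Mass balance (flux `D0·u_res/Δ` consumes
`m_total` per unit length) then gives a constant front speed

    v ≈ sqrt( D0 · u_res · k_swell / (m_total · ln(1/(1−θ))) ),

hence ΔX ∝ t (ballistic), v ∝ √u_res, and a front width W ∝ v·τ_θ ∝ v —
the linear velocity–width correlation.  The high-intensity peak is the gap
layer itself: fully bound but still compact material at ≈`m_total` lab
concentration against the fourfold-diluted plateau behind it, so
I_p/I_0 → f_swell for slow swelling and → 1 as `k_swell` grows.  When
`D1 = D0` the invasion is a classical moving-boundary problem,
X ≈ sqrt(2·D·(u_res/m_total)·t), the Fickian regime.

## Numerical scheme

`simulate_invasion` advances each macro step in three sub-steps:

1. analytic swelling conversion (exact exponential transfer M_arr → M_sw);
2. geometric width update from the new swollen fractions;
3. one backward-Euler finite-volume transport solve for `u` on the current
   non-uniform grid, with the binding sink `k_bind·m·c_u` folded into the
   tridiagonal matrix (barcode frozen over the step).  The invader bound
   during the step is then transferred to `M_arr` with exact bookkeeping
   (clamped so no species can go negative).

The implicit solve is unconditionally stable, which the default regime
requires: an explicit scheme at the default diffusivity contrast
(D1/D0 = 1e4) and invasion times (~1e6–1e7 s) would need ~1e9 steps per
run.  Treating binding inside the transport solve (rather than a fully
split reaction step) prevents the invader from artificially leaking past
the binding front during a long diffusion-only sub-step.  The scheme passes
two independent oracles: pure diffusion against the constant-source erfc
solution (RMS error ~3e-5 of the boundary value on a fine grid, bound
1e-2), and front-position convergence under halving dt / doubling n_cells
(change ~0.01%, bound 2%).  The standalone `reaction_step` (Strang-split
analytic binding + swelling, exact in all closed-form limits) and
`diffusion_step` (implicit, diffusion only) expose the individual
operators for testing and experimentation.

The kymograph is sampled every `dt_out` on a fixed lab-frame raster
spanning the maximally swollen domain, by linear interpolation of the
total-invader lab concentration (u + M_arr + M_sw per cell volume) from
cell centres.  The internal macro step defaults to `t_end/8000`, which
resolves the per-cell front transit time by a factor ~50 at the default
presets.

## Default parameters

The canonical presets live in YAML config files
(`src/balwave/presets/*.yaml`), not in code.  Anchors taken from the
experimental system: `m_total` = 1 mM, `u_res` = 1 µM, `f_swell` = 4,
`D1` = 10 µm²/s with `D1/D0` = 1e4, θ = 0.5 (threshold on the swollen
*fraction*, so behaviour is invariant to rescaling `m_total`).

The rate constants are not experimentally pinned; they control the model
through the layer scales discussed above, and the defaults are chosen so
that a finite-volume simulation can actually resolve those scales:

* `k_bind` = 0.1 1/(µM·s) (1e5 1/(M·s), near the diffusion-limited scale):
  the binding zone `sqrt(D0/(k_bind·m_total))` ≈ 3 nm is then effectively
  sharp — binding is flux-limited at the front, and the peak saturates at
  the compact barcode concentration.
* `k_swell` = 2e-6 1/s (wave preset): the gap layer Δ ≈ 0.2–0.7 µm across
  the concentration sweep spans tens of grid cells, while the relaxation
  tail (~3·v/k_swell in the lab frame) still fits inside the invaded
  region so the plateau I_0 is well defined.  Truly molecular-scale rates
  would shrink these layers below any affordable grid spacing; since only
  regimes and scaling laws are physically constrained, the rates are set
  by this separation-of-scales requirement.
* `L` = 12 µm, `n_cells` = 1920 (wave preset): the slab holds ~20 gap
  layers, giving a long steady-front window; cell width 6.25 nm… in lab
  units 0.00625 µm, about 1/30 of the smallest measured front width.
* Ballistic-front preset: `k_swell` = 3e-2 (τ_θ ≈ 23 s) — freshly bound
  material dynamizes within a fraction of a cell transit, so the gap layer
  collapses below the grid scale by design and the peak vanishes; a
  coarser grid (640 cells) suffices.
* Fickian preset: `D1 = D0`, `k_swell` = 3e-3.  Fast swelling reflects the
  experimental Fickian condition (low ionic strength, condensates already
  dynamic); with the wave preset's slow swelling a same-D run would carry a
  compact bound peak, which the Fickian regime does not show, and the
  second time scale biases the measured exponent.

Observation horizons: preset `t_end` values let the front consume ~70% of
the slab.  For parameter sweeps and phase scans, per-run horizons come
from `estimate_invasion_time`, a closed-form crossing-time estimate
(gap-layer speed, grid-limited speed, or the Fickian moving-boundary law,
targeting 75% depth), fixed before any measurement.

## Analysis conventions

* **Front position.** `peak`: position of the intensity maximum (ties
  toward the outermost coordinate); `half_rise`: outermost crossing of the
  mid level between the profile extremes, linearly interpolated.  Both are
  invariant to affine intensity rescaling.  Kymographs place the invasion
  origin at coordinate 0, fronts move to larger coordinates; the origin is
  an explicit field.
* **Front width W.** FWHM of the peak relative to the lowest intensity
  behind it (the swollen plateau; ~zero for an isolated bump) in the wave
  regime; the 16–84% rise distance for peak-free profiles.
* **Peak ratio I_p/I_0.** Peak maximum over the median of the 10% of
  positions immediately behind the peak.  When the relaxation tail is very
  long this local band overlies partially swollen material and biases I_0
  upward; sweeps probing the k_swell dependence therefore start at 10× the
  wave preset's rate, where the band is a clean plateau.
* **Kinetic fits.** α is the least-squares slope of log X vs log t; v the
  linear slope of X vs t (insensitive to the start-up offset of the wave).
  The default window excludes the final 20% of frames (end-stage front
  interference); steady-state measurements on simulated waves use
  0.35–0.85 of the run to also exclude the establishment transient
  (~2 τ_θ), during which the gap layer relaxes from its initial overshoot
  — the fitted α of a wave run is consequently a few percent above 1.
* **Regime taxonomy.** fickian if α < 0.7; else ballistic_wave if the
  median peak ratio ≥ 1.2, else ballistic_front (thresholds configurable).
* **FRAP.** Half-recovery midpoint between the post-bleach floor and the
  plateau (median of the final 10% of frames), linear interpolation, first
  crossing wins; an immobile fraction therefore does not distort t_1/2.
  Records recovering by less than 5% (relative) or never reaching the
  midpoint within 6000 s are arrested and report t_1/2 = 6000 s.
* **Phasor.** Both integrals run over the full period (midpoint rule on
  uniform bins); the transform is count-rescaling invariant, mixtures are
  exactly count-weighted convex combinations, and mono-exponential decays
  sit on the universal semicircle to discretization accuracy.

## Synthetic data: what it does and does not emulate

The generators reproduce the *functional forms* the analyses assume —
erfc invasion profiles, self-similar traveling fronts with a Gaussian
peak, exponential FRAP recovery with immobile fractions and global
acquisition bleaching, Gaussian point-bleach spreading, periodically
folded exponential decays with exact multinomial counting statistics —
plus multiplicative Gaussian noise for camera-type recordings.  They do
not emulate optics (PSF, z-drift, refocusing), segmentation, motion of
condensates, detector afterpulsing or instrument response functions.
Passing closed-loop tests therefore validates the estimators and their
numerical conventions, not robustness to those instrumental effects.

## Limitations

* 1D only; the radial geometry is a qualitative device (its kymograph uses
  depth from the maximal outer radius so the raster stays fixed, folding
  boundary growth into the displacement).  2D/3D effects such as
  late-stage front interference are only mirrored by the fit-window
  convention.
* Material expansion does not advect the free invader (the grid expands,
  amounts stay in their cells); whether the physical system couples
  swelling into an advective flux is unknown, and at the default dilution
  the correction is small.
* No interfacial partition coefficient at the condensate boundary: the
  reservoir concentration applies directly (Dirichlet), appropriate for a
  large bath (condensates ~100× diluted).
* The measured wave exponents inherit small, documented numerical biases:
  α ≈ 1.04 (start-up offset), v–concentration exponent 0.48, W–v exponent
  0.88 (front-tip smearing at the grid scale); all converge toward the
  ideal values with grid refinement.
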