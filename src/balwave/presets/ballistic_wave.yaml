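# Canonical ballistic-wave regime: large diffusivity contrast, near
# diffusion-limited binding and slow swelling. A sharp front carrying a
# high-intensity bound-invader peak propagates at constant velocity; behind
# it the material relaxes to the swollen, fourfold-diluted state. The grid
# resolves the bound-but-not-yet-swollen gap layer (~0.2 um at 1 uM invader)
# that sets the front speed and width.
D0: 1.0e-3        # um^2/s, arrested-region invader diffusivity
D1: 10.0          # um^2/s, swollen-region invader diffusivity (D1/D0 = 1e4)
k_bind: 1.0e-1    # 1/(uM s), irreversible invader-barcode binding
k_swell: 2.0e-6   # 1/s, arrested->swollen conversion of the bound complex
f_swell: 4.0      # fourfold volumetric swelling of converted material
theta: 0.5        # swollen-fraction threshold for the D0 -> D1 switch
m_total: 1.0      # mM, barcode concentration in the arrested condensate
u_res: 1.0        # uM, reservoir invader concentration
L: 12.0           # um, slab depth
n_cells: 1920
geometry: cartesian_1d
t_end: 7.0e+6     # s; front consumes ~70% of the slab
dt_out: 3.5e+4    # s; 200 kymograph frames
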