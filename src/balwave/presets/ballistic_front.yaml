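# Canonical ballistic-front regime: same diffusivity contrast as the wave
# preset but four orders of magnitude faster swelling. Freshly bound material
# dynamizes almost immediately, so the high-intensity peak vanishes while the
# front stays sharp and still propagates linearly with time. The swelling gap
# layer collapses below the grid scale, so no fine grid is needed.
D0: 1.0e-3
D1: 10.0
k_bind: 1.0e-1
k_swell: 3.0e-2
f_swell: 4.0
theta: 0.5
m_total: 1.0
u_res: 1.0
L: 12.0
n_cells: 640
geometry: cartesian_1d
t_end: 1.1e+5
dt_out: 5.5e+2
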