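# Canonical Fickian regime: no diffusivity contrast (D1 = D0) and fast
# swelling. Experimentally this is the low-ionic-strength condition where the
# condensate is already dynamic, so the arrested-to-swollen conversion is not
# rate limiting: binding still occurs but transport shows the classical
# blurry front, no high-intensity peak, and displacement ~ sqrt(t).
D0: 1.0e-3
D1: 1.0e-3
k_bind: 1.0e-1
k_swell: 3.0e-3
f_swell: 4.0
theta: 0.5
m_total: 1.0
u_res: 1.0
L: 12.0
n_cells: 640
geometry: cartesian_1d
t_end: 4.0e+7
dt_out: 2.0e+5
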