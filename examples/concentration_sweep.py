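"""Scaling laws of the ballistic wave: v ~ sqrt([invader]) and v ~ W.

Sweeps the reservoir invader concentration from 0.5 to 8 uM, measures the
steady front velocity and width of each run, and fits the two power laws
the model predicts: velocity grows as the square root of the invader
concentration, and velocity is linearly correlated with front width.
"""

import numpy as np

import balwave as bw

base = bw.load_preset("ballistic_wave")
concentrations = (0.5, 1.0, 2.0, 4.0, 8.0)  # uM

velocities, widths = [], []
for u in concentrations:
    t_end = bw.estimate_invasion_time(base.replace(u_res=u))
    p = base.replace(u_res=u, t_end=t_end, dt_out=t_end / 200.0)
    res = bw.simulate_invasion(p)
    tr = bw.front_trace(res.kymograph, convention="peak",
                        fit_window=(0.35 * t_end, 0.85 * t_end))
    sel = np.isfinite(tr.W) & (tr.t >= 0.35 * t_end) & (tr.t <= 0.85 * t_end)
    velocities.append(tr.v)
    widths.append(float(np.median(tr.W[sel])))
    print(f"[m*] = {u:4.1f} uM   v = {tr.v:.3e} um/s   W = {widths[-1]:.3f} um")

e_v, _, r2_v = bw.scaling_law_fit(concentrations, velocities)
e_w, _, r2_w = bw.scaling_law_fit(velocities, widths)
print(f"\nv ~ [m*]^p : p = {e_v:.3f}  (r^2 = {r2_v:.4f}; sqrt law predicts 0.5)")
print(f"W ~ v^q    : q = {e_w:.3f}  (r^2 = {r2_w:.4f}; linear correlation ~1)")
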