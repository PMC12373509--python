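"""FLIM phasor analysis: separating arrested and invaded regions.

In-chain fluorophores report the local chain environment: lifetimes of
~2.9 ns in the arrested region versus ~3.4 ns in the swollen, invaded
region.  Photon decays are transformed to phasor coordinates; pure
mono-exponential decays fall on the universal semicircle, and circular
cursors separate the two populations.
"""

import math

import balwave as bw

T = 25.0  # ns acquisition period


def semicircle_point(tau):
    w = 2 * math.pi / T
    return 1 / (1 + (w * tau) ** 2), w * tau / (1 + (w * tau) ** 2)


points, labels_true = [], []
for k, tau in enumerate((2.9, 3.4)):
    for i in range(10):
        decay, _ = bw.gen_decay([tau], [1.0], T=T, total_counts=50_000,
                                seed=10 * k + i)
        out = bw.analyze_decay(decay)
        points.append((out["g"], out["s"]))
        labels_true.append(k)
    print(f"tau = {tau} ns population: last phasor g={out['g']:.3f} "
          f"s={out['s']:.3f} -> lifetime readout {out['tau_ns']:.2f} ns")

cursors = [(g, s, 0.01) for g, s in (semicircle_point(2.9), semicircle_point(3.4))]
labels = bw.phasor_segment(points, cursors)
agree = sum(int(a == b) for a, b in zip(labels, labels_true))
print(f"cursor segmentation: {agree}/{len(labels)} points assigned to the "
      "correct lifetime population")
# Two well-separated distributions on the semicircle mirror the arrested
# vs invaded regions of a condensate imaged during invasion.
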