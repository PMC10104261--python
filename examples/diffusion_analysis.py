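"""Blur-corrected single-molecule diffusion analysis.

Simulates a 50/50 mixture of slow (condensed) and fast (cytoplasmic)
molecules with within-frame motion blur, fits each trajectory's
time-averaged MSD with the blur-corrected law
MSD = 4 D (tau - dt/3) + 4 sigma^2 (which reduces to (8/3) D dt + 4
sigma^2 at a one-frame lag), and summarizes the per-track log10 D values
with a two-state Gaussian mixture.
"""

import numpy as np

from condenscan import motion, simkit

DT = 0.040  # 40 ms per frame

# the motion-blur law itself: ensemble MSD at one-frame lag vs D*dt
ens = simkit.simulate_free_diffusion_ensemble(5000, 1.0, DT, n_frames=11,
                                              rng=1)
disp = ens.blurred[:, 1:, :] - ens.blurred[:, :-1, :]
ratio = np.mean(np.sum(disp**2, axis=2)) / DT
print(f"MSD(one frame)/(D dt) = {ratio:.3f}  (8/3 = 2.667: frame "
      "averaging shrinks the apparent one-frame MSD by a third)")

log_d = []
for D in (0.05, 1.0):
    tracks = simkit.simulate_free_diffusion_ensemble(
        1500, D, DT, n_frames=21, loc_precision=0.02, rng=int(100 * D))
    for tr in tracks.observed:
        fit = motion.fit_msd(tr, DT)         # lags 40-200 ms, R^2 >= 0.7
        if fit.accepted and fit.D_app > 0:
            log_d.append(np.log10(fit.D_app))

mix = motion.fit_mixture(np.array(log_d), seed=0)
for name, mean, sd, w in zip(("slow", "fast"), mix.means, mix.sds,
                             mix.weights):
    print(f"{name} state: D_app = {10**mean:.3f} um^2/s "
          f"(log10 spread {sd:.2f}), weight {w:.2f}")
print("the slow state maps to molecules inside the dense phase, the fast "
      "state to free cytoplasmic diffusion")
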