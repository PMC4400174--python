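"""Full-range reconstruction of simulated point-scatterer fringes.

Builds a calibration with a nonlinear wavenumber sampling map and quadratic
dispersion, synthesizes fringes for scatterers at positive and negative
depths (the frequency-shift carrier separates the two — "full-range"
imaging), reconstructs each A-line, and prints recovered vs true depth.
"""

import numpy as np

from ivoct import (
    AcquisitionConfig,
    ScattererSpec,
    demodulate_fullrange,
    depth_profile_db,
    linearize_and_compensate,
    make_calibration,
    preprocess_fringe,
    simulate_pullback_fringes,
)

depths = [-90, -40, 0, 25, 70]
cfg = AcquisitionConfig(n_samples=400, n_alines=2, n_channels=2, n_frames=len(depths))
cal = make_calibration(cfg, k_nonlinearity=0.12, dispersion_coeffs=(0.0, 0.0, 20.0), seed=0)
scatterers = [[ScattererSpec(depth_px=d, amplitude=1200.0)] for d in depths]
raw = simulate_pullback_fringes(scatterers, cal, cfg, noise_sd=1.0, seed=0)

print("true depth -> recovered depth (pixels; negative = mirror side of zero delay)")
for i, d in enumerate(depths):
    pre = preprocess_fringe(raw.samples[i, 0, 0], cal, channel=0)
    fringe = linearize_and_compensate(demodulate_fullrange(pre), cal)
    profile = depth_profile_db(fringe)
    found = int(np.argmax(profile)) - cfg.demod_length // 2
    print(f"  {d:4d} -> {found:4d}   (peak {profile.max():.1f} dB)")
print("A mismatch of 0-1 px means k-linearization and dispersion compensation undo")
print("the nonlinear sweep exactly; without them the peaks would smear and shift.")
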