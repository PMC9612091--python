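"""Demodulate a rendered three-phase stack and calibrate it to reflectance.

Builds a homogeneous 90/10 water/lipid scene, renders a noiseless
acquisition at 950 nm, and walks the first processing stage by hand.
"""

import numpy as np

from sfdikit import (AcquisitionSpec, calibrate, demodulate_ac, demodulate_dc,
                     make_scene, rd_forward, reference_phantom_properties,
                     render_stack)

scene = make_scene("homogeneous", water=90.0, lipid=10.0, shape=(32, 32))
acq = AcquisitionSpec(noise_sd=0.0, wavelengths=(950.0,))
sample, ref = render_stack(scene, acq)

wl, fx = 950.0, 0.2
amp_s = demodulate_ac(*(sample.frame(wl, fx, p)
                        for p in ("phase0", "phase120", "phase240")))
amp_r = demodulate_ac(*(ref.frame(wl, fx, p)
                        for p in ("phase0", "phase120", "phase240")))
dc_s = demodulate_dc(sample.frame(wl, 0.0, "white"), sample.frame(wl, 0.0, "black"))

ref_mu_a, ref_mu_s = reference_phantom_properties(np.array([wl]))
rd_pred = rd_forward(ref_mu_a[0], ref_mu_s[0], fx)
rd = calibrate(amp_s, amp_r, rd_pred)

mu_a, mu_s = scene.optical_properties(wl)
truth = rd_forward(mu_a, mu_s, fx)
print(f"demodulated AC amplitude (sample): {amp_s.mean():.3f} counts")
print(f"calibrated Rd at fx={fx} mm^-1:    {rd.mean():.6f}")
print(f"forward-model ground truth:        {truth.mean():.6f}")
print("-> calibration recovers the scene's diffuse reflectance exactly "
      "in the noiseless limit; the camera gain cancels in the ratio.")
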