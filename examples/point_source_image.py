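"""Image a 208 keV point source 1 m from the six-crystal CaF2 detector.

Simulates twofold Compton coincidences, reconstructs the sky map with the
conventional and the image-sharpening ring kernels, calibrates the intensity
scale k, and prints the evaluation indices.
"""

import rotcam as rc

det = rc.build_detector(W=10.0, material="CaF2")
run = rc.simulate_point_source(det, energy=208.0, distance_cm=100.0,
                               target_ordered=4000, seed=1)

print(f"emitted photons (effective isotropic): {run.c0_effective:.3g}")
print(f"events after photopeak cut:            {run.counts['adc']}")
print(f"absolute sensitivity:                  {run.sensitivity:.3g}")
eff = rc.detection_efficiency(run.sensitivity, 0.11)
print(f"detection efficiency (208 keV, 177Lu): {eff:.2f} cps/MBq")

# sharpening kernel with calibrated intensity scale: the peak reads in events
k = rc.calibrate_k(run.ordered, det)
sharp = rc.backproject(run.ordered, det, rc.KernelConfig("sharpening", 8.0, k))
peak, az, el = sharp.peak()
p, sigma = rc.angular_resolution(sharp, 0.0, 0.0)
print(f"\nsharpening map: peak {peak:.0f} (= projected events) "
      f"at azimuth {az:.0f} deg, elevation {el:.0f} deg")
print(f"angular resolution sigma = {sigma:.1f} deg, CNR = {rc.cnr(sharp):.1f}")

conv = rc.backproject(run.ordered, det, rc.KernelConfig("conventional", 8.0))
_, sigma_c = rc.angular_resolution(conv, 0.0, 0.0)
print(f"conventional map: sigma = {sigma_c:.1f} deg, CNR = {rc.cnr(conv):.1f}")
print("\nThe sharpening kernel drives the background to ~zero and sharpens the")
print("peak; the conventional kernel is broader but fastest to show a hotspot.")
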