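"""Measure SUVmax / SUVmean / SUVpeak of a lesion on a synthetic phantom.

Builds a uniform-background uptake volume on a clinical PET grid
(1.5 x 1.5 x 5.0 mm voxels), paints a hot spherical lesion, converts the
volume from activity concentration to body-weight SUV with radioactive
decay correction, and quantifies a spherical VOI placed over the lesion.
"""

from petln import ScanContext, SphereVOI, make_phantom, suv_max, suv_mean, suv_normalize, suv_peak

# 20 mm lesion at 12 kBq/mL on a 3 kBq/mL background
lesion = SphereVOI(center_mm=(24.0, 24.0, 40.0), diameter_mm=20.0, name="node")
volume = make_phantom(dims=(33, 33, 17), background=3.0,
                      lesions=[(lesion, 12.0)], units="kBq_per_ml")

# 236 MBq F-18-FDG, 75 kg patient, scanned 56 min after injection
ctx = ScanContext(injected_activity_mbq=236.0, body_weight_kg=75.0,
                  minutes_injection_to_scan=56.0)
suv_volume = suv_normalize(volume, ctx)

voi = SphereVOI(center_mm=(24.0, 24.0, 40.0), diameter_mm=30.0, name="node VOI")
print(f"SUVmax  = {suv_max(suv_volume, voi):.3f}")
print(f"SUVmean = {suv_mean(suv_volume, voi):.3f}")
print(f"SUVpeak = {suv_peak(suv_volume, voi):.3f}")

# SUVmax is the hottest voxel (the lesion value after SUV scaling);
# SUVmean averages the whole VOI including background, so it is lower;
# SUVpeak averages the best-placed 1.0 mL sphere — here it equals SUVmax
# because the sphere fits wholly inside the uniform lesion; on noisy or
# smaller lesions it falls between SUVmean and SUVmax.
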