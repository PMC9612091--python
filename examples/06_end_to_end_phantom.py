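"""Full pipeline on a rendered noisy phantom: frames to concentration maps.

Renders a homogeneous 85/15 water/lipid phantom with default camera noise,
runs demodulation, calibration, optical-property inversion and Beer's-law
unmixing, and reports ROI statistics against the ground truth.
"""

from sfdikit import AcquisitionSpec, build_lut, make_scene, render_stack
from sfdikit.pipeline import process_stack_pair

scene = make_scene("homogeneous", water=85.0, lipid=15.0, shape=(48, 48))
sample, ref = render_stack(scene, AcquisitionSpec(), seed=1)

result = process_stack_pair(sample, ref, build_lut(),
                            rois=[{"center": (24, 24), "diameter_mm": 2.0}])
print(result.roi_report.to_string(index=False))
print(f"out-of-range pixels: {int(result.out_of_range.sum())}")
print("-> ROI means recover the 85/15 recipe within fractions of a "
      "percentage point; per-pixel noise averages out over the region.")
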