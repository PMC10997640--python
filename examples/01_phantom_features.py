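"""Segment a sphere phantom and extract the twelve PET parameters.

Builds a noise-free digitized sphere of radius 20 mm (plateau SUV 10 on a
0.5 background) at 1 mm voxels, segments it at 41% of SUVmax and prints
the feature panel next to the closed-form values a perfect sphere would
give (V = 4/3·π·r³, S = 4π·r², TVSR = r/3, medPCD = r, diameter = 2r).
"""

from flpet import LesionSpec, PhantomSpec, feature_panel, make_phantom, segment_lesions, sphere_expectations

spec = PhantomSpec(
    shape=(56, 56, 56),
    spacing=(1.0, 1.0, 1.0),
    background_suv=0.5,
    noise_sd=0.0,
    lesions=[LesionSpec(shape="sphere", center_mm=(27, 27, 27), size_mm=20.0, peak_suv=10.0)],
)
vol, truth, _ = make_phantom(spec)
mask, lesions = segment_lesions(vol)
panel = feature_panel(vol, lesions)

analytic = sphere_expectations(20.0)
print(f"{'parameter':<14}{'computed':>10}{'analytic':>10}")
for name, value in panel.as_dict().items():
    ref = analytic.get(name, "")
    ref = f"{ref:.2f}" if isinstance(ref, float) else str(ref)
    print(f"{name:<14}{value:>10.2f}{ref:>10}")
print("\nSmall deviations from the analytic column are voxelization error "
      "at 1 mm spacing; they shrink as the grid is refined.")
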