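"""Generate a synthetic polymetastatic patient and inspect its ground truth.

The phantom is a body cylinder with a liver reference region (SUV mean 1.0,
sd 0.2) and well-separated hyperintense lesions; it stands in for the
FDG-PET/CT of a patient with widespread metastatic disease.
"""

from ldrtplan.phantom import generate_phantom
from ldrtplan.presets import polymetastatic_spec

spec = polymetastatic_spec(n_lesions=15, seed=1)
phantom = generate_phantom(spec)

print(f"grid: {phantom.grid.shape} voxels at {phantom.grid.spacing} mm")
print(f"body volume:  {phantom.external_mask.volume_cc:8.0f} cc")
print(f"liver volume: {phantom.liver_mask.volume_cc:8.0f} cc")
print(f"lesions: {len(phantom.truth_lesions)}")
for lesion in phantom.truth_lesions[:3]:
    print(f"  {lesion.id}: center z={lesion.center[2]:6.1f} mm, "
          f"volume {lesion.volume_cc():5.2f} cc, SUV {lesion.suv_level:.1f}")
print("  ...")
# Each lesion record is the ground truth that segmentation and adaptation
# are later checked against.
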