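"""Generate a small labeled phantom cohort and inspect its dimorphism.

Builds 10 synthetic head volumes (5 per sex) whose two-lobed air cavity is
on average 1.5x larger in the male class, writes them as NIfTI plus a CSV
manifest, and prints the per-class cavity statistics.
"""

import tempfile
from pathlib import Path

import sdetnet as sd

out = Path(tempfile.mkdtemp()) / "cohort"
spec = sd.PhantomSpec.tiny(dimorphism_factor=1.5, seed=0)
manifest = sd.generate_cohort(spec, n_male=5, n_female=5, out_dir=out)

print(manifest[["subject_id", "sex", "cavity_voxels", "major_axis", "split"]])
by_sex = manifest.groupby("sex")["cavity_voxels"].mean()
print(f"\nmean cavity volume  female: {by_sex[0]:.0f} vx   male: {by_sex[1]:.0f} vx")
print(f"empirical male/female ratio: {by_sex[1] / by_sex[0]:.2f} "
      f"(generative factor {spec.dimorphism_factor})")
# At n=5 per class the ratio is noisy; it converges to the factor as the
# cohort grows (see the Monte-Carlo test in the test suite).
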