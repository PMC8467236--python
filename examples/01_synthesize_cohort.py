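"""Generate a small labeled synthetic EEG cohort and export it as EDF.

The generator sums band-limited Gaussian noise with class-specific relative
band powers: the "apnea-like" profile is delta/theta heavy, the "normal"
profile alpha/beta heavy. The exported directory holds one EDF per subject
plus a labels.csv sidecar, so it can be fed straight back into the pipeline.
"""

import tempfile
from pathlib import Path

from apneabands import CohortSpec, export_cohort_edf, generate_cohort

cohort = generate_cohort(CohortSpec(n_per_class=3, seed=7))
out = export_cohort_edf(cohort, Path(tempfile.mkdtemp()) / "cohort")

print(f"wrote {len(cohort)} recordings to {out}")
for rec in cohort:
    print(f"  {rec.subject_id:12s} label={rec.label:6s} fs={rec.fs:.0f} Hz "
          f"duration={rec.duration_seconds:.0f} s")
print("labels sidecar:")
print((out / "labels.csv").read_text())
# Each line is one 30 s single-channel recording; the label column is the
# class the classifier will try to recover from the band features.
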