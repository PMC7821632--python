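"""Generate a small synthetic PD cohort and write it to disk.

Creates 3 male + 2 female subjects with UPDRS assessments at weeks
0/13/26 and weekly sessions of six sustained /ah:/ phonations, renders
the week-0 session to WAV files, and prints the cohort manifest.
"""

import tempfile
from pathlib import Path

from pdvoice import generate_cohort, write_cohort

cohort = generate_cohort(n_male=3, n_female=2, n_weeks=26, seed=42, link_strength=1.0)

print("subjects:")
for subj in cohort.subjects:
    traj = cohort.trajectories[subj.subject_id]
    print(f"  {subj.subject_id} ({subj.sex}, age {subj.age:.0f}): "
          f"motor-UPDRS {traj.motor_weekly[0]:.1f} -> {traj.motor_weekly[-1]:.1f} "
          f"over {subj.n_weeks} weeks")

out_dir = Path(tempfile.mkdtemp(prefix="pdvoice_cohort_"))
manifest = write_cohort(cohort, out_dir, weeks=(0,))
print(f"\nwrote {len(manifest)} week-0 phonations under {out_dir}")
print(manifest.head(8).to_string(index=False))
# Each row pairs one WAV file with its subject, session slot, loudness
# condition and the weekly UPDRS scores used as the regression target.
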