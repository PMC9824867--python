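"""Generate a small synthetic cohort and summarise its motion by class.

Draws 5 children per class with short stages, writes them to a JSON-lines
session file, and prints each class's mean per-frame joint speed for the
early (wait/game pairs 1-2) versus late (pairs 3-5) segments.  Normal
children stay quiet throughout, ADHD children move strongly throughout,
and at-risk children move like normal children early but like ADHD
children late — the structure every downstream analysis builds on.
"""

import numpy as np

import stagescreen as ss
from stagescreen.data import EARLY_STAGES, LATE_STAGES, STAGES, Label

params = ss.default_params(
    class_counts=(5, 5, 5),
    length_range={s: (40, 80) for s in STAGES},
    seed=7,
)
sessions = ss.simulate_dataset(params)
ss.write_sessions(sessions, "cohort.jsonl")
print(f"wrote {len(sessions)} sessions to cohort.jsonl\n")


def mean_speed(session, stages):
    return np.mean(
        [np.abs(np.diff(session.stages[s].coords, axis=0)).mean() for s in stages]
    )


print(f"{'class':<10}{'early m/frame':>16}{'late m/frame':>16}")
for lab in Label:
    members = [s for s in sessions if s.label is lab]
    early = np.mean([mean_speed(s, EARLY_STAGES) for s in members])
    late = np.mean([mean_speed(s, LATE_STAGES) for s in members])
    print(f"{lab.value:<10}{early:>16.4f}{late:>16.4f}")

print(
    "\nThe at-risk row is the signature: early motion at the normal level,"
    "\nlate motion approaching the ADHD level."
)
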