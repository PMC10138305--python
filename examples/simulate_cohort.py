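"""Generate a small synthetic cohort and inspect its structure.

Builds 3 stuttering (CWS) and 3 non-stuttering (CWNS) children with a 60 s
resting baseline and a 110 s speaking task each, then prints how many 20 s
detection windows the cohort yields and where the class-indicative patterns
were planted.  The pattern onsets are ground truth that exists only in
simulation — real recordings carry bag labels alone.
"""

from mimil import SynthConfig, generate_cohort

cfg = SynthConfig(
    n_subjects_per_group=3,
    seed=7,
    baseline_duration_s=60.0,
    task_duration_s=110.0,
)
recordings, truth = generate_cohort(cfg)

print(f"cohort: {len(recordings)} recordings, "
      f"{recordings[0].duration_s:.0f} s each at {cfg.sample_rate:.0f} Hz")
for rec in recordings[:2]:
    windows = truth.for_participant(rec.participant_id)
    n_patterns = sum(len(w.patterns) for w in windows)
    print(f"  {rec.participant_id} ({rec.group}): {len(windows)} task windows, "
          f"{n_patterns} class patterns")
    for w in windows[:2]:
        for p in w.patterns:
            print(f"    window@{w.window_start_s:.0f}s: {p.kind} in {p.modality} "
                  f"at +{p.onset_s:.1f}s for {p.duration_s:.1f}s")

# Each CWS task window hides at least one 2-5 s motif in at least one
# modality; CWNS windows carry only class-neutral spontaneous fluctuations.
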