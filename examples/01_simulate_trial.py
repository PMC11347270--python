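"""Generate a synthetic two-arm trial and look at its structure.

Builds the default cohort (1000 participants, trabeculectomy vs medication,
5 annual visits), prints arm sizes, baseline severity and how many eyes
progressed — the raw material every later stage consumes.
"""

import glaucoma_cea as g

config = g.TrialConfig(rng_seed=1)
records = g.generate_trial(config)

baseline = records[records["visit_year"] == 0]
final = records[records["visit_year"] == config.followup_years]

print(f"visit records: {len(records)} ({config.n_participants} participants)")
print("\narm sizes at baseline:")
print(baseline["arm"].value_counts().to_string())
print("\nindex-eye severity at baseline (every index eye enters at advanced disease or worse):")
print(baseline["index_eye_state"].value_counts(normalize=True).round(3).to_string())
print(f"\nalive at year {config.followup_years}: {final['alive'].sum()} "
      f"of {config.n_participants}")

base_states = baseline.set_index("participant_id")["index_eye_state"]
final_states = final.set_index("participant_id")["index_eye_state"]
progressed = final_states != base_states.reindex(final_states.index)
print(f"index eyes that progressed at least one level: {progressed.mean():.1%}")
print("\nMedication-arm eyes progress faster (annual hazard 0.10 vs 0.06), which is")
print("what the downstream model turns into a QALY difference between the arms.")
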