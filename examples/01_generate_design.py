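"""Generate a randomized partial-profile design and inspect its balance.

Builds two versions of an 18-task instrument over the built-in 14
attributes (3 alternatives per task, each described by 3 attributes with
no within-attribute level overlap), attaches the two fixed holdout
tasks, and tallies level exposure.
"""

from partworth import (
    DesignConfig,
    attach_holdouts,
    design_balance_report,
    ebp_preset,
    generate_design,
    generate_holdout_tasks,
)

attributes, _, _ = ebp_preset()
config = DesignConfig(
    n_versions=2,
    tasks_per_version=18,
    alternatives_per_task=3,
    attributes_per_task=3,
    holdout_positions=(6, 14),
    seed=7,
)

design = generate_design(attributes, config)
holdouts = generate_holdout_tasks(attributes, config)
sequence = attach_holdouts(design[1], holdouts, config.holdout_positions)

print(f"version 1: {len(sequence)} tasks "
      f"({sum(t.is_holdout for t in sequence)} holdouts at positions "
      f"{[t.position for t in sequence if t.is_holdout]})")
task = sequence[0]
print(f"first task shows attributes {task.shown_attributes} with level grid:")
print(task.level_assignment)  # rows = alternatives; no level repeats per column

report = design_balance_report(design, attributes)
print("\nlevel exposure counts (rows: attributes, columns: levels 1-4):")
print(report["levels"].to_string())
# Each attribute appears in ~18*3*2/14 tasks across the two versions and its
# four levels are shown near-equally often: the design is level-balanced.
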