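"""Simulate an online-adaptive session: scheduled vs. adapted plan.

The day-of anatomy moves one lesion 15 mm superiorly (beyond the 1 cm PTV
margin), grows another by 60%, and removes a third.  The scheduled plan is
the initial dose frozen in room coordinates; the adapted plan re-conforms
the dose to the day-of structures.
"""

from ldrtplan.adaptive import build_initial_plan, run_session
from ldrtplan.phantom import AnatomyChangeSpec, LesionChange, apply_anatomy_change, generate_phantom
from ldrtplan.presets import polymetastatic_spec

phantom = generate_phantom(polymetastatic_spec(n_lesions=6, seed=3, noise=False))
bundle = build_initial_plan(phantom)

ids = [l.id for l in phantom.truth_lesions]
change = AnatomyChangeSpec(per_lesion_changes={
    ids[0]: LesionChange(shift=(0.0, 0.0, 15.0)),   # movement
    ids[1]: LesionChange(scale=1.6),                # progression
    ids[2]: LesionChange(scale=0.0),                # complete regression
})
day = apply_anatomy_change(phantom, change)
session = run_session(bundle, day, change_spec=change)

for label, ev in (("reference", session.reference_eval),
                  ("scheduled", session.scheduled_eval),
                  ("adapted", session.adapted_eval)):
    print(f"{label:9s}: P1 goals passed {ev.passed('P1')}/{ev.n_goals('P1')}, "
          f"R50%={ev.r50:.2f}, D2cm={ev.d2cm:.1f}%")
print(f"scheduled available: {session.scheduled_available} "
      f"({session.availability_reason})")
print(f"selected: {session.selected} -- {session.rationale}")
# The moved and grown targets fail coverage under the frozen scheduled dose;
# the adapted plan re-covers them and drops the vanished target's goals, so
# it passes strictly more P1 goals and is selected.
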