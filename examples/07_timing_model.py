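"""Fit the adaptive-workflow duration model and predict a treatment slot.

Each workflow step (influencer/target generation and editing, plan
generation) is modelled as an ordinary least-squares line in the number of
targets; the total-duration model is the sum of the step models.
"""

from ldrtplan.adaptive import (
    WORKFLOW_STEPS,
    fit_timing_model,
    generate_timing_records,
    predict_session_duration,
)

records = generate_timing_records(n_records=24, seed=0)
model = fit_timing_model(records)

print(f"{'step':22s} {'slope s/target':>15s} {'intercept s':>12s} {'r^2':>6s}")
for step in WORKFLOW_STEPS:
    f = model.steps[step]
    print(f"{step:22s} {f.slope:15.1f} {f.intercept:12.0f} {f.r_squared:6.2f}")
f = model.total
print(f"{'total':22s} {f.slope:15.1f} {f.intercept:12.0f} {f.r_squared:6.2f}")

for n in (5, 15, 30):
    pred = predict_session_duration(model, n)
    print(f"predicted session for {n:2d} targets: {pred['total'] / 60:5.1f} min")
# Generation/editing of influencer organs is nearly flat in target count;
# target editing dominates the growth, so the slot length scales with the
# patient's lesion burden.
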