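"""Plan and execute one dot-probe training session headlessly.

Builds the 4x50-trial plan (probe always on an approach/positive-or-neutral
stimulus), runs it with a simulated responder that errs on 5% of trials,
and prints the per-block feedback a participant would see plus the
tutorial gate decision.
"""

import numpy as np

from steptrain import (
    block_summary,
    build_session_plan,
    classify_for_training,
    make_inventory,
    run_session,
    tutorial_gate,
)

part = classify_for_training(make_inventory("demo"))
plan = build_session_plan(part.probe_targets, part.distractors, seed=7)
print(f"plan: {len(plan)} trials in 4 blocks")

rng = np.random.default_rng(7)


def responder(spec):
    rt = 2400 + rng.normal(0, 150) + rng.exponential(300) - 300
    if rng.random() < 0.05:  # occasional lapse
        return ("left" if spec.probe_side == "right" else "right"), rt
    return spec.probe_side, rt


log = run_session(plan, responder, participant_id="demo", session_index=1)
for i, block in enumerate(log.blocks, 1):
    s = block_summary(block)
    print(f"block {i}: mean RT {s.mean_rt_ms:.0f} ms, accuracy {s.accuracy:.0%}")

gate = tutorial_gate(log)
print(f"session accuracy {log.accuracy:.0%} -> tutorial gate: {'PASS' if gate.passed else 'FAIL'}")
# The gate requires >= 80% accuracy; feedback (the audible alert) fires only
# on the incorrect trials recorded in the log.
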