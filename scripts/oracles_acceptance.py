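"""Brute-force availability oracle used by the acceptance script.

Independent of the package's model helpers: states are recomputed from the
raw activity-id and edge lists alone.
"""

from __future__ import annotations


def state_oracle(activity_ids, edges, executed):
    states = {}
    for act in activity_ids:
        if act in executed:
            states[act] = "executed"
            continue
        preds = [f for (f, t) in edges if t == act]
        if not preds or any(p in executed for p in preds):
            states[act] = "available"
        else:
            states[act] = "locked"
    return states
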