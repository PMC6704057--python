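"""Vary the step-input magnitude u over the standard 0.025-0.15 range.

The gains and the input magnitude enter the linear stage only through the
product K*u, so sweeping u doubles as a sweep of the gain.
"""

import numpy as np

from memflex import CONTROL, KNOCKDOWN, builtin_protocol, sweep_input

proto = builtin_protocol("sequential-short")
u_values = np.linspace(0.025, 0.15, 6)
for params in (CONTROL, KNOCKDOWN):
    table = sweep_input(proto, params, u_values)
    task2 = table[table.event == "task2"]
    print(f"\n{params.label}: task-2 memory at test vs u")
    for _, row in task2.iterrows():
        print(f"  u={row.u:.3f}  memory={row.memory_at_test:.3f}")

# Control task-2 memory is insensitive to u (its have/need stays above 1),
# while knockdown interference deepens with stronger inputs: the larger the
# first experience's footprint, the less capacity remains.
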