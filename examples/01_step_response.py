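"""Step responses of the two signaling pathways for both genotypes.

A learning experience is a step input u into a fast memory-strengthening
pathway (tau1 = 0.5 h) and a slow memory-weakening one (tau2 = 36 h in
controls, 144 h without functional WT1).  Each pathway approaches its
steady state K*u exponentially.
"""

import numpy as np

from memflex import CONTROL, KNOCKDOWN, first_order_step, pathway_activity

for params in (CONTROL, KNOCKDOWN):
    print(f"\n{params.label}: tau1={params.tau1} h, tau2={params.tau2} h, "
          f"K={params.K1}, u={params.u_nominal}")
    for t in (0.5, 2.0, 24.0, 100.0):
        x1 = first_order_step(t, 0.0, params.tau1, params.K1, params.u_nominal)
        x2 = first_order_step(t, 0.0, params.tau2, params.K2, params.u_nominal)
        pa = pathway_activity(x1, x2)
        print(f"  t={t:6.1f} h  x1={x1:.4f}  x2={x2:.4f}  pathway_activity={pa:.4f}")

# x1 rises within the hour; x2 catches up over days and erodes the net
# activity — that erosion is the model's forgetting.  Removing WT1 slows
# x2 (144 h) and raises the gain, so activity stays high much longer.
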