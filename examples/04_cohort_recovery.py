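"""Generate a synthetic behavioral cohort and recover (K, tau2) from it.

Thirty animals per readout, 5 % Gaussian noise on a freezing scale.  The
design reads task 1 at +24 h and +48 h and task 2 at +24 h — the task-2
interference pins down the gain K, which a normalised single-task trace
cannot see.
"""

from memflex import KNOCKDOWN, ReadoutLink, builtin_protocol, generate_cohort, recover_parameters
from memflex.cohort import DEFAULT_READOUT_TIMES

proto = builtin_protocol("sequential-short")
link = ReadoutLink("freezing", noise_sd=5.0)
cohort = generate_cohort(proto, KNOCKDOWN, link, n=30, seed=11,
                         readout_times=DEFAULT_READOUT_TIMES)
print(cohort.groupby(["task", "time_h"])["readout_pct"].mean().round(1))

rec = recover_parameters(cohort, proto, link, template=KNOCKDOWN)
print(f"\ntruth:     K={KNOCKDOWN.K1}, tau2={KNOCKDOWN.tau2} h")
print(f"recovered: K={rec.best.K1}, tau2={rec.best.tau2} h "
      f"(identifiable={rec.identifiable})")

# With this design the grid search lands on (or next to) the true
# (K=7.2, tau2=144): the three cohort means over-determine the two unknowns.
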