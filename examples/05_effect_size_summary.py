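"""Which simulation factors drive power?  Eta-squared and paired-t r².

Runs a small balanced PCM grid crossing noise proportion, autocorrelation,
and the presence of a mini-reversal, then decomposes the variability of the
power estimates: one-way eta-squared per factor, the interaction
eta-squared of noise x autocorrelation, and the Fritz r² for the paired
reversal contrast.
"""

from ccdrand import (
    SimulationCondition,
    eta_squared_interaction,
    eta_squared_oneway,
    paired_t_r2,
    run_condition_grid,
)

conditions = [
    SimulationCondition(procedure="pcm", n_phases=4, m=16, pattern="uniform",
                        variability=v, phi=phi, reversal=rev, replications=400)
    for v in (0.10, 0.25, 0.50)
    for phi in (-0.3, 0.0, 0.3)
    for rev in (False, True)
]
grid = run_condition_grid(conditions, seed=2)

for factor in ("variability", "phi", "reversal"):
    print(f"eta^2[{factor:11s}] = {eta_squared_oneway(grid, factor):.3f}")
print(f"eta^2[variability x phi] = "
      f"{eta_squared_interaction(grid, 'variability', 'phi'):.3f}")

paired = grid.pivot_table(index=["variability", "phi"], columns="reversal", values="rate")
t, r2 = paired_t_r2(paired[True].to_numpy(), paired[False].to_numpy())
print(f"reversal benefit: paired t = {t:.2f} on {len(paired) - 1} df, r^2 = {r2:.3f}")
print(f"mean power gain from a mini-reversal: {(paired[True] - paired[False]).mean():+.3f}")
print()
print("the noise proportion dominates power (large eta^2); autocorrelation")
print("matters far less; reinstating a previous criterion level (reversal)")
print("adds power because mismatched assignments fit the kinked staircase badly.")
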