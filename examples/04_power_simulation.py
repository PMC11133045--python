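"""Type I error and power of both randomization tests by Monte Carlo.

Each condition simulates criterion-tracking (or flat, no-effect) series
with AR(1) errors whose scale is proportional to the criterion's elevation
above baseline, randomizes the actual assignment per replicate, applies the
test, and reports the rejection rate at alpha = .05 over 500 replicates
(1000 is the conventional choice; 500 keeps this demo fast).
"""

from ccdrand import SimulationCondition, run_condition_grid

conditions = [
    # power of BAC (10 phases x 3) across noise levels, positive autocorrelation
    SimulationCondition(procedure="bac", n_phases=10, phase_length=3,
                        phi=0.3, variability=v, replications=500)
    for v in (0.10, 0.25, 0.50)
] + [
    # power of PCM with the same 30 measurements in 5 phases
    SimulationCondition(procedure="pcm", n_phases=5, phase_length=6,
                        phi=0.3, variability=v, replications=500)
    for v in (0.10, 0.25)
] + [
    # type I error: flat data, criterion labels retained
    SimulationCondition(procedure="bac", n_phases=10, phase_length=3,
                        phi=0.0, variability=0.25, effect=False, replications=500),
    SimulationCondition(procedure="pcm", n_phases=4, phase_length=5,
                        phi=0.0, variability=0.25, effect=False,
                        replications=500, randomize_actual=True),
]

table = run_condition_grid(conditions, seed=11)
print(table[["procedure", "n_phases", "m", "variability", "phi", "effect",
             "n_randomizations", "rate", "se"]].to_string(index=False))
print()
print("'rate' is power for effect rows and the type I error rate for the two")
print("no-effect rows (it should sit at or below .05). With the same 30")
print("measurements, PCM's much larger randomization set buys more power")
print("than BAC; power falls as the noise proportion rises.")
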