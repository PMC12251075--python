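"""Run a full validation experiment on the infusion-line digital twin.

Simulates the step-change programme (saline/EG/TZ pumps at 7/3/3 mL/h for
15 min, then 3/7/3 for 20 min), three noisy trials, recovers the dye
concentrations from the simulated intensities, and prints the steady-state
accuracy and repeatability per phase.
"""

import flowspec as fs

result = fs.run_experiment("exp_b", n_trials=3, seed=0)

print("phase  dye  expected C/C0   mean C/C0   accuracy(ug/mL)  SEM(ug/mL)")
for (phase, dye), rep in sorted(result.reports.items()):
    stock = rep.expected / rep.expected_norm
    print(f"  {phase + 1}    {dye}      {rep.expected_norm:.3f}        "
          f"{rep.grand_mean / stock:.4f}       {rep.accuracy:.4f}         "
          f"{rep.sem_max:.4f}")

print("\nEach dye's steady normalized concentration equals its pump's share of")
print("the 13 mL/h total flow; the EG fraction steps from 0.23 to 0.54 after")
print("the pump swap while TZ stays at 0.23. Accuracy is the worst deviation")
print("of the cross-trial mean from that expectation inside the last 5 min of")
print("each phase; SEM is the repeatability across the three trials.")
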