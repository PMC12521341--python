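"""How fragile is the optimal schedule to imprecise drug administration?

Perturbs the reference optimal dosing traces with temporally-correlated
(Ornstein-Uhlenbeck) noise, clips back to the admissible range, re-simulates
the cell dynamics and reports the worst relative change of the final total
cell count per noise amplitude.
"""

import celldose as cd

model = cd.build_two_population(cd.TwoPopulationParams(alpha=0.5, beta=0.5))
problem = cd.default_problem(model, "two_population")
solution = cd.solve(problem)

result = cd.noise_robustness(
    problem, solution, [0.0125, 0.025, 0.05], replicates=20, seed=7
)

print(f"baseline final total count: {result.baseline_final_total:.4f}")
for sigma, dev in zip(
    result.noise_amplitudes, result.max_relative_final_count_deviation
):
    print(f"  noise std {sigma:>6.4f}: worst final-count deviation {dev:7.2%}")
print()
print("Deviations grow quickly with amplitude because sustained under-dosing")
print("compounds exponentially over the treatment week; near-optimal outcomes")
print("require dose errors well below a few percent of the full scale.")
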