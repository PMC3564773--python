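"""Fit the closure model to the bundled observed time courses.

Runs a reduced-budget squeeze-and-breathe fit (the default budget takes a
few minutes; this example trades some polish for speed) and prints the
objective trace and the fitted predictions against the recorded means.
"""

import numpy as np

import guardcell as gc

dataset = gc.experimental_dataset()
config = gc.FitConfig(n_samples=100, n_rounds=4, n_refine=1,
                      refine_max_nfev=80, final_polish_max_nfev=200, seed=0)
fit = gc.squeeze_and_breathe_fit(dataset, config, variant="primary")

print(f"objective (inverse-SEM weighted SSE): {fit.objective:.3f}")
print("best-score trace:", np.round(fit.trace, 2))

times = np.array([0.0, 5.0, 15.0, 30.0, 45.0, 60.0])
df = dataset.records
for dose in dataset.treatments():
    traj = gc.simulate(fit.best_params, dose, times)
    sub = df[(df.treatment_aba_um == dose.aba) & (df.treatment_acc_um == dose.acc)]
    for _, row in sub.iterrows():
        pred = traj.at("ros" if row.variable == "ros" else "k", row.time_min)
        print(f"  ({dose.aba:>4.0f},{dose.acc:>4.0f}) {row.variable:>9} "
              f"t={row.time_min:>4.0f}  observed {row.mean_pct:>6.1f}  "
              f"fitted {pred:>6.1f}")
print("\nObserved and fitted values are percent of untreated control.")
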