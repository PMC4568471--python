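"""Select the age-trajectory shape by AIC over the candidate-model grid.

Fits the null, polynomial, single-threshold and two-threshold broken-stick
logistic GLMMs on the full bin table (identical base covariates and random
intercepts throughout) and ranks them by AIC.  Writes
``results/selection.csv``; the best model's second threshold is the onset of
reproductive senescence used downstream.
"""

from stressborn import io
from stressborn.trajectory import ThresholdGrid, select_trajectory

table = io.read_csv("results/bins.csv")
selection = select_trajectory(table, ThresholdGrid())
io.write_csv(selection.table, "results/selection.csv")

top = selection.table.head(5)
print("top candidates by AIC:")
for row in top.itertuples(index=False):
    print(f"  {row.label:<12} AIC {row.aic:10.2f}  dAIC {row.delta_aic:7.2f}")
best = selection.best.spec
print(f"best model: {best.label}")
if len(best.thresholds) == 2:
    print(
        f"three-stage trajectory: flat to ~{best.thresholds[0]}, rise to a peak at "
        f"{best.thresholds[1]}, decline afterwards; senescent phase starts at "
        f"{best.thresholds[1]}"
    )
print("wrote results/selection.csv")
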