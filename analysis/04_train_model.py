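"""Train the CV-LASSO logistic classifier on the ICC-retained features.

70/30 stratified learning/testing split, tenfold cross-validation of the
misclassification error along a descending lambda path, lambda chosen at
the minimum, final refit on the whole learning set.  Writes
results/cv_path.csv, results/model.json and results/split.json.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from liporadiomics import model as M
from liporadiomics.reproducibility import filter_reproducible

ROOT = Path(__file__).resolve().parents[1]
RES = ROOT / "results"

table = pd.read_csv(RES / "features.csv", index_col=0)
screen = pd.read_csv(RES / "reproducibility.csv", index_col=0)
retained = filter_reproducible(screen, 0.75)
print(f"{len(retained)} ICC-retained features enter selection")

plan = M.make_split(table, ratio=0.7, folds=10, seed=20230328)
print(f"learning set {len(plan.learning_ids)}, testing set {len(plan.testing_ids)}")

path = M.cv_select_lambda(table, plan, retained)
final = M.finalize(table, plan, retained, path.chosen_lambda)

path.to_frame().to_csv(RES / "cv_path.csv", index=False)
final.to_json(RES / "model.json")
(RES / "split.json").write_text(
    json.dumps(
        {
            "learning_ids": list(plan.learning_ids),
            "testing_ids": list(plan.testing_ids),
            "fold_assignment": plan.fold_assignment,
        },
        indent=2,
    )
)

i = int(np.flatnonzero(path.lambda_grid == path.chosen_lambda)[0])
print(
    f"lambda = {path.chosen_lambda:.4g} (log lambda = {np.log(path.chosen_lambda):.2f}), "
    f"CV misclassification error {path.cv_error_mean[i]:.3f} +/- {path.cv_error_sd[i]:.3f}"
)
print("feature importance (|standardized coefficient|):")
for name, mag in M.importance_ranking(final):
    print(f"  {name:45s} {mag:.3f}")
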