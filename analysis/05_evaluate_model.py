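"""Evaluate the trained model and compare it with two synthetic readers.

Reports AUC, sensitivity, specificity and accuracy with 95% CIs on the
held-out testing set; runs Bonferroni-corrected Mann-Whitney U tests on
the selected features over the whole cohort; and compares the model with
two synthetic "readers" (noisy threshold calls derived from the planted
class structure — stand-ins for human readings, which do not exist for
phantoms) using DeLong's test and Cohen's kappa.  Writes
results/evaluation.json and results/comparison.json.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from liporadiomics import evaluation as E, model as M

ROOT = Path(__file__).resolve().parents[1]
RES = ROOT / "results"

table = pd.read_csv(RES / "features.csv", index_col=0)
final = M.FinalModel.from_json(RES / "model.json")
split = json.loads((RES / "split.json").read_text())
test = table.loc[split["testing_ids"]]

scored = E.ScoredSet.from_arrays(
    test.index, test["label"].to_numpy(), M.predict_proba(final, test)
)
report = E.classification_report(scored, threshold=0.5)
(RES / "evaluation.json").write_text(json.dumps(report, indent=2, default=float))

print("model performance on the held-out testing set:")
lo, hi = report["auc_ci"]
print(f"  AUC {report['auc']:.2f} (95% CI {lo:.2f}-{hi:.2f})")
for m in ("sensitivity", "specificity", "accuracy"):
    lo, hi = report[f"{m}_ci"]
    print(f"  {m} {100 * report[m]:.1f}% (95% CI {100 * lo:.1f}-{100 * hi:.1f}%)")

group = E.group_feature_tests(table, list(final.selected_features))
group.to_csv(RES / "group_tests.csv")
n_sig = (group["p_bonferroni"] < 0.05).sum()
print(
    f"{n_sig}/{len(group)} selected features differ between classes after "
    "Bonferroni correction"
)

# synthetic readers: correct calls except for seeded random flips
rng = np.random.default_rng(99)
truth = (test["label"] == "malignant").to_numpy()
readers = {}
for name, flip_rate in (("reader_1", 0.08), ("reader_2", 0.15)):
    calls = np.where(rng.random(len(truth)) < flip_rate, ~truth, truth)
    readers[name] = E.ScoredSet.from_arrays(
        test.index, truth.astype(float), calls.astype(float)
    )

comparison = {}
for name, reader in readers.items():
    d = E.delong_test(scored, reader)
    comparison[name] = {
        "reader_auc": E.roc_auc(reader)["auc"],
        "delong_z": d["z"],
        "delong_p": d["p"],
    }
    print(
        f"  model vs {name}: reader AUC {comparison[name]['reader_auc']:.2f}, "
        f"DeLong p = {d['p']:.2f}"
    )
kap = E.cohen_kappa(readers["reader_1"].scores, readers["reader_2"].scores)
comparison["reader_agreement"] = kap
print(
    f"  reader agreement kappa = {kap['kappa']:.2f} "
    f"(95% CI {kap['kappa_ci'][0]:.2f}-{kap['kappa_ci'][1]:.2f})"
)
(RES / "comparison.json").write_text(json.dumps(comparison, indent=2, default=float))
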