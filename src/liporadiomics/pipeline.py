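"""End-to-end orchestration: simulate -> extract -> screen -> train -> evaluate.

The pipeline reproduces segmentation variability with seeded boundary
re-draws of every tumor mask: one re-draw stands in for the same
observer's repeat session (intra-observer) and an independent one for a
second observer (inter-observer).  Features must pass both ICC screens
before entering the model.  All artifacts are written as plain CSV/JSON
so a run is fully inspectable; outputs are byte-deterministic for a fixed
config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import liporadiomics
from liporadiomics import evaluation, model as model_mod, reproducibility as repro_mod
from liporadiomics.features import ExtractionConfig, extract_cohort
from liporadiomics.phantom import (
    MaskSet,
    PhantomCase,
    PhantomSpec,
    generate_cohort,
    simulate_resegmentation,
    write_cohort,
)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and context."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a run depends on; defaults mirror the module contracts."""

    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    bin_width: float = 25.0
    icc_threshold: float = 0.75
    ratio: float = 0.7
    folds: int = 10
    split_seed: int = 0
    threshold: float = 0.5
    write_volumes: bool = False

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        phantom = raw.pop("phantom", None)
        if phantom is not None:
            from liporadiomics.phantom import ClassParams

            for key in ("benign_params", "malignant_params"):
                if key in phantom:
                    p = {
                        k: tuple(v) if isinstance(v, list) else v
                        for k, v in phantom[key].items()
                    }
                    phantom[key] = ClassParams(**p)
            for key in ("grid_shape", "spacing_mm"):
                if key in phantom:
                    phantom[key] = tuple(phantom[key])
            raw["phantom"] = PhantomSpec(**phantom)
        return cls(**raw)


@dataclass
class PipelineResult:
    config: PipelineConfig
    features: pd.DataFrame
    reproducibility: pd.DataFrame
    retained_features: list[str]
    plan: model_mod.SplitPlan
    path: model_mod.LassoPath
    model: model_mod.FinalModel
    evaluation: dict
    group_tests: pd.DataFrame
    out_dir: Path | None = None


def _resegmented(case: PhantomCase, index: int, seed: int, stream: int) -> PhantomCase:
    """Observer variant of a case: seeded boundary re-draw of the tumor ROI."""
    rng = np.random.default_rng([seed, index, stream])
    tumor = simulate_resegmentation(case.masks.tumor, rng)
    masks = MaskSet(tumor=tumor, bone=case.masks.bone, reference=case.masks.reference)
    return dataclasses.replace(case, masks=masks)


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> PipelineResult:
    """Run every stage and (optionally) write the report bundle.

    Raises :class:`PipelineError` naming the failing stage.
    """
    extraction = ExtractionConfig(bin_width=config.bin_width)

    try:
        cases = generate_cohort(config.phantom)
    except Exception as exc:
        raise PipelineError("simulate", str(exc)) from exc

    seed = config.phantom.seed
    try:
        base = extract_cohort(cases, config=extraction)
        intra = extract_cohort(
            [_resegmented(c, i, seed, 1) for i, c in enumerate(cases)],
            config=extraction,
        )
        inter = extract_cohort(
            [_resegmented(c, i, seed, 2) for i, c in enumerate(cases)],
            config=extraction,
        )
    except Exception as exc:
        raise PipelineError("extract", str(exc)) from exc

    try:
        screen_intra = repro_mod.agreement_suite(base, intra, config.icc_threshold)
        screen_inter = repro_mod.agreement_suite(base, inter, config.icc_threshold)
        report = repro_mod.combine_screens(screen_intra, screen_inter, config.icc_threshold)
        retained = repro_mod.filter_reproducible(report, config.icc_threshold)
    except Exception as exc:
        raise PipelineError("screen", str(exc)) from exc

    if not retained:
        raise PipelineError(
            "train",
            f"no feature passed the ICC screen at threshold {config.icc_threshold}",
        )

    try:
        plan = model_mod.make_split(
            base, ratio=config.ratio, folds=config.folds, seed=config.split_seed
        )
        path = model_mod.cv_select_lambda(
            base, plan, retained, threshold=config.threshold
        )
        final = model_mod.finalize(
            base, plan, retained, path.chosen_lambda, threshold=config.threshold
        )
    except Exception as exc:
        raise PipelineError("train", str(exc)) from exc

    try:
        test = base.loc[list(plan.testing_ids)]
        scored = evaluation.ScoredSet.from_arrays(
            test.index, test["label"].to_numpy(), model_mod.predict_proba(final, test)
        )
        eval_report = evaluation.classification_report(scored, config.threshold)
        eval_report["selected_features"] = list(final.selected_features)
        eval_report["chosen_lambda"] = final.chosen_lambda
        eval_report["log_chosen_lambda"] = float(np.log(final.chosen_lambda))
        eval_report["n_learning"] = len(plan.learning_ids)
        eval_report["n_testing"] = len(plan.testing_ids)
        eval_report["n_retained_features"] = len(retained)
        tested = list(final.selected_features) or retained
        group = evaluation.group_feature_tests(base, tested)
    except Exception as exc:
        raise PipelineError("evaluate", str(exc)) from exc

    result = PipelineResult(
        config=config,
        features=base,
        reproducibility=report,
        retained_features=retained,
        plan=plan,
        path=path,
        model=final,
        evaluation=eval_report,
        group_tests=group,
    )

    if out_dir is not None:
        result.out_dir = Path(out_dir)
        _write_bundle(result, cases, intra, inter, extraction)
    return result


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _write_bundle(result: PipelineResult, cases, intra, inter, extraction) -> None:
    out = result.out_dir
    out.mkdir(parents=True, exist_ok=True)
    result.features.to_csv(out / "features.csv")
    intra.to_csv(out / "features_intra.csv")
    inter.to_csv(out / "features_inter.csv")
    result.reproducibility.to_csv(out / "reproducibility.csv")
    result.path.to_frame().to_csv(out / "cv_path.csv", index=False)
    result.model.to_json(out / "model.json")
    (out / "evaluation.json").write_text(_to_json(result.evaluation))
    result.group_tests.to_csv(out / "group_tests.csv")
    (out / "extraction_config.json").write_text(_to_json(extraction.to_dict()))
    manifest = {
        "config": result.config.to_dict(),
        "config_hash": _config_hash(result.config),
        "package_version": liporadiomics.__version__,
        "numpy_version": np.__version__,
        "n_cases": len(cases),
        "retained_features": result.retained_features,
        "selected_features": list(result.model.selected_features),
    }
    (out / "manifest.json").write_text(_to_json(manifest))
    if result.config.write_volumes:
        write_cohort(cases, out / "cohort")


def _to_json(obj) -> str:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, tuple):
            return list(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    return json.dumps(obj, indent=2, sort_keys=True, default=default)


def report(bundle: PipelineResult | str | Path) -> str:
    """Human-readable summary of a run (from memory or a bundle directory)."""
    if isinstance(bundle, PipelineResult):
        ev = bundle.evaluation
        group = bundle.group_tests
    else:
        bundle = Path(bundle)
        ev_path = bundle / "evaluation.json"
        if not ev_path.exists():
            raise PipelineError("report", f"missing file: {ev_path}")
        ev = json.loads(ev_path.read_text())
        gt = bundle / "group_tests.csv"
        group = pd.read_csv(gt, index_col=0) if gt.exists() else None

    lines = ["Model performance on the held-out testing set"]
    lines.append(
        f"  AUC {ev['auc']:.2f} (95% CI {ev['auc_ci'][0]:.2f}-{ev['auc_ci'][1]:.2f})"
    )
    for metric in ("sensitivity", "specificity", "accuracy"):
        lo, hi = ev[f"{metric}_ci"]
        lines.append(
            f"  {metric} {100 * ev[metric]:.1f}% (95% CI {100 * lo:.1f}-{100 * hi:.1f}%)"
        )
    lines.append(
        f"  lambda {ev['chosen_lambda']:.4g} (log {ev['log_chosen_lambda']:.2f}); "
        f"{len(ev['selected_features'])} selected of {ev['n_retained_features']} "
        "ICC-retained features"
    )
    if ev.get("selected_features"):
        lines.append("  selected: " + ", ".join(ev["selected_features"]))
    if group is not None and len(group):
        lines.append("Group differences (Bonferroni-corrected Mann-Whitney U)")
        for name, row in group.iterrows():
            lines.append(f"  {name}: adjusted p = {row['p_bonferroni']:.3g}")
    for key in ("delong", "kappa"):
        if key in ev:
            lines.append(f"  {key}: {ev[key]}")
    return "\n".join(lines)
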