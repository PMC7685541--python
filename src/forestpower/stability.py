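"""Nested cross-validation stability selection.

The outer loop splits samples 75:25 four times so that every sample is
held out exactly once.  Within each outer training set, a tenth of the
data tunes the forest hyperparameters and the remaining nine-tenths host
repeated runs of each feature-selection method (fresh random seeds per
run).  A variable's stability is its selection frequency over those
runs: low-stringency (LS) membership requires strictly more than
``ls_threshold`` selections, high-stringency (HS) at least
``hs_threshold``.  Validation forests are trained per rotation on the
outer-train samples restricted to each stable set and scored on the
held-out outer-test samples (R² for regression, class error for
classification); frequencies are averaged across the four rotations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .rf import ForestSpec, default_tuning_grid, fit_forest, tune_hyperparameters
from .selectors import (SelectionOutcome, boruta_select, permutation_select,
                        rfe_select)
from .simdata import ConfigurationError, Dataset, TRUTH_INFORMATIVE

__all__ = [
    "NestedCVPlan",
    "FrequencyTable",
    "StabilityReport",
    "make_outer_splits",
    "run_stability",
    "evaluate_truth",
    "METHODS",
]


@dataclass(frozen=True)
class NestedCVPlan:
    """Nested-CV layout and stringency thresholds.

    ``ls_threshold`` is exclusive (``count > ls``), ``hs_threshold``
    inclusive (``count >= hs``); both are counts out of
    ``n_iterations``.  ``inner_tune_fraction`` of the outer-train set is
    used for hyperparameter tuning, the rest for the selection runs.
    """

    outer_train_fraction: float = 0.75
    outer_rotations: int = 4
    inner_tune_fraction: float = 0.1
    n_iterations: int = 100
    ls_threshold: int = 5
    hs_threshold: int = 90
    tune: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.ls_threshold < self.hs_threshold <= self.n_iterations):
            raise ConfigurationError(
                "need 0 < ls_threshold < hs_threshold <= n_iterations")
        if self.outer_rotations < 1:
            raise ConfigurationError("outer_rotations must be >= 1")
        if not 0.0 < self.outer_train_fraction < 1.0:
            raise ConfigurationError("outer_train_fraction must be in (0, 1)")


@dataclass
class FrequencyTable:
    """Selection counts per method × variable, averaged over rotations."""

    counts: pd.DataFrame  # index: variable, columns: method
    n_iterations: int
    n_rotations: int

    def stable_set(self, method: str, threshold: float, inclusive: bool) -> list[str]:
        col = self.counts[method]
        mask = col >= threshold if inclusive else col > threshold
        return list(col.index[mask])


@dataclass
class StabilityReport:
    """Stable sets, truth evaluation and held-out validation per method."""

    ls_sets: dict
    hs_sets: dict
    truth_eval: dict          # method -> {"ls": (tp, fp), "hs": (tp, fp)} or {}
    validation: pd.DataFrame  # rows: (method, stringency, rotation) -> score
    flags: list = field(default_factory=list)
    tuned_specs: list = field(default_factory=list)

    def __post_init__(self) -> None:
        for m, hs in self.hs_sets.items():
            if not set(hs) <= set(self.ls_sets[m]):
                raise AssertionError(f"HS set not within LS set for {m}")


def make_outer_splits(n_samples: int, plan: NestedCVPlan):
    """Partition samples into ``outer_rotations`` held-out test folds.

    Returns a list of (train_idx, test_idx) pairs whose test folds are
    pairwise disjoint and jointly cover every sample exactly once.
    """
    if n_samples < plan.outer_rotations:
        raise ConfigurationError("fewer samples than outer rotations")
    rng = np.random.default_rng(plan.seed)
    perm = rng.permutation(n_samples)
    folds = np.array_split(perm, plan.outer_rotations)
    splits = []
    for k, fold in enumerate(folds):
        test = np.sort(fold)
        train = np.sort(np.concatenate([f for j, f in enumerate(folds) if j != k]))
        splits.append((train, test))
    return splits


def evaluate_truth(selected, truth: pd.Series) -> tuple[int, int]:
    """(tp, fp) of a selected set against per-variable truth labels.

    True positives are selections among the outcome-generating
    (informative) variables; everything else selected counts as a false
    positive.
    """
    sel = set(selected)
    informative = set(truth.index[truth == TRUTH_INFORMATIVE])
    tp = len(sel & informative)
    fp = len(sel - informative)
    return tp, fp


def _run_boruta(X, y, spec, seed, **kw):
    return {"boruta": boruta_select(X, y, spec=spec, seed=seed, **kw)}


def _run_rfe(X, y, spec, seed, **kw):
    return {"rfe": rfe_select(X, y, spec=spec, seed=seed, **kw)}


def _run_perm(which):
    def run(X, y, spec, seed, **kw):
        out = permutation_select(X, y, spec=spec, seed=seed, correction="none", **kw)
        res = {}
        if "perm_raw" in which:
            res["perm_raw"] = out
        if "perm_corrected" in which:
            from statsmodels.stats.multitest import multipletests
            raw = out.diagnostics["raw_p_values"]
            alpha = kw.get("alpha", 0.05)
            _, p_adj, _, _ = multipletests(raw.to_numpy(), alpha=alpha, method="fdr_bh")
            sel = [n for n, pa in zip(raw.index, p_adj) if pa < alpha]
            res["perm_corrected"] = SelectionOutcome(
                method="perm_corrected", selected=sel,
                p_values=pd.Series(p_adj, index=raw.index, name="p_value"),
                diagnostics={"raw_p_values": raw})
        return res
    return run


METHODS = ("boruta", "perm_raw", "perm_corrected", "rfe")


def run_stability(data: Dataset, methods, plan: NestedCVPlan, task: str,
                  base_spec: Optional[ForestSpec] = None,
                  method_params: Optional[dict] = None,
                  tuning_grid: Optional[list] = None,
                  progress: Optional[Callable[[str], None]] = None):
    """Run the full nested-CV stability procedure.

    Parameters
    ----------
    data : Dataset with the outcome required by ``task``.
    methods : iterable of method names among
        {'boruta', 'perm_raw', 'perm_corrected', 'rfe'}.
    plan : NestedCVPlan.
    task : 'regression' or 'classification'.
    base_spec : forest parameters used where tuning is off (and as the
        template the tuned mtry is written into).
    method_params : optional per-method keyword overrides, e.g.
        ``{"boruta": {"max_runs": 50}}``.
    tuning_grid : explicit list of ForestSpec to tune over; defaults to
        :func:`default_tuning_grid`.

    Returns
    -------
    (FrequencyTable, StabilityReport)
    """
    methods = list(methods)
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ConfigurationError(f"unknown methods: {sorted(unknown)}")
    method_params = method_params or {}
    if base_spec is None:
        base_spec = ForestSpec(task=task)
    if base_spec.task != task:
        base_spec = replace(base_spec, task=task)

    y_all = data.outcome(task).to_numpy()
    X_all = data.X
    names = data.variables
    rng = np.random.default_rng(plan.seed)
    splits = make_outer_splits(data.n_obs, plan)

    # per-iteration runners; the two permutation variants share null draws
    runners = _build_runners(methods, method_params)

    counts_sum = pd.DataFrame(0.0, index=names, columns=methods)
    validation_rows = []
    flags = []
    tuned_specs = []
    per_rotation_sets = []

    for rot, (train_idx, test_idx) in enumerate(splits):
        X_tr, y_tr = X_all.iloc[train_idx], y_all[train_idx]
        n_tr = len(train_idx)
        n_tune = max(int(round(plan.inner_tune_fraction * n_tr)), 2)
        tune_loc = rng.choice(n_tr, size=n_tune, replace=False)
        sel_loc = np.setdiff1d(np.arange(n_tr), tune_loc)
        X_sel, y_sel = X_tr.iloc[sel_loc], y_tr[sel_loc]

        spec = base_spec
        if plan.tune:
            grid = tuning_grid or default_tuning_grid(
                X_all.shape[1], task, n_trees=base_spec.n_trees,
                seed=int(rng.integers(2**31 - 1)))
            try:
                spec = replace(tune_hyperparameters(
                    X_tr.iloc[tune_loc], y_tr[tune_loc], grid), task=task,
                    n_trees=base_spec.n_trees)
            except Exception as exc:  # tiny tune folds can be degenerate
                flags.append(f"rotation {rot}: tuning failed ({exc}); using base spec")
                spec = base_spec
        tuned_specs.append(spec)

        counts_rot = pd.DataFrame(0, index=names, columns=methods, dtype=int)
        for it in range(plan.n_iterations):
            it_seed = int(rng.integers(2**31 - 1))
            for _, runner, kw in runners:
                outcomes = runner(X_sel, y_sel, replace(spec, seed=it_seed),
                                  it_seed, **kw)
                for m, oc in outcomes.items():
                    counts_rot.loc[oc.selected, m] += 1
            if progress:
                progress(f"rotation {rot} iteration {it + 1}/{plan.n_iterations}")

        counts_sum += counts_rot

        # per-rotation stable sets -> validation on the held-out fold
        rot_sets = {}
        for m in methods:
            ls = list(counts_rot.index[counts_rot[m] > plan.ls_threshold])
            hs = list(counts_rot.index[counts_rot[m] >= plan.hs_threshold])
            rot_sets[m] = {"ls": ls, "hs": hs}
            for stringency, sset in (("ls", ls), ("hs", hs)):
                if not sset:
                    flags.append(
                        f"rotation {rot}: {m} {stringency.upper()} set empty; "
                        "validation skipped")
                    validation_rows.append(
                        {"method": m, "stringency": stringency, "rotation": rot,
                         "n_features": 0, "score": np.nan})
                    continue
                score = _validate(X_all, y_all, train_idx, test_idx, sset,
                                  replace(spec, seed=int(rng.integers(2**31 - 1))),
                                  task)
                validation_rows.append(
                    {"method": m, "stringency": stringency, "rotation": rot,
                     "n_features": len(sset), "score": score})
        per_rotation_sets.append(rot_sets)

    freq = FrequencyTable(counts=counts_sum / plan.outer_rotations,
                          n_iterations=plan.n_iterations,
                          n_rotations=plan.outer_rotations)
    ls_sets = {m: freq.stable_set(m, plan.ls_threshold, inclusive=False)
               for m in methods}
    hs_sets = {m: freq.stable_set(m, plan.hs_threshold, inclusive=True)
               for m in methods}
    truth_eval = {}
    if data.truth is not None:
        for m in methods:
            truth_eval[m] = {"ls": evaluate_truth(ls_sets[m], data.truth),
                             "hs": evaluate_truth(hs_sets[m], data.truth)}
    report = StabilityReport(
        ls_sets=ls_sets, hs_sets=hs_sets, truth_eval=truth_eval,
        validation=pd.DataFrame(validation_rows), flags=flags,
        tuned_specs=tuned_specs)
    return freq, report


def run_selection_only(data: Dataset, methods, plan: NestedCVPlan, task: str,
                       base_spec: Optional[ForestSpec] = None,
                       method_params: Optional[dict] = None):
    """Repeated selection on the full data, without the outer CV.

    For sample sizes too small to split, this runs ``n_iterations``
    freshly seeded method runs on all samples and derives LS/HS sets
    from the raw counts; no validation scores are produced.
    """
    methods = list(methods)
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ConfigurationError(f"unknown methods: {sorted(unknown)}")
    method_params = method_params or {}
    if base_spec is None:
        base_spec = ForestSpec(task=task)
    base_spec = replace(base_spec, task=task)
    y_all = data.outcome(task).to_numpy()
    names = data.variables
    rng = np.random.default_rng(plan.seed)

    runners = _build_runners(methods, method_params)
    counts = pd.DataFrame(0, index=names, columns=methods, dtype=int)
    for _ in range(plan.n_iterations):
        it_seed = int(rng.integers(2**31 - 1))
        for _, runner, kw in runners:
            outcomes = runner(data.X, y_all, replace(base_spec, seed=it_seed),
                              it_seed, **kw)
            for m, oc in outcomes.items():
                counts.loc[oc.selected, m] += 1

    freq = FrequencyTable(counts=counts.astype(float),
                          n_iterations=plan.n_iterations, n_rotations=1)
    ls_sets = {m: freq.stable_set(m, plan.ls_threshold, inclusive=False)
               for m in methods}
    hs_sets = {m: freq.stable_set(m, plan.hs_threshold, inclusive=True)
               for m in methods}
    truth_eval = {}
    if data.truth is not None:
        truth_eval = {m: {"ls": evaluate_truth(ls_sets[m], data.truth),
                          "hs": evaluate_truth(hs_sets[m], data.truth)}
                      for m in methods}
    report = StabilityReport(
        ls_sets=ls_sets, hs_sets=hs_sets, truth_eval=truth_eval,
        validation=pd.DataFrame(
            columns=["method", "stringency", "rotation", "n_features", "score"]),
        flags=["no outer CV: selection run on the full data"],
        tuned_specs=[base_spec])
    return freq, report


def _build_runners(methods, method_params):
    runners = []
    perm_variants = [m for m in methods if m in ("perm_raw", "perm_corrected")]
    if "boruta" in methods:
        runners.append(("boruta", _run_boruta, method_params.get("boruta", {})))
    if perm_variants:
        kw = dict(method_params.get("perm_raw", {}))
        kw.update(method_params.get("perm_corrected", {}))
        runners.append(("perm", _run_perm(perm_variants), kw))
    if "rfe" in methods:
        runners.append(("rfe", _run_rfe, method_params.get("rfe", {})))
    return runners


def _validate(X_all, y_all, train_idx, test_idx, feature_set, spec, task):
    """Train on outer-train restricted to ``feature_set``, score on outer-test."""
    fitted = fit_forest(X_all.iloc[train_idx][feature_set], y_all[train_idx],
                        spec, compute_importance=False)
    X_test = X_all.iloc[test_idx][feature_set].to_numpy(dtype=float)
    y_test = y_all[test_idx]
    if task == "classification":
        pred_enc = fitted.model.predict(X_test)
        pred = fitted.classes_[pred_enc.astype(int)]
        return float(np.mean(pred != y_test))
    pred = fitted.model.predict(X_test)
    y_test = y_test.astype(float)
    sst = float(np.sum((y_test - y_test.mean()) ** 2))
    sse = float(np.sum((y_test - pred) ** 2))
    return 1.0 - sse / sst if sst > 0 else float("nan")
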