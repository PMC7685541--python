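"""Four random-forest feature-selection algorithms.

* ``boruta_select`` — shadow-variable testing: each run fits a forest on
  the real variables plus column-permuted copies ("shadows"); a variable
  scores a hit when its OOB permutation importance exceeds the best
  shadow's, and a Bonferroni-adjusted binomial test on the hit count
  confirms or rejects it.
* ``permutation_select`` — importance significance by outcome
  permutation: the observed importance of each variable is compared with
  its own null distribution from forests refit on permuted outcomes;
  p-values are used raw or after Benjamini–Hochberg adjustment.
* ``model_permutation_test`` — the model-level analogue: how often does
  a permuted-outcome forest explain as much as the real one.
* ``rfe_select`` — backward elimination: iteratively drop the
  least-important fraction of variables, track the OOB error curve, and
  keep the smallest subset within ``se_rule`` standard errors of the
  minimum.

All selectors are deterministic given their seed and return a
:class:`SelectionOutcome`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .rf import ForestSpec, fit_forest
from .simdata import ConfigurationError, Dataset

__all__ = [
    "SelectionOutcome",
    "boruta_select",
    "permutation_select",
    "model_permutation_test",
    "rfe_select",
]

CONFIRMED = "confirmed"
REJECTED = "rejected"
TENTATIVE = "tentative"


@dataclass
class SelectionOutcome:
    """Result of one run of one selector."""

    method: str
    selected: list[str]
    decision: Optional[pd.Series] = None  # per-variable confirmed/rejected/tentative
    p_values: Optional[pd.Series] = None  # per-variable, in [0, 1]
    diagnostics: dict = field(default_factory=dict)

    @property
    def selected_set(self) -> set[str]:
        return set(self.selected)


def _resolve_xy(data, y=None, task=None):
    """Accept a Dataset or an (X, y) pair; return (X DataFrame, y array)."""
    if isinstance(data, Dataset):
        if task is None:
            raise ValueError("task required when passing a Dataset")
        y = data.outcome(task).to_numpy()
        return data.X, y
    X = data if isinstance(data, pd.DataFrame) else pd.DataFrame(np.asarray(data))
    if y is None:
        raise ValueError("y required when passing a raw matrix")
    return X, np.asarray(y)


def _seed_stream(seed: int):
    """Independent sub-seeds (< 2**31) derived from one master seed."""
    rng = np.random.default_rng(seed)
    while True:
        yield int(rng.integers(0, 2**31 - 1))


# ---------------------------------------------------------------------------
# Boruta

def boruta_select(data, y=None, *, spec: ForestSpec, alpha: float = 0.05,
                  max_runs: int = 100, seed: Optional[int] = None) -> SelectionOutcome:
    """Shadow-variable selection with binomial hit testing.

    Per run, every not-yet-rejected variable gets a column-permuted
    shadow copy (padded to at least five shadows so the null maximum is
    not trivially weak); a hit is importance strictly above the best
    shadow.  Hit counts over the runs so far feed one-sided binomial
    tests at level ``alpha``, Bonferroni-adjusted across the variables
    still undecided; rejected variables leave the forest.  Variables
    still tentative at termination are not selected.
    """
    if max_runs < 1:
        raise ConfigurationError("max_runs must be >= 1")
    X, y = _resolve_xy(data, y, spec.task)
    names = list(X.columns)
    p = len(names)
    Xm = X.to_numpy(dtype=float)
    seeds = _seed_stream(spec.seed if seed is None else seed)
    rng = np.random.default_rng(next(seeds))

    decision = np.array([TENTATIVE] * p, dtype=object)
    hits = np.zeros(p, dtype=np.int64)
    runs = 0

    for _ in range(max_runs):
        undecided = decision == TENTATIVE
        if not undecided.any():
            break
        kept = decision != REJECTED
        kept_idx = np.flatnonzero(kept)
        Xk = Xm[:, kept_idx]
        n_shadow = max(kept_idx.size, 5)
        sh_src = np.resize(kept_idx, n_shadow)
        shadows = Xm[:, sh_src].copy()
        for c in range(n_shadow):
            shadows[:, c] = rng.permutation(shadows[:, c])
        Xrun = np.hstack([Xk, shadows])
        fitted = fit_forest(Xrun, y, ForestSpec(
            task=spec.task, n_trees=spec.n_trees,
            mtry=spec.mtry if spec.mtry is not None else max(1, int(np.sqrt(Xrun.shape[1]))),
            min_node_size=spec.min_node_size, seed=next(seeds)))
        imp = fitted.importance.scores
        shadow_max = imp[kept_idx.size:].max()
        hit_now = imp[: kept_idx.size] > shadow_max
        und_local = undecided[kept_idx]
        hits[kept_idx[und_local]] += hit_now[und_local]
        runs += 1

        und_idx = np.flatnonzero(decision == TENTATIVE)
        k = und_idx.size
        h = hits[und_idx]
        p_conf = stats.binom.sf(h - 1, runs, 0.5)  # P(X >= h)
        p_rej = stats.binom.cdf(h, runs, 0.5)      # P(X <= h)
        decision[und_idx[np.minimum(p_conf * k, 1.0) < alpha]] = CONFIRMED
        decision[und_idx[np.minimum(p_rej * k, 1.0) < alpha]] = REJECTED

    selected = [names[i] for i in range(p) if decision[i] == CONFIRMED]
    return SelectionOutcome(
        method="boruta",
        selected=selected,
        decision=pd.Series(decision, index=names, name="decision"),
        diagnostics={"runs": runs, "hits": pd.Series(hits, index=names),
                     "n_tentative": int((decision == TENTATIVE).sum())},
    )


# ---------------------------------------------------------------------------
# Outcome-permutation selection

def permutation_select(data, y=None, *, spec: ForestSpec, n_perm: int = 1000,
                       alpha: float = 0.05, correction: str = "none",
                       pooled_null: bool = False,
                       seed: Optional[int] = None) -> SelectionOutcome:
    """Per-variable importance significance by outcome permutation.

    The observed OOB permutation importance of each variable is compared
    with the importances obtained from ``n_perm`` forests refit after
    permuting the outcome; ``p = (1 + #{null ≥ observed}) / (n_perm + 1)``.
    ``correction='none'`` selects raw ``p < alpha``;
    ``'benjamini_hochberg'`` adjusts first (its selection is always a
    subset of the raw one).  ``pooled_null`` compares each variable
    against the null importances pooled over all variables instead of
    its own.
    """
    if n_perm < 20:
        raise ConfigurationError("n_perm must be >= 20")
    if correction not in ("none", "benjamini_hochberg"):
        raise ConfigurationError(f"unknown correction {correction!r}")
    if 1.0 / (n_perm + 1) > alpha:
        warnings.warn(
            f"n_perm={n_perm} cannot reach p < {alpha}; selection will be empty",
            stacklevel=2)
    X, y = _resolve_xy(data, y, spec.task)
    names = list(X.columns)
    seeds = _seed_stream(spec.seed if seed is None else seed)
    rng = np.random.default_rng(next(seeds))

    observed = fit_forest(X, y, ForestSpec(
        task=spec.task, n_trees=spec.n_trees, mtry=spec.mtry,
        min_node_size=spec.min_node_size, seed=next(seeds))).importance.scores

    exceed = np.zeros(len(names), dtype=np.int64)
    pooled = [] if pooled_null else None
    for _ in range(n_perm):
        y_perm = rng.permutation(y)
        null_imp = fit_forest(X, y_perm, ForestSpec(
            task=spec.task, n_trees=spec.n_trees, mtry=spec.mtry,
            min_node_size=spec.min_node_size, seed=next(seeds))).importance.scores
        if pooled_null:
            pooled.append(null_imp)
        else:
            exceed += null_imp >= observed
    if pooled_null:
        pool = np.sort(np.concatenate(pooled))
        ge = pool.size - np.searchsorted(pool, observed, side="left")
        pvals = (1.0 + ge) / (pool.size + 1.0)
    else:
        pvals = (1.0 + exceed) / (n_perm + 1.0)

    if correction == "benjamini_hochberg":
        reject, p_adj, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
        selected_mask = p_adj < alpha
        method = "perm_corrected"
        p_report = p_adj
    else:
        selected_mask = pvals < alpha
        method = "perm_raw"
        p_report = pvals

    selected = [n for n, s in zip(names, selected_mask) if s]
    return SelectionOutcome(
        method=method,
        selected=selected,
        p_values=pd.Series(p_report, index=names, name="p_value"),
        diagnostics={"n_perm": n_perm, "raw_p_values": pd.Series(pvals, index=names)},
    )


def model_permutation_test(data, y=None, *, spec: ForestSpec, n_perm: int = 1000,
                           seed: Optional[int] = None) -> float:
    """Model-level permutation p-value.

    Fraction (with +1 smoothing) of permuted-outcome forests whose score
    — percent variance explained (regression) or OOB accuracy
    (classification) — is at least the unpermuted model's.
    """
    if n_perm < 20:
        raise ConfigurationError("n_perm must be >= 20")
    X, y = _resolve_xy(data, y, spec.task)
    seeds = _seed_stream(spec.seed if seed is None else seed)
    rng = np.random.default_rng(next(seeds))

    def score(yy):
        perf = fit_forest(X, yy, ForestSpec(
            task=spec.task, n_trees=spec.n_trees, mtry=spec.mtry,
            min_node_size=spec.min_node_size, seed=next(seeds)),
            compute_importance=False).performance
        return (1.0 - perf.oob_error) if spec.task == "classification" \
            else perf.pct_var_explained

    obs = score(y)
    exceed = sum(score(rng.permutation(y)) >= obs for _ in range(n_perm))
    return (1.0 + exceed) / (n_perm + 1.0)


# ---------------------------------------------------------------------------
# Recursive feature elimination

def rfe_trajectory_sizes(p: int, drop_fraction: float) -> list[int]:
    """Subset sizes visited by the drop rule, from ``p`` down to 1."""
    sizes = [p]
    while sizes[-1] > 1:
        cur = sizes[-1]
        sizes.append(max(cur - math.ceil(drop_fraction * cur), 1))
    return sizes


def rfe_select(data, y=None, *, spec: ForestSpec, drop_fraction: float = 0.2,
               se_rule: float = 1.0, recompute_importance: bool = False,
               seed: Optional[int] = None) -> SelectionOutcome:
    """Backward elimination on the importance ranking.

    At each step a forest is refit on the surviving variables and its
    OOB loss recorded; ``ceil(drop_fraction · p_current)`` variables with
    the smallest importance are discarded until one remains.  The
    selected subset is the smallest whose loss is within
    ``se_rule × se`` of the minimum loss (``se_rule=0`` picks the strict
    minimum).  By default the ranking comes from the initial full fit
    (the reference behaviour); ``recompute_importance=True`` re-ranks at
    every step.
    """
    if not 0.0 < drop_fraction < 1.0:
        raise ConfigurationError("drop_fraction must be in (0, 1)")
    X, y = _resolve_xy(data, y, spec.task)
    names = np.array(X.columns)
    Xm = X.to_numpy(dtype=float)
    n = Xm.shape[0]
    seeds = _seed_stream(spec.seed if seed is None else seed)

    current = np.arange(len(names))
    ranking_scores = None
    trajectory = []  # (size, loss, se, indices)

    while True:
        need_imp = recompute_importance or ranking_scores is None
        fitted = fit_forest(Xm[:, current], y, ForestSpec(
            task=spec.task, n_trees=spec.n_trees, mtry=spec.mtry,
            min_node_size=spec.min_node_size, seed=next(seeds)),
            compute_importance=need_imp and current.size > 1)
        perf = fitted.performance
        pred = fitted.oob_predictions
        ok = ~np.isnan(pred)
        m = int(ok.sum())
        if spec.task == "classification":
            loss = perf.oob_error
            se = math.sqrt(max(loss * (1 - loss), 0.0) / m) if m else float("inf")
        else:
            loss = perf.oob_mse
            sq = (pred[ok] - np.asarray(y, dtype=float)[ok]) ** 2
            se = float(np.std(sq, ddof=1) / math.sqrt(m)) if m > 1 else float("inf")
        trajectory.append((current.size, loss, se, current.copy()))
        if current.size == 1:
            break
        if need_imp:
            ranking_scores = np.full(len(names), -np.inf)
            ranking_scores[current] = fitted.importance.scores
        n_drop = math.ceil(drop_fraction * current.size)
        order = np.lexsort((current, -ranking_scores[current]))  # best first
        current = np.sort(current[order[: current.size - n_drop]])

    losses = np.array([t[1] for t in trajectory])
    ses = np.array([t[2] for t in trajectory])
    i_min = int(np.argmin(losses))
    threshold = losses[i_min] + se_rule * ses[i_min]
    # trajectory runs from largest to smallest; pick the smallest subset
    eligible = [t for t in trajectory if t[1] <= threshold]
    best = min(eligible, key=lambda t: t[0])
    selected_idx = best[3]
    selected = [str(names[i]) for i in selected_idx]
    decision = pd.Series(
        np.where(np.isin(np.arange(len(names)), selected_idx), CONFIRMED, REJECTED),
        index=names, name="decision")
    return SelectionOutcome(
        method="rfe",
        selected=selected,
        decision=decision,
        diagnostics={
            "sizes": [t[0] for t in trajectory],
            "losses": losses.tolist(),
            "ses": ses.tolist(),
            "min_loss": float(losses[i_min]),
            "threshold": float(threshold),
        },
    )
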