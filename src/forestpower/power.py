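"""Simulation-based power analysis for putative biomarkers.

The observed feature matrix is modelled as multivariate log-normal so
that synthetic datasets of any sample size preserve both the marginal
scales and the correlation structure of the input.  Power for a
candidate variable is then estimated by Monte-Carlo: at each sample
size, synthetic data are drawn, an outcome is constructed at the
variable's observed effect size — a Pearson correlation for continuous
outcomes or a Cohen's d mean shift between two groups — and the fraction
of replicates in which the variable (or one of its highly correlated
partners) reaches significance is recorded.

Highly correlated variables can be grouped (single linkage on absolute
Pearson correlation) and represented by their largest-effect member, so
power is quantified once per biomarker group rather than once per
redundant feature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .simdata import ConfigurationError

__all__ = [
    "LogNormalModel",
    "CorrelatedGroups",
    "EffectSpec",
    "PowerGrid",
    "fit_lognormal",
    "synthesize",
    "effect_size",
    "group_correlated",
    "power_regression",
    "power_classification",
    "sample_size_recommendation",
    "effect_size_label",
    "DEFAULT_GRID",
]

# doubling series; "highly correlated" cutoff and MC defaults are
# package choices, configurable at every call site
DEFAULT_GRID = (5, 10, 20, 40, 80, 160, 320, 640, 1280, 2560)
DEFAULT_GROUP_THRESHOLD = 0.8
DEFAULT_REPS = 200


@dataclass
class LogNormalModel:
    """Multivariate log-normal fit of a feature matrix.

    ``shift`` is the per-variable offset added before the log transform
    to make every value strictly positive (zero for already-positive
    variables); ``mean``/``cov`` are estimated on the log scale.
    """

    mean: np.ndarray
    cov: np.ndarray
    shift: np.ndarray
    names: list[str]
    psd_repaired: bool = False
    zero_variance: list[str] = field(default_factory=list)

    @property
    def p(self) -> int:
        return self.mean.size


@dataclass
class EffectSpec:
    """A variable's effect size against the outcome."""

    variable: str
    effect_type: str  # "pearson_r" | "cohens_d"
    value: float

    def __post_init__(self) -> None:
        if self.effect_type == "pearson_r" and not -1.0 <= self.value <= 1.0:
            raise ConfigurationError("pearson_r effect must lie in [-1, 1]")
        if self.effect_type not in ("pearson_r", "cohens_d"):
            raise ConfigurationError(f"unknown effect_type {self.effect_type!r}")


@dataclass
class CorrelatedGroups:
    """Partition of variables into correlation groups with representatives."""

    groups: list[list[str]]
    representatives: list[str]
    threshold: float
    effects: dict

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def partners(self, variable: str) -> list[str]:
        """Other members of ``variable``'s group."""
        for g in self.groups:
            if variable in g:
                return [v for v in g if v != variable]
        return []


@dataclass
class PowerGrid:
    """Monte-Carlo power estimates over a sample-size grid.

    One row per (variable, n): estimated power (group-aware true
    positive rate), per-variable TPR, FPR over non-partner variables,
    the replicate count and the binomial MC standard error of the power
    estimate.
    """

    table: pd.DataFrame

    def row(self, variable: str) -> pd.DataFrame:
        return self.table[self.table["variable"] == variable]

    def power_at(self, variable: str, n: int) -> float:
        r = self.table[(self.table["variable"] == variable) & (self.table["n"] == n)]
        if r.empty:
            raise KeyError(f"no power estimate for {variable} at n={n}")
        return float(r["power"].iloc[0])


def fit_lognormal(X) -> LogNormalModel:
    """Fit a multivariate log-normal model to a feature matrix.

    Variables containing non-positive values are shifted by
    ``-min + range/100`` (falling back to 1 for constant columns) before
    the log; the covariance is symmetrised and, if needed, repaired to
    the nearest positive semi-definite matrix by eigenvalue clipping
    (flagged on the model).
    """
    if isinstance(X, pd.DataFrame):
        names = [str(c) for c in X.columns]
        Xm = X.to_numpy(dtype=float)
    else:
        Xm = np.asarray(X, dtype=float)
        if Xm.ndim == 1:
            Xm = Xm.reshape(-1, 1)
        names = [f"V{i+1}" for i in range(Xm.shape[1])]
    n, p = Xm.shape
    if n < 3:
        raise ConfigurationError("need at least 3 samples to fit the model")

    mins = Xm.min(axis=0)
    rng_ = np.ptp(Xm, axis=0)
    zero_var = [names[j] for j in range(p) if rng_[j] == 0]
    delta = np.where(rng_ > 0, rng_ / 100.0, 1.0)
    shift = np.where(mins > 0, 0.0, -mins + delta)

    logX = np.log(Xm + shift)
    mean = logX.mean(axis=0)
    cov = np.cov(logX, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    cov = (cov + cov.T) / 2.0
    repaired = False
    eigvals = np.linalg.eigvalsh(cov)
    if eigvals.min() < -1e-10 * max(eigvals.max(), 1.0):
        w, V = np.linalg.eigh(cov)
        cov = (V * np.clip(w, 0.0, None)) @ V.T
        cov = (cov + cov.T) / 2.0
        repaired = True
    return LogNormalModel(mean=mean, cov=cov, shift=shift, names=names,
                          psd_repaired=repaired, zero_variance=zero_var)


def synthesize(model: LogNormalModel, n: int, seed=None,
               rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Draw ``n`` synthetic samples: exp of a multivariate normal on the
    log scale, minus the positivity shift."""
    if n < 2:
        raise ConfigurationError("n must be >= 2")
    if rng is None:
        rng = np.random.default_rng(seed)
    Z = rng.multivariate_normal(model.mean, model.cov, size=n,
                                method="cholesky" if _is_pd(model.cov) else "eigh")
    return np.exp(Z) - model.shift


def _is_pd(cov: np.ndarray) -> bool:
    try:
        np.linalg.cholesky(cov)
        return True
    except np.linalg.LinAlgError:
        return False


def effect_size(x, outcome, effect_type: str) -> EffectSpec:
    """Observed effect size of one variable.

    ``pearson_r``: sample Pearson correlation with a continuous outcome.
    ``cohens_d``: |mean difference| / pooled sd between the two outcome
    levels.
    """
    x = np.asarray(x, dtype=float)
    name = getattr(x, "name", None) or "x"
    if effect_type == "pearson_r":
        outcome = np.asarray(outcome, dtype=float)
        if np.std(x) == 0 or np.std(outcome) == 0:
            raise ConfigurationError("zero variance; effect size undefined")
        r = float(np.corrcoef(x, outcome)[0, 1])
        return EffectSpec(variable=str(name), effect_type="pearson_r", value=r)
    if effect_type == "cohens_d":
        outcome = np.asarray(outcome)
        levels = np.unique(outcome)
        if levels.size != 2:
            raise ConfigurationError("cohens_d needs a two-level outcome")
        a, b = x[outcome == levels[0]], x[outcome == levels[1]]
        na, nb = a.size, b.size
        pooled = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1))
                         / (na + nb - 2))
        if pooled == 0:
            raise ConfigurationError("zero pooled sd; effect size undefined")
        d = float(abs(a.mean() - b.mean()) / pooled)
        return EffectSpec(variable=str(name), effect_type="cohens_d", value=d)
    raise ConfigurationError(f"unknown effect_type {effect_type!r}")


def effect_sizes(X: pd.DataFrame, outcome, effect_type: str) -> dict:
    """Observed effect size for every column of ``X``."""
    out = {}
    for c in X.columns:
        spec = effect_size(X[c].to_numpy(), outcome, effect_type)
        spec.variable = str(c)
        out[str(c)] = spec
    return out


def group_correlated(X: pd.DataFrame, effects: dict,
                     threshold: float = DEFAULT_GROUP_THRESHOLD) -> CorrelatedGroups:
    """Single-linkage grouping on |Pearson correlation| >= threshold.

    The representative of each group is its member with the largest
    absolute effect size (ties broken by column order).  Groups are
    reported in order of first appearance.
    """
    if not 0.0 < threshold < 1.0:
        raise ConfigurationError("threshold must be in (0, 1)")
    names = [str(c) for c in X.columns]
    corr = np.abs(np.corrcoef(X.to_numpy(dtype=float), rowvar=False))
    corr = np.atleast_2d(corr)
    p = len(names)
    # union-find single linkage
    parent = list(range(p))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(p):
        for j in range(i + 1, p):
            if corr[i, j] >= threshold:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)

    roots: dict[int, list[int]] = {}
    for i in range(p):
        roots.setdefault(find(i), []).append(i)
    groups, reps = [], []
    for root in sorted(roots):
        members = [names[i] for i in roots[root]]
        groups.append(members)
        with_eff = [v for v in members if v in effects]
        if with_eff:
            best_val = max(abs(effects[v].value) for v in with_eff)
            best = next(v for v in with_eff if abs(effects[v].value) == best_val)
        else:  # ties and missing effects both fall back to column order
            best = members[0]
        reps.append(best)
    return CorrelatedGroups(groups=groups, representatives=reps,
                            threshold=threshold, effects=effects)


def _mc_se(phat: float, reps: int) -> float:
    return float(np.sqrt(max(phat * (1.0 - phat), 0.0) / reps))


def _regression_pvals(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Two-sided p-values of the slope in simple regression of y on each
    column (equivalently the Pearson correlation test), vectorised."""
    n = X.shape[0]
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((Xc ** 2).sum(axis=0))
    sy = np.sqrt((yc ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc * yc[:, None]).sum(axis=0) / (sx * sy)
    r = np.clip(np.nan_to_num(r), -0.9999999, 0.9999999)
    t = r * np.sqrt((n - 2) / (1.0 - r ** 2))
    return 2.0 * stats.t.sf(np.abs(t), df=n - 2)


def _anova_pvals(Xa: np.ndarray, Xb: np.ndarray) -> np.ndarray:
    """One-way ANOVA p-value per column for two groups, vectorised."""
    na, nb = Xa.shape[0], Xb.shape[0]
    ma, mb = Xa.mean(axis=0), Xb.mean(axis=0)
    grand = (na * ma + nb * mb) / (na + nb)
    ss_between = na * (ma - grand) ** 2 + nb * (mb - grand) ** 2
    ss_within = ((Xa - ma) ** 2).sum(axis=0) + ((Xb - mb) ** 2).sum(axis=0)
    df_b, df_w = 1, na + nb - 2
    with np.errstate(invalid="ignore", divide="ignore"):
        F = (ss_between / df_b) / (ss_within / df_w)
    F = np.nan_to_num(F)
    return stats.f.sf(F, df_b, df_w)


def power_regression(model: LogNormalModel, target: EffectSpec,
                     partners: Sequence[str] = (), n_grid=DEFAULT_GRID,
                     alpha: float = 0.05, reps: int = DEFAULT_REPS,
                     seed: int = 0) -> PowerGrid:
    """Monte-Carlo power of a continuous-outcome association.

    Per replicate and sample size ``n``: synthesize ``n`` samples, build
    the outcome as ``r·standardize(target) + sqrt(1−r²)·noise`` so its
    population correlation with the target is the requested effect, and
    run the per-variable simple regression at level ``alpha``.  A
    replicate scores a hit when the significant set intersects the
    target-or-partners group; the FPR counts significant variables
    outside the group.
    """
    if target.effect_type != "pearson_r":
        raise ConfigurationError("power_regression needs a pearson_r effect")
    if abs(target.value) >= 1.0:
        raise ConfigurationError("power is undefined at |r| = 1")
    if reps < 50:
        warnings.warn(f"reps={reps} gives wide Monte-Carlo intervals", stacklevel=2)
    r = float(target.value)
    n_grid = _check_grid(n_grid)
    tgt = model.names.index(target.variable)
    group_idx = {tgt} | {model.names.index(v) for v in partners}
    out_idx = np.array(sorted(set(range(model.p)) - group_idx))
    rng = np.random.default_rng(seed)

    rows = []
    for n in n_grid:
        hits = 0
        tpr_sum = 0.0
        fpr_sum = 0.0
        for _ in range(reps):
            X = synthesize(model, n, rng=rng)
            x = X[:, tgt]
            sd = x.std()
            z = (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)
            y = r * z + np.sqrt(max(1.0 - r * r, 0.0)) * rng.standard_normal(n)
            pv = _regression_pvals(X, y)
            sig = pv < alpha
            group_sig = any(sig[i] for i in group_idx)
            hits += group_sig
            tpr_sum += float(sig[tgt])
            if out_idx.size:
                fpr_sum += float(sig[out_idx].mean())
        power = hits / reps
        rows.append({"variable": target.variable, "effect_type": "pearson_r",
                     "effect": r, "n": n, "power": power,
                     "tpr": tpr_sum / reps,
                     "fpr": fpr_sum / reps if out_idx.size else np.nan,
                     "reps": reps, "mc_se": _mc_se(power, reps)})
    return PowerGrid(table=pd.DataFrame(rows))


def power_classification(model: LogNormalModel, target: EffectSpec,
                         partners: Sequence[str] = (), n_grid=DEFAULT_GRID,
                         alpha: float = 0.05, reps: int = DEFAULT_REPS,
                         seed: int = 0) -> PowerGrid:
    """Monte-Carlo power of a two-group difference.

    Per replicate and per-group sample size ``n``: synthesize two groups
    of ``n``, shift the target and each partner in group two by
    ``d × sd`` (sd observed on the replicate's pooled pre-shift data, so
    the realized Cohen's d tracks the request), and run a one-way ANOVA
    per variable at level ``alpha``.  Hits and FPR as in the regression
    scheme.
    """
    if target.effect_type != "cohens_d":
        raise ConfigurationError("power_classification needs a cohens_d effect")
    if target.value < 0:
        raise ConfigurationError("cohens_d must be >= 0")
    if reps < 50:
        warnings.warn(f"reps={reps} gives wide Monte-Carlo intervals", stacklevel=2)
    d = float(target.value)
    n_grid = _check_grid(n_grid)
    tgt = model.names.index(target.variable)
    group_idx = {tgt} | {model.names.index(v) for v in partners}
    shift_idx = np.array(sorted(group_idx))
    out_idx = np.array(sorted(set(range(model.p)) - group_idx))
    rng = np.random.default_rng(seed)

    rows = []
    for n in n_grid:
        hits = 0
        tpr_sum = 0.0
        fpr_sum = 0.0
        for _ in range(reps):
            Xa = synthesize(model, n, rng=rng)
            Xb = synthesize(model, n, rng=rng)
            sd = np.vstack([Xa, Xb])[:, shift_idx].std(axis=0, ddof=1)
            Xb[:, shift_idx] += d * sd
            pv = _anova_pvals(Xa, Xb)
            sig = pv < alpha
            hits += any(sig[i] for i in group_idx)
            tpr_sum += float(sig[tgt])
            if out_idx.size:
                fpr_sum += float(sig[out_idx].mean())
        power = hits / reps
        rows.append({"variable": target.variable, "effect_type": "cohens_d",
                     "effect": d, "n": n, "power": power,
                     "tpr": tpr_sum / reps,
                     "fpr": fpr_sum / reps if out_idx.size else np.nan,
                     "reps": reps, "mc_se": _mc_se(power, reps)})
    return PowerGrid(table=pd.DataFrame(rows))


def sample_size_recommendation(grid_row: PowerGrid, power_target: float,
                               variable: Optional[str] = None):
    """Smallest grid sample size reaching ``power_target``.

    Returns an int, or the string ``"beyond grid"`` when even the
    largest grid point falls short.
    """
    if not 0.0 < power_target <= 1.0:
        raise ConfigurationError("power_target must be in (0, 1]")
    tab = grid_row.table
    if variable is not None:
        tab = tab[tab["variable"] == variable]
    if tab.empty:
        raise ConfigurationError("empty power grid")
    tab = tab.sort_values("n")
    ok = tab[tab["power"] >= power_target]
    if ok.empty:
        return "beyond grid"
    return int(ok["n"].iloc[0])


def effect_size_label(effect_type: str, value: float) -> str:
    """Verbal magnitude label (Cohen / Sawilowsky convention); annotation only."""
    v = abs(value)
    if effect_type == "pearson_r":
        cuts = [(0.5, "large"), (0.3, "medium"), (0.1, "small")]
    else:
        cuts = [(2.0, "huge"), (1.2, "very large"), (0.8, "large"),
                (0.5, "medium"), (0.2, "small")]
    for cut, label in cuts:
        if v >= cut:
            return label
    return "negligible"


def _check_grid(n_grid) -> list[int]:
    grid = [int(n) for n in n_grid]
    if not grid:
        raise ConfigurationError("empty sample-size grid")
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise ConfigurationError("sample-size grid must be strictly increasing")
    if grid[0] < 2:
        raise ConfigurationError("sample sizes must be >= 2")
    return grid
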