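"""Simulated omics-style datasets with known ground truth.

The generator produces a samples × features matrix in which the first
``n_groups × group_size`` columns form correlated blocks: each block ``i``
is built from a latent variable ``x_i`` plus noise whose scale grows with
the within-group index ``j``, so correlation with the latent decays along
the block.  A continuous outcome ``y`` is a nonlinear function of the
first three latents only, which makes groups 1-3 informative, groups 4-6
correlated-but-uninformative, and every remaining column pure noise.

The outcome for latents ``(x1, x2, x3)`` is

    y = 0.25·exp(4·x1) + 4 / (1 + exp(-20·(x2 - 0.5))) + 3·x3 + ε,

with ε ~ N(0, noise_sd_outcome).  The three terms decay in how strongly
they correlate with ``y``, giving a graded signal across the informative
groups.  Latents are either U(0,1) (``uniform01``) or standard normal
(``standard_normal``); for classification the outcome is split at its
mean (uniform scheme) or median (normal scheme, which balances the
classes under the skewed exp term).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "Dataset",
    "simulate_uniform",
    "simulate_normal",
    "simulate",
    "eval_outcome",
    "binarize_outcome",
    "TRUTH_INFORMATIVE",
    "TRUTH_CORRELATED",
    "TRUTH_NOISE",
]

TRUTH_INFORMATIVE = "informative"
TRUTH_CORRELATED = "correlated_noninformative"
TRUTH_NOISE = "noise"


class ConfigurationError(ValueError):
    """Raised when a simulation or run configuration is invalid."""


class DegenerateOutcomeError(ValueError):
    """Raised when an outcome vector cannot support the requested task."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic dataset generator.

    Defaults correspond to the reference simulation design: 200
    observations, 5000 predictors of which sixty (six groups of ten) are
    correlated, group-noise sd 0.3 and outcome-noise sd 0.2.
    """

    n_obs: int = 200
    p_total: int = 5000
    n_groups: int = 6
    group_size: int = 10
    base_distribution: Literal["uniform01", "standard_normal"] = "uniform01"
    noise_sd_group: float = 0.3
    noise_sd_outcome: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_obs", "p_total", "n_groups", "group_size"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v <= 0:
                raise ConfigurationError(f"{name} must be a positive integer, got {v!r}")
        if self.n_groups * self.group_size > self.p_total:
            raise ConfigurationError(
                "n_groups * group_size exceeds p_total "
                f"({self.n_groups}*{self.group_size} > {self.p_total})"
            )
        if self.noise_sd_group <= 0 or self.noise_sd_outcome <= 0:
            raise ConfigurationError("noise standard deviations must be strictly positive")
        if self.base_distribution not in ("uniform01", "standard_normal"):
            raise ConfigurationError(
                f"unknown base_distribution {self.base_distribution!r}"
            )


@dataclass
class Dataset:
    """A feature matrix with outcome(s) and optional ground truth.

    Attributes
    ----------
    X : pandas.DataFrame
        n_obs × p numeric matrix, columns named ``V1 .. Vp``.
    y : pandas.Series
        Continuous outcome.
    y_class : pandas.Series, optional
        Binary class labels (two non-empty levels).
    truth : pandas.Series, optional
        Per-variable label in {informative, correlated_noninformative,
        noise}, indexed by variable name.
    latents : pandas.DataFrame, optional
        The latent ``x_i`` draws (diagnostic; simulated data only).
    """

    X: pd.DataFrame
    y: pd.Series
    y_class: Optional[pd.Series] = None
    truth: Optional[pd.Series] = None
    latents: Optional[pd.DataFrame] = None
    config: Optional[SimulationConfig] = None

    def __post_init__(self) -> None:
        if self.X.isna().any().any():
            raise ValueError("feature matrix contains missing values")
        if len(self.X) != len(self.y):
            raise ValueError("rows of X and length of y differ")
        if self.y_class is not None:
            levels = pd.unique(self.y_class)
            if len(levels) != 2:
                raise DegenerateOutcomeError(
                    f"y_class must have exactly two levels, got {len(levels)}"
                )

    @property
    def n_obs(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def variables(self) -> list[str]:
        return list(self.X.columns)

    def outcome(self, task: str) -> pd.Series:
        """Return the outcome for ``task`` ('regression' or 'classification')."""
        if task == "regression":
            return self.y
        if task == "classification":
            if self.y_class is None:
                raise DegenerateOutcomeError("dataset has no class outcome")
            return self.y_class
        raise ValueError(f"unknown task {task!r}")


def eval_outcome(x1: float, x2: float, x3: float, noise: float = 0.0):
    """Nonlinear outcome as a function of the first three latents.

    ``0.25·exp(4·x1) + 4/(1+exp(-20·(x2-0.5))) + 3·x3 + noise``.
    Accepts scalars or arrays (vectorised).
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    x3 = np.asarray(x3, dtype=float)
    out = 0.25 * np.exp(4.0 * x1) + 4.0 / (1.0 + np.exp(-20.0 * (x2 - 0.5))) + 3.0 * x3 + noise
    if out.ndim == 0:
        return float(out)
    return out


def binarize_outcome(y, rule: Literal["mean", "median"] = "mean") -> np.ndarray:
    """Split a continuous outcome into two classes.

    ``rule='mean'``: class 1 below the mean, class 2 otherwise.
    ``rule='median'``: class 1 below the median, class 2 otherwise (gives a
    near-balanced split even for skewed outcomes).
    """
    y = np.asarray(y, dtype=float)
    if np.ptp(y) == 0:
        raise DegenerateOutcomeError("outcome is constant; cannot binarize")
    if rule == "mean":
        cut = y.mean()
    elif rule == "median":
        cut = np.median(y)
    else:
        raise ConfigurationError(f"unknown binarization rule {rule!r}")
    classes = np.where(y < cut, 1, 2)
    if len(np.unique(classes)) < 2:
        # ties exactly at the cutoff can empty a class; move them below
        classes = np.where(y <= cut, 1, 2)
    if len(np.unique(classes)) < 2:
        raise DegenerateOutcomeError("binarization produced a single class")
    return classes


def _noise_coefficient(j: int, group_size: int) -> float:
    """Noise multiplier for the j-th (1-based) member of a correlated group."""
    if group_size == 1:
        return 0.01
    return 0.01 + 0.5 * (j - 1) / (group_size - 1)


def simulate(config: SimulationConfig) -> Dataset:
    """Generate a dataset under ``config`` (dispatches on base distribution)."""
    rng = np.random.default_rng(config.seed)
    n, p = config.n_obs, config.p_total
    g, m = config.n_groups, config.group_size

    if config.base_distribution == "uniform01":
        latents = rng.uniform(0.0, 1.0, size=(n, g))
        draw_rest = lambda size: rng.uniform(0.0, 1.0, size=size)  # noqa: E731
        class_rule = "mean"
    else:
        latents = rng.standard_normal(size=(n, g))
        draw_rest = rng.standard_normal
        class_rule = "median"

    X = np.empty((n, p), dtype=float)
    col = 0
    for i in range(g):
        for j in range(1, m + 1):
            coef = _noise_coefficient(j, m)
            X[:, col] = latents[:, i] + coef * rng.normal(0.0, config.noise_sd_group, size=n)
            col += 1
    n_noise = p - col
    if n_noise:
        X[:, col:] = draw_rest((n, n_noise))

    y = eval_outcome(
        latents[:, 0],
        latents[:, 1] if g >= 2 else np.zeros(n),
        latents[:, 2] if g >= 3 else np.zeros(n),
        noise=rng.normal(0.0, config.noise_sd_outcome, size=n),
    )
    y_class = binarize_outcome(y, rule=class_rule)

    names = [f"V{k}" for k in range(1, p + 1)]
    truth = np.full(p, TRUTH_NOISE, dtype=object)
    n_inf_groups = min(3, g)
    truth[: n_inf_groups * m] = TRUTH_INFORMATIVE
    truth[n_inf_groups * m : g * m] = TRUTH_CORRELATED

    return Dataset(
        X=pd.DataFrame(X, columns=names),
        y=pd.Series(y, name="y"),
        y_class=pd.Series(y_class, name="y_class"),
        truth=pd.Series(truth, index=names, name="truth"),
        latents=pd.DataFrame(latents, columns=[f"x{i+1}" for i in range(g)]),
        config=config,
    )


def simulate_uniform(config: Optional[SimulationConfig] = None, **kwargs) -> Dataset:
    """Uniform-latent simulation (classes split at the outcome mean)."""
    if config is None:
        config = SimulationConfig(base_distribution="uniform01", **kwargs)
    if config.base_distribution != "uniform01":
        raise ConfigurationError("simulate_uniform requires base_distribution='uniform01'")
    return simulate(config)


def simulate_normal(config: Optional[SimulationConfig] = None, **kwargs) -> Dataset:
    """Standard-normal-latent simulation (classes split at the outcome median)."""
    if config is None:
        config = SimulationConfig(base_distribution="standard_normal", **kwargs)
    if config.base_distribution != "standard_normal":
        raise ConfigurationError(
            "simulate_normal requires base_distribution='standard_normal'"
        )
    return simulate(config)
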