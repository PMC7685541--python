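"""Tabular I/O and report files.

Input is a samples × features CSV/TSV with a header row; one column
holds the outcome.  Outputs are TSV tables plus a JSON summary, written
with deterministic column order so reruns with the same configuration
are byte-identical.
"""

from __future__ import annotations

import json
import sys
import warnings
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .power import PowerGrid, sample_size_recommendation
from .simdata import Dataset, DegenerateOutcomeError
from .stability import FrequencyTable, StabilityReport

__all__ = ["read_table", "write_dataset", "write_stability_report",
           "write_power_report", "provenance_record"]


class TableFormatError(ValueError):
    """Raised for unparseable or contract-violating input tables."""


def _read_raw(path, transpose=False) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep, index_col=None)
    if transpose:
        df = df.set_index(df.columns[0]).T.reset_index(drop=True)
    return df


def read_table(path, outcome_column: str = "y", class_mode: bool = False,
               class_column: Optional[str] = None,
               transpose: bool = False) -> Dataset:
    """Load a Dataset from a CSV/TSV file.

    Samples are rows and features columns (``transpose=True`` for the
    other dialect).  ``outcome_column`` is parsed as the continuous
    outcome, or as a two-level class outcome when ``class_mode`` is
    set; ``class_column`` optionally names an additional class column.
    Rows with a missing outcome are dropped (with a warning giving the
    count); missing or non-numeric feature cells are a hard error
    naming the offending column.
    """
    df = _read_raw(path, transpose=transpose)
    if outcome_column not in df.columns:
        raise TableFormatError(
            f"outcome column {outcome_column!r} not found in {path} "
            "(set --outcome-column)")
    n_missing = int(df[outcome_column].isna().sum())
    if n_missing:
        warnings.warn(f"dropped {n_missing} rows with missing outcome",
                      stacklevel=2)
        df = df[df[outcome_column].notna()].reset_index(drop=True)

    outcome = df[outcome_column]
    drop = [outcome_column]
    y_class = None
    if class_column is not None:
        if class_column not in df.columns:
            raise TableFormatError(f"class column {class_column!r} not found")
        y_class = df[class_column]
        drop.append(class_column)

    feat = df.drop(columns=drop)
    numeric = feat.apply(pd.to_numeric, errors="coerce")
    bad = numeric.columns[numeric.isna().any()]
    if len(bad):
        col = bad[0]
        row = int(numeric[col].isna().idxmax())
        raise TableFormatError(
            f"non-numeric or missing feature value at row {row}, column {col!r}")

    if class_mode:
        levels = pd.unique(outcome.dropna())
        if len(levels) != 2:
            raise DegenerateOutcomeError(
                f"class outcome must have exactly 2 levels, found {len(levels)}")
        y_class = outcome
        y = pd.to_numeric(outcome, errors="coerce")
        if y.isna().any():  # labels may be non-numeric; keep a numeric stand-in
            y = pd.Series(pd.factorize(outcome)[0].astype(float), name="y")
    else:
        y = pd.to_numeric(outcome, errors="raise")

    if y_class is not None:
        levels = pd.unique(y_class)
        if len(levels) != 2:
            raise DegenerateOutcomeError(
                f"class column must have exactly 2 levels, found {len(levels)}")
        y_class = pd.Series(y_class.to_numpy(), name="y_class")

    return Dataset(X=numeric.reset_index(drop=True),
                   y=pd.Series(y.to_numpy(dtype=float), name="y"),
                   y_class=y_class)


def write_dataset(dataset: Dataset, path, sidecar: bool = True) -> list[Path]:
    """Write a Dataset as CSV (features, y, optional y_class) plus a JSON
    sidecar with truth labels and the generating configuration."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = dataset.X.copy()
    out["y"] = dataset.y.to_numpy()
    if dataset.y_class is not None:
        out["y_class"] = dataset.y_class.to_numpy()
    out.to_csv(path, index=False)
    written = [path]
    if sidecar:
        side = path.with_suffix(path.suffix + ".json")
        payload = {
            "truth": dataset.truth.to_dict() if dataset.truth is not None else None,
            "config": config_dict(dataset.config),
        }
        side.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        written.append(side)
    return written


def config_dict(config):
    if config is None:
        return None
    from dataclasses import asdict
    return asdict(config)


def write_stability_report(freq: FrequencyTable, report: StabilityReport,
                           outdir, prefix: str = "stability") -> list[Path]:
    """Write frequency TSV, one stable-set TSV per method, and the JSON
    summary.  Empty stable sets produce a header-only TSV and a flag in
    the JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    fpath = outdir / f"{prefix}_frequencies.tsv"
    freq.counts.rename_axis("variable").reset_index().to_csv(
        fpath, sep="\t", index=False, float_format="%.6g")
    written.append(fpath)

    for method in freq.counts.columns:
        spath = outdir / f"{prefix}_stable_{method}.tsv"
        ls, hs = set(report.ls_sets[method]), set(report.hs_sets[method])
        rows = [{"variable": v, "ls": int(v in ls), "hs": int(v in hs)}
                for v in sorted(ls, key=list(freq.counts.index).index)]
        pd.DataFrame(rows, columns=["variable", "ls", "hs"]).to_csv(
            spath, sep="\t", index=False)
        written.append(spath)

    jpath = outdir / f"{prefix}_report.json"
    payload = {
        "ls_sets": {m: list(v) for m, v in report.ls_sets.items()},
        "hs_sets": {m: list(v) for m, v in report.hs_sets.items()},
        "truth_eval": {m: {s: list(tpfp) for s, tpfp in d.items()}
                       for m, d in report.truth_eval.items()},
        "validation": report.validation.to_dict(orient="records"),
        "flags": list(report.flags)
                 + [f"{m} {s} set empty"
                    for m in report.hs_sets
                    for s, ss in (("ls", report.ls_sets[m]), ("hs", report.hs_sets[m]))
                    if not ss],
        "n_iterations": freq.n_iterations,
        "n_rotations": freq.n_rotations,
    }
    jpath.write_text(json.dumps(payload, indent=2, sort_keys=True,
                                default=_json_default) + "\n")
    written.append(jpath)
    return written


def write_power_report(grids: list[PowerGrid], outdir, power_target: float = 0.8,
                       prefix: str = "power") -> list[Path]:
    """Write the long-format power TSV and a JSON summary with
    sample-size recommendations at ``power_target``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table = pd.concat([g.table for g in grids], ignore_index=True)
    cols = ["variable", "effect_type", "effect", "n", "power", "tpr", "fpr",
            "reps", "mc_se"]
    tpath = outdir / f"{prefix}_grid.tsv"
    table[cols].to_csv(tpath, sep="\t", index=False, float_format="%.6g")

    summary = {}
    for g in grids:
        var = str(g.table["variable"].iloc[0])
        rec = sample_size_recommendation(g, power_target)
        summary[var] = {
            "effect_type": str(g.table["effect_type"].iloc[0]),
            "effect": float(g.table["effect"].iloc[0]),
            "recommended_n": rec,
            "power_target": power_target,
        }
    jpath = outdir / f"{prefix}_summary.json"
    jpath.write_text(json.dumps(summary, indent=2, sort_keys=True,
                                default=_json_default) + "\n")
    return [tpath, jpath]


def provenance_record(outdir, command: str, params: dict, seed) -> Path:
    """Write a JSON provenance record (command, parameters, seed,
    versions) alongside the outputs."""
    import sklearn

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rec = {
        "command": command,
        "params": params,
        "seed": seed,
        "versions": {
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__,
        },
    }
    path = outdir / f"{command}_provenance.json"
    path.write_text(json.dumps(rec, indent=2, sort_keys=True,
                               default=_json_default) + "\n")
    return path


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (set, tuple)):
        return list(o)
    if isinstance(o, float) and np.isnan(o):
        return None
    return str(o)
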