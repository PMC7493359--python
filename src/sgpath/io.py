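"""Delimited-text readers and writers for problem inputs and path outputs.

Input layout
------------
* y file: one numeric column (the response), no header.
* X file (optional): q numeric columns of unpenalized covariates.
* Z file: p numeric columns; an optional header row carries feature
  identifiers (otherwise features are named f1..fp by position).
* groups file: two columns, feature_id <tab> group_label, one row per
  penalized feature.
* weights file (optional): two columns, feature_id <tab> weight; absent
  file means unit weights.

Output layout
-------------
* ``<prefix>_coefficients.tsv``: long format with columns lambda_index,
  lambda, coefficient_id, group_label (empty for unpenalized effects) and
  estimate, ordered by decreasing lambda then input feature order.
* ``<prefix>_diagnostics.tsv``: one row per lambda with iterations,
  convergence flag, KKT residual and exact non-zero count.

Floats are written with 17 significant digits so a round trip reproduces
every estimate bit for bit.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DuplicateFeatureError, ParseError, UnknownFeatureError
from .problem import Hyperparameters, ProblemData, validate_problem
from .solver import PathResult

__all__ = ["RunConfig", "read_problem", "write_path"]

_FLOAT_FMT = "%.17g"


@dataclass
class RunConfig:
    """File paths, parsing options and solver settings for one CLI run."""

    y_path: str
    z_path: str
    groups_path: str
    x_path: str | None = None
    weights_path: str | None = None
    delimiter: str = "\t"
    header: bool = True
    hyperparameters: Hyperparameters = field(default_factory=Hyperparameters)
    out_prefix: str = "sgpath"
    verbosity: int = 1


def _read_table(path: str, delimiter: str, header: bool) -> pd.DataFrame:
    try:
        return pd.read_csv(
            path, sep=delimiter, header=0 if header else None, dtype=float
        )
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise ParseError(f"could not parse {path!r} as a delimited table: {exc}")


def _read_two_column(path: str, delimiter: str, what: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep=delimiter, header=None, dtype=str)
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise ParseError(f"could not parse {what} file {path!r}: {exc}")
    if df.shape[1] != 2:
        raise ParseError(
            f"{what} file {path!r} must have exactly two columns, "
            f"got {df.shape[1]}"
        )
    if df[0].duplicated().any():
        dup = df[0][df[0].duplicated()].iloc[0]
        raise DuplicateFeatureError(
            f"feature {dup!r} occurs more than once in {what} file {path!r}"
        )
    return df


def read_problem(config: RunConfig) -> ProblemData:
    """Assemble and validate a ProblemData from the configured files."""
    y = np.loadtxt(config.y_path, delimiter=None, ndmin=1)
    if y.ndim != 1:
        raise ParseError(f"y file {config.y_path!r} must hold a single column")

    zdf = _read_table(config.z_path, config.delimiter, config.header)
    if config.header:
        feature_ids = [str(c) for c in zdf.columns]
    else:
        feature_ids = [f"f{j + 1}" for j in range(zdf.shape[1])]
    if len(set(feature_ids)) != len(feature_ids):
        raise DuplicateFeatureError(
            f"Z header in {config.z_path!r} contains duplicated feature ids"
        )
    Z = zdf.to_numpy(dtype=float)

    gdf = _read_two_column(config.groups_path, config.delimiter, "groups")
    group_of = dict(zip(gdf[0], gdf[1]))
    unknown = set(gdf[0]) - set(feature_ids)
    if unknown:
        raise UnknownFeatureError(
            f"groups file references features absent from Z: {sorted(unknown)[:5]}"
        )
    missing = [f for f in feature_ids if f not in group_of]
    if missing:
        raise UnknownFeatureError(
            f"groups file lacks an entry for Z features: {missing[:5]}"
        )
    groups = np.array([group_of[f] for f in feature_ids], dtype=object)

    weights = None
    if config.weights_path is not None:
        wdf = _read_two_column(config.weights_path, config.delimiter, "weights")
        unknown = set(wdf[0]) - set(feature_ids)
        if unknown:
            raise UnknownFeatureError(
                f"weights file references features absent from Z: "
                f"{sorted(unknown)[:5]}"
            )
        w_of = {k: float(v) for k, v in zip(wdf[0], wdf[1])}
        missing = [f for f in feature_ids if f not in w_of]
        if missing:
            raise UnknownFeatureError(
                f"weights file lacks an entry for Z features: {missing[:5]}"
            )
        weights = np.array([w_of[f] for f in feature_ids])

    X = None
    unpen_ids = None
    if config.x_path is not None:
        xdf = _read_table(config.x_path, config.delimiter, config.header)
        X = xdf.to_numpy(dtype=float)
        unpen_ids = (
            [str(c) for c in xdf.columns]
            if config.header
            else [f"b{j + 1}" for j in range(X.shape[1])]
        )

    return validate_problem(
        ProblemData(
            y=y,
            Z=Z,
            groups=groups,
            X=X,
            feature_weights=weights,
            feature_ids=feature_ids,
            unpenalized_ids=unpen_ids,
        )
    )


def write_path(path: PathResult, config: RunConfig) -> tuple[str, str]:
    """Write coefficient and diagnostics tables; returns the two paths."""
    coef_path = f"{config.out_prefix}_coefficients.tsv"
    diag_path = f"{config.out_prefix}_diagnostics.tsv"
    d = config.delimiter

    with open(coef_path, "w") as fh:
        fh.write(d.join(
            ["lambda_index", "lambda", "coefficient_id", "group_label", "estimate"]
        ) + "\n")
        for k, (lam, state) in enumerate(zip(path.grid.values, path.states)):
            lam_s = _FLOAT_FMT % lam
            for j, name in enumerate(path.unpenalized_ids):
                fh.write(d.join(
                    [str(k), lam_s, name, "", _FLOAT_FMT % state.b[j]]
                ) + "\n")
            for j, name in enumerate(path.feature_ids):
                fh.write(d.join(
                    [str(k), lam_s, name, str(path.feature_group_labels[j]),
                     _FLOAT_FMT % state.u[j]]
                ) + "\n")

    with open(diag_path, "w") as fh:
        fh.write(d.join(
            ["lambda", "iterations", "converged", "kkt_residual", "nonzero_count"]
        ) + "\n")
        for lam, st, dg in zip(path.grid.values, path.states, path.diagnostics):
            fh.write(d.join([
                _FLOAT_FMT % lam,
                str(dg.iterations),
                str(dg.converged),
                _FLOAT_FMT % dg.kkt_residual,
                str(int(np.count_nonzero(st.u))),
            ]) + "\n")

    if config.verbosity >= 1:
        print(f"wrote {coef_path} and {diag_path}", file=sys.stderr)
    return coef_path, diag_path
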