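"""Delimited-text input/output.

Abundance matrices are read from CSV/TSV with sites in rows: the first
column holds site identifiers and the header row species names.  Covariate
files follow the same convention and are aligned to the response matrix by
site identifier, not row order.  Parameter sets round-trip through a flat
JSON representation with named blocks.
"""

from __future__ import annotations

import json
import os
from typing import Optional

import numpy as np
import pandas as pd

from .model_core import AbundanceData, ParameterSet

__all__ = [
    "read_abundance",
    "write_abundance",
    "params_to_json",
    "params_from_json",
]


def _read_table(path: str, transpose: bool = False) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    if transpose:
        df = df.T
    for i, row in enumerate(df.itertuples(index=False)):
        for j, val in enumerate(row):
            if not isinstance(val, (int, float, np.integer, np.floating)):
                raise ValueError(
                    f"{path}: non-numeric cell at row {df.index[i]!r}, "
                    f"column {df.columns[j]!r}: {val!r}"
                )
    if df.isna().any().any():
        where = np.argwhere(df.isna().values)[0]
        raise ValueError(
            f"{path}: missing value at row {df.index[where[0]]!r}, "
            f"column {df.columns[where[1]]!r}"
        )
    return df


def read_abundance(
    path: str,
    covariates_path: Optional[str] = None,
    family: str = "poisson",
    link: Optional[str] = None,
    transpose: bool = False,
) -> AbundanceData:
    """Read a response matrix (and optional covariates) from delimited text."""
    ydf = _read_table(path, transpose=transpose)
    Y = ydf.values.astype(float)
    if family in ("poisson", "negative_binomial", "nb", "bernoulli"):
        bad = np.argwhere((Y < 0) | (Y != np.round(Y)))
        if bad.size:
            i, j = bad[0]
            raise ValueError(
                f"{path}: invalid count at row {ydf.index[i]!r}, "
                f"column {ydf.columns[j]!r}: {Y[i, j]}"
            )
    X = None
    if covariates_path is not None:
        xdf = _read_table(covariates_path)
        missing = [s for s in ydf.index if s not in xdf.index]
        if missing:
            raise ValueError(
                f"{covariates_path}: site IDs missing from covariate file: "
                f"{missing[:5]}"
            )
        xdf = xdf.loc[ydf.index]
        X = xdf.values.astype(float)
    return AbundanceData(
        Y=Y,
        X=X,
        family=family,
        link=link,
        site_ids=list(ydf.index),
        species_names=list(ydf.columns),
    )


def write_abundance(data: AbundanceData, path: str, covariates_path: Optional[str] = None):
    sites = data.site_ids or [f"site{i+1}" for i in range(data.n)]
    species = data.species_names or [f"sp{j+1}" for j in range(data.m)]
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    Y = data.Y
    if np.all(Y == np.round(Y)):
        Y = Y.astype(int)
    pd.DataFrame(Y, index=sites, columns=species).to_csv(path, sep=sep, index_label="site")
    if covariates_path is not None and data.X is not None:
        cols = [f"x{l+1}" for l in range(data.k)]
        pd.DataFrame(data.X, index=sites, columns=cols).to_csv(
            covariates_path, sep=sep, index_label="site"
        )


def params_to_json(params: ParameterSet, path: Optional[str] = None):
    obj = {
        "beta0": params.beta0.tolist(),
        "B": None if params.B is None else params.B.tolist(),
        "Gamma": params.Gamma.tolist(),
        "phi": None if params.phi is None else params.phi.tolist(),
        "sigma2": params.sigma2,
    }
    if path is not None:
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)
    return obj


def params_from_json(source) -> ParameterSet:
    if isinstance(source, (str, os.PathLike)):
        with open(source) as fh:
            obj = json.load(fh)
    else:
        obj = source
    return ParameterSet(
        beta0=np.asarray(obj["beta0"], dtype=float),
        B=None if obj.get("B") is None else np.asarray(obj["B"], dtype=float),
        Gamma=np.asarray(obj["Gamma"], dtype=float),
        phi=None if obj.get("phi") is None else np.asarray(obj["phi"], dtype=float),
        sigma2=obj.get("sigma2"),
    ).validate()
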