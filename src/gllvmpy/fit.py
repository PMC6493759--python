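"""Convenience driver tying starting values to the two engines, with
multi-start handling (the best objective across sets wins)."""

from __future__ import annotations

from typing import Optional

from .fitbase import FitControl
from .laplace import fit_la
from .model_core import AbundanceData, ModelSpec
from .starting_values import make_start
from .variational import fit_va

__all__ = ["fit_model"]


def fit_model(
    data: AbundanceData,
    spec: ModelSpec,
    method: str = "va",
    start: str = "res",
    n_sets: int = 3,
    jitter_sd: float = 0.2,
    seed: int = 0,
    control: Optional[FitControl] = None,
):
    """Fit the model with the requested engine and starting-value strategy.

    With a multi-start strategy every set is fitted and the fit with the
    highest objective is returned.
    """
    if method not in ("va", "la"):
        raise ValueError(f"unknown method {method!r}; choose 'va' or 'la'")
    starts = make_start(
        data, spec, method=start, n_sets=n_sets, jitter_sd=jitter_sd, seed=seed
    )
    engine = fit_va if method == "va" else fit_la
    best = None
    for sv in starts:
        fit = engine(data, spec, sv, control)
        if best is None or fit.objective > best.objective:
            best = fit
    return best
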