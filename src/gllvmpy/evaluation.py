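"""Evaluation metrics and the simulation-study harness.

Implements the quantities used to compare engines on synthetic data: average
bias, RMSE, empirical coverage and mean width of Wald intervals per parameter
block; scaled Procrustes errors between estimated and true latent scores and
loadings; the variation-explained statistic against an intercept-only null;
and starting-strategy comparisons on the final objective.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence

import numpy as np

from .families import get_family
from .fit import fit_model
from .fitbase import FitControl
from .inference import standard_errors
from .laplace import LAFit
from .model_core import (
    AbundanceData,
    ModelSpec,
    ParameterSet,
    constrain_loadings,
    simulate_responses,
)
from .packing import ParamPacker
from .variational import VAFit

__all__ = [
    "SimulationDesign",
    "SimulationSummary",
    "procrustes_error",
    "variation_explained",
    "summarize_cell",
    "run_design",
    "compare_starts",
    "fitted_means",
    "null_means",
]


def procrustes_error(estimate: np.ndarray, truth: np.ndarray) -> float:
    """Per-entry RMS residual after full Procrustes superposition.

    The estimate is optimally translated, rotated/reflected and uniformly
    scaled onto the truth; the minimized residual sum of squares is divided
    by the number of entries and square-rooted.
    """
    E = np.atleast_2d(np.asarray(estimate, dtype=float))
    T = np.atleast_2d(np.asarray(truth, dtype=float))
    if E.shape != T.shape:
        raise ValueError("estimate and truth must have matching shapes")
    Ec = E - E.mean(axis=0)
    Tc = T - T.mean(axis=0)
    normE2 = np.sum(Ec**2)
    if normE2 <= 0:
        raise ValueError("estimate configuration has rank 0 after centering")
    # rotation from the SVD of the cross-product; scale from the trace
    M = Ec.T @ Tc
    _, s, _ = np.linalg.svd(M)
    trace = np.sum(s)
    ss = np.sum(Tc**2) - trace**2 / normE2
    ss = max(ss, 0.0)
    return float(np.sqrt(ss / T.size))


def variation_explained(mu_hat, mu_null_hat, mu_true) -> float:
    """VE = 1 - sum|mu_hat - mu| / sum|mu_null - mu| on the mean scale."""
    mu_hat = np.asarray(mu_hat, dtype=float)
    mu_null_hat = np.asarray(mu_null_hat, dtype=float)
    mu_true = np.asarray(mu_true, dtype=float)
    if not (mu_hat.shape == mu_null_hat.shape == mu_true.shape):
        raise ValueError("mean matrices must have matching shapes")
    denom = np.sum(np.abs(mu_null_hat - mu_true))
    if denom == 0:
        raise ValueError("variation explained undefined: null error is zero")
    return float(1.0 - np.sum(np.abs(mu_hat - mu_true)) / denom)


def fitted_means(fit) -> np.ndarray:
    """Predicted means from a fitted model at the predicted latent values."""
    data, spec, params = fit.data, fit.spec, fit.params
    fam = spec.family_obj()
    Gstar = params.gamma_star(spec.row_effect)
    fixed = np.tile(params.beta0, (data.n, 1))
    if data.X is not None and params.B is not None:
        fixed = fixed + data.X @ params.B.T
    if isinstance(fit, VAFit):
        a = fit.varstate.a
    elif isinstance(fit, LAFit):
        a = fit.latents_hat.ustar()
    else:
        raise TypeError(f"unsupported fit type {type(fit).__name__}")
    return fam.mean(fixed + a @ Gstar.T)


def null_means(data: AbundanceData, spec: ModelSpec) -> np.ndarray:
    """Means of per-species intercept-only GLMs (column means, clipped for
    binary data), broadcast to the data shape."""
    col = data.Y.mean(axis=0)
    if spec.family == "bernoulli":
        col = np.clip(col, 0.5 / data.n, 1.0 - 0.5 / data.n)
    else:
        col = np.maximum(col, 0.5 / data.n)
    return np.tile(col, (data.n, 1))


# ---------------------------------------------------------------------------
# simulation harness
# ---------------------------------------------------------------------------


@dataclass
class SimulationDesign:
    """Declarative description of a simulation study."""

    truth: ParameterSet
    spec: ModelSpec
    grid: Sequence[int]
    vary: str = "n"  # 'n' (sites) or 'm' (species)
    n_sites: Optional[int] = None  # required when vary == 'm'
    n_reps: int = 500
    engines: Sequence[str] = ("va",)
    start_method: str = "res"
    seed_base: int = 1000
    level: float = 0.95
    make_X: Optional[Callable[[int, np.random.Generator], np.ndarray]] = None

    def __post_init__(self):
        if len(self.grid) == 0:
            raise ValueError("grid must be nonempty")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.vary not in ("n", "m"):
            raise ValueError("vary must be 'n' or 'm'")
        if self.vary == "m" and self.n_sites is None:
            raise ValueError("varying m requires n_sites")


@dataclass
class SimulationSummary:
    cells: Dict = field(default_factory=dict)  # (engine, grid value) -> cell dict

    def table(self):
        import pandas as pd

        rows = []
        for (engine, g), cell in self.cells.items():
            for block, stats_ in cell["blocks"].items():
                rows.append(
                    dict(engine=engine, cell=g, block=block, **stats_)
                )
        return pd.DataFrame(rows)


def _subset_species(params: ParameterSet, idx: np.ndarray) -> ParameterSet:
    Gamma_sub = params.Gamma[idx]
    Gamma_new, _ = constrain_loadings(Gamma_sub)
    return ParameterSet(
        beta0=params.beta0[idx],
        B=None if params.B is None else params.B[idx],
        Gamma=Gamma_new,
        phi=None if params.phi is None else params.phi[idx],
        sigma2=params.sigma2,
    )


def summarize_cell(
    results: List[dict],
    truth: ParameterSet,
    spec: ModelSpec,
    level: float = 0.95,
) -> dict:
    """Aggregate replicate fits into bias/RMSE/coverage/CI-width per block.

    ``results`` holds per-replicate dicts with keys ``estimates``, ``se``,
    ``lower``, ``upper`` (free-vector arrays) plus optional metric entries
    (``procrustes_lv``, ``procrustes_loadings``, ``ve``, ``objective``).
    Failed replicates are passed as None and counted.
    """
    ok = [r for r in results if r is not None]
    n_failed = len(results) - len(ok)
    if not ok:
        return dict(blocks={}, n_ok=0, n_failed=n_failed, empty=True)
    m = truth.m
    k = truth.k
    ppack = ParamPacker(m, k, truth.d, truth.phi is not None, truth.sigma2 is not None)
    xtrue = ppack.pack(truth)
    blocks = {}
    block_names = ["beta0"] + (["B"] if k > 0 else [])
    if truth.phi is not None:
        block_names.append("log_phi")
    if truth.sigma2 is not None:
        block_names.append("log_sigma2")
    for block in block_names:
        idx = ppack.block_indices(block)
        tr = xtrue[idx]
        est = np.stack([r["estimates"][idx] for r in ok])
        se = np.stack([r["se"][idx] for r in ok])
        lo = np.stack([r["lower"][idx] for r in ok])
        hi = np.stack([r["upper"][idx] for r in ok])
        dev = est - tr[None, :]
        cover_mask = (lo <= tr[None, :]) & (tr[None, :] <= hi)
        finite = np.isfinite(se)
        blocks[block] = dict(
            bias=float(np.mean(dev)),
            rmse=float(np.sqrt(np.mean(dev**2))),
            coverage=float(np.mean(cover_mask[finite])) if finite.any() else float("nan"),
            ci_width=float(np.mean((hi - lo)[finite])) if finite.any() else float("nan"),
        )
    out = dict(blocks=blocks, n_ok=len(ok), n_failed=n_failed, empty=False)
    for key in ("procrustes_lv", "procrustes_loadings", "ve", "objective"):
        vals = [r[key] for r in ok if key in r and r[key] is not None]
        if vals:
            out[f"mean_{key}"] = float(np.mean(vals))
            out[f"median_{key}"] = float(np.median(vals))
    return out


def _replicate_result(fit, report, truth_sub, latent_true, spec):
    from .variational import VAFit as _VAFit

    if isinstance(fit, _VAFit):
        lv_est = fit.varstate.a[:, (1 if spec.row_effect else 0):]
    else:
        lv_est = fit.latents_hat.U
    mu_true = get_family(spec.family, spec.link).mean(
        _true_eta(truth_sub, fit.data, latent_true, spec)
    )
    res = dict(
        estimates=report.estimates,
        se=report.se,
        lower=report.ci_lower,
        upper=report.ci_upper,
        objective=float(fit.objective),
        converged=bool(fit.converged),
        procrustes_lv=procrustes_error(lv_est, latent_true.U),
        procrustes_loadings=procrustes_error(fit.params.Gamma, truth_sub.Gamma),
        ve=variation_explained(
            fitted_means(fit), null_means(fit.data, spec), mu_true
        ),
    )
    return res


def _true_eta(params, data, latent, spec):
    from .model_core import linear_predictor

    return linear_predictor(params, data, latent, spec)


def run_design(design: SimulationDesign, out_dir: Optional[str] = None) -> SimulationSummary:
    """Run a full simulation study; deterministic given the design seeds.

    Per-replicate results are persisted as JSON under ``out_dir`` when given,
    and reloaded on rerun, so an interrupted study resumes where it stopped.
    """
    summary = SimulationSummary()
    control = FitControl()
    for g in design.grid:
        if design.vary == "n":
            truth = design.truth
            n = int(g)
        else:
            rng_idx = np.random.default_rng(design.seed_base + 7 * int(g))
            idx = np.sort(rng_idx.choice(design.truth.m, size=int(g), replace=False))
            truth = _subset_species(design.truth, idx)
            n = int(design.n_sites)
        per_engine = {e: [] for e in design.engines}
        for rep in range(design.n_reps):
            seed = design.seed_base + 1000 * int(g) + rep
            rngX = np.random.default_rng(seed + 500_000)
            X = None
            if truth.k > 0:
                maker = design.make_X or (lambda nn, rr: rr.standard_normal((nn, truth.k)))
                X = maker(n, rngX)
            data, latent = simulate_responses(truth, X, design.spec, n, seed)
            for engine in design.engines:
                rec = None
                cache = _cache_path(out_dir, engine, g, rep)
                if cache and os.path.exists(cache):
                    with open(cache) as fh:
                        rec = _decode(json.load(fh))
                else:
                    try:
                        fit = fit_model(
                            data, design.spec, method=engine,
                            start=design.start_method, seed=seed, control=control,
                        )
                        report = standard_errors(fit, level=design.level, control=control)
                        rec = _replicate_result(fit, report, truth, latent, design.spec)
                    except Exception:
                        rec = None
                    if cache:
                        with open(cache, "w") as fh:
                            json.dump(_encode(rec), fh)
                per_engine[engine].append(rec)
        for engine in design.engines:
            summary.cells[(engine, g)] = summarize_cell(
                per_engine[engine], truth, design.spec, design.level
            )
    return summary


def _cache_path(out_dir, engine, g, rep):
    if out_dir is None:
        return None
    os.makedirs(out_dir, exist_ok=True)
    return os.path.join(out_dir, f"rep_{engine}_{g}_{rep}.json")


def _encode(rec):
    if rec is None:
        return None
    out = {}
    for key, val in rec.items():
        out[key] = val.tolist() if isinstance(val, np.ndarray) else val
    return out


def _decode(rec):
    if rec is None:
        return None
    arrays = {"estimates", "se", "lower", "upper"}
    return {
        key: (np.asarray(val, dtype=float) if key in arrays else val)
        for key, val in rec.items()
    }


def compare_starts(
    data: AbundanceData,
    spec: ModelSpec,
    engine: str = "va",
    methods: Sequence[str] = ("res", "res3", "zero", "random"),
    seed: int = 0,
    control: Optional[FitControl] = None,
) -> dict:
    """Final objectives per starting strategy and differences versus res3.

    A negative difference means the strategy ended below the res3 reference.
    """
    if not methods:
        raise ValueError("methods must be nonempty")
    objectives = {}
    for method in methods:
        try:
            fit = fit_model(
                data, spec, method=engine, start=method, seed=seed, control=control
            )
            objectives[method] = float(fit.objective)
        except Exception:
            objectives[method] = None
    ref_fit = None
    if "res3" in objectives and objectives["res3"] is not None:
        ref = objectives["res3"]
    else:
        ref_fit = fit_model(data, spec, method=engine, start="res3", seed=seed, control=control)
        ref = float(ref_fit.objective)
    diffs = {
        meth: (None if obj is None else obj - ref) for meth, obj in objectives.items()
    }
    return dict(objectives=objectives, reference=ref, differences=diffs)
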