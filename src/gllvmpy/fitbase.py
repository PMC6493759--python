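"""Shared fitting infrastructure: control settings and the result base."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np


@dataclass
class FitControl:
    """Optimizer settings shared by both engines."""

    max_iter: int = 2000
    # relative objective-change tolerance (maps to L-BFGS-B ftol)
    ftol: float = 1e-10
    # gradient max-norm tolerance declaring convergence
    gtol: float = 1e-4
    inner_tol: float = 1e-9  # Laplace inner Newton gradient tolerance
    fd_step: float = 1e-5  # Laplace outer finite-difference step


@dataclass
class FitResult:
    """Common surface of a fitted model."""

    params: object
    objective: float
    converged: bool
    n_iter: int
    grad_norm: float
    start_objective: float
    spec: object = None
    data: object = None
    message: str = ""

    def __post_init__(self):
        if not np.isfinite(self.objective):
            raise ValueError("fit produced a non-finite objective")
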