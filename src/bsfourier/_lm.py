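"""Small dense Levenberg-Marquardt optimiser shared by the node-wise
consistency correction and the inverse (reference-frame) mapping.

Damping schedule: start at ``damping``; multiply by ``factor`` on a
rejected step, divide on an accepted one.  Stops on relative cost change
below ``rtol`` (accepted steps), absolute cost below ``atol`` or
``cost_tol``, or ``max_iter``.  An optional seeded jitter perturbs the
iterate when progress stalls above ``cost_tol`` (used by the mapping,
where flat regions of the cost can trap the descent).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LMParams", "LMResult", "lm_minimise"]


@dataclass
class LMParams:
    damping: float = 1e-3
    factor: float = 10.0
    max_iter: int = 100
    rtol: float = 1e-8
    atol: float = 1e-18


@dataclass
class LMResult:
    x: np.ndarray
    cost: float
    n_iter: int
    converged: bool
    initial_cost: float = np.nan


def lm_minimise(residual_fn, jac_fn, x0, params: LMParams | None = None, *,
                cost_tol: float = 0.0, jitter_scale: float = 0.0,
                jitter_after: int = 3, rng=None,
                project=None) -> LMResult:
    """Minimise ``||residual_fn(x)||^2`` from ``x0``.

    ``project`` (optional) maps trial iterates back into the feasible
    region (e.g. lattice support clamping).  The iteration count is the
    number of damped steps attempted.
    """
    if params is None:
        params = LMParams()
    x = np.asarray(x0, dtype=float).copy()
    if project is not None:
        x = project(x)
    r = residual_fn(x)
    cost = float(r @ r)
    initial_cost = cost
    lam = params.damping
    stall = 0
    n_iter = 0
    best_x, best_cost = x.copy(), cost
    converged = cost <= max(cost_tol, params.atol)
    while not converged and n_iter < params.max_iter:
        J = jac_fn(x)
        JtJ = J.T @ J
        g = J.T @ r
        diag = np.diag(JtJ).copy()
        floor = 1e-12 * max(diag.max(), 1.0)
        diag[diag < floor] = floor
        accepted = False
        while n_iter < params.max_iter:
            n_iter += 1
            try:
                step = np.linalg.solve(JtJ + lam * np.diag(diag), -g)
            except np.linalg.LinAlgError:
                lam *= params.factor
                continue
            x_new = x + step
            if project is not None:
                x_new = project(x_new)
            r_new = residual_fn(x_new)
            if not np.all(np.isfinite(r_new)):
                raise ValueError("non-finite residual during LM iteration")
            cost_new = float(r_new @ r_new)
            if cost_new < cost:
                rel = (cost - cost_new) / max(cost, np.finfo(float).tiny)
                x, r, cost = x_new, r_new, cost_new
                if cost < best_cost:
                    best_x, best_cost = x.copy(), cost
                lam = max(lam / params.factor, 1e-15)
                accepted = True
                if cost <= max(cost_tol, params.atol):
                    converged = True
                elif rel < params.rtol:
                    converged = True
                stall = stall + 1 if rel < 1e-10 else 0
                break
            lam *= params.factor
            if lam > 1e12:
                break
        if not accepted and lam > 1e12:
            if jitter_scale > 0.0 and cost > cost_tol and n_iter < params.max_iter:
                # damping exploded away from the target: restart nearby
                if rng is None:
                    rng = np.random.default_rng(0)
                x = x + rng.normal(0.0, jitter_scale, size=x.shape)
                if project is not None:
                    x = project(x)
                r = residual_fn(x)
                cost = float(r @ r)
                lam = params.damping
                stall = 0
                continue
            # no direction improves: local minimum to working precision
            converged = cost <= cost_tol or cost_tol == 0.0
            break
        if (jitter_scale > 0.0 and stall >= jitter_after
                and cost > cost_tol and not converged):
            if rng is None:
                rng = np.random.default_rng(0)
            x = x + rng.normal(0.0, jitter_scale, size=x.shape)
            if project is not None:
                x = project(x)
            r = residual_fn(x)
            cost = float(r @ r)
            stall = 0
    if best_cost < cost:
        x, cost = best_x, best_cost
    return LMResult(x=x, cost=cost, n_iter=n_iter, converged=converged,
                    initial_cost=initial_cost)
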