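"""Covariance Matrix Adaptation Evolution Strategy (CMA-ES).

A compact, seeded implementation of the (mu/mu_w, lambda) CMA-ES with
rank-one and rank-mu covariance updates, cumulative step-size
adaptation, and active (negative-weight) recombination, following
Hansen's canonical default parameterisation.  It is derivative-free and
suits the 6-parameter rigid-pose search of the registration stage
(smooth but ill-conditioned cost, moderate dimension, modest budgets).

Per-parameter scaling is supported by passing a vector ``sigma0``:
internally the problem is optimised in coordinates normalised by that
vector, which is equivalent to a diagonal initial covariance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class CMAResult:
    """Best point found plus the full per-evaluation history."""

    x: np.ndarray
    fun: float
    n_evaluations: int
    converged: bool
    history: list = field(default_factory=list)  # (eval_index, x, f)


def cma_es_minimize(
    fun,
    x0,
    sigma0,
    popsize: int = 50,
    max_evals: int = 2000,
    target_f: float | None = None,
    seed: int = 0,
    record_history: bool = True,
) -> CMAResult:
    """Minimise ``fun`` starting from ``x0``.

    Parameters
    ----------
    sigma0 : float or (n,) array
        Initial step size per coordinate.  A vector sets per-parameter
        scales (useful when coordinates mix units, e.g. degrees and mm).
    popsize : int
        Offspring per generation (lambda).
    max_evals : int
        Total evaluation budget; generations run until it is exhausted.
    target_f : float, optional
        Stop early once the best objective value reaches this target;
        the result is then flagged ``converged``.
    seed : int
        Seeds the sampler; identical seeds give identical runs.
    """
    x0 = np.asarray(x0, dtype=float).ravel()
    n = x0.size
    scale = np.broadcast_to(np.asarray(sigma0, dtype=float), (n,)).astype(float)
    if np.any(scale <= 0):
        raise ValueError("sigma0 must be positive")
    rng = np.random.default_rng(seed)

    lam = int(popsize)
    if lam < 4:
        raise ValueError("population size must be at least 4")
    mu = lam // 2

    # Recombination weights: positive for the mu best offspring, negative
    # (active CMA) for the worst, scaled per Hansen's default bounds.
    w_prime = np.log((lam + 1) / 2.0) - np.log(np.arange(1, lam + 1))
    mueff = w_prime[:mu].sum() ** 2 / np.sum(w_prime[:mu] ** 2)
    mueff_neg = w_prime[mu:].sum() ** 2 / np.sum(w_prime[mu:] ** 2)

    cc = (4 + mueff / n) / (n + 4 + 2 * mueff / n)
    cs = (mueff + 2) / (n + mueff + 5)
    c1 = 2 / ((n + 1.3) ** 2 + mueff)
    cmu = min(1 - c1, 2 * (mueff - 2 + 1 / mueff) / ((n + 2) ** 2 + mueff))
    damps = 1 + 2 * max(0.0, np.sqrt((mueff - 1) / (n + 1)) - 1) + cs
    chi_n = np.sqrt(n) * (1 - 1 / (4 * n) + 1 / (21 * n**2))

    alpha_mu = 1 + c1 / cmu
    alpha_mueff = 1 + 2 * mueff_neg / (mueff + 2)
    alpha_posdef = (1 - c1 - cmu) / (n * cmu)
    w = np.empty(lam)
    w[:mu] = w_prime[:mu] / w_prime[:mu].sum()
    w[mu:] = (
        min(alpha_mu, alpha_mueff, alpha_posdef)
        * w_prime[mu:]
        / np.abs(w_prime[mu:]).sum()
    )

    # State in normalised coordinates z, with x = x0 + scale * z.
    mean = np.zeros(n)
    sigma = 1.0
    C = np.eye(n)
    B = np.eye(n)
    D = np.ones(n)
    ps = np.zeros(n)
    pc = np.zeros(n)

    best_x = x0.copy()
    best_f = float(fun(best_x))
    n_evals = 1
    history = [(0, best_x.copy(), best_f)] if record_history else []
    converged = target_f is not None and best_f <= target_f

    gen = 0
    while n_evals < max_evals and not converged:
        gen += 1
        z = rng.standard_normal((lam, n))
        y = z @ (B * D).T  # y_i = B diag(D) z_i
        xs_norm = mean + sigma * y
        fs = np.full(lam, np.inf)
        n_done = 0
        for i in range(lam):
            x_real = x0 + scale * xs_norm[i]
            fs[i] = fun(x_real)
            if record_history:
                history.append((n_evals, x_real, float(fs[i])))
            if fs[i] < best_f:
                best_f = float(fs[i])
                best_x = x_real.copy()
            n_evals += 1
            n_done += 1
            if (target_f is not None and best_f <= target_f) or n_evals >= max_evals:
                break
        if target_f is not None and best_f <= target_f:
            converged = True
            break
        if n_done < lam:
            break  # budget exhausted mid-generation; skip a partial update

        order = np.argsort(fs)
        ysort = y[order]
        zsort = z[order]
        yw = w[:mu] @ ysort[:mu]
        zw = w[:mu] @ zsort[:mu]
        mean = mean + sigma * yw

        ps = (1 - cs) * ps + np.sqrt(cs * (2 - cs) * mueff) * (B @ zw)
        hsig = (
            np.linalg.norm(ps) / np.sqrt(1 - (1 - cs) ** (2 * gen)) / chi_n
            < 1.4 + 2 / (n + 1)
        )
        pc = (1 - cc) * pc + hsig * np.sqrt(cc * (2 - cc) * mueff) * yw

        # Negative weights are rescaled so the update stays positive
        # definite regardless of where the bad offspring lie.
        w_circ = w.copy()
        znorm2 = np.sum(zsort**2, axis=1)
        w_circ[mu:] = w[mu:] * n / np.maximum(znorm2[mu:], 1e-12)
        delta_hsig = (1 - hsig) * cc * (2 - cc)
        C = (
            (1 + c1 * delta_hsig - c1 - cmu * w.sum()) * C
            + c1 * np.outer(pc, pc)
            + cmu * (ysort.T * w_circ) @ ysort
        )
        sigma *= np.exp((cs / damps) * (np.linalg.norm(ps) / chi_n - 1))
        sigma = float(np.clip(sigma, 1e-16, 1e8))

        C = (C + C.T) / 2
        evals_C, B = np.linalg.eigh(C)
        D = np.sqrt(np.clip(evals_C, 1e-20, None))

    return CMAResult(
        x=best_x,
        fun=best_f,
        n_evaluations=n_evals,
        converged=converged,
        history=history,
    )
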