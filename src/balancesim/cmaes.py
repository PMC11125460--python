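"""Covariance Matrix Adaptation Evolution Strategy (CMA-ES).

A compact (mu/mu_w, lambda) implementation of the standard strategy: rank-mu
and rank-one covariance updates, cumulative step-size adaptation, and
log-linear recombination weights.  Box constraints are handled by repairing
samples onto the box and adding a quadratic out-of-box penalty to the
evaluated fitness, so the strategy itself remains unconstrained.

Deterministic given the seed; used here to tune the 42 controller gains but
written as a general function minimizer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np


@dataclass
class CMAResult:
    x_best: np.ndarray
    f_best: float
    evaluations: int
    generations: int
    stop_reason: str
    f_history: list = field(default_factory=list)
    meta_best: object = None


def default_popsize(n: int) -> int:
    return 4 + int(3 * math.log(n))


def minimize(func, x0, sigma0, *, bounds=None, popsize=None, seed=0,
             max_generations=300, ftarget=None, accept=None,
             penalty_weight=1e4, tol_sigma=1e-12, tol_flat=1e-14):
    """Minimize ``func`` with CMA-ES.

    Parameters
    ----------
    func : callable(x) -> float or (float, meta)
        Objective; an optional second return value is carried along with
        the incumbent (used to attach trajectories to solutions).
    bounds : (lo, hi) arrays or None
        Box; samples are clipped onto it and penalized quadratically for
        the repair distance.
    ftarget : float or None
        Stop as soon as the best fitness reaches this value (and, when
        ``accept`` is given, the accept predicate holds for its meta).
    accept : callable(meta) -> bool or None
        Extra condition on the incumbent for ftarget-based stopping.
    """
    x0 = np.asarray(x0, dtype=float)
    n = x0.size
    lam = popsize if popsize else default_popsize(n)
    mu = lam // 2
    w = np.log(mu + 0.5) - np.log(np.arange(1, mu + 1))
    w /= w.sum()
    mueff = 1.0 / np.sum(w ** 2)

    cc = (4 + mueff / n) / (n + 4 + 2 * mueff / n)
    cs = (mueff + 2) / (n + mueff + 5)
    c1 = 2 / ((n + 1.3) ** 2 + mueff)
    cmu = min(1 - c1, 2 * (mueff - 2 + 1 / mueff) / ((n + 2) ** 2 + mueff))
    damps = 1 + 2 * max(0.0, math.sqrt((mueff - 1) / (n + 1)) - 1) + cs
    chi_n = math.sqrt(n) * (1 - 1 / (4 * n) + 1 / (21 * n * n))

    rng = np.random.default_rng(seed)
    mean = x0.copy()
    sigma = float(sigma0)
    C = np.eye(n)
    pc = np.zeros(n)
    ps = np.zeros(n)
    B = np.eye(n)
    D = np.ones(n)
    eigen_stale = 0

    if bounds is not None:
        lo = np.asarray(bounds[0], dtype=float)
        hi = np.asarray(bounds[1], dtype=float)

    def evaluate(x):
        if bounds is not None:
            xr = np.clip(x, lo, hi)
            pen = penalty_weight * float(np.sum((x - xr) ** 2))
        else:
            xr, pen = x, 0.0
        out = func(xr)
        if isinstance(out, tuple):
            f, meta = out
        else:
            f, meta = out, None
        if not math.isfinite(f):
            f = 1e12
        return f + pen, f, xr, meta

    # evaluate the starting mean: a warm start that already meets the
    # target must count, and the incumbent must never regress below it
    f_best, _, x_best, meta_best = evaluate(mean)
    evals = 1
    hist = []
    reason = "max_generations"
    if ftarget is not None and f_best <= ftarget and \
            (accept is None or accept(meta_best)):
        return CMAResult(x_best=x_best, f_best=float(f_best), evaluations=1,
                         generations=0, stop_reason="ftarget",
                         f_history=[float(f_best)], meta_best=meta_best)

    for gen in range(max_generations):
        # refresh the eigendecomposition lazily
        if eigen_stale >= max(1, int(1 / ((c1 + cmu) * n * 10))):
            C = np.triu(C) + np.triu(C, 1).T
            D2, B = np.linalg.eigh(C)
            D = np.sqrt(np.maximum(D2, 1e-20))
            eigen_stale = 0

        Z = rng.standard_normal((lam, n))
        Y = Z * D @ B.T          # y_i = B D z_i
        X = mean + sigma * Y
        fs = np.empty(lam)
        raw = np.empty(lam)
        metas = [None] * lam
        for i in range(lam):
            fs[i], raw[i], xr, metas[i] = evaluate(X[i])
            evals += 1
            if fs[i] < f_best:
                f_best = fs[i]
                x_best = xr.copy()
                meta_best = metas[i]
        order = np.argsort(fs)
        hist.append(float(fs[order[0]]))

        sel = order[:mu]
        y_w = w @ Y[sel]
        mean = mean + sigma * y_w

        # step-size path (in the isotropic coordinate system)
        z_w = w @ Z[sel]
        ps = (1 - cs) * ps + math.sqrt(cs * (2 - cs) * mueff) * (B @ z_w)
        hsig = (np.linalg.norm(ps)
                / math.sqrt(1 - (1 - cs) ** (2 * (gen + 1))) / chi_n
                < 1.4 + 2 / (n + 1))
        pc = (1 - cc) * pc + hsig * math.sqrt(cc * (2 - cc) * mueff) * y_w

        # covariance update
        C = (1 - c1 - cmu) * C + c1 * (np.outer(pc, pc)
                                       + (not hsig) * cc * (2 - cc) * C)
        for i, idx in enumerate(sel):
            C += cmu * w[i] * np.outer(Y[idx], Y[idx])
        eigen_stale += 1

        sigma *= math.exp((cs / damps) * (np.linalg.norm(ps) / chi_n - 1))

        if ftarget is not None and f_best <= ftarget and \
                (accept is None or accept(meta_best)):
            reason = "ftarget"
            break
        if sigma * float(np.max(D)) < tol_sigma:
            reason = "tol_sigma"
            break
        if len(hist) > 20 and abs(hist[-1] - hist[-20]) < tol_flat \
                and hist[-1] <= f_best + tol_flat:
            reason = "flat_fitness"
            break

    return CMAResult(x_best=x_best, f_best=float(f_best), evaluations=evals,
                     generations=len(hist), stop_reason=reason,
                     f_history=hist, meta_best=meta_best)
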