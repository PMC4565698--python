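"""Hierarchy-constrained null model for directed aggression networks.

The null asks: what would aggression look like in a group with the *same*
dominance structure (EC power scores) and the same per-individual activity
levels, but no further strategy about whom to attack? It samples win-count
matrices that

* reproduce each individual's total outgoing aggression **exactly**, and
* reproduce the observed EC power-score vector ``v`` **on average** over
  the ensemble,

but are otherwise unstructured. Construction: fit a zero-diagonal,
row-stochastic *null kernel* whose stationary distribution matches ``v``
(initialize ``t_ij`` proportional to ``v_j`` and iteratively rescale
columns by ``v_j / w_j`` where ``w`` is the current stationary vector),
then draw each individual's outgoing events as an independent multinomial
across targets with the kernel row as probabilities. Rows are
conditionally independent categorical draws, so no correlation beyond the
two constraints is injected. Any single sample's EC deviates from ``v`` by
multinomial noise; only the ensemble mean is constrained.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .events import AggressionMatrix
from .ranking import PowerScores, stationary_distribution

__all__ = [
    "NullKernel",
    "NullEnsemble",
    "NullBand",
    "fit_null_kernel",
    "sample_null_ensemble",
    "null_band",
]


@dataclass(frozen=True)
class NullKernel:
    """Row-stochastic target-choice kernel whose stationary vector matches v."""

    t_null: np.ndarray
    target_v: np.ndarray
    roster: tuple[str, ...]
    achieved_error: float  # max-norm distance of stationary vector from target_v
    iterations: int


@dataclass(frozen=True)
class NullEnsemble:
    """B sampled win matrices with exact outgoing totals; kernel + seed kept."""

    samples: np.ndarray  # (B, N, N) integer counts
    kernel: NullKernel
    row_totals: np.ndarray
    rng_seed: int | None

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    def matrices(self) -> list[AggressionMatrix]:
        return [
            AggressionMatrix(s, self.kernel.roster, window_label=f"null{b}")
            for b, s in enumerate(self.samples)
        ]

    def save(self, path) -> None:
        """Persist as compressed arrays plus a JSON audit sidecar."""
        import json
        from pathlib import Path

        path = Path(path)
        np.savez_compressed(
            path.with_suffix(".npz"),
            samples=self.samples,
            t_null=self.kernel.t_null,
            target_v=self.kernel.target_v,
            row_totals=self.row_totals,
        )
        sidecar = {
            "roster": list(self.kernel.roster),
            "n_samples": int(self.n_samples),
            "rng_seed": self.rng_seed,
            "kernel_residual": self.kernel.achieved_error,
            "kernel_iterations": self.kernel.iterations,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path) -> "NullEnsemble":
        import json
        from pathlib import Path

        path = Path(path)
        with np.load(path.with_suffix(".npz")) as z:
            samples = z["samples"]
            t_null = z["t_null"]
            target_v = z["target_v"]
            row_totals = z["row_totals"]
        meta = json.loads(path.with_suffix(".json").read_text())
        kernel = NullKernel(
            t_null,
            target_v,
            tuple(meta["roster"]),
            meta["kernel_residual"],
            meta["kernel_iterations"],
        )
        return cls(samples, kernel, row_totals, meta["rng_seed"])


def fit_null_kernel(
    v: PowerScores | np.ndarray,
    roster: Sequence[str] | None = None,
    tol: float = 1e-8,
    max_iter: int = 10_000,
) -> NullKernel:
    """Fit the maximally unstructured kernel with stationary distribution v.

    Deterministic given ``v``. Raises with the achieved residual if the
    rescaling iteration cannot reach ``tol`` (possible for extreme score
    vectors, e.g. any N=2 chain is forced to stationary (0.5, 0.5)).
    """
    if isinstance(v, PowerScores):
        roster = v.roster
        v = v.scores
    v = np.asarray(v, dtype=float)
    n = len(v)
    if roster is None:
        roster = tuple(f"i{k}" for k in range(n))
    roster = tuple(roster)
    if n < 2:
        raise ValueError("need at least two individuals")
    if np.any(v <= 0) or abs(v.sum() - 1.0) > 1e-8:
        raise ValueError("v must be a strictly positive probability vector")

    off = ~np.eye(n, dtype=bool)
    diag = np.eye(n, dtype=bool)
    t = np.where(off, np.tile(v, (n, 1)), 0.0)
    t /= t.sum(axis=1, keepdims=True)
    err = np.inf
    # fast path: column rescaling converges in a handful of iterations for
    # moderate rosters, but decays only ~1/iter for very small N
    rescale_iters = min(max_iter, 500)
    for it in range(1, rescale_iters + 1):
        w = stationary_distribution(t)
        err = float(np.max(np.abs(w - v)))
        if err < tol:
            return NullKernel(t, v.copy(), roster, err, it)
        t = t * (v / w)[None, :]
        t[diag] = 0.0
        t /= t.sum(axis=1, keepdims=True)

    # slow-convergence fallback: solve for positive column multipliers x
    # with t_ij ~ v_j x_j (j != i) such that the stationary vector hits v
    from scipy import optimize

    def kernel_from(y: np.ndarray) -> np.ndarray:
        col = v * np.exp(np.concatenate(([0.0], y)))
        tk = np.where(off, np.tile(col, (n, 1)), 0.0)
        return tk / tk.sum(axis=1, keepdims=True)

    def residual(y: np.ndarray) -> np.ndarray:
        return (stationary_distribution(kernel_from(y)) - v)[1:]

    sol = optimize.root(residual, np.zeros(n - 1), method="hybr")
    t_sol = kernel_from(sol.x)
    err_sol = float(np.max(np.abs(stationary_distribution(t_sol) - v)))
    if err_sol < err:
        t, err = t_sol, err_sol
    if err < tol:
        return NullKernel(t, v.copy(), roster, err, rescale_iters + int(sol.nfev))
    raise RuntimeError(
        f"null kernel did not converge (residual {err:.3g}); the target "
        "score vector may be unreachable for this roster size"
    )


def sample_null_ensemble(
    kernel: NullKernel,
    row_totals: Sequence[int] | np.ndarray,
    n_samples: int,
    rng: np.random.Generator | int | None = None,
) -> NullEnsemble:
    """Draw B null win matrices with exact per-individual outgoing totals.

    Each individual's ``row_totals[i]`` events are distributed over targets
    by a multinomial with probabilities ``kernel.t_null[i]``; reproducible
    under a seed.
    """
    if n_samples < 1:
        raise ValueError("need at least one sample")
    row_totals = np.asarray(row_totals, dtype=np.int64)
    n = len(kernel.roster)
    if row_totals.shape != (n,) or np.any(row_totals < 0):
        raise ValueError("row_totals must be N non-negative integers")
    seed = rng if isinstance(rng, (int, np.integer)) else None
    gen = np.random.default_rng(rng)
    samples = np.empty((n_samples, n, n), dtype=np.int64)
    for i in range(n):
        samples[:, i, :] = gen.multinomial(
            row_totals[i], kernel.t_null[i], size=n_samples
        )
    return NullEnsemble(samples, kernel, row_totals, seed)


@dataclass(frozen=True)
class NullBand:
    """Ensemble summary of a scalar statistic plus an empirical p-value."""

    mean: float
    sd: float
    observed: float | None
    p_value: float | None
    direction: str
    n_used: int
    n_dropped: int
    values: np.ndarray

    def z(self) -> float:
        if self.observed is None or self.sd == 0:
            return np.nan
        return (self.observed - self.mean) / self.sd


def null_band(
    statistic: Callable[[AggressionMatrix], float],
    ensemble: NullEnsemble,
    observed: float | None = None,
    direction: str = "greater",
) -> NullBand:
    """Evaluate a scalar statistic across the ensemble.

    Returns the null mean and 1-sigma band, and — when an observed value is
    supplied — the one-sided empirical p-value: the fraction of null
    samples at least as extreme, with the (count + 1)/(B + 1)
    small-sample correction. ``direction`` is 'greater', 'less', or
    'two-sided' (doubles the smaller tail, capped at 1). Samples on which
    the statistic is undefined (NaN) are dropped and counted.
    """
    vals = np.array([statistic(m) for m in ensemble.matrices()], dtype=float)
    ok = np.isfinite(vals)
    used = vals[ok]
    if not len(used):
        raise ValueError("statistic undefined on every null sample")
    mean, sd = float(used.mean()), float(used.std(ddof=1)) if len(used) > 1 else 0.0
    p = None
    if observed is not None:
        b = len(used)
        p_hi = (np.sum(used >= observed) + 1) / (b + 1)
        p_lo = (np.sum(used <= observed) + 1) / (b + 1)
        if direction == "greater":
            p = p_hi
        elif direction == "less":
            p = p_lo
        elif direction == "two-sided":
            p = min(1.0, 2 * min(p_hi, p_lo))
        else:
            raise ValueError("direction must be greater, less, or two-sided")
        p = float(p)
    return NullBand(
        mean, sd, observed, p, direction, int(ok.sum()), int((~ok).sum()), used
    )
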