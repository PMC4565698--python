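"""Aggression-chain motifs: weighted rank difference W(n) and fractional
transitivity T(n).

An *aggression chain* of length ``n`` is a directed path
``i -> j -> k -> ...`` of ``n`` edges with all ``n + 1`` individuals
pairwise distinct and strictly positive win counts along every edge. Each
chain carries a weight: the product of the win counts along its edges.

``W(n)`` is the chain-weight-weighted mean rank difference between the
chain's originator and its terminal individual (positive when the
terminal sits below the originator). It measures how much rank
information an observer could extract from witnessing a chain.

``T(n)`` asks whether originators *act* on that information: the
chain-weight-weighted mean of ``(d[i, terminal] - b) / b`` where ``b`` is
the originator's baseline (average) aggression toward individuals outside
the chain. ``T > 0`` means chains predict extra aggression toward their
terminal individual; ``T < 0`` means avoidance. Two baselines are
available for ``n > 2``: exclude every interior chain member (default) or
only the first intermediate (the literal two-step rule). Chains whose
baseline is zero are excluded and counted.

The production enumerator is a depth-first search over nonzero edges with
an incremental interior-baseline update (numba-accelerated when numba is
importable, pure Python otherwise). A naive all-tuples oracle over
explicit vertex permutations is kept as an independent cross-check.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .events import AggressionMatrix
from .nullmodel import NullEnsemble
from .ranking import RankOrder

__all__ = [
    "ChainSpec",
    "ChainValue",
    "ChainStatistics",
    "chain_scan",
    "weighted_rank_difference",
    "fractional_transitivity",
    "weighted_rank_difference_naive",
    "fractional_transitivity_naive",
    "chain_statistics_suite",
    "chain_statistics_frame",
    "enumeration_cost",
]

MAX_ENUMERATION_COST = 2_000_000_000


@dataclass(frozen=True)
class ChainSpec:
    """Chain-length request: n edges, n+1 pairwise-distinct individuals."""

    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("chain length must be at least 1 edge")


@dataclass(frozen=True)
class ChainValue:
    """A single W(n) or T(n) evaluation with its components."""

    n: int
    value: float  # NaN when undefined (no chain with positive weight)
    total_weight: float
    chains_counted: int
    excluded_chains: int = 0  # zero-baseline chains dropped from T

    @property
    def defined(self) -> bool:
        return np.isfinite(self.value)


def enumeration_cost(n_individuals: int, max_n: int) -> int:
    """Upper bound on DFS node visits: sum over n of N!/(N-n-1)!."""
    total = 0
    for n in range(1, max_n + 1):
        paths = 1
        for k in range(n + 1):
            paths *= max(n_individuals - k, 0)
        total += paths
    return total


# ---------------------------------------------------------------------------
# Core DFS: accumulates W and T (both baseline variants) for every chain
# length 1..max_n in a single pass. acc layout (rows indexed by n):
#   0 W_num | 1 W_den | 2 chains
#   3 T_num_interior | 4 T_den_interior | 5 T_excl_interior
#   6 T_num_first    | 7 T_den_first    | 8 T_excl_first
# ---------------------------------------------------------------------------


def _scan_py(d, rank, nbr, nnbr, max_n, acc):
    n_ind = d.shape[0]
    row_sum = np.zeros(n_ind, dtype=np.float64)
    for a in range(n_ind):
        for b in range(n_ind):
            row_sum[a] += d[a, b]
    path = np.empty(max_n + 1, dtype=np.int64)
    cand = np.empty(max_n + 1, dtype=np.int64)
    wprod = np.empty(max_n + 1, dtype=np.float64)
    intsum = np.empty(max_n + 1, dtype=np.float64)
    visited = np.zeros(n_ind, dtype=np.bool_)
    for i in range(n_ind):
        path[0] = i
        visited[i] = True
        cand[0] = 0
        wprod[0] = 1.0
        intsum[0] = 0.0
        depth = 0
        s_i = row_sum[i]
        while depth >= 0:
            u = path[depth]
            progressed = False
            while cand[depth] < nnbr[u]:
                v = nbr[u, cand[depth]]
                cand[depth] += 1
                if visited[v]:
                    continue
                w = wprod[depth] * d[u, v]
                m = depth + 1
                acc[0, m] += w * (rank[v] - rank[i])
                acc[1, m] += w
                acc[2, m] += 1.0
                if m >= 2:
                    new_int = intsum[depth] + d[i, u]
                    b = (s_i - new_int) / (n_ind - m)
                    if b > 0.0:
                        acc[3, m] += w * (d[i, v] - b) / b
                        acc[4, m] += w
                    else:
                        acc[5, m] += 1.0
                    b2 = (s_i - d[i, path[1]]) / (n_ind - 2)
                    if b2 > 0.0:
                        acc[6, m] += w * (d[i, v] - b2) / b2
                        acc[7, m] += w
                    else:
                        acc[8, m] += 1.0
                else:
                    new_int = 0.0
                if m < max_n:
                    depth += 1
                    path[depth] = v
                    visited[v] = True
                    cand[depth] = 0
                    wprod[depth] = w
                    intsum[depth] = new_int
                    progressed = True
                    break
            if progressed:
                continue
            visited[path[depth]] = False
            depth -= 1
    return acc


try:  # pragma: no cover - exercised implicitly wherever numba is present
    from numba import njit

    _scan_jit = njit(cache=True)(_scan_py)
except Exception:  # pragma: no cover
    _scan_jit = None


def chain_scan(
    m: AggressionMatrix,
    order: RankOrder | None,
    max_n: int,
    cost_cap: int = MAX_ENUMERATION_COST,
) -> dict[str, np.ndarray]:
    """Enumerate all distinct-vertex chains up to ``max_n`` edges once.

    Returns accumulator arrays indexed by chain length n:
    ``W_num, W_den, chains, T_num/T_den/T_excluded`` for both baseline
    variants (``*_interior``, ``*_first``). ``order`` may be None when
    only T is needed (W rank differences are then reported as zero).
    """
    if max_n < 1:
        raise ValueError("max_n must be >= 1")
    cost = enumeration_cost(m.n, max_n)
    if cost > cost_cap:
        raise ValueError(
            f"chain enumeration would visit ~{cost:.2e} paths "
            f"(cap {cost_cap:.2e}); lower max_n or raise cost_cap explicitly"
        )
    d = np.ascontiguousarray(m.counts, dtype=np.float64)
    n = m.n
    if order is None:
        rank = np.zeros(n, dtype=np.int64)
    else:
        if tuple(order.roster) != tuple(m.roster):
            raise ValueError("rank order roster must match matrix roster")
        rank = np.asarray(order.ranks, dtype=np.int64)
    nbr = np.zeros((n, n), dtype=np.int64)
    nnbr = np.zeros(n, dtype=np.int64)
    for u in range(n):
        nz = np.flatnonzero(d[u] > 0)
        nnbr[u] = len(nz)
        nbr[u, : len(nz)] = nz
    acc = np.zeros((9, max_n + 1), dtype=np.float64)
    scanner = _scan_jit if _scan_jit is not None else _scan_py
    scanner(d, rank, nbr, nnbr, max_n, acc)
    return {
        "W_num": acc[0],
        "W_den": acc[1],
        "chains": acc[2].astype(np.int64),
        "T_num_interior": acc[3],
        "T_den_interior": acc[4],
        "T_excluded_interior": acc[5].astype(np.int64),
        "T_num_first": acc[6],
        "T_den_first": acc[7],
        "T_excluded_first": acc[8].astype(np.int64),
    }


def _w_from_scan(scan: dict[str, np.ndarray], n: int) -> ChainValue:
    den = scan["W_den"][n]
    val = scan["W_num"][n] / den if den > 0 else np.nan
    return ChainValue(n, float(val), float(den), int(scan["chains"][n]))


def _t_from_scan(scan: dict[str, np.ndarray], n: int, baseline: str) -> ChainValue:
    key = {"interior": "interior", "first": "first"}[baseline]
    den = scan[f"T_den_{key}"][n]
    val = scan[f"T_num_{key}"][n] / den if den > 0 else np.nan
    return ChainValue(
        n, float(val), float(den), int(scan["chains"][n]),
        int(scan[f"T_excluded_{key}"][n]),
    )


def weighted_rank_difference(
    m: AggressionMatrix, order: RankOrder, spec: ChainSpec | int
) -> ChainValue:
    """W(n): chain-weighted mean rank difference originator -> terminal.

    ``n = 1`` reduces to the dyadic weighted mean rank difference of
    aggression. Undefined (NaN value) when no chain has positive weight.
    """
    n = spec.n if isinstance(spec, ChainSpec) else int(spec)
    return _w_from_scan(chain_scan(m, order, n), n)


def fractional_transitivity(
    m: AggressionMatrix, spec: ChainSpec | int, baseline: str = "interior"
) -> ChainValue:
    """T(n): relative excess of originator->terminal aggression over baseline.

    ``baseline='interior'`` (default) averages the originator's aggression
    over everyone except itself and the chain's interior members;
    ``baseline='first'`` excludes only the first intermediate (the literal
    two-step definition; both coincide at n = 2).
    """
    n = spec.n if isinstance(spec, ChainSpec) else int(spec)
    if n < 2:
        raise ValueError("fractional transitivity requires n >= 2")
    return _t_from_scan(chain_scan(m, None, n), n, baseline)


# ---------------------------------------------------------------------------
# Naive all-tuples oracle (independent of the DFS path)
# ---------------------------------------------------------------------------


def weighted_rank_difference_naive(
    m: AggressionMatrix, order: RankOrder, n: int
) -> ChainValue:
    """Brute-force W(n) by explicit loop over all distinct (n+1)-tuples."""
    d = m.counts.astype(float)
    rank = np.asarray(order.ranks)
    num = den = 0.0
    chains = 0
    for tup in itertools.permutations(range(m.n), n + 1):
        w = 1.0
        for a, b in zip(tup[:-1], tup[1:]):
            w *= d[a, b]
            if w == 0.0:
                break
        if w == 0.0:
            continue
        chains += 1
        num += w * (rank[tup[-1]] - rank[tup[0]])
        den += w
    return ChainValue(n, num / den if den > 0 else np.nan, den, chains)


def fractional_transitivity_naive(
    m: AggressionMatrix, n: int, baseline: str = "interior"
) -> ChainValue:
    """Brute-force T(n) over all distinct (n+1)-tuples."""
    if n < 2:
        raise ValueError("fractional transitivity requires n >= 2")
    d = m.counts.astype(float)
    row_sum = d.sum(axis=1)
    num = den = 0.0
    chains = excluded = 0
    n_ind = m.n
    for tup in itertools.permutations(range(n_ind), n + 1):
        w = 1.0
        for a, b in zip(tup[:-1], tup[1:]):
            w *= d[a, b]
            if w == 0.0:
                break
        if w == 0.0:
            continue
        chains += 1
        i, k = tup[0], tup[-1]
        if baseline == "interior":
            interior = tup[1:-1]
            b_val = (row_sum[i] - sum(d[i, v] for v in interior)) / (n_ind - n)
        elif baseline == "first":
            b_val = (row_sum[i] - d[i, tup[1]]) / (n_ind - 2)
        else:
            raise ValueError("baseline must be 'interior' or 'first'")
        if b_val > 0:
            num += w * (d[i, k] - b_val) / b_val
            den += w
        else:
            excluded += 1
    return ChainValue(n, num / den if den > 0 else np.nan, den, chains, excluded)


# ---------------------------------------------------------------------------
# Suite with null comparisons
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChainStatistics:
    """W(n) and T(n) for one chain length, with null bands and p-values."""

    n: int
    W: float
    T: float  # NaN for n = 1
    total_weight: float
    chains_counted: int
    t_excluded_chains: int
    W_null_mean: float = np.nan
    W_null_sd: float = np.nan
    W_p: float = np.nan
    W_p_direction: str = ""
    T_null_mean: float = np.nan
    T_null_sd: float = np.nan
    T_p: float = np.nan
    T_p_direction: str = ""


def _one_sided_p(null_vals: np.ndarray, observed: float) -> tuple[float, str]:
    """One-sided empirical p in the direction of the observed deviation."""
    ok = np.isfinite(null_vals)
    vals = null_vals[ok]
    if not len(vals) or not np.isfinite(observed):
        return np.nan, ""
    b = len(vals)
    if observed >= vals.mean():
        return float((np.sum(vals >= observed) + 1) / (b + 1)), "greater"
    return float((np.sum(vals <= observed) + 1) / (b + 1)), "less"


def chain_statistics_suite(
    m: AggressionMatrix,
    order: RankOrder,
    ensemble: NullEnsemble | None = None,
    max_n: int = 6,
    baseline: str = "interior",
    cost_cap: int = MAX_ENUMERATION_COST,
) -> list[ChainStatistics]:
    """W(1..max_n) and T(2..max_n) with null means, 1-sigma bands, p-values.

    Null matrices are scored against the *observed* rank order (the null
    preserves the power scores by construction). p-values are one-sided in
    the direction of the observed deviation from the null mean, with the
    (count + 1)/(B + 1) correction; the direction used is recorded.
    """
    scan = chain_scan(m, order, max_n, cost_cap)
    null_scans = []
    if ensemble is not None:
        for mat in ensemble.matrices():
            null_scans.append(chain_scan(mat, order, max_n, cost_cap))
    out = []
    for n in range(1, max_n + 1):
        wv = _w_from_scan(scan, n)
        tv = _t_from_scan(scan, n, baseline) if n >= 2 else None
        kw: dict = {}
        if null_scans:
            w_null = np.array([_w_from_scan(s, n).value for s in null_scans])
            w_ok = w_null[np.isfinite(w_null)]
            if len(w_ok):
                kw["W_null_mean"] = float(w_ok.mean())
                kw["W_null_sd"] = float(w_ok.std(ddof=1)) if len(w_ok) > 1 else 0.0
                kw["W_p"], kw["W_p_direction"] = _one_sided_p(w_null, wv.value)
            if tv is not None:
                t_null = np.array(
                    [_t_from_scan(s, n, baseline).value for s in null_scans]
                )
                t_ok = t_null[np.isfinite(t_null)]
                if len(t_ok):
                    kw["T_null_mean"] = float(t_ok.mean())
                    kw["T_null_sd"] = float(t_ok.std(ddof=1)) if len(t_ok) > 1 else 0.0
                    kw["T_p"], kw["T_p_direction"] = _one_sided_p(t_null, tv.value)
        out.append(
            ChainStatistics(
                n=n,
                W=wv.value,
                T=tv.value if tv is not None else np.nan,
                total_weight=wv.total_weight,
                chains_counted=wv.chains_counted,
                t_excluded_chains=tv.excluded_chains if tv is not None else 0,
                **kw,
            )
        )
    return out


def chain_statistics_frame(stats: list[ChainStatistics], window: str = "") -> pd.DataFrame:
    """Tidy CSV-ready view of a chain-statistics suite."""
    return pd.DataFrame(
        {
            "window": window,
            "n": [s.n for s in stats],
            "W": [s.W for s in stats],
            "W_null_mean": [s.W_null_mean for s in stats],
            "W_null_sd": [s.W_null_sd for s in stats],
            "W_p": [s.W_p for s in stats],
            "T": [s.T for s in stats],
            "T_null_mean": [s.T_null_mean for s in stats],
            "T_null_sd": [s.T_null_sd for s in stats],
            "T_p": [s.T_p for s in stats],
            "total_weight": [s.total_weight for s in stats],
            "chains": [s.chains_counted for s in stats],
        }
    )
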