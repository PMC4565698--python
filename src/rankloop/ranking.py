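"""Power scores and dominance ranks from directed aggression networks.

Three scorings are provided:

* **Eigenvector-centrality (EC) power scores** — the primary, "depth"
  measure. The win matrix is row-normalized with a small regularizer
  epsilon into a stochastic matrix ``t``; the power-score vector ``v`` is
  the stationary distribution of the Markov chain with transition matrix
  ``t`` (the unique probability vector with ``v^T t = v^T``). Centrality
  accrues through *incoming* aggression: an individual has low power when
  it receives much aggression from individuals who themselves have low
  power. High ``v`` therefore means low power, and rank 1 (most dominant)
  is the individual with the smallest EC score.

  Note on the fixed point: the naive row-sum recursion ``v = t v`` is
  degenerate for a row-stochastic ``t`` (its solution is uniform); the
  stationary-distribution form is the non-degenerate reading consistent
  with the verbal definition, and is what this module computes.

* **Weighted Simple Consensus (WSC)** — a "breadth" measure: total
  incoming aggression multiplied by the number of distinct aggressors.
  Higher WSC = lower rank.

* **David's Score (DS)** — a two-step depth measure on dyadic win
  proportions, ``DS = w + w2 - l - l2``. Higher DS = more dominant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats
from scipy.sparse import csgraph

from .events import AggressionEventLog, AggressionMatrix, build_matrix

__all__ = [
    "NormalizedMatrix",
    "PowerScores",
    "RankOrder",
    "normalize_aggression",
    "stationary_distribution",
    "ec_power",
    "wsc_power",
    "davids_score",
    "rank_agreement",
    "RankAgreement",
    "bootstrap_power",
]

DEFAULT_EPSILON = 0.01
_DENSE_EIG_MAX_N = 64


@dataclass(frozen=True)
class NormalizedMatrix:
    """Row-stochastic, zero-diagonal normalized aggression ``t[i, j]``."""

    t: np.ndarray
    roster: tuple[str, ...]
    epsilon: float

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        if np.any(np.diag(t) != 0):
            raise ValueError("normalized matrix must have a zero diagonal")
        if not np.allclose(t.sum(axis=1), 1.0, atol=1e-10):
            raise ValueError("rows must sum to 1")
        object.__setattr__(self, "t", t)


@dataclass(frozen=True)
class RankOrder:
    """Ordinal dominance ranks 1..N (1 = most dominant)."""

    roster: tuple[str, ...]
    ranks: np.ndarray  # ranks[i] = rank of roster[i]
    tie_policy: str = "stable roster order"

    def __post_init__(self) -> None:
        r = np.asarray(self.ranks, dtype=int)
        if sorted(r) != list(range(1, len(self.roster) + 1)):
            raise ValueError("ranks must be a permutation of 1..N")
        object.__setattr__(self, "ranks", r)

    @property
    def n(self) -> int:
        return len(self.roster)

    def rank_of(self, individual: str) -> int:
        return int(self.ranks[self.roster.index(individual)])

    def ids_by_rank(self) -> list[str]:
        return [self.roster[i] for i in np.argsort(self.ranks, kind="stable")]

    def index_at_rank(self) -> np.ndarray:
        """``out[r-1]`` = roster index of the individual holding rank r."""
        return np.argsort(self.ranks, kind="stable")


@dataclass(frozen=True)
class PowerScores:
    """Continuous power scores plus the score→rank convention.

    ``higher_is_dominant`` records the polarity: False for EC and WSC
    (high score = much incoming aggression = low power), True for DS.
    """

    roster: tuple[str, ...]
    scores: np.ndarray
    method: str
    higher_is_dominant: bool = False

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=float)
        if len(s) != len(self.roster):
            raise ValueError("scores length must match roster")
        if not np.all(np.isfinite(s)):
            raise ValueError("scores must be finite")
        object.__setattr__(self, "scores", s)

    def rank_order(self) -> RankOrder:
        """Ordinal ranks with ties broken by stable roster order."""
        key = -self.scores if self.higher_is_dominant else self.scores
        order = np.argsort(key, kind="stable")
        ranks = np.empty(len(key), dtype=int)
        ranks[order] = np.arange(1, len(key) + 1)
        return RankOrder(self.roster, ranks)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.roster,
                "method": self.method,
                "score": self.scores,
                "rank": self.rank_order().ranks,
            }
        )


def normalize_aggression(
    m: AggressionMatrix, epsilon: float = DEFAULT_EPSILON
) -> NormalizedMatrix:
    """Row-normalize win counts: ``t_ij = (d_ij + eps) / sum_k!=i (d_ik + eps)``.

    epsilon > 0 guarantees a strictly positive off-diagonal (hence an
    irreducible chain) and must be small relative to typical row totals.
    With ``epsilon=0`` an all-zero row (an individual who never attacked)
    is an error.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be non-negative")
    d = m.counts.astype(float)
    n = m.n
    off = ~np.eye(n, dtype=bool)
    w = np.where(off, d + epsilon, 0.0)
    row = w.sum(axis=1)
    if np.any(row <= 0):
        silent = [m.roster[i] for i in np.flatnonzero(row <= 0)]
        raise ValueError(
            f"rows with no outgoing aggression ({silent}); use epsilon > 0"
        )
    return NormalizedMatrix(w / row[:, None], m.roster, float(epsilon))


def stationary_distribution(
    t: np.ndarray, tol: float = 1e-12, max_iter: int = 100_000
) -> np.ndarray:
    """Stationary distribution ``v`` of a row-stochastic matrix (v^T t = v^T).

    Dense eigen-decomposition of ``t.T`` for small matrices; power
    iteration above ``N = 64``. Raises on a reducible chain.
    """
    t = np.asarray(t, dtype=float)
    n = t.shape[0]
    if n == 1:
        return np.ones(1)
    if not np.all(t >= 0) or not np.allclose(t.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("matrix must be row-stochastic")
    ncomp, _ = csgraph.connected_components(t > 0, directed=True, connection="strong")
    if ncomp > 1:
        raise ValueError(
            "aggression chain is reducible; regularize with epsilon > 0 to "
            "obtain a unique stationary distribution"
        )
    if n <= _DENSE_EIG_MAX_N:
        vals, vecs = linalg.eig(t.T)
        k = int(np.argmin(np.abs(vals - 1.0)))
        v = np.real(vecs[:, k])
        v = np.abs(v)
    else:
        v = np.full(n, 1.0 / n)
        for _ in range(max_iter):
            nxt = v @ t
            if np.max(np.abs(nxt - v)) < tol:
                v = nxt
                break
            v = nxt
        else:
            raise RuntimeError("power iteration did not converge")
    v = v / v.sum()
    # one refinement step damps eigen-solver noise
    v = v @ t
    return v / v.sum()


def ec_power(t: NormalizedMatrix) -> PowerScores:
    """EC power scores: the stationary distribution of the aggression chain.

    Scores sum to one; higher score = lower power. The derived
    :class:`RankOrder` sorts ascending score, so rank 1 is the most
    dominant (least central) individual.
    """
    v = stationary_distribution(t.t)
    return PowerScores(t.roster, v, method="EC", higher_is_dominant=False)


def wsc_power(m: AggressionMatrix) -> PowerScores:
    """Weighted Simple Consensus: incoming events x distinct aggressors."""
    incoming = m.counts.sum(axis=0).astype(float)
    n_aggressors = (m.counts > 0).sum(axis=0).astype(float)
    return PowerScores(
        m.roster, incoming * n_aggressors, method="WSC", higher_is_dominant=False
    )


def davids_score(m: AggressionMatrix) -> PowerScores:
    """David's Score: DS_i = w_i + w2_i - l_i - l2_i.

    ``w_i`` is the sum over opponents of i's dyadic win proportion
    ``P_ij = d_ij / (d_ij + d_ji)`` (dyads with no interactions are
    skipped); ``w2_i = sum_j P_ij w_j`` extends it one step to the targets'
    targets; ``l`` and ``l2`` are the mirror-image loss terms. Higher DS =
    more dominant.
    """
    d = m.counts.astype(float)
    tot = d + d.T
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(tot > 0, d / np.where(tot > 0, tot, 1.0), 0.0)
    w = p.sum(axis=1)
    l = p.sum(axis=0)
    w2 = p @ w
    l2 = p.T @ l
    return PowerScores(
        m.roster, w + w2 - l - l2, method="DS", higher_is_dominant=True
    )


@dataclass(frozen=True)
class RankAgreement:
    """Correlation report between two scorings of the same roster."""

    pearson_r: float
    pearson_p: float
    spearman_rho: float
    spearman_p: float
    signed_r2: float  # sign(r) * r^2 on the Pearson correlation
    degenerate: bool = False


def rank_agreement(a: PowerScores, b: PowerScores, on: str = "score") -> RankAgreement:
    """Agreement between two scorings (e.g. EC vs WSC).

    ``on="score"`` correlates the raw score vectors (methods must share a
    polarity for the sign to be meaningful); ``on="rank"`` correlates the
    derived dominance ranks, which is polarity-safe. The signed r-squared
    convention is ``sign(r) * r^2``, so perfectly anticorrelated scorings
    report -1.
    """
    if a.roster != b.roster:
        raise ValueError("scorings must share a roster")
    if on == "score":
        x, y = a.scores, b.scores
    elif on == "rank":
        x = a.rank_order().ranks.astype(float)
        y = b.rank_order().ranks.astype(float)
    else:
        raise ValueError("on must be 'score' or 'rank'")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return RankAgreement(np.nan, np.nan, np.nan, np.nan, np.nan, degenerate=True)
    pr = stats.pearsonr(x, y)
    sr = stats.spearmanr(x, y)
    r = float(pr.statistic)
    return RankAgreement(
        r,
        float(pr.pvalue),
        float(sr.statistic),
        float(sr.pvalue),
        float(np.sign(r) * r * r),
    )


def bootstrap_power(
    log: AggressionEventLog,
    n_boot: int = 500,
    rng: np.random.Generator | int | None = None,
    epsilon: float = DEFAULT_EPSILON,
    method: str = "EC",
) -> pd.DataFrame:
    """Event-resampling bootstrap of power scores and ranks.

    Resamples the event list with replacement (keeping the event count),
    re-scores each replicate end to end, and summarizes per individual:
    mean/sd of the score, the 1-sigma range (mean +- sd), the mean and
    modal bootstrap rank, and the modal-rank frequency (a rank-stability
    summary).
    """
    if n_boot < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    if not log.n_events:
        raise ValueError("cannot bootstrap an empty log")
    scorer = {
        "EC": lambda mat: ec_power(normalize_aggression(mat, epsilon)),
        "WSC": wsc_power,
        "DS": davids_score,
    }[method.upper()]
    rng = np.random.default_rng(rng)
    n_ev, n = log.n_events, log.n_individuals
    scores = np.empty((n_boot, n))
    ranks = np.empty((n_boot, n), dtype=int)
    for b in range(n_boot):
        take = rng.integers(0, n_ev, size=n_ev)
        ev = log.events.iloc[np.sort(take)].reset_index(drop=True)
        mat = build_matrix(
            AggressionEventLog(ev, log.roster, log.t_obs_minutes, label=log.label)
        )
        ps = scorer(mat)
        scores[b] = ps.scores
        ranks[b] = ps.rank_order().ranks
    modal = np.empty(n, dtype=int)
    modal_freq = np.empty(n)
    for i in range(n):
        vals, cnt = np.unique(ranks[:, i], return_counts=True)
        modal[i] = vals[np.argmax(cnt)]
        modal_freq[i] = cnt.max() / n_boot
    sd = scores.std(axis=0, ddof=1)
    mean = scores.mean(axis=0)
    return pd.DataFrame(
        {
            "id": log.roster,
            "method": method.upper(),
            "score_mean": mean,
            "boot_sd": sd,
            "boot_lo": mean - sd,
            "boot_hi": mean + sd,
            "rank_mean": ranks.mean(axis=0),
            "rank_sd": ranks.std(axis=0, ddof=1),
            "modal_rank": modal,
            "modal_rank_freq": modal_freq,
        }
    )
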