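"""Study-scale validation runs: oracle agreement, null validity, recovery.

These routines exercise the whole pipeline at the emulated study's
problem sizes and are used both by the test suite and by
``scripts/acceptance.py``. Each takes explicit seeds and problem sizes
so runs are reproducible and budget-scalable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .events import (
    AggressionEventLog,
    AggressionMatrix,
    apply_win_cooldown,
    build_matrix,
    event_log_from_frame,
    exclude_individuals,
    split_windows,
)
from .motifs import (
    chain_statistics_suite,
    fractional_transitivity,
    fractional_transitivity_naive,
    weighted_rank_difference,
    weighted_rank_difference_naive,
)
from .nullmodel import fit_null_kernel, sample_null_ensemble
from .profiles import above_null_ratio, profile_null_band, rank_aggression
from .ranking import ec_power, normalize_aggression
from .synth import GeneratorConfig, simulate_events

__all__ = [
    "random_matrix",
    "oracle_agreement",
    "null_model_validity",
    "structured_recovery",
    "unstructured_coverage",
    "signature_recovery",
    "worked_examples",
]


def random_matrix(rng: np.random.Generator, n: int, max_count: int = 6) -> AggressionMatrix:
    """Random integer aggression matrix (zero diagonal) for oracle checks."""
    c = rng.integers(0, max_count + 1, size=(n, n))
    np.fill_diagonal(c, 0)
    return AggressionMatrix(c, tuple(f"i{k}" for k in range(n)))


def oracle_agreement(
    seed: int, n_matrices: int = 50, max_side: int = 7, max_n: int = 5
) -> dict:
    """Max |optimized - brute force| for W(n), T(n) over random matrices.

    Matrices have N <= ``max_side`` individuals and chain lengths run up
    to ``min(max_n, N - 1)``; both T baselines are compared.
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    checks = 0
    for _ in range(n_matrices):
        n_ind = int(rng.integers(4, max_side + 1))
        m = random_matrix(rng, n_ind)
        order = ec_power(normalize_aggression(m, 0.01)).rank_order()
        for n in range(1, min(max_n, n_ind - 1) + 1):
            a = weighted_rank_difference(m, order, n)
            b = weighted_rank_difference_naive(m, order, n)
            if a.defined or b.defined:
                worst = max(worst, abs(a.value - b.value))
                checks += 1
            if n >= 2:
                for baseline in ("interior", "first"):
                    ta = fractional_transitivity(m, n, baseline)
                    tb = fractional_transitivity_naive(m, n, baseline)
                    if ta.defined or tb.defined:
                        worst = max(worst, abs(ta.value - tb.value))
                        checks += 1
    return {"max_abs_difference": worst, "n_checks": checks}


def null_model_validity(seed: int, n_individuals: int = 10, n_samples: int = 200) -> dict:
    """The null model's own validity criterion on a synthetic hierarchy.

    Fits the kernel to the EC scores of a structured synthetic group,
    draws the ensemble, and reports the max-norm error of the
    ensemble-mean EC against the target v plus the count of row-total
    violations (which must be zero by construction).
    """
    cfg = GeneratorConfig(
        n_individuals=n_individuals,
        total_events=60.0 * n_individuals,
        phase_change_day=0.0,
        rng_seed=seed,
    )
    log, _ = simulate_events(cfg)
    m = build_matrix(apply_win_cooldown(log))
    ec = ec_power(normalize_aggression(m))
    kernel = fit_null_kernel(ec)
    ens = sample_null_ensemble(kernel, m.counts.sum(axis=1), n_samples, rng=seed + 1)
    mean_ec = np.mean(
        [ec_power(normalize_aggression(s)).scores for s in ens.matrices()], axis=0
    )
    violations = int(
        np.sum(ens.samples.sum(axis=2) != ens.row_totals[None, :])
    )
    return {
        "mean_ec_max_error": float(np.abs(mean_ec - ec.scores).max()),
        "row_total_violations": violations,
        "kernel_residual": kernel.achieved_error,
        "n_samples": n_samples,
    }


def _analyzed_structured(seed: int, cfg: GeneratorConfig, n_null: int):
    log, truth = simulate_events(cfg, rng=seed)
    m = build_matrix(apply_win_cooldown(log))
    ec = ec_power(normalize_aggression(m))
    order = ec.rank_order()
    kernel = fit_null_kernel(ec)
    ens = sample_null_ensemble(kernel, m.counts.sum(axis=1), n_null, rng=seed + 1)
    return log, truth, m, ec, order, ens


def structured_recovery(seed: int, n_null: int = 200) -> dict:
    """Parameter recovery on a fully structured stream at study scale.

    Generator at its default structured settings (focus_strength 3,
    N = 20, ~1200 events) with no unstructured warm-up; reports the
    above-null ratio for targets one-to-five ranks below, its empirical
    p, and the Spearman correlation between EC ranks and latent ranks.
    """
    cfg = GeneratorConfig(phase_change_day=0.0, rng_seed=None)
    log, truth, m, ec, order, ens = _analyzed_structured(seed, cfg, n_null)
    r = above_null_ratio(m, ens, order, (1, 5))
    rho = spearmanr(order.ranks, truth.latent_ranks).statistic
    return {
        "above_null_ratio": float(r.ratio),
        "p_value": float(r.p_value),
        "rank_recovery_spearman": float(rho),
        "n_events": m.total_events,
    }


def unstructured_coverage(
    seed: int, n_seeds: int = 50, n_null: int = 100, max_n: int = 3
) -> dict:
    """Null self-consistency of the unstructured phase.

    For each replicate stream drawn with the uniform (rank-blind) target
    kernel, checks how many of the pointwise statistics — every R(Delta),
    W(1..max_n), T(2..max_n) — fall inside their own null ensemble's
    2-sigma band. Reports the pooled in-band fraction and the per-family
    breakdown. The W/T families are expected to run liberal here: any
    kernel whose stationary vector must reproduce the *estimated* power
    scores necessarily converts their sampling noise into systematic
    target preference, so chain statistics of a truly unstructured matrix
    sit low relative to that null (see docs).
    """
    counts = {"R": [0, 0], "W": [0, 0], "T": [0, 0]}
    for k in range(n_seeds):
        s = seed + k
        cfg = GeneratorConfig(kernel="uniform", rng_seed=None)
        log, _, m, ec, order, ens = _analyzed_structured(s, cfg, n_null)
        _, mu, sd = profile_null_band(ens, order, log.t_obs_minutes)
        obs = rank_aggression(m, order).values
        ok = np.abs(obs - mu) <= 2 * sd + 1e-12
        counts["R"][0] += int(ok.sum())
        counts["R"][1] += ok.size
        for st in chain_statistics_suite(m, order, ens, max_n=max_n):
            if np.isfinite(st.W_null_sd):
                counts["W"][0] += int(abs(st.W - st.W_null_mean) <= 2 * st.W_null_sd)
                counts["W"][1] += 1
            if st.n >= 2 and np.isfinite(st.T_null_sd):
                counts["T"][0] += int(abs(st.T - st.T_null_mean) <= 2 * st.T_null_sd)
                counts["T"][1] += 1
    pooled = sum(v[0] for v in counts.values()) / sum(v[1] for v in counts.values())
    out = {"pooled_in_band_fraction": float(pooled), "n_seeds": n_seeds}
    for fam, (hit, tot) in counts.items():
        out[f"{fam}_in_band_fraction"] = hit / tot if tot else np.nan
    return out


def signature_recovery(
    seed: int,
    n_groups: int = 3,
    events_per_group: float = 4800.0,
    n_null: int = 40,
    max_n: int = 5,
) -> dict:
    """Qualitative chain signatures in the strong-avoidance regime.

    Simulates ``n_groups`` replicate fully structured strong-avoidance
    groups and averages their chain statistics. The expected pattern is
    W(n) above its null and increasing for n >= 3 while the null stays
    flat in n, plus preference inversion: T(2) > 0 and T(n) < 0 for
    n >= 3.

    The event density per group is deliberately higher than a single
    study group's: the W-vs-null crossing at n = 3 is a fine-grained
    contrast (a few tenths of a rank) that estimated power scores mask at
    ~1200 events, because the null kernel absorbs score-estimation noise
    as systematic target preference and sits high by roughly the same
    few tenths (the noise-free expected matrices show the crossing
    cleanly; see docs). The inversion signature itself is robust at
    ordinary stream sizes.
    """
    acc_W, acc_Wn, acc_T, acc_Tn = [], [], [], []
    n_events = 0
    for g in range(n_groups):
        cfg = GeneratorConfig.strong_structure(
            total_events=events_per_group, rng_seed=None
        )
        _, _, m, _, order, ens = _analyzed_structured(seed + g, cfg, n_null)
        stats = chain_statistics_suite(m, order, ens, max_n=max_n)
        acc_W.append([s.W for s in stats])
        acc_Wn.append([s.W_null_mean for s in stats])
        acc_T.append([s.T for s in stats])
        acc_Tn.append([s.T_null_mean for s in stats])
        n_events += m.total_events
    return {
        "n": list(range(1, max_n + 1)),
        "W": list(np.mean(acc_W, axis=0)),
        "W_null_mean": list(np.mean(acc_Wn, axis=0)),
        "T": list(np.mean(acc_T, axis=0)),
        "T_null_mean": list(np.mean(acc_Tn, axis=0)),
        "n_groups": n_groups,
        "n_events": n_events,
    }


def worked_examples() -> dict:
    """Deterministic protocol checks on constructed toy inputs.

    * a 10-second barrage of six attacks collapses to one win under the
      60-s cooldown;
    * a 24-day log splits into four 6-day quarters;
    * dropping one individual from a 19-bird roster leaves ranks 1..18,
      hence a maximum rank difference of 17.
    """
    burst = event_log_from_frame(
        pd.DataFrame(
            {"time": np.linspace(0, 10, 6), "actor": "A", "target": "B"}
        ),
        roster=("A", "B"),
    )
    retained = apply_win_cooldown(burst, 60.0).n_events

    rng = np.random.default_rng(12345)
    n_ev = 240
    roster = tuple(f"P{k:02d}" for k in range(19))
    actors = rng.integers(0, 19, n_ev)
    offs = rng.integers(1, 19, n_ev)
    targets = (actors + offs) % 19
    day_log = event_log_from_frame(
        pd.DataFrame(
            {
                "time": np.sort(rng.uniform(0, 24 * 86_400.0, n_ev)),
                "actor": [roster[a] for a in actors],
                "target": [roster[t] for t in targets],
            }
        ),
        roster=roster,
        t_obs_minutes=24 * 1_440.0,
    )
    quarters = split_windows(day_log, 6.0)
    dropped = exclude_individuals(day_log, [roster[-1]])
    m = build_matrix(dropped)
    order = ec_power(normalize_aggression(m, 0.01)).rank_order()
    prof = rank_aggression(m, order)
    return {
        "cooldown_burst_retained": int(retained),
        "n_quarters": len(quarters),
        "max_rank_difference": int(prof.deltas.max()),
    }
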