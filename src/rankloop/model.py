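"""Model/Results front end over the full analysis pipeline.

:class:`DominanceModel` holds an aggression event log plus an
:class:`~rankloop.config.AnalysisConfig`; :meth:`DominanceModel.fit` runs
the complete analysis — win-cooldown filter, exclusions, windowing,
power scores and ranks (EC/WSC/DS), hierarchy-constrained null ensemble,
rank-aggression profiles with above-null ratios, chain-motif statistics,
and optional bootstrap uncertainty — and returns a
:class:`DominanceResults` carrying estimates, null bands, p-values and
tidy exports, with a human-readable ``summary()``.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import AnalysisConfig
from .events import (
    AggressionEventLog,
    AggressionMatrix,
    apply_win_cooldown,
    build_matrix,
    exclude_individuals,
    network_density,
    read_event_log,
    split_windows,
)
from .motifs import ChainStatistics, chain_statistics_frame, chain_statistics_suite
from .nullmodel import NullEnsemble, fit_null_kernel, sample_null_ensemble
from .profiles import (
    AboveNullRatio,
    RankAggressionProfile,
    above_null_ratio,
    bootstrap_profile,
    profile_null_band,
    rank_aggression,
    smooth_profile,
)
from .ranking import (
    PowerScores,
    RankAgreement,
    RankOrder,
    bootstrap_power,
    davids_score,
    ec_power,
    normalize_aggression,
    rank_agreement,
    wsc_power,
)

__all__ = ["DominanceModel", "DominanceResults", "WindowResult"]


@dataclass(frozen=True)
class WindowResult:
    """Everything computed for one observation window."""

    label: str
    log: AggressionEventLog
    matrix: AggressionMatrix
    density: float
    scores: dict[str, PowerScores]
    order: RankOrder  # EC-derived dominance order used downstream
    agreement: dict[str, RankAgreement]
    profile: RankAggressionProfile
    profile_smoothed: RankAggressionProfile
    ensemble: NullEnsemble | None
    null_profile_mean: np.ndarray | None
    null_profile_sd: np.ndarray | None
    ratio: AboveNullRatio | None
    chains: list[ChainStatistics]
    boot_power: pd.DataFrame | None = None
    boot_profile_sd: np.ndarray | None = None

    @property
    def n_events(self) -> int:
        return self.matrix.total_events


class DominanceModel:
    """Dominance-hierarchy analysis of a directed aggression event log.

    Parameters
    ----------
    log
        Raw (unfiltered) aggressive-win event log.
    config
        Analysis settings; defaults follow the emulated study protocol.
    """

    def __init__(self, log: AggressionEventLog, config: AnalysisConfig | None = None):
        self.raw_log = log
        self.config = config or AnalysisConfig()

    @classmethod
    def from_csv(cls, path, roster=None, t_obs_minutes=None, config=None):
        """Build a model from a ``time,actor,target`` CSV."""
        return cls(read_event_log(path, roster, t_obs_minutes), config)

    # -- pipeline stages -------------------------------------------------

    def prepared_log(self) -> AggressionEventLog:
        """Cooldown-filtered, exclusion-applied whole-study log."""
        cfg = self.config
        log = apply_win_cooldown(self.raw_log, cfg.cooldown_seconds)
        return exclude_individuals(log, cfg.excluded_ids)

    def _fit_window(
        self,
        wlog: AggressionEventLog,
        fixed_order: RankOrder | None,
        with_null: bool,
        with_bootstrap: bool,
    ) -> WindowResult:
        cfg = self.config
        mat = build_matrix(wlog)
        ec = ec_power(normalize_aggression(mat, cfg.epsilon))
        wsc = wsc_power(mat)
        ds = davids_score(mat)
        order = fixed_order if fixed_order is not None else ec.rank_order()
        agreement = {
            "EC_vs_WSC": rank_agreement(ec, wsc),
            "EC_vs_DS": rank_agreement(ec, ds, on="rank"),
        }
        profile = rank_aggression(mat, order)
        smoothed = smooth_profile(profile, halfwidth=1)

        ensemble = null_mean = null_sd = ratio = None
        chains: list[ChainStatistics] = []
        if with_null and mat.total_events > 0 and cfg.null_replicates > 0:
            kernel = fit_null_kernel(ec)
            ensemble = sample_null_ensemble(
                kernel,
                mat.counts.sum(axis=1),
                cfg.null_replicates,
                rng=cfg.seed_for(f"null:{wlog.label}"),
            )
            _, null_mean, null_sd = profile_null_band(
                ensemble, order, wlog.t_obs_minutes
            )
            lo, hi = cfg.delta_range
            hi = min(hi, mat.n - 1)
            ratio = above_null_ratio(mat, ensemble, order, (lo, hi))
        if mat.total_events > 0:
            max_n = min(cfg.max_chain_length, mat.n - 1)
            chains = chain_statistics_suite(
                mat, order, ensemble, max_n=max_n, baseline=cfg.t_baseline
            )

        boot_power_df = boot_sd = None
        if with_bootstrap and cfg.bootstrap_replicates >= 2 and wlog.n_events:
            boot_power_df = bootstrap_power(
                wlog,
                cfg.bootstrap_replicates,
                rng=cfg.seed_for(f"boot-power:{wlog.label}"),
                epsilon=cfg.epsilon,
            )
            _, _, boot_sd = bootstrap_profile(
                wlog,
                cfg.bootstrap_replicates,
                rng=cfg.seed_for(f"boot-profile:{wlog.label}"),
                epsilon=cfg.epsilon,
                rerank=cfg.rerank_bootstrap,
                order=order,
            )
        return WindowResult(
            label=wlog.label or "all",
            log=wlog,
            matrix=mat,
            density=network_density(mat, cfg.density_directed),
            scores={"EC": ec, "WSC": wsc, "DS": ds},
            order=order,
            agreement=agreement,
            profile=profile,
            profile_smoothed=smoothed,
            ensemble=ensemble,
            null_profile_mean=null_mean,
            null_profile_sd=null_sd,
            ratio=ratio,
            chains=chains,
            boot_power=boot_power_df,
            boot_profile_sd=boot_sd,
        )

    def fit(self, with_null: bool = True, with_bootstrap: bool | None = None):
        """Run the full analysis; returns :class:`DominanceResults`."""
        cfg = self.config
        t0 = time.perf_counter()
        log = self.prepared_log()
        if with_bootstrap is None:
            with_bootstrap = cfg.bootstrap_replicates >= 2
        if cfg.window_days:
            windows = split_windows(log, cfg.window_days)
        else:
            windows = [log]
        whole = self._fit_window(
            AggressionEventLog(
                log.events, log.roster, log.t_obs_minutes, label="all"
            ),
            None,
            with_null,
            with_bootstrap,
        )
        fixed = None if cfg.recompute_ranks_per_window else whole.order
        window_results = [
            self._fit_window(w, fixed, with_null, with_bootstrap) for w in windows
        ]
        return DominanceResults(
            model=self,
            config=cfg,
            whole=whole,
            windows=window_results,
            elapsed_seconds=time.perf_counter() - t0,
        )


@dataclass(frozen=True)
class DominanceResults:
    """Fitted analysis: per-window estimates, null bands, and exports."""

    model: DominanceModel
    config: AnalysisConfig
    whole: WindowResult
    windows: list[WindowResult]
    elapsed_seconds: float

    # -- tidy exports ----------------------------------------------------

    def scores_frame(self) -> pd.DataFrame:
        """Tidy `id,method,score,rank[,boot_*]` table across windows."""
        rows = []
        for w in [self.whole, *self.windows]:
            for method, ps in w.scores.items():
                f = ps.to_frame()
                f.insert(0, "window", w.label)
                if method == "EC" and w.boot_power is not None:
                    f = f.merge(
                        w.boot_power[["id", "boot_sd", "boot_lo", "boot_hi"]],
                        on="id",
                        how="left",
                    )
                rows.append(f)
        return pd.concat(rows, ignore_index=True)

    def profile_frame(self) -> pd.DataFrame:
        """Tidy `window,delta,R,R_smoothed,null_mean,null_sd,boot_sd`."""
        rows = []
        for w in [self.whole, *self.windows]:
            f = w.profile.to_frame().rename(columns={"R": "R"})
            f["window"] = w.label
            f["R_smoothed"] = w.profile_smoothed.values
            f["null_mean"] = w.null_profile_mean if w.null_profile_mean is not None else np.nan
            f["null_sd"] = w.null_profile_sd if w.null_profile_sd is not None else np.nan
            f["boot_sd"] = w.boot_profile_sd if w.boot_profile_sd is not None else np.nan
            rows.append(f)
        return pd.concat(rows, ignore_index=True)

    def chains_frame(self) -> pd.DataFrame:
        return pd.concat(
            [chain_statistics_frame(w.chains, w.label) for w in [self.whole, *self.windows]],
            ignore_index=True,
        )

    def ratio_frame(self) -> pd.DataFrame:
        rows = []
        for w in [self.whole, *self.windows]:
            if w.ratio is None:
                continue
            rows.append(
                {
                    "window": w.label,
                    "events": w.n_events,
                    "density": w.density,
                    "above_null_ratio": w.ratio.ratio,
                    "p": w.ratio.p_value,
                    "delta_lo": w.ratio.delta_range[0],
                    "delta_hi": w.ratio.delta_range[1],
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Readable per-window report of the headline quantities."""
        cfg = self.config
        lines = [
            "Dominance hierarchy analysis",
            "=" * 60,
            f"individuals: {self.whole.matrix.n}   "
            f"events (post-filter): {self.whole.n_events}   "
            f"epsilon: {cfg.epsilon}   seed: {cfg.rng_seed}",
            f"network density (directed): {self.whole.density:.2f}",
        ]
        ag = self.whole.agreement["EC_vs_WSC"]
        if not ag.degenerate:
            lines.append(
                f"EC vs WSC agreement: signed r^2 = {ag.signed_r2:.2f} "
                f"(Spearman rho = {ag.spearman_rho:.2f})"
            )
        lines.append("")
        hdr = f"{'window':>7} {'events':>7} {'ratio':>7} {'p':>8}   W(2)      T(2)"
        lines.append(hdr)
        lines.append("-" * len(hdr))
        for w in [self.whole, *self.windows]:
            ratio = f"{w.ratio.ratio:7.2f}" if w.ratio else "      -"
            p = f"{w.ratio.p_value:8.3f}" if w.ratio else "       -"
            w2 = next((c.W for c in w.chains if c.n == 2), np.nan)
            t2 = next((c.T for c in w.chains if c.n == 2), np.nan)
            lines.append(
                f"{w.label:>7} {w.n_events:>7} {ratio} {p}  {w2:7.2f}  {t2:8.2f}"
            )
        lines.append("")
        lines.append(
            "ratio = observed / null aggression at Delta in "
            f"[{cfg.delta_range[0]}, {cfg.delta_range[1]}] (rank-focused "
            "aggression); p is one-sided empirical vs the "
            f"B={cfg.null_replicates} hierarchy-constrained nulls."
        )
        return "\n".join(lines)

    def save(self, outdir) -> dict:
        """Write tidy CSVs plus a JSON run manifest; returns the manifest."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        files = {
            "scores.csv": self.scores_frame(),
            "profiles.csv": self.profile_frame(),
            "chains.csv": self.chains_frame(),
            "ratios.csv": self.ratio_frame(),
        }
        for name, frame in files.items():
            frame.to_csv(out / name, index=False)
        manifest = {
            "package_version": __version__,
            "config": self.config.to_dict(),
            "roster": list(self.whole.matrix.roster),
            "n_events": self.whole.n_events,
            "windows": [w.label for w in self.windows],
            "stage_seeds": {
                f"null:{w.label}": self.config.seed_for(f"null:{w.label}")
                for w in [self.whole, *self.windows]
            },
            "elapsed_seconds": self.elapsed_seconds,
            "outputs": sorted(files),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return manifest
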