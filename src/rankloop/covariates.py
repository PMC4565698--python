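"""Simpler candidate signals of rank: body size and spatial proximity.

If dominance rank could be read off morphology (wing chord, culmen depth,
culmen width, mass) or off spatial association (who perches next to
whom), individuals would not need social observation to infer it. These
tests quantify how much rank signal those simpler cues carry; in the
study system they carry essentially none, which is what makes the social
signals interesting.

Conventions shared with the ranking module: signed r-squared is
``sign(r) * r^2``; both Pearson and Spearman variants are reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ranking import RankOrder

__all__ = [
    "MORPHOMETRIC_TRAITS",
    "morphometric_rank_signal",
    "neighbor_rank_signal",
    "NeighborRankSignal",
    "validate_scan_table",
]

MORPHOMETRIC_TRAITS = ("wing_chord", "culmen_depth", "culmen_width", "mass")


def _signed_r2(r: float) -> float:
    return float(np.sign(r) * r * r)


def morphometric_rank_signal(
    table: pd.DataFrame, order: RankOrder
) -> pd.DataFrame:
    """Per-trait correlation between body size and dominance rank.

    ``table`` has one row per individual (column ``id``) and numeric trait
    columns. Returns a tidy frame with per-trait Pearson and Spearman
    signed r-squared and two-sided p-values; constant traits are flagged
    undefined rather than dropped silently.
    """
    if "id" not in table.columns:
        raise ValueError("morphometric table needs an 'id' column")
    ids = table["id"].astype(str)
    if ids.duplicated().any():
        raise ValueError("one row per individual required")
    known = set(order.roster)
    sub = table.loc[ids.isin(known)].copy()
    if len(sub) < 3:
        raise ValueError("need at least 3 individuals with morphometric data")
    ranks = np.array([order.rank_of(i) for i in sub["id"].astype(str)], dtype=float)
    traits = [c for c in sub.columns if c != "id"]
    rows = []
    for trait in traits:
        x = pd.to_numeric(sub[trait], errors="coerce").to_numpy(dtype=float)
        ok = np.isfinite(x)
        if ok.sum() < 3 or np.ptp(x[ok]) == 0:
            rows.append(
                dict(signal=trait, signed_r2=np.nan, p=np.nan,
                     spearman_signed_r2=np.nan, spearman_p=np.nan,
                     n=int(ok.sum()), degenerate=True)
            )
            continue
        pr = stats.pearsonr(x[ok], ranks[ok])
        sr = stats.spearmanr(x[ok], ranks[ok])
        rows.append(
            dict(
                signal=trait,
                signed_r2=_signed_r2(float(pr.statistic)),
                p=float(pr.pvalue),
                spearman_signed_r2=_signed_r2(float(sr.statistic)),
                spearman_p=float(sr.pvalue),
                n=int(ok.sum()),
                degenerate=False,
            )
        )
    return pd.DataFrame(rows)


def validate_scan_table(scans: pd.DataFrame, order: RankOrder | None = None) -> pd.DataFrame:
    """Validate a ``scan_id,focal,neighbor`` nearest-neighbor table."""
    missing = {"scan_id", "focal", "neighbor"} - set(scans.columns)
    if missing:
        raise ValueError(f"scan table missing columns {sorted(missing)}")
    out = scans.copy()
    out["focal"] = out["focal"].astype(str)
    out["neighbor"] = out["neighbor"].astype(str)
    bad = out.index[out["focal"] == out["neighbor"]]
    if len(bad):
        raise ValueError(f"focal == neighbor at rows {bad.tolist()}")
    if order is not None:
        known = set(order.roster)
        ids = set(out["focal"]) | set(out["neighbor"])
        if not ids.issubset(known):
            raise ValueError(f"scan ids outside roster: {sorted(ids - known)}")
    return out


@dataclass(frozen=True)
class NeighborRankSignal:
    """Dyadic proximity-vs-rank-distance correlation report."""

    signed_r2: float
    p: float
    spearman_signed_r2: float
    spearman_p: float
    n_pairs: int
    n_scans: int
    low_power: bool
    dyadic_table: pd.DataFrame


def neighbor_rank_signal(
    scans: pd.DataFrame, order: RankOrder, directed: bool = True
) -> NeighborRankSignal:
    """Does spatial proximity track rank distance?

    Builds the dyadic table of (|rank difference|, number of scans in
    which ``i`` was ``j``'s nearest neighbor) over ordered pairs
    (``directed=True``, default; set False to pool the two directions of
    each dyad) and correlates the two columns. Rank neighbors spending
    time together shows up as a negative signed r-squared. Total counts
    equal the number of scans (ordered case). Fewer than 10 scans is
    flagged low-power.
    """
    scans = validate_scan_table(scans, order)
    if not len(scans):
        raise ValueError("need at least one scan sample")
    n = order.n
    idx = {ind: i for i, ind in enumerate(order.roster)}
    counts = np.zeros((n, n), dtype=np.int64)  # counts[i, j]: i seen as j's neighbor
    for _, row in scans.iterrows():
        counts[idx[row["neighbor"]], idx[row["focal"]]] += 1
    ranks = np.asarray(order.ranks)
    drank = np.abs(ranks[:, None] - ranks[None, :])
    if directed:
        mask = ~np.eye(n, dtype=bool)
        table = pd.DataFrame(
            {"abs_rank_diff": drank[mask], "neighbor_count": counts[mask]}
        )
    else:
        iu = np.triu_indices(n, k=1)
        table = pd.DataFrame(
            {
                "abs_rank_diff": drank[iu],
                "neighbor_count": counts[iu] + counts.T[iu],
            }
        )
    x = table["abs_rank_diff"].to_numpy(dtype=float)
    y = table["neighbor_count"].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("no variation in neighbor counts; correlation undefined")
    pr = stats.pearsonr(x, y)
    sr = stats.spearmanr(x, y)
    return NeighborRankSignal(
        _signed_r2(float(pr.statistic)),
        float(pr.pvalue),
        _signed_r2(float(sr.statistic)),
        float(sr.pvalue),
        len(table),
        int(len(scans)),
        low_power=len(scans) < 10,
        dyadic_table=table,
    )
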