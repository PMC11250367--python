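"""Screen-level quality control applied before model fitting.

Three independent checks mirror the exclusions a screen analyst makes:
poor replicate-to-replicate correlation at a timepoint, a strong
dependence of early depletion on distance from the Cas9 cut site
(positional editing artifact), and a high wild-type read fraction late
in the timecourse (failed editing).  All checks are pure functions of
the counts and thresholds; exclusions are advisory flags unless the
pipeline runs in strict mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .screen_io import CountMatrix


@dataclass
class QCReport:
    replicate_correlations: pd.DataFrame = field(default_factory=pd.DataFrame)
    positional_effect: pd.DataFrame = field(default_factory=pd.DataFrame)
    late_wildtype: pd.DataFrame = field(default_factory=pd.DataFrame)
    exclusions: list = field(default_factory=list)  # (unit, reason)

    def add_exclusion(self, unit: tuple, reason: str) -> None:
        self.exclusions.append((unit, reason))

    def to_frame(self) -> pd.DataFrame:
        """Flat one-row-per-flag table for TSV export."""
        rows = []
        for df, metric in (
            (self.replicate_correlations, "median_replicate_r"),
            (self.positional_effect, "positional_rho"),
            (self.late_wildtype, "unedited_fraction"),
        ):
            if df.empty:
                continue
            flagged = df[df["flag"]]
            for _, r in flagged.iterrows():
                rows.append({"unit": r.get("unit", ""), "metric": metric,
                             "value": r.get("value", np.nan), "reason": r.get("reason", "")})
        return pd.DataFrame(rows, columns=["unit", "metric", "value", "reason"])


def replicate_correlation(
    cm: CountMatrix, region: str, library: str, day: int, threshold: float = 0.7
) -> pd.DataFrame:
    """Pairwise Pearson correlation of replicates on log2(count + 1).

    A replicate-timepoint is flagged when its median pairwise r falls
    below ``threshold``; an all-constant replicate has undefined
    correlation and is flagged ``degenerate``.
    """
    samples = cm.sample_names(region=region, library=library, day=day)
    if len(samples) < 2:
        raise ValueError(f"replicate correlation needs >=2 replicates, got {len(samples)} for "
                         f"{region}/{library}/D{day}")
    vids = [v for v in cm.region_variants(region) if v in cm.counts.index]
    logc = np.log2(cm.counts.loc[vids, samples].to_numpy(dtype=float) + 1.0)
    rows = []
    n = len(samples)
    r_mat = np.full((n, n), np.nan)
    degenerate = [np.ptp(logc[:, i]) == 0 for i in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            if degenerate[i] or degenerate[j]:
                continue
            r_mat[i, j] = r_mat[j, i] = stats.pearsonr(logc[:, i], logc[:, j])[0]
    for i, s in enumerate(samples):
        pair_r = r_mat[i, [j for j in range(n) if j != i]]
        if degenerate[i]:
            rows.append({"unit": s, "region_id": region, "library": library, "day": day,
                         "value": np.nan, "flag": True, "reason": "degenerate"})
            continue
        med = float(np.nanmedian(pair_r))
        flag = bool(med < threshold)
        rows.append({"unit": s, "region_id": region, "library": library, "day": day,
                     "value": med, "flag": flag, "reason": "low_correlation" if flag else ""})
    return pd.DataFrame(rows)


def positional_effect_flag(
    cm: CountMatrix,
    region: str,
    library: str,
    cut_site: int,
    rho_threshold: float = 0.5,
    p_threshold: float = 0.01,
) -> dict:
    """Test early depletion for dependence on distance to the cut site.

    The per-variant log ratio log2((mean D4 + 0.5) / (plasmid + 0.5)) is
    Spearman-correlated against |pos - cut_site|; a library-experiment
    with |rho| >= ``rho_threshold`` and p < ``p_threshold`` is flagged as
    having a strong positional editing effect.
    """
    plasmid = cm.sample_names(region=region, library=library, day="plasmid")
    if not plasmid:
        raise ValueError(f"no plasmid sample for {region}/{library}")
    d4 = cm.sample_names(region=region, library=library, day=4)
    if not d4:
        raise ValueError(f"no D4 samples for {region}/{library}")
    vids = [v for v in cm.region_variants(region) if v in cm.counts.index]
    if len(vids) < 10:
        return {"unit": (region, library), "flag": False, "reason": "insufficient_data",
                "rho": np.nan, "p": np.nan}
    mean_d4 = cm.counts.loc[vids, d4].mean(axis=1).to_numpy(dtype=float)
    plas = cm.counts.loc[vids, plasmid].mean(axis=1).to_numpy(dtype=float)
    ratio = np.log2((mean_d4 + 0.5) / (plas + 0.5))
    dist = np.abs(cm.variants.loc[vids, "pos"].to_numpy(dtype=float) - cut_site)
    if np.ptp(ratio) == 0 or np.ptp(dist) == 0:
        return {"unit": (region, library), "flag": False, "reason": "",
                "rho": np.nan, "p": np.nan}
    rho, p = stats.spearmanr(ratio, dist)
    flag = bool(abs(rho) >= rho_threshold and p < p_threshold)
    return {"unit": (region, library), "flag": flag,
            "reason": "positional_effect" if flag else "", "rho": float(rho), "p": float(p)}


def late_wildtype_flag(
    summary: pd.DataFrame, threshold: float = 0.30, late_days: tuple[int, ...] = (14, 21)
) -> pd.DataFrame:
    """Flag late-timepoint samples whose wild-type read fraction > threshold.

    ``summary`` is the output of :func:`sgescore.screen_io.editing_summary`.
    The inequality is strict: exactly 30% unedited does not flag.
    """
    late = summary[summary["day"].isin(late_days)].copy()
    late["value"] = late["unedited"]
    late["flag"] = late["unedited"] > threshold
    late["reason"] = np.where(late["flag"], "high_wildtype", "")
    late["unit"] = late.index
    return late[["unit", "region_id", "library", "replicate", "day", "value", "flag", "reason"]]
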