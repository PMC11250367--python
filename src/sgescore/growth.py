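"""Per-variant apparent growth rates from the SGE timecourse.

Counts K_vj for variant v in timepoint-replicate j are modeled as
negative binomial with a log-linear mean in continuous time,

    log2 mu_vj = log2 s_j + beta0_v + beta_v * t_j ,

where s_j is a per-sample normalization factor computed from the
fitness-neutral controls (synonymous and intronic variants), t_j maps
collection days {4, 7, 10, 14, 21} to {0, 3, 6, 10, 17}, and beta_v is
the apparent growth rate in log2 units per day (the continuous LFC).
Dispersions are estimated per variant by maximizing the Cox-Reid
adjusted profile likelihood; slopes and Wald standard errors come from
an IRLS fit at the estimated dispersion.  Internals run on the natural
log and convert at the interface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _nbglm
from .screen_io import DAY_TO_TIME, CountMatrix

LN2 = float(np.log(2.0))
MIN_CONTROLS = 5


@dataclass
class NormalizationFactors:
    """Positive per-sample scale factors, rescaled to geometric mean 1."""

    factors: pd.Series

    def __post_init__(self):
        if (self.factors <= 0).any():
            raise ValueError("normalization factors must be positive")
        gm = np.exp(np.mean(np.log(self.factors.to_numpy(dtype=float))))
        self.factors = self.factors / gm


@dataclass
class DesignSpec:
    """Samples, times and normalization for one (region, library) fit."""

    samples: list[str]
    time_values: np.ndarray
    normalization: NormalizationFactors

    def __post_init__(self):
        self.time_values = np.asarray(self.time_values, dtype=float)
        if len(np.unique(self.time_values)) < 2:
            raise ValueError("design needs >=2 distinct time values")
        missing = [s for s in self.samples if s not in self.normalization.factors.index]
        if missing:
            raise ValueError(f"samples lack normalization factors: {missing}")

    @property
    def offsets(self) -> np.ndarray:
        """ln s_j aligned with ``samples`` (natural-log offsets)."""
        return np.log(self.normalization.factors.loc[self.samples].to_numpy(dtype=float))


@dataclass
class GrowthFit:
    variant_id: str
    region_id: str
    library: str
    lfc_per_day: float
    se: float
    intercept: float
    dispersion: float
    converged: bool
    n_samples: int


def control_normalization_factors(counts: pd.DataFrame, control_mask: pd.Series | np.ndarray) -> NormalizationFactors:
    """Median-of-ratios size factors restricted to control variants.

    For each control with all-nonzero counts, a reference is formed as
    the geometric mean of its counts across samples; the factor of
    sample j is the median over controls of count_vj / ref_v, rescaled
    so the factors have geometric mean 1.
    """
    mask = np.asarray(control_mask, dtype=bool)
    ctrl = counts.loc[mask] if mask.shape[0] == counts.shape[0] else counts.loc[control_mask]
    arr = ctrl.to_numpy(dtype=float)
    usable = (arr > 0).all(axis=1)
    if int(usable.sum()) < MIN_CONTROLS:
        raise ValueError(
            f"insufficient controls: {int(usable.sum())} usable (< {MIN_CONTROLS}) for normalization"
        )
    arr = arr[usable]
    ref = np.exp(np.mean(np.log(arr), axis=1, keepdims=True))
    s = np.median(arr / ref, axis=0)
    return NormalizationFactors(pd.Series(s, index=counts.columns))


def _design_matrix(design: DesignSpec) -> np.ndarray:
    return np.column_stack([np.ones(len(design.samples)), design.time_values])


def estimate_dispersion(variant_counts: np.ndarray, design: DesignSpec) -> tuple[float | None, str]:
    """Cox-Reid dispersion for one variant; (None, reason) when undefined."""
    y = np.asarray(variant_counts, dtype=float)
    if y.sum() == 0:
        return None, "no signal"
    if y.size < 4:
        raise ValueError("dispersion estimation needs >=4 samples")
    X = _design_matrix(design)
    alpha = estimate_dispersions_block(y[None, :], X, design.offsets[None, :])
    return float(alpha[0]), ""


def estimate_dispersions_block(
    Y: np.ndarray, X: np.ndarray, offsets: np.ndarray, moderate: bool = False
) -> np.ndarray:
    """Vectorized CR dispersion, iterating means and dispersion.

    A Poisson fit provides starting means; the CR-adjusted profile
    likelihood is maximized, the means are refitted under the NB model
    at that dispersion, and the profile is maximized once more at the
    refined means.  With ``moderate=True`` a parametric mean-dispersion
    trend (a0 + a1/mu) is fitted across variants and per-variant
    estimates become MAP values under a log-normal prior centered on
    the trend (off by default: classification uses raw per-variant
    estimates unless explicitly asked to moderate).
    """
    _, _, mu, _, _, _ = _nbglm.irls_nb(Y, X, offsets, np.full(Y.shape[0], _nbglm.ALPHA_FLOOR))
    alpha = _nbglm.estimate_alpha_cr(Y, mu, X)
    _, _, mu, _, _, _ = _nbglm.irls_nb(Y, X, offsets, alpha)
    alpha = _nbglm.estimate_alpha_cr(Y, mu, X)
    if moderate and Y.shape[0] >= 10:
        trend = _dispersion_trend(mu.mean(axis=1), alpha)
        alpha = _nbglm.estimate_alpha_cr(Y, mu, X, prior_log_mean=np.log(trend))
    return alpha


def _dispersion_trend(mean_counts: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Fit the parametric trend alpha(mu) = a0 + a1/mu by trimmed LS."""
    keep = alpha > 10 * _nbglm.ALPHA_FLOOR
    mu = mean_counts[keep]
    a = alpha[keep]
    a0, a1 = np.median(a), 0.0
    if keep.sum() >= 10:
        for _ in range(3):  # trim gross outliers and refit
            pred = a0 + a1 / mu
            resid = np.abs(a - pred)
            ok = resid <= 3.0 * np.median(resid) + 1e-12
            A = np.column_stack([np.ones(ok.sum()), 1.0 / mu[ok]])
            coef, *_ = np.linalg.lstsq(A, a[ok], rcond=None)
            a0, a1 = float(max(coef[0], _nbglm.ALPHA_FLOOR)), float(max(coef[1], 0.0))
    return np.maximum(a0 + a1 / np.maximum(mean_counts, 1.0), _nbglm.ALPHA_FLOOR)


def fit_growth_rate(
    variant_counts: np.ndarray,
    design: DesignSpec,
    dispersion: float,
    variant_id: str = "",
    region_id: str = "",
    library: str = "",
) -> GrowthFit:
    """NB regression of one variant's counts on continuous time."""
    y = np.asarray(variant_counts, dtype=float)
    if y.sum() == 0:
        raise ValueError("all counts zero at every time")
    X = _design_matrix(design)
    beta, se, _, _, conv, _ = _nbglm.irls_nb(
        y[None, :], X, design.offsets[None, :], np.array([max(dispersion, _nbglm.ALPHA_FLOOR)])
    )
    return GrowthFit(
        variant_id=variant_id,
        region_id=region_id,
        library=library,
        lfc_per_day=float(beta[0, 1] / LN2),
        se=float(se[0, 1] / LN2),
        intercept=float(beta[0, 0] / LN2),
        dispersion=float(dispersion),
        converged=bool(conv[0]),
        n_samples=int(y.size),
    )


def build_design(cm: CountMatrix, region: str, library: str) -> DesignSpec:
    """Design for one library-experiment: genomic samples, control factors."""
    samples = cm.sample_names(region=region, library=library, genomic_only=True)
    if not samples:
        raise ValueError(f"no genomic samples for {region}/{library}")
    vids = [v for v in cm.region_variants(region) if v in cm.counts.index]
    active = cm.mask.loc[vids, samples].all(axis=1)
    vids = [v for v, a in zip(vids, active) if a]
    factors = control_normalization_factors(
        cm.counts.loc[vids, samples].astype(float), cm.variants.loc[vids, "is_control"].to_numpy(dtype=bool)
    )
    times = np.array([DAY_TO_TIME[cm.samples.loc[s, "day"]] for s in samples])
    return DesignSpec(samples=samples, time_values=times, normalization=factors)


def fit_experiment(
    cm: CountMatrix, region: str, library: str, moderate_dispersion: bool = False
) -> pd.DataFrame:
    """Fit every usable variant of one (region, library) experiment.

    Returns a GrowthFit table (one row per variant) with columns
    variant_id, region_id, library, lfc_per_day, se, intercept,
    dispersion, converged, n_samples.  Fully vectorized across variants.
    """
    design = build_design(cm, region, library)
    samples = design.samples
    vids = [v for v in cm.region_variants(region) if v in cm.counts.index]
    active = cm.mask.loc[vids, samples].all(axis=1)
    vids = [v for v, a in zip(vids, active) if a]
    Y = cm.counts.loc[vids, samples].to_numpy(dtype=float)
    nonzero = Y.sum(axis=1) > 0
    X = _design_matrix(design)
    offsets = np.broadcast_to(design.offsets, Y.shape)
    alpha = np.full(Y.shape[0], _nbglm.ALPHA_FLOOR)
    alpha[nonzero] = estimate_dispersions_block(
        Y[nonzero], X, offsets[nonzero], moderate=moderate_dispersion
    )
    beta = np.full((Y.shape[0], 2), np.nan)
    se = np.full((Y.shape[0], 2), np.nan)
    conv = np.zeros(Y.shape[0], dtype=bool)
    if nonzero.any():
        b, s, _, _, c, _ = _nbglm.irls_nb(Y[nonzero], X, offsets[nonzero], alpha[nonzero])
        beta[nonzero] = b
        se[nonzero] = s
        conv[nonzero] = c
    out = pd.DataFrame(
        {
            "variant_id": vids,
            "region_id": region,
            "library": library,
            "lfc_per_day": beta[:, 1] / LN2,
            "se": se[:, 1] / LN2,
            "intercept": beta[:, 0] / LN2,
            "dispersion": alpha,
            "converged": conv,
            "n_samples": len(samples),
        }
    )
    return out[nonzero]  # all-zero variants carry no growth information


def pairwise_lfc(
    cm: CountMatrix, region: str, library: str, day_from: int = 4, day_to: int = 21
) -> pd.DataFrame:
    """NB log2 fold change between two collection days (factor model).

    Same observation model as the continuous fit but with a two-level
    day factor; the returned log2fc is the ``day_to`` vs ``day_from``
    contrast with its Wald SE.
    """
    s_from = cm.sample_names(region=region, library=library, day=day_from)
    s_to = cm.sample_names(region=region, library=library, day=day_to)
    if not s_from or not s_to:
        raise ValueError(f"missing timepoint D{day_from if not s_from else day_to} for {region}/{library}")
    design = build_design(cm, region, library)
    samples = [s for s in design.samples if s in set(s_from) | set(s_to)]
    factors = design.normalization.factors.loc[samples]
    vids = [v for v in cm.region_variants(region) if v in cm.counts.index]
    active = cm.mask.loc[vids, samples].all(axis=1)
    vids = [v for v, a in zip(vids, active) if a]
    Y = cm.counts.loc[vids, samples].to_numpy(dtype=float)
    nonzero = Y.sum(axis=1) > 0
    level = np.array([1.0 if s in set(s_to) else 0.0 for s in samples])
    X = np.column_stack([np.ones(len(samples)), level])
    offsets = np.broadcast_to(np.log(factors.to_numpy(dtype=float)), Y.shape)
    alpha = np.full(Y.shape[0], _nbglm.ALPHA_FLOOR)
    alpha[nonzero] = _nbglm.estimate_alpha_cr(
        Y[nonzero],
        _nbglm.irls_nb(Y[nonzero], X, offsets[nonzero], alpha[nonzero])[2],
        X,
    )
    beta = np.full((Y.shape[0], 2), np.nan)
    se = np.full((Y.shape[0], 2), np.nan)
    if nonzero.any():
        b, s, _, _, _, _ = _nbglm.irls_nb(Y[nonzero], X, offsets[nonzero], alpha[nonzero])
        beta[nonzero] = b
        se[nonzero] = s
    return pd.DataFrame(
        {
            "variant_id": vids,
            "region_id": region,
            "library": library,
            "day_from": day_from,
            "day_to": day_to,
            "log2fc": beta[:, 1] / LN2,
            "se": se[:, 1] / LN2,
        }
    )
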