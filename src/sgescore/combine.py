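"""Median scaling, dual-library combination and variant classification.

Library-level growth rates are first centered so the median control
(synonymous/intronic) rate in each (region, library) is zero, then
combined per variant by fixed-effect inverse-variance weighting: first
library A with library B within a region, then across overlapping
regions.  The combined score F and its SE give z = F / SE, a two-tailed
normal p-value, and Benjamini-Hochberg FDR across all unique variants;
variants are called depleted (FDR < threshold, F < 0), enriched
(FDR < threshold, F > 0) or unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import qc as qc_mod
from .growth import MIN_CONTROLS, fit_experiment
from .screen_io import CountMatrix, filter_low_count_variants, load_count_table

RESULT_COLUMNS = [
    "variant_id", "functional_score", "combined_se", "z", "p", "fdr",
    "classification", "n_sources", "single_library", "excluded", "excluded_reason",
]


def median_scale(fits: pd.DataFrame, control_mask: pd.Series) -> pd.DataFrame:
    """Subtract the per-(region, library) median control LFC from every fit.

    ``control_mask`` is indexed by variant_id.  SEs are unchanged; after
    scaling the median control ``scaled_lfc`` in each unit is exactly 0.
    """
    out = fits.copy()
    is_ctrl = out["variant_id"].map(control_mask).astype(bool)
    out["scaled_lfc"] = np.nan
    for (region, lib), idx in out.groupby(["region_id", "library"]).groups.items():
        sub = out.loc[idx]
        ctrl_lfcs = sub.loc[is_ctrl.loc[idx], "lfc_per_day"]
        if len(ctrl_lfcs) < MIN_CONTROLS:
            raise ValueError(
                f"median scaling needs >={MIN_CONTROLS} control fits in {region}/{lib}, got {len(ctrl_lfcs)}"
            )
        out.loc[idx, "scaled_lfc"] = sub["lfc_per_day"] - float(ctrl_lfcs.median())
    return out


def inverse_variance_combine(estimates: list[tuple[float, float]]) -> tuple[float, float]:
    """Fixed-effect inverse-variance weighted mean of (value, se) pairs."""
    if not estimates:
        raise ValueError("no estimates to combine")
    values = np.array([e[0] for e in estimates], dtype=float)
    ses = np.array([e[1] for e in estimates], dtype=float)
    if (ses <= 0).any():
        raise ValueError("all standard errors must be > 0")
    w = 1.0 / ses**2
    return float(np.sum(w * values) / np.sum(w)), float(np.sqrt(1.0 / np.sum(w)))


def combine_variant_estimates(scaled: pd.DataFrame, variants: pd.DataFrame) -> pd.DataFrame:
    """Collapse per-(region, library) scaled fits to one estimate per variant.

    Stage 1 combines libraries A/B within each region; stage 2 combines
    region-level estimates across overlapping regions (both stages via
    inverse-variance weighting, which makes staged == pooled).  Variants
    inside a PPE codon seen by only one library are excluded, since their
    counts reflect the library-specific protection edit.
    """
    rows = []
    for vid, sub in scaled.groupby("variant_id", sort=True):
        sub = sub.dropna(subset=["scaled_lfc", "se"])
        sub = sub[sub["se"] > 0]
        in_ppe = bool(variants.loc[vid, "in_ppe_codon"]) if vid in variants.index else False
        if sub.empty:
            rows.append({"variant_id": vid, "functional_score": np.nan, "combined_se": np.nan,
                         "n_sources": 0, "single_library": False, "excluded": True,
                         "excluded_reason": "no_estimate"})
            continue
        n_libraries = sub["library"].nunique()
        if in_ppe and n_libraries < 2:
            rows.append({"variant_id": vid, "functional_score": np.nan, "combined_se": np.nan,
                         "n_sources": int(len(sub)), "single_library": True, "excluded": True,
                         "excluded_reason": "ppe_codon_single_library"})
            continue
        region_estimates = []
        for _, rsub in sub.groupby("region_id"):
            region_estimates.append(
                inverse_variance_combine(list(zip(rsub["scaled_lfc"], rsub["se"])))
            )
        score, se = inverse_variance_combine(region_estimates)
        rows.append({"variant_id": vid, "functional_score": score, "combined_se": se,
                     "n_sources": int(len(sub)), "single_library": bool(n_libraries == 1),
                     "excluded": False, "excluded_reason": ""})
    return pd.DataFrame(rows)


def classify_variants(table: pd.DataFrame, fdr_threshold: float = 0.01) -> pd.DataFrame:
    """Two-tailed z-test and BH FDR over all included unique variants."""
    if table.empty:
        raise ValueError("empty results table")
    out = table.copy()
    inc = ~out["excluded"].astype(bool)
    z = out.loc[inc, "functional_score"] / out.loc[inc, "combined_se"]
    p = 2.0 * stats.norm.sf(np.abs(z))  # survival function: stable at |z| > 8
    fdr = stats.false_discovery_control(p, method="bh")
    out.loc[inc, "z"] = z
    out.loc[inc, "p"] = p
    out.loc[inc, "fdr"] = fdr
    sig = out["fdr"] < fdr_threshold
    out["classification"] = "unchanged"
    out.loc[inc & sig & (out["functional_score"] < 0), "classification"] = "depleted"
    out.loc[inc & sig & (out["functional_score"] > 0), "classification"] = "enriched"
    out.loc[~inc, "classification"] = ""
    return out


@dataclass
class PipelineConfig:
    """Thresholds and switches for the end-to-end scoring run."""

    min_total: int = 10
    fdr_threshold: float = 0.01
    replicate_corr_threshold: float = 0.7
    late_wildtype_threshold: float = 0.30
    positional_rho_threshold: float = 0.5
    positional_p_threshold: float = 0.01
    qc_strict: bool = False
    dispersion_moderation: bool = False
    cut_sites: dict = field(default_factory=dict)  # region -> 1-based cut site

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def run_functional_scoring(
    cm: CountMatrix, config: PipelineConfig | None = None
) -> tuple[pd.DataFrame, qc_mod.QCReport, pd.DataFrame]:
    """Full scoring pipeline: filter -> QC -> fit -> scale -> combine -> classify.

    Returns ``(results, qc_report, fits)``.  ``results`` has one row per
    unique variant; ``fits`` is the per-(region, library) audit table of
    scaled growth-rate estimates.  Deterministic given inputs.
    """
    config = config or PipelineConfig()
    cm, _removed = filter_low_count_variants(cm, min_total=config.min_total)

    report = qc_mod.QCReport()
    corr_rows, pos_rows = [], []
    excluded_samples: set[str] = set()
    excluded_experiments: set[tuple[str, str]] = set()
    for region, library in cm.experiments():
        days = sorted({d for d in cm.samples.loc[cm.sample_names(region=region, library=library), "day"]
                       if d != "plasmid"})
        for day in days:
            samples = cm.sample_names(region=region, library=library, day=day)
            if len(samples) < 2:
                continue
            df = qc_mod.replicate_correlation(cm, region, library, day,
                                              threshold=config.replicate_corr_threshold)
            corr_rows.append(df)
            for _, r in df[df["flag"]].iterrows():
                report.add_exclusion((r["unit"],), r["reason"])
                if config.qc_strict:
                    excluded_samples.add(r["unit"])
        if region in config.cut_sites:
            try:
                res = qc_mod.positional_effect_flag(
                    cm, region, library, config.cut_sites[region],
                    rho_threshold=config.positional_rho_threshold,
                    p_threshold=config.positional_p_threshold,
                )
            except ValueError:
                res = None
            if res is not None:
                pos_rows.append({"unit": f"{region}_{library}", **{k: res[k] for k in ("flag", "reason", "rho", "p")},
                                 "value": res["rho"]})
                if res["flag"]:
                    report.add_exclusion((region, library), "positional_effect")
                    if config.qc_strict:
                        excluded_experiments.add((region, library))
    if corr_rows:
        report.replicate_correlations = pd.concat(corr_rows, ignore_index=True)
    if pos_rows:
        report.positional_effect = pd.DataFrame(pos_rows)

    has_specials = any(v.startswith(("ref_seq_", "pam_seq_")) for v in cm.counts.index)
    if has_specials:
        from .screen_io import editing_summary

        summary = editing_summary(cm)
        late = qc_mod.late_wildtype_flag(summary, threshold=config.late_wildtype_threshold)
        report.late_wildtype = late
        for _, r in late[late["flag"]].iterrows():
            report.add_exclusion((r["unit"],), r["reason"])
            if config.qc_strict:
                excluded_samples.add(r["unit"])

    if excluded_samples:
        keep = [s for s in cm.counts.columns if s not in excluded_samples]
        cm = CountMatrix(counts=cm.counts[keep], variants=cm.variants,
                         samples=cm.samples.loc[keep], mask=cm.mask[keep])

    fit_tables = []
    for region, library in cm.experiments():
        if (region, library) in excluded_experiments:
            continue
        try:
            fit_tables.append(
                fit_experiment(cm, region, library, moderate_dispersion=config.dispersion_moderation)
            )
        except ValueError as exc:
            raise ValueError(f"growth-model stage failed for {region}/{library}: {exc}") from exc
    fits = pd.concat(fit_tables, ignore_index=True)

    scaled = median_scale(fits, cm.variants["is_control"])
    combined = combine_variant_estimates(scaled, cm.variants)
    results = classify_variants(combined, fdr_threshold=config.fdr_threshold)

    ann_cols = ["chrom", "pos", "ref", "alt", "consequence", "is_control", "in_ppe_codon"]
    ann = cm.variants[[c for c in ann_cols if c in cm.variants.columns]]
    results = results.merge(ann, left_on="variant_id", right_index=True, how="left")
    return results, report, scaled
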