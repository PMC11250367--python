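"""Synthetic SGE screens with known ground truth.

Emulates the statistical structure the scoring pipeline assumes: two
independent template libraries (A/B) per target region, three
transfection replicates sampled at days 4/7/10/14/21, negative-binomial
read counts around a latent abundance that decays exponentially for
deleterious variants (a_v * 2^(beta_v * t)), log-normal initial library
representation, a small constant wild-type (unedited) and PPE-only read
fraction, and optionally variants shared between overlapping regions.
Depletion is deterministic decay plus NB observation noise; there is no
explicit cell-bottleneck simulation, which is exactly the log-linear
model the scoring assumes and what makes parameter-recovery tests
well-posed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .screen_io import DAY_TO_TIME, CountMatrix

#: simulated variant classes -> annotation consequence category
CLASS_CONSEQUENCE = {
    "synonymous": "synonymous",
    "intron": "intron",
    "missense_neutral": "missense",
    "missense_lof": "missense",
    "missense_hypomorph": "missense",
    "stop_gained": "stop_gained",
    "inframe_deletion_lof": "inframe_deletion",
}

DEFAULT_CLASS_MIX = {
    "synonymous": 0.15,
    "intron": 0.10,
    "missense_neutral": 0.35,
    "missense_lof": 0.20,
    "missense_hypomorph": 0.05,
    "stop_gained": 0.10,
    "inframe_deletion_lof": 0.05,
}

#: true growth-rate effects (log2 per day); the loss-of-function effect
#: matches the typical depleted-variant magnitude in an essential gene
DEFAULT_TRUE_BETA = {
    "synonymous": 0.0,
    "intron": 0.0,
    "missense_neutral": 0.0,
    "missense_lof": -0.13,
    "missense_hypomorph": -0.06,
    "stop_gained": -0.13,
    "inframe_deletion_lof": -0.13,
}


@dataclass
class SimConfig:
    n_regions: int = 2
    variants_per_region: int = 500
    class_mix: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_MIX))
    true_beta: dict = field(default_factory=lambda: dict(DEFAULT_TRUE_BETA))
    dispersion: float = 0.05
    initial_abundance_mu: float = 0.0
    initial_abundance_sigma: float = 0.5
    depth_per_sample: float = 500.0
    unedited_fraction: float = 0.01
    ppe_only_fraction: float = 0.03
    timepoint_days: tuple[int, ...] = (4, 7, 10, 14, 21)
    replicates: int = 3
    libraries: tuple[str, ...] = ("A", "B")
    overlap_spec: list | None = None  # [(region_a, region_b, n_shared), ...]
    ppe_codon_fraction: float = 0.0
    include_plasmid: bool = True
    seed: int = 0

    def validate(self) -> None:
        if abs(sum(self.class_mix.values()) - 1.0) > 1e-9:
            raise ValueError("class_mix proportions must sum to 1")
        if self.depth_per_sample <= 0:
            raise ValueError("depth_per_sample must be > 0")
        if not 0 <= self.unedited_fraction < 1:
            raise ValueError("unedited_fraction must be in [0, 1)")
        missing = set(self.class_mix) - set(self.true_beta)
        if missing:
            raise ValueError(f"classes without a true_beta: {sorted(missing)}")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """NB2 sample via the gamma-Poisson mixture (Poisson when alpha ~ 0)."""
    mean = np.maximum(mean, 1e-12)
    if alpha <= 1e-12:
        return rng.poisson(mean)
    shape = 1.0 / alpha
    lam = rng.gamma(shape, alpha * mean)
    return rng.poisson(lam)


def _region_name(i: int) -> str:
    return f"{i + 1:02d}"


def simulate_screen(config: SimConfig) -> tuple[CountMatrix, pd.DataFrame]:
    """Draw a full synthetic screen; returns (CountMatrix, truth table).

    The truth table has one row per unique variant: class, true_beta and
    region membership.  Bit-identical for a fixed ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    classes = list(config.class_mix)
    probs = np.array([config.class_mix[c] for c in classes])
    region_span = 300
    variant_rows: dict[str, dict] = {}
    region_members: dict[str, list[str]] = {}

    overlap = {}
    if config.overlap_spec:
        for ra, rb, n_shared in config.overlap_spec:
            overlap[rb] = (ra, int(n_shared))

    base_pos = 100
    for r in range(config.n_regions):
        region = _region_name(r)
        start = base_pos + r * region_span
        shared_ids: list[str] = []
        if region in overlap:
            donor, n_shared = overlap[region]
            shared_ids = region_members[donor][-n_shared:]
            for vid in shared_ids:
                variant_rows[vid]["region_ids"] += f";{region}"
        n_new = config.variants_per_region - len(shared_ids)
        cls_draw = rng.choice(len(classes), size=n_new, p=probs)
        # collision-free candidate pools: 3 possible SNVs per base (the
        # reference base is fixed), deletions of increasing length
        span = 245
        bases = "ACGT"
        refs = rng.choice(list(bases), size=span)
        snv_pool = [
            (start + i, refs[i], alt)
            for i in range(span)
            for alt in bases
            if alt != refs[i]
        ]
        rng.shuffle(snv_pool)
        if n_new > len(snv_pool):
            raise ValueError(
                f"variants_per_region={config.variants_per_region} exceeds the "
                f"{len(snv_pool)} distinct variants a {span}-bp region supports; add regions instead"
            )
        del_lengths = iter(range(2, 2 + n_new))
        del_positions: list[tuple[int, int]] = []
        snv_i = 0
        new_ids = []
        for k in range(n_new):
            cls = classes[cls_draw[k]]
            if CLASS_CONSEQUENCE[cls] == "inframe_deletion":
                if not del_positions:
                    length = next(del_lengths)
                    del_positions = [(start + i, length) for i in rng.permutation(span)]
                pos, length = del_positions.pop()
                ref, alt = refs[pos - start], ""
                vid = f"c.{pos}_{pos + length}del"
            else:
                pos, ref, alt = snv_pool[snv_i]
                snv_i += 1
                vid = f"c.{pos}{ref}>{alt}"
            variant_rows[vid] = {
                "variant_id": vid,
                "chrom": "chr3",
                "pos": pos,
                "ref": str(ref),
                "alt": str(alt),
                "consequence": CLASS_CONSEQUENCE[cls],
                "is_control": CLASS_CONSEQUENCE[cls] in {"synonymous", "intron"},
                "region_ids": region,
                "in_ppe_codon": bool(rng.random() < config.ppe_codon_fraction),
                "protein_change": "",
                "sim_class": cls,
                "true_beta": float(config.true_beta[cls]),
            }
            new_ids.append(vid)
        region_members[region] = shared_ids + new_ids

    variants = pd.DataFrame(variant_rows.values()).set_index("variant_id")
    truth = variants[["sim_class", "true_beta", "region_ids"]].rename(columns={"sim_class": "class"}).reset_index()
    ann = variants.drop(columns=["sim_class", "true_beta"])

    all_ids = list(ann.index)
    id_pos = {v: i for i, v in enumerate(all_ids)}
    specials = []
    for r in range(config.n_regions):
        region = _region_name(r)
        specials += [f"ref_seq_{region}", f"pam_seq_{region}"]
    n_rows = len(all_ids) + len(specials)

    sample_cols: dict[str, np.ndarray] = {}
    times = {d: DAY_TO_TIME[d] for d in config.timepoint_days}
    for r in range(config.n_regions):
        region = _region_name(r)
        members = region_members[region]
        idx = np.array([id_pos[v] for v in members])
        beta = truth.set_index("variant_id").loc[members, "true_beta"].to_numpy(dtype=float)
        n_reads = config.depth_per_sample * len(members)
        for lib in config.libraries:
            a_v = rng.lognormal(config.initial_abundance_mu, config.initial_abundance_sigma, size=len(members))
            if config.include_plasmid:
                p = a_v / a_v.sum()
                col = np.zeros(n_rows, dtype=np.int64)
                col[idx] = _nb_draw(rng, n_reads * p, config.dispersion)
                sample_cols[f"{region}_{lib}_R1_Dplasmid"] = col
            for rep in range(1, config.replicates + 1):
                for day in config.timepoint_days:
                    lam = a_v * np.power(2.0, beta * times[day])
                    frac_var = 1.0 - config.unedited_fraction - config.ppe_only_fraction
                    p = frac_var * lam / lam.sum()
                    mean = np.zeros(n_rows)
                    mean[idx] = n_reads * p
                    mean[len(all_ids) + 2 * r] = n_reads * config.unedited_fraction
                    mean[len(all_ids) + 2 * r + 1] = n_reads * config.ppe_only_fraction
                    sample_cols[f"{region}_{lib}_R{rep}_D{day}"] = _nb_draw(rng, mean, config.dispersion)

    counts = pd.DataFrame(sample_cols, index=all_ids + specials).astype(np.int64)
    from .screen_io import parse_sample_name

    samples = pd.DataFrame([parse_sample_name(c) for c in counts.columns]).set_index("sample")
    cm = CountMatrix(counts=counts, variants=ann, samples=samples)
    return cm, truth


def recovery_report(results: pd.DataFrame, truth: pd.DataFrame, fdr_threshold: float = 0.01) -> dict:
    """Estimation and classification accuracy against simulation truth.

    Reports per-class bias and RMSE of the functional score relative to
    the true growth-rate effect, sensitivity of depleted calls for each
    deleterious class, specificity (fraction unchanged) for neutral
    classes, and the empirical false-discovery proportion among all
    depleted/enriched calls.
    """
    merged = results.merge(truth, on="variant_id", how="inner")
    if merged.empty:
        raise ValueError("no shared variant ids between results and truth")
    if len(merged) < len(truth):
        missing = set(truth["variant_id"]) - set(results["variant_id"])
        if missing and len(merged) == 0:
            raise ValueError("variant id mismatch")
    inc = merged[~merged["excluded"].astype(bool)].copy()
    per_class = {}
    for cls, sub in inc.groupby("class"):
        err = sub["functional_score"] - sub["true_beta"]
        entry = {"n": int(len(sub)), "bias": float(err.mean()), "rmse": float(np.sqrt((err**2).mean()))}
        if (sub["true_beta"] < 0).all():
            entry["sensitivity"] = float((sub["classification"] == "depleted").mean())
        if (sub["true_beta"] == 0).all():
            entry["specificity"] = float((sub["classification"] == "unchanged").mean())
        per_class[cls] = entry
    calls = inc[inc["classification"].isin(["depleted", "enriched"])]
    false_calls = (
        ((calls["classification"] == "depleted") & (calls["true_beta"] >= 0))
        | ((calls["classification"] == "enriched") & (calls["true_beta"] <= 0))
    )
    fdp = float(false_calls.mean()) if len(calls) else 0.0
    neutral = inc[inc["true_beta"] == 0]
    deleterious = inc[inc["true_beta"] < 0]
    return {
        "per_class": per_class,
        "n_included": int(len(inc)),
        "n_calls": int(len(calls)),
        "false_discovery_proportion": fdp,
        "false_call_rate": float(false_calls.sum() / len(inc)),
        "sensitivity_deleterious": (
            float((deleterious["classification"] == "depleted").mean()) if len(deleterious) else None
        ),
        "specificity_neutral": (
            float((neutral["classification"] == "unchanged").mean()) if len(neutral) else None
        ),
        "fdr_threshold": fdr_threshold,
    }
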