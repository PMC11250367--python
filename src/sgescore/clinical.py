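"""Clinical calibration of SGE functional scores against truth sets.

Covers ROC analysis (lower score predicts pathogenic), 2x2 truth-table
concordance, ACMG PS3/BS3 likelihood ratios with evidence strengths on
the published odds-of-pathogenicity scale, the strong/weak depletion
split about the median depleted score, and a small facade over the
standard group-comparison tests used alongside screen results.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

#: likelihood-ratio thresholds of the ACMG evidence-strength calibration
STRENGTH_THRESHOLDS = {
    "supporting": 2.08,
    "moderate": 4.33,
    "strong": 18.7,
    "very_strong": 350.0,
}


@dataclass
class EvidenceTable:
    """2x2 readout counts: truth label x (depleted | unchanged/enriched)."""

    a: int  # pathogenic, depleted
    b: int  # pathogenic, unchanged/enriched
    c: int  # benign, depleted
    d: int  # benign, unchanged/enriched

    def __post_init__(self):
        for name in "abcd":
            if getattr(self, name) < 0:
                raise ValueError(f"count {name} must be >= 0")


@dataclass
class EvidenceResult:
    lr_path: float
    lr_ben: float
    strength_path: str
    strength_ben: str
    lr_path_uncorrected: float
    lr_ben_uncorrected: float


@dataclass
class RocSummary:
    auc: float
    pr_auc: float
    ideal_threshold: float
    sensitivity: float
    specificity: float
    error_rate: float


def _round_half_up(x: float, ndigits: int = 1) -> float:
    return float(Decimal(repr(x)).quantize(Decimal(10) ** -ndigits, rounding=ROUND_HALF_UP))


def roc_metrics(scores: np.ndarray, labels: np.ndarray) -> RocSummary:
    """ROC/PR summary with orientation 'pathogenic iff score <= threshold'.

    AUC uses the rank (Mann-Whitney) formulation with tie correction,
    the ideal threshold maximizes Youden's J (ties broken toward the
    lower, more conservative threshold), and the PR AUC is the
    step-interpolated area of the precision-recall curve.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    path = scores[labels == "pathogenic"]
    ben = scores[labels == "benign"]
    if len(path) == 0 or len(ben) == 0:
        raise ValueError("both pathogenic and benign labels are required")

    ranks = stats.rankdata(scores)  # ascending; pathogenic should rank low
    r_path = ranks[labels == "pathogenic"].sum()
    u_path = r_path - len(path) * (len(path) + 1) / 2.0  # pairs with ben < path (+0.5 ties)
    auc = 1.0 - u_path / (len(path) * len(ben))

    thresholds = np.unique(scores)
    sens = np.array([(path <= t).mean() for t in thresholds])
    spec = np.array([(ben > t).mean() for t in thresholds])
    j = sens + spec - 1.0
    best = int(np.flatnonzero(j == j.max())[0])  # lowest threshold among ties
    n = len(scores)
    fn = int((path > thresholds[best]).sum())
    fp = int((ben <= thresholds[best]).sum())

    order = np.argsort(scores, kind="stable")  # most pathogenic-looking first
    is_path = (labels[order] == "pathogenic").astype(float)
    tp = np.cumsum(is_path)
    recall = tp / len(path)
    precision = tp / np.arange(1, n + 1)
    dr = np.diff(np.concatenate([[0.0], recall]))
    pr_auc = float(np.sum(dr * precision))

    return RocSummary(
        auc=float(auc),
        pr_auc=pr_auc,
        ideal_threshold=float(thresholds[best]),
        sensitivity=float(sens[best]),
        specificity=float(spec[best]),
        error_rate=(fn + fp) / n,
    )


def truth_table_metrics(classifications: pd.Series, truth: pd.DataFrame) -> tuple[EvidenceTable, dict]:
    """Count depleted vs unchanged/enriched readouts per truth label.

    ``classifications`` maps variant_id -> class; ``truth`` has columns
    ``variant_id`` and ``label`` in {pathogenic, benign}.  Returns the
    2x2 table and concordance percentages rounded to one decimal.
    """
    missing = [v for v in truth["variant_id"] if v not in classifications.index]
    if missing:
        raise ValueError(f"truth variants missing from results: {missing[:10]}")
    cls = classifications.loc[truth["variant_id"].to_numpy()]
    depleted = (cls == "depleted").to_numpy()
    is_path = (truth["label"] == "pathogenic").to_numpy()
    table = EvidenceTable(
        a=int((is_path & depleted).sum()),
        b=int((is_path & ~depleted).sum()),
        c=int((~is_path & depleted).sum()),
        d=int((~is_path & ~depleted).sum()),
    )
    pct = {
        "pct_pathogenic_depleted": (
            _round_half_up(100.0 * table.a / (table.a + table.b)) if table.a + table.b else None
        ),
        "pct_benign_unchanged_enriched": (
            _round_half_up(100.0 * table.d / (table.c + table.d)) if table.c + table.d else None
        ),
    }
    return table, pct


def acmg_likelihood_ratio(table: EvidenceTable) -> EvidenceResult:
    """PS3/BS3 likelihood ratios from a truth-set readout table.

    A conservative +1 correction is applied to the opposing class's
    discordant count (so a zero cell cannot produce an infinite ratio):

        LR_path = (a / (a+b)) / ((c + 1) / (c+d))
        LR_ben  = (d / (c+d)) / ((b + 1) / (a+b))

    Ratios are reported rounded half-up to one decimal; the raw
    uncorrected ratios (possibly infinite) are kept alongside.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if a + b == 0 or c + d == 0:
        raise ValueError("likelihood ratios need at least one variant in each truth class")
    lr_path = (a / (a + b)) / ((c + 1) / (c + d))
    lr_ben = (d / (c + d)) / ((b + 1) / (a + b))
    with np.errstate(divide="ignore"):
        raw_path = (a / (a + b)) / (c / (c + d)) if c > 0 else np.inf
        raw_ben = (d / (c + d)) / (b / (a + b)) if b > 0 else np.inf
    return EvidenceResult(
        lr_path=_round_half_up(lr_path),
        lr_ben=_round_half_up(lr_ben),
        strength_path=evidence_strength(lr_path),
        strength_ben=evidence_strength(lr_ben),
        lr_path_uncorrected=float(raw_path),
        lr_ben_uncorrected=float(raw_ben),
    )


def evidence_strength(lr: float) -> str:
    """Map a likelihood ratio to an ACMG evidence strength category."""
    if lr < 0:
        raise ValueError("likelihood ratio must be >= 0")
    strength = "none"
    for name, thr in STRENGTH_THRESHOLDS.items():
        if lr >= thr:
            strength = name
    return strength


@dataclass
class DepletionSplit:
    median_score: float
    assignment: pd.Series  # variant_id -> strongly_depleted | weakly_depleted


def depletion_split(depleted: pd.DataFrame) -> DepletionSplit:
    """Split depleted variants about their median functional score.

    Scores <= median (more negative = stronger depletion) are strongly
    depleted; with odd n and distinct scores the strong side has one
    more member.
    """
    if len(depleted) < 2:
        raise ValueError("depletion split needs >=2 depleted variants")
    scores = depleted["functional_score"].astype(float)
    med = float(scores.median())
    assignment = pd.Series(
        np.where(scores <= med, "strongly_depleted", "weakly_depleted"),
        index=depleted["variant_id"].to_numpy(),
    )
    return DepletionSplit(median_score=med, assignment=assignment)


# -- standard group-comparison facade -----------------------------------

@dataclass
class GroupComparison:
    statistic: float
    p: float
    pairwise: pd.DataFrame | None = None


def _dunn_bh(values: np.ndarray, groups: np.ndarray) -> pd.DataFrame:
    """Dunn's post hoc rank test with tie correction and BH adjustment."""
    ranks = stats.rankdata(values)
    n = len(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12.0 * (n - 1))
    var_base = n * (n + 1) / 12.0 - tie_term
    names = sorted(pd.unique(groups))
    rows = []
    for i, gi in enumerate(names):
        for gj in names[i + 1 :]:
            ri = ranks[groups == gi]
            rj = ranks[groups == gj]
            se = np.sqrt(var_base * (1.0 / len(ri) + 1.0 / len(rj)))
            z = (ri.mean() - rj.mean()) / se
            rows.append({"group1": gi, "group2": gj, "z": z, "p": 2.0 * stats.norm.sf(abs(z))})
    out = pd.DataFrame(rows)
    out["q"] = stats.false_discovery_control(out["p"], method="bh")
    return out


def compare_groups(values, group_labels=None, method: str = "mann_whitney") -> GroupComparison:
    """Two-sided standard tests used around screen results.

    ``mann_whitney`` and ``kruskal_dunn_bh`` take values plus group
    labels; ``chi_square`` takes a contingency table as ``values``;
    ``spearman``/``pearson`` correlate ``values`` with ``group_labels``
    as a paired vector.
    """
    if method == "chi_square":
        table = np.asarray(values, dtype=float)
        res = stats.chi2_contingency(table, correction=False)
        return GroupComparison(statistic=float(res.statistic), p=float(res.pvalue))
    if method in {"spearman", "pearson"}:
        x = np.asarray(values, dtype=float)
        y = np.asarray(group_labels, dtype=float)
        fn = stats.spearmanr if method == "spearman" else stats.pearsonr
        r, p = fn(x, y)
        return GroupComparison(statistic=float(r), p=float(p))
    values = np.asarray(values, dtype=float)
    groups = np.asarray(group_labels)
    names = pd.unique(groups)
    if len(names) < 2:
        raise ValueError("need >=2 groups")
    samples = [values[groups == g] for g in names]
    if any(len(s) == 0 for s in samples):
        raise ValueError("degenerate (empty) group")
    if method == "mann_whitney":
        if len(names) != 2:
            raise ValueError("mann_whitney requires exactly 2 groups")
        res = stats.mannwhitneyu(samples[0], samples[1], alternative="two-sided")
        return GroupComparison(statistic=float(res.statistic), p=float(res.pvalue))
    if method == "kruskal_dunn_bh":
        res = stats.kruskal(*samples)
        return GroupComparison(statistic=float(res.statistic), p=float(res.pvalue),
                               pairwise=_dunn_bh(values, groups))
    raise ValueError(f"unknown method {method!r}")


def load_truth_set(path) -> pd.DataFrame:
    """Read a truth-set TSV with columns variant_id, label, source."""
    truth = pd.read_csv(path, sep="\t")
    bad = set(truth["label"]) - {"pathogenic", "benign"}
    if bad:
        raise ValueError(f"truth labels must be pathogenic/benign, got {sorted(bad)}")
    return truth


def reclassify_from_scores(scores: pd.DataFrame, fdr_threshold: float = 0.01) -> pd.Series:
    """Recompute classifications from a published score/FDR table.

    Validation path for externally deposited datasets: given columns
    ``variant_id``, ``functional_score`` and ``fdr``, applies the
    classification rule (FDR < threshold with the score's sign) and
    returns variant_id -> class.
    """
    sig = scores["fdr"] < fdr_threshold
    cls = np.where(sig & (scores["functional_score"] < 0), "depleted",
                   np.where(sig & (scores["functional_score"] > 0), "enriched", "unchanged"))
    return pd.Series(cls, index=scores["variant_id"].to_numpy())
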