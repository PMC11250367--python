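#!/usr/bin/env python
"""Clinical calibration: ROC, truth-table concordance and ACMG evidence.

Evaluates the synthetic screen's classifications against its ground
truth (deleterious classes = 'pathogenic', neutral classes = 'benign'),
then recomputes the likelihood ratios for the two published truth-set
readout tables and splits depleted variants about their median score.
"""

import dataclasses
import json
from pathlib import Path

import pandas as pd

from sgescore.clinical import (
    EvidenceTable,
    acmg_likelihood_ratio,
    depletion_split,
    roc_metrics,
    truth_table_metrics,
)

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    results = pd.read_csv(BASE / "functional_scores.tsv", sep="\t")
    truth_sim = pd.read_csv(BASE / "synthetic_screen" / "truth.tsv", sep="\t")
    inc = results[~results["excluded"].astype(bool)]
    merged = inc.merge(truth_sim, on="variant_id")
    truth = pd.DataFrame({
        "variant_id": merged["variant_id"],
        "label": merged["true_beta"].lt(0).map({True: "pathogenic", False: "benign"}),
        "source": "synthetic",
    })

    roc = roc_metrics(merged["functional_score"].to_numpy(), truth["label"].to_numpy())
    table, pct = truth_table_metrics(inc.set_index("variant_id")["classification"], truth)
    ev_synth = acmg_likelihood_ratio(table)
    dep = inc[inc["classification"] == "depleted"]
    split = depletion_split(dep)

    report = {
        "synthetic_truth_set": {
            "roc": dataclasses.asdict(roc),
            "evidence_table": dataclasses.asdict(table),
            "concordance_pct": pct,
            "likelihood_ratios": dataclasses.asdict(ev_synth),
        },
        "published_truth_tables": {
            "systematic": dataclasses.asdict(acmg_likelihood_ratio(EvidenceTable(2419, 4, 4, 134))),
            "clinvar_1star": dataclasses.asdict(acmg_likelihood_ratio(EvidenceTable(7, 0, 0, 6))),
        },
        "depletion_split": {
            "median_score": split.median_score,
            "n_strong": int((split.assignment == "strongly_depleted").sum()),
            "n_weak": int((split.assignment == "weakly_depleted").sum()),
        },
    }
    out = BASE / "clinical_evaluation.json"
    out.write_text(json.dumps(report, indent=2) + "\n")
    print(f"synthetic truth set: AUC {roc.auc:.4f}, sensitivity {roc.sensitivity:.3f}, "
          f"specificity {roc.specificity:.3f} at threshold {roc.ideal_threshold:+.4f}")
    print(f"synthetic evidence: LR+ {ev_synth.lr_path} ({ev_synth.strength_path}), "
          f"LR- {ev_synth.lr_ben} ({ev_synth.strength_ben})")
    print(f"depleted split about {split.median_score:+.4f}: "
          f"{report['depletion_split']['n_strong']} strong / {report['depletion_split']['n_weak']} weak")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
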