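import numpy as np
import pandas as pd
import pytest

from sgescore import combine, simulate
from sgescore.screen_io import CountMatrix


def make_count_matrix(counts: dict, variants: dict, region: str = "05") -> CountMatrix:
    """Build a small validated CountMatrix from plain dicts.

    ``counts``: sample name -> list of counts (one per variant row, in
    ``variants`` order, specials appended).  ``variants``: variant_id ->
    (pos, consequence) or (pos, consequence, extra_fields_dict).
    """
    from sgescore.screen_io import CONTROL_CONSEQUENCES, parse_sample_name

    var_rows = {}
    for vid, spec in variants.items():
        pos, cons = spec[0], spec[1]
        extra = spec[2] if len(spec) > 2 else {}
        var_rows[vid] = {
            "chrom": "chr3",
            "pos": pos,
            "ref": "A",
            "alt": "T",
            "consequence": cons,
            "is_control": cons in CONTROL_CONSEQUENCES,
            "region_ids": region,
            "in_ppe_codon": False,
            "protein_change": "",
            **extra,
        }
    vdf = pd.DataFrame(var_rows).T
    vdf.index.name = "variant_id"
    cdf = pd.DataFrame(counts, index=list(vdf.index) + [], dtype=np.int64)
    samples = pd.DataFrame([parse_sample_name(c) for c in cdf.columns]).set_index("sample")
    return CountMatrix(counts=cdf, variants=vdf, samples=samples)


@pytest.fixture(scope="session")
def small_screen():
    """A small two-region dual-library synthetic screen plus its truth."""
    cfg = simulate.SimConfig(n_regions=2, variants_per_region=120, seed=42)
    cm, truth = simulate.simulate_screen(cfg)
    return cm, truth


@pytest.fixture(scope="session")
def small_screen_results(small_screen):
    cm, truth = small_screen
    results, report, fits = combine.run_functional_scoring(cm)
    return results, report, fits, truth
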