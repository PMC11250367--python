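"""Count-table I/O, exact-match template counting and pre-model filters.

An SGE screen is stored as a variants x samples integer count matrix.
Sample columns follow the fixed convention ``<region>_<library>_R<rep>_D<day>``
with day ``plasmid`` or one of {4, 7, 10, 14, 21}.  Two special rows per
region, ``ref_seq_<region>`` (unedited wild type) and ``pam_seq_<region>``
(protection-edit-only alleles), carry the editing-efficiency read counts.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: day label -> continuous time used in the growth-rate regression
DAY_TO_TIME = {4: 0.0, 7: 3.0, 10: 6.0, 14: 10.0, 21: 17.0}
GENOMIC_DAYS = (4, 7, 10, 14, 21)

CONSEQUENCES = {
    "synonymous",
    "missense",
    "stop_gained",
    "intron",
    "splice_donor",
    "splice_acceptor",
    "utr_5",
    "utr_3",
    "inframe_deletion",
    "frameshift",
    "other",
}
#: consequences whose variants serve as fitness-neutral controls
CONTROL_CONSEQUENCES = {"synonymous", "intron"}

_SAMPLE_RE = re.compile(r"^(?P<region>.+)_(?P<library>[AB])_R(?P<rep>\d+)_D(?P<day>plasmid|4|7|10|14|21)$")

_ANNOTATION_COLS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "consequence",
    "is_control",
    "region_ids",
    "in_ppe_codon",
    "protein_change",
]


class ScreenFormatError(ValueError):
    """Malformed count table, annotation table or template library."""


def parse_sample_name(name: str) -> dict:
    """Split ``<region>_<library>_R<rep>_D<day>`` into its sample key."""
    m = _SAMPLE_RE.match(name)
    if m is None:
        raise ScreenFormatError(f"sample column {name!r} does not match <region>_<library>_R<rep>_D<day>")
    day = m.group("day")
    day_val: object = "plasmid" if day == "plasmid" else int(day)
    return {
        "sample": name,
        "region_id": m.group("region"),
        "library": m.group("library"),
        "replicate": int(m.group("rep")),
        "day": day_val,
        "time_value": DAY_TO_TIME.get(day_val, np.nan) if day_val != "plasmid" else np.nan,
    }


def special_role(variant_id: str) -> tuple[str, str] | None:
    """Return (role, region) for ref_seq_/pam_seq_ rows, else None."""
    for role in ("ref_seq", "pam_seq"):
        if variant_id.startswith(role + "_"):
            return role, variant_id[len(role) + 1 :]
    return None


@dataclass
class CountMatrix:
    """Integer counts (variants + special rows) x samples with metadata.

    ``counts`` rows are indexed by variant_id (plus ``ref_seq_<region>`` /
    ``pam_seq_<region>``), columns by sample name.  ``variants`` holds one
    annotation row per true variant; ``samples`` one row per column.
    ``mask`` marks count cells that remain usable after per-experiment
    exclusions (low-count filtering); it never alters the counts.
    """

    counts: pd.DataFrame
    variants: pd.DataFrame
    samples: pd.DataFrame
    mask: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.mask is None:
            self.mask = pd.DataFrame(True, index=self.counts.index, columns=self.counts.columns)

    # -- accessors -------------------------------------------------------
    @property
    def variant_ids(self) -> list[str]:
        return [v for v in self.counts.index if special_role(v) is None]

    def sample_names(self, region: str | None = None, library: str | None = None,
                     day: object | None = None, genomic_only: bool = False) -> list[str]:
        s = self.samples
        keep = pd.Series(True, index=s.index)
        if region is not None:
            keep &= s["region_id"] == region
        if library is not None:
            keep &= s["library"] == library
        if day is not None:
            keep &= s["day"] == day
        if genomic_only:
            keep &= s["day"] != "plasmid"
        return list(s.index[keep])

    def regions(self) -> list[str]:
        return sorted(self.samples["region_id"].unique())

    def region_variants(self, region: str) -> list[str]:
        """Variant ids whose region membership includes ``region``."""
        in_region = self.variants["region_ids"].str.split(";").apply(lambda r: region in r)
        return list(self.variants.index[in_region])

    def experiments(self) -> list[tuple[str, str]]:
        """(region, library) pairs present among the samples."""
        pairs = self.samples[["region_id", "library"]].drop_duplicates()
        return sorted(map(tuple, pairs.itertuples(index=False)))

    def validate(self) -> None:
        c = self.counts
        if c.index.duplicated().any():
            dup = c.index[c.index.duplicated()][0]
            raise ScreenFormatError(f"duplicate variant row {dup!r}")
        if c.columns.duplicated().any():
            dup = c.columns[c.columns.duplicated()][0]
            raise ScreenFormatError(f"duplicate sample column {dup!r}")
        arr = c.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            raise ScreenFormatError("counts must be integers")
        if (arr < 0).any():
            vi, si = np.argwhere(arr < 0)[0]
            raise ScreenFormatError(f"negative count at row {c.index[vi]!r}, column {c.columns[si]!r}")
        key = self.samples[["region_id", "library", "replicate", "day"]]
        if key.duplicated().any():
            bad = self.samples.index[key.duplicated()][0]
            raise ScreenFormatError(f"duplicate sample key for column {bad!r}")
        for v in c.index:
            if special_role(v) is None and v not in self.variants.index:
                raise ScreenFormatError(f"variant row {v!r} has no annotation")
        validate_annotations(self.variants)


def validate_annotations(variants: pd.DataFrame) -> None:
    bad_cons = set(variants["consequence"]) - CONSEQUENCES
    if bad_cons:
        raise ScreenFormatError(f"unknown consequence categories: {sorted(bad_cons)}")
    expect_ctrl = variants["consequence"].isin(CONTROL_CONSEQUENCES)
    if (variants["is_control"].astype(bool) != expect_ctrl).any():
        bad = variants.index[variants["is_control"].astype(bool) != expect_ctrl][0]
        raise ScreenFormatError(
            f"variant {bad!r}: is_control must hold exactly for synonymous/intron variants"
        )
    if (variants["pos"] < 1).any():
        bad = variants.index[variants["pos"] < 1][0]
        raise ScreenFormatError(f"variant {bad!r}: pos must be 1-based (>= 1)")
    if (variants["region_ids"].astype(str).str.len() == 0).any():
        bad = variants.index[variants["region_ids"].astype(str).str.len() == 0][0]
        raise ScreenFormatError(f"variant {bad!r}: region_ids must be non-empty")


def load_count_table(path: str | Path, variant_annotations: str | Path) -> CountMatrix:
    """Read and validate a counts TSV plus its annotation TSV.

    The first counts column is ``variant_id``; every other header must be
    a well-formed sample name.  Round-trips losslessly with
    :func:`write_count_table`.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    names = header[1:]
    seen: set[str] = set()
    for n in names:
        if n in seen:
            raise ScreenFormatError(f"duplicate sample column {n!r}")
        seen.add(n)
    counts = pd.read_csv(path, sep="\t", index_col=0)
    try:
        counts = counts.astype(np.int64)
    except (ValueError, TypeError) as exc:
        raise ScreenFormatError(f"non-integer count in {path.name}: {exc}") from exc
    samples = pd.DataFrame([parse_sample_name(n) for n in counts.columns]).set_index("sample")
    variants = pd.read_csv(
        variant_annotations, sep="\t", index_col="variant_id",
        dtype={"chrom": str, "region_ids": str}, keep_default_na=False, na_values=[],
    )
    missing = [c for c in _ANNOTATION_COLS if c not in variants.columns]
    if missing:
        raise ScreenFormatError(f"annotation table missing columns: {missing}")
    variants["is_control"] = variants["is_control"].astype(str).str.lower().isin({"true", "1"})
    variants["in_ppe_codon"] = variants["in_ppe_codon"].astype(str).str.lower().isin({"true", "1"})
    variants["pos"] = variants["pos"].astype(int)
    cm = CountMatrix(counts=counts, variants=variants, samples=samples)
    cm.validate()
    return cm


def write_count_table(cm: CountMatrix, counts_path: str | Path, annotations_path: str | Path | None = None) -> None:
    cm.counts.to_csv(counts_path, sep="\t", index_label="variant_id")
    if annotations_path is not None:
        cm.variants.to_csv(annotations_path, sep="\t", index_label="variant_id")


# -- template counting ---------------------------------------------------

@dataclass
class TemplateLibrary:
    """Designed HDR template sequences for one target region."""

    entries: pd.DataFrame  # columns: sequence, role, variant_id, region_id

    def __post_init__(self):
        if self.entries["sequence"].duplicated().any():
            dup = self.entries["sequence"][self.entries["sequence"].duplicated()].iloc[0]
            raise ScreenFormatError(f"duplicate template sequence {dup[:30]!r}...")
        missing = self.entries.query("role == 'variant'")["variant_id"].isna()
        if missing.any():
            raise ScreenFormatError("role=variant template entries must carry a variant_id")


def load_template_library(path: str | Path, region_id: str = "") -> TemplateLibrary:
    """Load templates from TSV (sequence, role, variant_id, region_id) or FASTA."""
    from Bio import SeqIO

    path = Path(path)
    if path.suffix.lower() in {".fa", ".fasta", ".fna"}:
        rows = []
        for rec in SeqIO.parse(str(path), "fasta"):
            role = "variant"
            vid: object = rec.id
            if rec.id in {"ref_seq", "pam_seq"}:
                role, vid = rec.id, np.nan
            rows.append({"sequence": str(rec.seq).upper(), "role": role,
                         "variant_id": vid, "region_id": region_id})
        entries = pd.DataFrame(rows)
    else:
        entries = pd.read_csv(path, sep="\t")
    return TemplateLibrary(entries=entries)


def match_reads_to_templates(reads: list[str], library: TemplateLibrary) -> tuple[dict[str, int], int]:
    """Full-length exact-match counting of trimmed reads against templates.

    Returns ``(counts_by_sequence, unmapped_count)``.  Any read containing
    ``N`` or differing from every template at >= 1 position is unmapped;
    reads are conserved: sum(counts) + unmapped == len(reads).
    """
    lut = {s: 0 for s in library.entries["sequence"]}
    unmapped = 0
    for r in reads:
        r = r.upper()
        if "N" in r or r not in lut:
            unmapped += 1
        else:
            lut[r] += 1
    return lut, unmapped


# -- editing summary and low-count filter --------------------------------

def editing_summary(cm: CountMatrix) -> pd.DataFrame:
    """Per-sample unedited / PPE-only / variant-edited read fractions.

    The unedited fraction is ``ref_seq`` reads over all mapped reads of
    that sample's region; ``pam_seq`` gives the protection-edit-only
    fraction; everything else is variant-edited HDR product.
    """
    rows = []
    region_rows: dict[str, list[str]] = {}
    for sample, meta in cm.samples.iterrows():
        region = meta["region_id"]
        if region not in region_rows:
            vids = set(cm.region_variants(region))
            region_rows[region] = [
                v for v in cm.counts.index
                if v in vids or special_role(v) == ("ref_seq", region) or special_role(v) == ("pam_seq", region)
            ]
        col = cm.counts.loc[region_rows[region], sample]
        total = int(col.sum())
        if total == 0:
            raise ScreenFormatError(f"no mapped reads in sample {sample!r}")
        ref = int(col.get(f"ref_seq_{region}", 0))
        pam = int(col.get(f"pam_seq_{region}", 0))
        rows.append(
            {
                "sample": sample,
                "region_id": region,
                "library": meta["library"],
                "replicate": meta["replicate"],
                "day": meta["day"],
                "total_mapped": total,
                "unedited": ref / total,
                "ppe_only": pam / total,
                "variant_edited": (total - ref - pam) / total,
            }
        )
    return pd.DataFrame(rows).set_index("sample")


def filter_low_count_variants(cm: CountMatrix, min_total: int = 10) -> tuple[CountMatrix, list[tuple[str, str, str]]]:
    """Remove variants with fewer than ``min_total`` reads per experiment.

    The total is taken across all genomic timepoint replicates (days
    4-21, plasmid excluded) of one (region, library) experiment; removal
    masks that variant only in that experiment.  Variants removed from
    every experiment are dropped from the matrix.  Idempotent.
    """
    if min_total < 0:
        raise ValueError("min_total must be >= 0")
    mask = cm.mask.copy()
    removed: list[tuple[str, str, str]] = []
    for region, library in cm.experiments():
        samp = cm.sample_names(region=region, library=library, genomic_only=True)
        if not samp:
            continue
        vids = [v for v in cm.region_variants(region) if v in cm.counts.index]
        sub = cm.counts.loc[vids, samp]
        usable = cm.mask.loc[vids, samp]
        totals = sub.where(usable, 0).sum(axis=1)
        was_active = usable.any(axis=1)
        low = (totals < min_total) & was_active
        for v in sub.index[low]:
            mask.loc[v, samp] = False
            removed.append((v, region, library))
    keep_specials = [v for v in cm.counts.index if special_role(v) is not None]
    variant_alive = mask.loc[cm.variant_ids].any(axis=1)
    keep = [v for v in cm.variant_ids if variant_alive[v]] + keep_specials
    keep = [v for v in cm.counts.index if v in set(keep)]
    out = CountMatrix(
        counts=cm.counts.loc[keep],
        variants=cm.variants.loc[[v for v in keep if special_role(v) is None]],
        samples=cm.samples.copy(),
        mask=mask.loc[keep],
    )
    return out, removed
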