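"""Summary outputs: Venn partition of identifications, per-fraction
membrane-annotation tallies, fold-change summaries and functional-category
distributions.

The package also ships, as plain-text data, the published reference tables
of Arabidopsis membrane-associated proteins reported significantly under-
and over-represented under microgravity, with their printed linear
abundance ratios and functional-category headings; they serve as fixed
inputs for summary statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources

import numpy as np
import pandas as pd

VENN_REGIONS = (
    "ug_only", "ground_only", "iss_only",
    "ug_ground_only", "ug_iss_only", "ground_iss_only", "all_three",
)


def _round_half_up(x: float, decimals: int = 1) -> float:
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class VennPartition:
    counts: dict
    total: int
    percentages: dict

    def __getitem__(self, region: str) -> int:
        return self.counts[region]


def venn_partition(ug: set, ground: set, iss: set) -> VennPartition:
    """Exact 7-region partition of three identification sets.

    Percentages are of the union size, rounded half-up to one decimal.
    """
    ug, ground, iss = set(ug), set(ground), set(iss)
    counts = {
        "ug_only": len(ug - ground - iss),
        "ground_only": len(ground - ug - iss),
        "iss_only": len(iss - ug - ground),
        "ug_ground_only": len((ug & ground) - iss),
        "ug_iss_only": len((ug & iss) - ground),
        "ground_iss_only": len((ground & iss) - ug),
        "all_three": len(ug & ground & iss),
    }
    total = len(ug | ground | iss)
    if total:
        percentages = {k: _round_half_up(100.0 * v / total)
                       for k, v in counts.items()}
    else:
        percentages = {k: 0.0 for k in counts}
    return VennPartition(counts=counts, total=total, percentages=percentages)


def reference_identification_sets() -> tuple[set, set, set]:
    """Identification sets reproducing the published Venn region counts.

    The study reports 3861 proteins in total, 1687 identified in all three
    gravity conditions, 583 specific to microgravity, 321 specific to 1 g
    ground and 369 specific to 1 g on the ISS centrifuge. The three
    pairwise-only overlaps were not printed; the remaining 901 accessions
    are split 301/300/300 between them (synthetic, underdetermined) so the
    partition sums to the published union.
    """
    sizes = {
        "all_three": 1687, "ug_only": 583, "ground_only": 321,
        "iss_only": 369, "ug_ground_only": 301, "ug_iss_only": 300,
        "ground_iss_only": 300,
    }
    assert sum(sizes.values()) == 3861
    pools = {}
    start = 0
    for region, size in sizes.items():
        pools[region] = {f"ACC{j:05d}" for j in range(start, start + size)}
        start += size
    ug = (pools["ug_only"] | pools["ug_ground_only"] | pools["ug_iss_only"]
          | pools["all_three"])
    ground = (pools["ground_only"] | pools["ug_ground_only"]
              | pools["ground_iss_only"] | pools["all_three"])
    iss = (pools["iss_only"] | pools["ug_iss_only"]
           | pools["ground_iss_only"] | pools["all_three"])
    return ug, ground, iss


def fraction_annotation_tally(protein_fractions: pd.DataFrame,
                              annotations: pd.DataFrame) -> pd.DataFrame:
    """Per-fraction tallies for proteins specific to one extraction
    fraction (and, upstream, common to the gravity conditions).

    ``protein_fractions`` maps protein_accession -> extraction_fraction.
    Returns one row per fraction with total, with at least one
    transmembrane segment, GO-membrane, and unannotated counts; proteins
    missing from the annotation table are never silently dropped.
    """
    merged = protein_fractions.merge(
        annotations[["protein_accession", "n_tm_segments", "is_go_membrane"]],
        on="protein_accession", how="left")
    rows = []
    for fraction, grp in merged.groupby("extraction_fraction", sort=True):
        known = grp["n_tm_segments"].notna()
        rows.append({
            "extraction_fraction": fraction,
            "total": len(grp),
            "with_tm": int((grp["n_tm_segments"] >= 1).sum()),
            "go_membrane": int(grp["is_go_membrane"].eq(True).sum()),
            "unannotated": int((~known).sum()),
        })
    return pd.DataFrame(rows)


def proteins_unique_to_one_fraction(features: pd.DataFrame,
                                    min_conditions: int = 3) -> pd.DataFrame:
    """Proteins identified in exactly one extraction fraction and in all
    gravity conditions, from an identified feature table."""
    ident = features[features["identified"].astype(bool)]
    per_prot = ident.groupby("protein_accession").agg(
        n_fractions=("fraction", "nunique"),
        n_conditions=("condition", "nunique"),
        extraction_fraction=("fraction", "first"))
    keep = per_prot[(per_prot["n_fractions"] == 1)
                    & (per_prot["n_conditions"] >= min_conditions)]
    return keep.reset_index()[["protein_accession", "extraction_fraction"]]


def fold_change_summary(records: pd.DataFrame,
                        ratio_column: str = "ratio_ug_vs_1gspace",
                        call_column: str = "call") -> dict:
    """Mean fold change and share of fold changes above 2, per direction.

    Over-represented proteins: the linear ratio itself; under-represented:
    its reciprocal, so both directions are reported as fold changes >= 1.
    Directions with no protein are absent from the result, not zero.
    """
    out = {}
    for direction in ("over", "under"):
        sub = records[records[call_column] == direction]
        if sub.empty:
            continue
        fold = sub[ratio_column].astype(float)
        if direction == "under":
            fold = 1.0 / fold
        out[direction] = {
            "n": int(len(fold)),
            "mean_fold_change": float(fold.mean()),
            "share_above_2": float((fold > 2).mean()),
        }
    return out


def category_distribution(records: pd.DataFrame,
                          annotations: pd.DataFrame,
                          call_column: str = "call") -> pd.DataFrame:
    """Counts and percentages per functional category per direction.

    Proteins lacking a category fall into ``Unknown``. The wide pivot of
    this table (category x direction) is the side-by-side comparison of
    the two groups.
    """
    called = records[records[call_column].isin(["over", "under"])]
    merged = called.merge(
        annotations[["protein_accession", "functional_category"]],
        on="protein_accession", how="left")
    merged["functional_category"] = merged["functional_category"].fillna("Unknown")
    rows = []
    for direction, grp in merged.groupby(call_column):
        counts = grp["functional_category"].value_counts()
        for category, count in counts.sort_index().items():
            rows.append({
                "direction": direction,
                "functional_category": category,
                "count": int(count),
                "percent": _round_half_up(100.0 * count / len(grp)),
            })
    return pd.DataFrame(rows)


def load_reference_table(direction: str) -> pd.DataFrame:
    """Published reference ratio table ('over' or 'under' in microgravity).

    Columns: uniprot, agi_locus, functional_category, ratio (linear
    microgravity / 1 g abundance ratio).
    """
    names = {"under": "microgravity_under_represented.tsv",
             "over": "microgravity_over_represented.tsv"}
    if direction not in names:
        raise ValueError("direction must be 'over' or 'under'")
    with resources.files("gravlfq.data").joinpath(names[direction]).open() as fh:
        return pd.read_csv(fh, sep="\t")
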