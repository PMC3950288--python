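"""XIC-based label-free quantification across LC-MS runs.

The chain implemented here turns validated per-run peptide-ion tables into
a normalized protein x run abundance matrix:

1. the retention time of each identified ion is the MS survey-scan time of
   its most intense matched MS2 event;
2. ions identified in every run of a comparable group anchor a retention
   time matrix; predicted RTs in any run follow by piecewise-linear
   interpolation;
3. ions identified in only some runs are cross-assigned: their XIC area is
   looked up in the other runs at the predicted RT within a tolerance
   window (match-between-runs);
4. each run is rescaled by the median of area ratios against a reference
   run;
5. protein abundance per run is the sum of its quantified peptide-ion
   areas, reported only when at least two distinct peptide sequences were
   quantified.

Missing evidence stays missing: a cell is never zero-filled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

ION_KEY = ["peptide_sequence", "charge"]


class MissingIdentificationError(ValueError):
    """Signals an ion with no MS2 event: it must be cross-assigned."""


class AlignmentError(ValueError):
    pass


class NormalizationError(ValueError):
    pass


def select_ms2_event(events: Sequence[tuple[float, float]]) -> float:
    """Scan time of the MS2 event with the highest precursor intensity.

    Ties are broken toward the earliest scan time, deterministically.
    """
    if not len(events):
        raise MissingIdentificationError(
            "no MS2 event matched to this ion; route to cross-assignment")
    best_time, best_int = None, -np.inf
    for scan_time, intensity in events:
        if intensity > best_int or (intensity == best_int
                                    and scan_time < best_time):
            best_time, best_int = scan_time, intensity
    return best_time


def assign_rt_from_ms2(ms2_events: pd.DataFrame) -> pd.DataFrame:
    """Vectorized :func:`select_ms2_event` over an MS2 event table.

    Returns one row per (run_id, peptide_sequence, charge) with the
    retained ``rt_observed``.
    """
    df = ms2_events.sort_values(
        ["run_id", "peptide_sequence", "charge",
         "precursor_intensity", "scan_time"],
        ascending=[True, True, True, False, True], kind="stable")
    out = df.drop_duplicates(["run_id", "peptide_sequence", "charge"])
    return out.rename(columns={"scan_time": "rt_observed"})[
        ["run_id", "peptide_sequence", "charge", "rt_observed"]]


@dataclass
class RTAlignment:
    """Retention-time matrix between a reference run and the other runs.

    ``anchors[run]`` is a pair of arrays ``(rt_reference, rt_run)`` sorted
    by reference RT with duplicate reference values collapsed by averaging.
    """

    reference_run: str
    anchors: dict = field(default_factory=dict)

    def runs(self) -> list[str]:
        return list(self.anchors)


def _interp_extrap(x: np.ndarray, xp: np.ndarray, fp: np.ndarray) -> np.ndarray:
    """np.interp with linear extrapolation from the two edge anchors."""
    x = np.asarray(x, dtype=float)
    y = np.interp(x, xp, fp)
    if len(xp) >= 2:
        lo = x < xp[0]
        hi = x > xp[-1]
        if lo.any():
            s = (fp[1] - fp[0]) / (xp[1] - xp[0])
            y = np.where(lo, fp[0] + s * (x - xp[0]), y)
        if hi.any():
            s = (fp[-1] - fp[-2]) / (xp[-1] - xp[-2])
            y = np.where(hi, fp[-1] + s * (x - xp[-1]), y)
    return y


def choose_reference_run(features: pd.DataFrame) -> str:
    """Run with the most identified peptide ions (ties: smallest run_id)."""
    counts = (features[features["identified"]]
              .groupby("run_id").size().sort_index())
    if counts.empty:
        raise AlignmentError("no identified ions in any run")
    return counts.index[np.argmax(counts.values)]


def build_alignment(features: pd.DataFrame,
                    reference_run: str | None = None) -> RTAlignment:
    """Build the retention-time matrix for one group of comparable runs.

    Anchor ions are the peptide ions identified in every run of the group;
    their observed RTs in the reference run define the reference axis.
    """
    run_ids = sorted(features["run_id"].unique())
    if len(run_ids) < 2:
        raise AlignmentError("need at least two runs to align")
    ident = features[features["identified"]]
    per_run = ident.groupby(ION_KEY + ["run_id"])["rt_observed"].mean().unstack()
    per_run = per_run.reindex(columns=run_ids)
    common = per_run.dropna()
    if len(common) < 2:
        raise AlignmentError(
            "fewer than two peptide ions identified in all runs")
    if reference_run is None:
        reference_run = choose_reference_run(features)
    alignment = RTAlignment(reference_run=reference_run)
    ref_rt = common[reference_run].values
    for run in run_ids:
        pairs = pd.DataFrame({"ref": ref_rt, "run": common[run].values})
        pairs = pairs.groupby("ref", sort=True)["run"].mean().reset_index()
        alignment.anchors[run] = (pairs["ref"].values, pairs["run"].values)
    return alignment


def predict_rt(alignment: RTAlignment, run_id: str, rt_reference):
    """Predicted RT in ``run_id`` for reference-axis RTs, by piecewise
    linear interpolation (linear extrapolation outside the anchor range)."""
    if run_id not in alignment.anchors:
        raise AlignmentError(f"run {run_id!r} not in alignment")
    xp, fp = alignment.anchors[run_id]
    if len(xp) < 2:
        raise AlignmentError(f"run {run_id!r} has fewer than two anchors")
    out = _interp_extrap(rt_reference, xp, fp)
    return float(out) if np.isscalar(rt_reference) else out


def to_reference(alignment: RTAlignment, run_id: str, rt_run):
    """Inverse map: observed RT in ``run_id`` -> reference-axis RT."""
    xp, fp = alignment.anchors[run_id]
    order = np.argsort(fp, kind="stable")
    out = _interp_extrap(rt_run, fp[order], xp[order])
    return float(out) if np.isscalar(rt_run) else out


def cross_assign(ion: pd.Series, alignment: RTAlignment, target_run: str,
                 target_features: pd.DataFrame,
                 rt_tolerance: float = 1.0) -> pd.Series | None:
    """Transfer an XIC area to ``target_run`` for one unidentified ion.

    ``ion`` must carry ``peptide_sequence``, ``charge`` and ``rt_reference``
    (its RT on the reference axis). Returns the matched feature row with
    ``identified=False``, or ``None`` when no feature of the same
    (sequence, charge) lies within the RT window — the ion then stays
    unquantified in that run (missing, not zero).
    """
    predicted = predict_rt(alignment, target_run, ion["rt_reference"])
    cand = target_features[
        (target_features["run_id"] == target_run)
        & (target_features["peptide_sequence"] == ion["peptide_sequence"])
        & (target_features["charge"] == ion["charge"])]
    if cand.empty:
        return None
    dist = (cand["rt_observed"] - predicted).abs()
    if dist.min() > rt_tolerance:
        return None
    row = cand.loc[dist.idxmin()].copy()
    row["identified"] = False
    return row


def cross_assign_group(features: pd.DataFrame, alignment: RTAlignment,
                       rt_tolerance: float = 1.0
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cross-assign every ion of one comparable group of runs.

    Adds a boolean ``quantified`` column: identified ions are quantified
    as such, and unidentified feature rows whose ion was identified in at
    least one other run are quantified when their RT lies within
    ``rt_tolerance`` of the RT predicted from the alignment. Returns the
    annotated group and a log of cross-assignment attempts.
    """
    feats = features.copy()
    feats["quantified"] = feats["identified"].astype(bool)

    ident = feats[feats["identified"]]
    if ident.empty:
        return feats, pd.DataFrame(
            columns=ION_KEY + ["run_id", "predicted_rt", "matched"])
    # reference-axis RT per ion: median of inverse-mapped identified RTs
    parts = []
    for run, grp in ident.groupby("run_id"):
        ref = to_reference(alignment, run, grp["rt_observed"].values)
        parts.append(pd.DataFrame({
            "peptide_sequence": grp["peptide_sequence"].values,
            "charge": grp["charge"].values,
            "rt_reference": ref}))
    ion_ref = (pd.concat(parts).groupby(ION_KEY)["rt_reference"]
               .median().reset_index())

    unid = (feats[~feats["identified"]]
            .reset_index()  # keep original row ids through the merge
            .merge(ion_ref, on=ION_KEY, how="inner"))
    logs = []
    matched_rows: list = []
    for run, grp in unid.groupby("run_id"):
        xp, fp = alignment.anchors[run]
        predicted = _interp_extrap(grp["rt_reference"].values, xp, fp)
        ok = np.abs(grp["rt_observed"].values - predicted) <= rt_tolerance
        logs.append(pd.DataFrame({
            "peptide_sequence": grp["peptide_sequence"].values,
            "charge": grp["charge"].values,
            "run_id": run,
            "predicted_rt": predicted,
            "matched": ok}))
        matched_rows.extend(grp["index"].values[ok])
    if logs:
        log = pd.concat(logs, ignore_index=True)
    else:
        log = pd.DataFrame(
            columns=ION_KEY + ["run_id", "predicted_rt", "matched"])
    feats.loc[matched_rows, "quantified"] = True
    return feats, log


@dataclass
class RunNormalization:
    run_id: str
    factor: float
    reference_run: str


def normalize_runs(features: pd.DataFrame,
                   reference_run: str | None = None
                   ) -> tuple[list[RunNormalization], pd.DataFrame]:
    """Median-of-ratios normalization of one group of comparable runs.

    For each run the factor is the median over shared quantified ions of
    (reference area / run area); all of the run's areas are multiplied by
    it, so after normalization the median ratio against the reference is 1.
    """
    flag = "quantified" if "quantified" in features.columns else "identified"
    quant = features[features[flag].astype(bool)]
    if reference_run is None:
        reference_run = choose_reference_run(features)
    ref = quant[quant["run_id"] == reference_run].set_index(ION_KEY)["xic_area"]
    norms = []
    out = features.copy()
    for run in sorted(features["run_id"].unique()):
        if run == reference_run:
            norms.append(RunNormalization(run, 1.0, reference_run))
            continue
        cur = quant[quant["run_id"] == run].set_index(ION_KEY)["xic_area"]
        shared = ref.index.intersection(cur.index)
        if len(shared) == 0:
            raise NormalizationError(
                f"run {run!r} shares no quantified ion with the reference")
        ratios = (ref.loc[shared] / cur.loc[shared]).values
        factor = float(np.median(ratios))
        out.loc[out["run_id"] == run, "xic_area"] *= factor
        norms.append(RunNormalization(run, factor, reference_run))
    return norms, out


@dataclass
class QuantMatrix:
    """Protein x run abundance matrix with per-cell peptide counts.

    ``abundance`` columns are a MultiIndex (condition, sample, fraction);
    cells backed by fewer than ``min_peptides`` distinct quantified peptide
    sequences are NaN.
    """

    abundance: pd.DataFrame
    peptide_count: pd.DataFrame
    min_peptides: int = 2


def build_quant_matrix(features: pd.DataFrame,
                       min_peptides: int = 2) -> QuantMatrix:
    """Sum quantified peptide-ion areas into protein abundances per run.

    Peptide sequences shared between several proteins are excluded from
    every protein sum. Identified and cross-assigned ions contribute alike.
    """
    flag = "quantified" if "quantified" in features.columns else "identified"
    quant = features[features[flag].astype(bool)].copy()
    shared = (quant.groupby("peptide_sequence")["protein_accession"]
              .nunique())
    shared_seqs = set(shared[shared > 1].index)
    if shared_seqs:
        quant = quant[~quant["peptide_sequence"].isin(shared_seqs)]

    keys = ["protein_accession", "condition", "sample", "fraction"]
    agg = quant.groupby(keys).agg(
        abundance=("xic_area", "sum"),
        peptide_count=("peptide_sequence", "nunique"))
    agg = agg[agg["peptide_count"] >= min_peptides]
    abundance = agg["abundance"].unstack(["condition", "sample", "fraction"])
    counts = agg["peptide_count"].unstack(["condition", "sample", "fraction"])
    abundance = abundance.sort_index(axis=1)
    counts = counts.reindex(columns=abundance.columns)
    return QuantMatrix(abundance=abundance, peptide_count=counts,
                       min_peptides=min_peptides)
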