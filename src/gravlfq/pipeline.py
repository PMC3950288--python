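"""End-to-end orchestration: simulate -> validate -> quantify -> test -> report.

Every intermediate is persisted as a TSV with headers (floats at six
significant digits) plus a JSON manifest recording the configuration hash,
the seed and row counts for each stage, so identical configurations produce
identical output trees.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import differential, quantification, reporting, simulate, validation
from .config import CONDITIONS, PipelineConfig, SimConfig

FLOAT_FORMAT = "%.6g"


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


def write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)


def read_features(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t",
                       dtype={"identified": bool, "is_decoy": bool})


def read_psms(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"is_decoy": bool})


def quant_matrix_to_frame(matrix: quantification.QuantMatrix) -> pd.DataFrame:
    ab = matrix.abundance.copy()
    ab.columns = ["|".join(map(str, c)) for c in ab.columns]
    cnt = matrix.peptide_count.copy()
    cnt.columns = ["n_peptides|" + "|".join(map(str, c)) for c in cnt.columns]
    return pd.concat([ab, cnt], axis=1).reset_index()


def frame_to_quant_matrix(df: pd.DataFrame,
                          min_peptides: int = 2) -> quantification.QuantMatrix:
    df = df.set_index("protein_accession")
    ab_cols = [c for c in df.columns if not c.startswith("n_peptides|")]
    ab = df[ab_cols]
    ab.columns = pd.MultiIndex.from_tuples(
        [(c.split("|")[0], c.split("|")[1], int(c.split("|")[2]))
         for c in ab_cols],
        names=["condition", "sample", "fraction"])
    cnt_cols = [c for c in df.columns if c.startswith("n_peptides|")]
    cnt = df[cnt_cols]
    cnt.columns = ab.columns
    return quantification.QuantMatrix(abundance=ab, peptide_count=cnt,
                                      min_peptides=min_peptides)


def config_hash(config: PipelineConfig) -> str:
    d = config.to_dict()
    d.pop("out_dir", None)  # analysis identity excludes where results land
    payload = json.dumps(d, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def condition_identification_sets(validated_psms: pd.DataFrame,
                                  run_conditions: pd.DataFrame,
                                  min_peptides: int = 2) -> dict:
    """Per-condition sets of proteins identified from >= min_peptides
    distinct validated peptides within that condition's runs."""
    merged = validated_psms.merge(run_conditions, on="run_id", how="left")
    sets = {}
    for condition in CONDITIONS:
        sub = merged[(merged["condition"] == condition)
                     & ~merged["is_decoy"].astype(bool)]
        counts = sub.groupby("protein_accession")["peptide_sequence"].nunique()
        sets[condition] = set(counts[counts >= min_peptides].index)
    return sets


def quantify_features(features: pd.DataFrame,
                      rt_tolerance: float = 1.0,
                      min_peptides: int = 2):
    """Alignment, cross-assignment and normalization per fraction group,
    then protein summation over all runs."""
    groups = []
    norm_records = []
    for fraction, grp in features.groupby("fraction", sort=True):
        alignment = quantification.build_alignment(grp)
        grp, _log = quantification.cross_assign_group(
            grp, alignment, rt_tolerance=rt_tolerance)
        norms, grp = quantification.normalize_runs(
            grp, reference_run=alignment.reference_run)
        norm_records.extend(
            {"fraction": fraction, "run_id": n.run_id, "factor": n.factor,
             "reference_run": n.reference_run} for n in norms)
        groups.append(grp)
    combined = pd.concat(groups, ignore_index=True)
    matrix = quantification.build_quant_matrix(combined,
                                               min_peptides=min_peptides)
    return matrix, combined, pd.DataFrame(norm_records)


def run_all(config: PipelineConfig) -> dict:
    """Run the full analysis and write all output tables and the manifest.

    Returns a dictionary with every in-memory artifact (dataset, validated
    PSMs, quantification matrix, null fit, differential table, reports).
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": config_hash(config),
                      "seed": config.seed, "stages": {}}

    # --- stage: inputs ---------------------------------------------------
    try:
        if config.sim is not None:
            dataset = simulate.generate_dataset(config.sim)
            features, psms, truth = (dataset.features, dataset.psms,
                                     dataset.truth)
            annotations = simulate.generate_annotations(truth,
                                                        seed=config.sim.seed)
            write_tsv(truth, out_dir / "truth.tsv")
            write_tsv(annotations, out_dir / "annotations.tsv")
        else:
            in_dir = Path(config.input_dir)
            features = read_features(in_dir / "features.tsv")
            psms = read_psms(in_dir / "psms.tsv")
            truth = None
            ann_path = in_dir / "annotations.tsv"
            annotations = (pd.read_csv(ann_path, sep="\t")
                           if ann_path.exists() else None)
    except Exception as exc:  # noqa: BLE001 - annotate stage and re-raise
        raise PipelineStageError("input", exc) from exc
    manifest["stages"]["input"] = {"n_features": len(features),
                                   "n_psms": len(psms)}

    # --- stage: validation -----------------------------------------------
    try:
        summaries, validated = validation.validate_psms_per_run(
            psms, fdr_limit=config.fdr_limit,
            min_length=config.min_peptide_length)
        validated_proteins = validation.validate_proteins(
            validated, min_peptides=config.min_peptides)
        key = ["run_id", "peptide_sequence", "charge"]
        val_keys = set(map(tuple, validated.loc[
            ~validated["is_decoy"].astype(bool), key].itertuples(index=False)))
        feat_keys = list(map(tuple, features[key].itertuples(index=False)))
        features = features.copy()
        features["identified"] = (features["identified"].astype(bool)
                                  & pd.Series([k in val_keys for k in feat_keys],
                                              index=features.index))
        features = features[
            features["protein_accession"].isin(validated_proteins)]
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError("validation", exc) from exc
    write_tsv(validated, out_dir / "validated_psms.tsv")
    fdr_report = pd.DataFrame([
        {"run_id": run, "score_threshold": s.score_threshold,
         "n_target_validated": s.n_target_validated,
         "n_decoy_validated": s.n_decoy_validated,
         "fdr_percent": s.fdr_percent, "status": s.status}
        for run, s in sorted(summaries.items())])
    write_tsv(fdr_report, out_dir / "fdr_report.tsv")
    manifest["stages"]["validation"] = {
        "n_validated_psms": len(validated),
        "n_validated_proteins": len(validated_proteins)}

    # --- stage: quantification -------------------------------------------
    try:
        matrix, quantified_features, norms = quantify_features(
            features, rt_tolerance=config.rt_tolerance,
            min_peptides=config.min_peptides)
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError("quantification", exc) from exc
    write_tsv(quant_matrix_to_frame(matrix), out_dir / "quant_matrix.tsv")
    write_tsv(norms, out_dir / "normalization_factors.tsv")
    # downstream stages consume the serialized matrix, so re-running them
    # on the saved intermediate reproduces their outputs byte-for-byte
    matrix = frame_to_quant_matrix(
        pd.read_csv(out_dir / "quant_matrix.tsv", sep="\t"),
        min_peptides=config.min_peptides)
    manifest["stages"]["quantification"] = {
        "n_proteins_quantified": int(matrix.abundance.notna().any(axis=1).sum()),
        "n_runs": int(matrix.abundance.shape[1])}

    # --- stage: differential ---------------------------------------------
    try:
        ratios = differential.control_log_ratios(matrix)
        null = differential.fit_laplace(ratios)
        table = differential.differential_table(matrix, null=null,
                                                alpha=config.alpha)
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError("differential", exc) from exc
    write_tsv(table, out_dir / "differential.tsv")
    table = pd.read_csv(out_dir / "differential.tsv", sep="\t")
    null_report = pd.DataFrame([{
        "location": null.location, "scale": null.scale,
        "n_ratios": null.n_ratios,
        "qq_correlation_laplace": null.qq_correlation_laplace,
        "qq_correlation_normal": null.qq_correlation_normal}])
    write_tsv(null_report, out_dir / "laplace_null.tsv")
    calls = table["call"].value_counts().to_dict()
    manifest["stages"]["differential"] = {
        "n_testable": int((table["call"] != "untestable").sum()),
        "n_over": int(calls.get("over", 0)),
        "n_under": int(calls.get("under", 0)),
        "null_location": null.location, "null_scale": null.scale}

    # --- stage: reporting ------------------------------------------------
    try:
        run_conditions = features[["run_id", "condition"]].drop_duplicates()
        id_sets = condition_identification_sets(
            validated, run_conditions, min_peptides=config.min_peptides)
        venn = reporting.venn_partition(
            id_sets[CONDITIONS[0]], id_sets[CONDITIONS[2]],
            id_sets[CONDITIONS[1]])
        fc = reporting.fold_change_summary(table)
        reports = {"venn": venn, "fold_change": fc}
        venn_df = pd.DataFrame(
            [{"region": k, "count": venn.counts[k],
              "percent": venn.percentages[k]} for k in reporting.VENN_REGIONS])
        write_tsv(venn_df, out_dir / "venn.tsv")
        if annotations is not None:
            cat = reporting.category_distribution(table, annotations)
            write_tsv(cat, out_dir / "category_distribution.tsv")
            uniq = reporting.proteins_unique_to_one_fraction(features)
            tally = reporting.fraction_annotation_tally(uniq, annotations)
            write_tsv(tally, out_dir / "fraction_tally.tsv")
            reports["category_distribution"] = cat
            reports["fraction_tally"] = tally
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError("reporting", exc) from exc
    manifest["stages"]["reporting"] = {
        "venn_total": venn.total,
        "fold_change": fc}

    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return {"features": features, "psms": psms, "truth": truth,
            "validated": validated, "summaries": summaries,
            "matrix": matrix, "normalization": norms, "null": null,
            "differential": table, "reports": reports,
            "manifest": manifest, "id_sets": id_sets}
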