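"""Target-decoy validation of peptide-spectrum matches.

PSMs searched against a concatenated target + reversed-sequence (decoy)
database are validated by sweeping a score threshold and estimating the
false discovery rate as

    FDR = 100 * D / (T + D)

where ``T`` and ``D`` count validated target and decoy hits above the
threshold. The operating point retained is the one validating the most
target PSMs while keeping the FDR strictly below the requested limit
(default 1.3 %), after removing peptides shorter than the minimum length
(default 8 residues). Decoy and target hits are validated by the same
criteria throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class UndefinedFDRError(ValueError):
    """FDR is undefined when no PSM is validated at all."""


@dataclass
class ValidationSummary:
    score_threshold: float
    n_target_validated: int
    n_decoy_validated: int
    fdr_percent: float
    validated_proteins: set
    validated: pd.DataFrame = field(repr=False, default=None)
    status: str = "ok"


def compute_fdr(n_target: int, n_decoy: int) -> float:
    """Percentage FDR from validated target and decoy counts."""
    if n_target < 0 or n_decoy < 0:
        raise ValueError("counts must be non-negative")
    if n_target + n_decoy == 0:
        raise UndefinedFDRError("FDR undefined: no validated hits")
    return 100.0 * n_decoy / (n_target + n_decoy)


def _ensure_length(psms: pd.DataFrame) -> pd.DataFrame:
    if "length" not in psms.columns:
        psms = psms.assign(length=psms["peptide_sequence"].str.len())
    return psms


def validate_psms(psms: pd.DataFrame, fdr_limit: float = 1.3,
                  min_length: int = 8) -> ValidationSummary:
    """Choose a score threshold by target-decoy sweep on one PSM table.

    Candidate thresholds are the distinct observed scores in descending
    order; PSMs with score >= threshold are validated. Among thresholds
    whose FDR is strictly below ``fdr_limit`` the one validating the most
    targets is selected (ties resolved toward the higher threshold, which
    admits fewer decoys). If no threshold satisfies the limit an empty
    summary with ``status='no_feasible_threshold'`` is returned and a
    warning is emitted.
    """
    if psms.empty:
        raise ValueError("PSM table is empty")
    if not (0 < fdr_limit <= 100):
        raise ValueError("fdr_limit must lie in (0, 100]")
    if min_length < 1:
        raise ValueError("min_length must be >= 1")

    psms = _ensure_length(psms)
    kept = psms[psms["length"] >= min_length]
    if kept.empty:
        warnings.warn("all PSMs shorter than the minimum peptide length")
        return ValidationSummary(np.inf, 0, 0, 0.0, set(),
                                 kept, "no_feasible_threshold")

    order = np.argsort(-kept["score"].values, kind="stable")
    scores = kept["score"].values[order]
    is_decoy = kept["is_decoy"].values[order].astype(bool)
    cum_decoy = np.cumsum(is_decoy)
    cum_target = np.cumsum(~is_decoy)
    # last index of each distinct score block = counts at threshold=score
    boundary = np.nonzero(np.diff(scores, append=-np.inf) != 0)[0]
    thr = scores[boundary]
    t_at = cum_target[boundary]
    d_at = cum_decoy[boundary]
    fdr_at = 100.0 * d_at / (t_at + d_at)

    feasible = np.nonzero(fdr_at < fdr_limit)[0]
    if len(feasible) == 0:
        warnings.warn(
            f"no score threshold reaches FDR < {fdr_limit}%; "
            "returning empty validation")
        return ValidationSummary(np.inf, 0, 0, 0.0, set(),
                                 kept.iloc[0:0], "no_feasible_threshold")
    best = feasible[np.argmax(t_at[feasible])]
    threshold = thr[best]
    validated = kept[kept["score"] >= threshold]
    n_t = int(t_at[best])
    n_d = int(d_at[best])
    proteins = set(validated.loc[~validated["is_decoy"].astype(bool),
                                 "protein_accession"])
    return ValidationSummary(float(threshold), n_t, n_d,
                             compute_fdr(n_t, n_d), proteins, validated)


def validate_psms_per_run(psms: pd.DataFrame, fdr_limit: float = 1.3,
                          min_length: int = 8) -> tuple[dict, pd.DataFrame]:
    """Apply :func:`validate_psms` independently to each run's table.

    Mirrors FDR control per analyzed sample; returns the per-run summaries
    and the concatenated validated PSM rows.
    """
    summaries: dict[str, ValidationSummary] = {}
    frames = []
    for run_id, grp in psms.groupby("run_id", sort=True):
        s = validate_psms(grp, fdr_limit=fdr_limit, min_length=min_length)
        summaries[run_id] = s
        if s.validated is not None and len(s.validated):
            frames.append(s.validated)
    validated = (pd.concat(frames, ignore_index=True) if frames
                 else psms.iloc[0:0])
    return summaries, validated


def validate_proteins(validated_psms: pd.DataFrame,
                      min_peptides: int = 2) -> set:
    """Accessions of non-decoy proteins with >= ``min_peptides`` distinct
    validated peptide sequences (charge states collapse)."""
    if min_peptides < 1:
        raise ValueError("min_peptides must be >= 1")
    if validated_psms.empty:
        return set()
    targets = validated_psms[~validated_psms["is_decoy"].astype(bool)]
    counts = targets.groupby("protein_accession")["peptide_sequence"].nunique()
    return set(counts[counts >= min_peptides].index)
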