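"""Configuration objects for simulation and the end-to-end pipeline.

The experimental design mirrors a spaceflight membrane-proteomics layout:
one microgravity sample, three 1 g on-board control samples (grown on a
centrifuge in orbit) and one 1 g ground sample, each processed through five
sequential extraction fractions, so each sample contributes five LC-MS runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Tuple

#: Condition labels, fixed by the experimental design.
UG_SPACE = "ug_space"
ONEG_SPACE = "onep_g_space"
ONEG_GROUND = "onep_g_ground"
CONDITIONS = (UG_SPACE, ONEG_SPACE, ONEG_GROUND)

#: Sample layout: (sample_id, condition). The three onep_g_space samples are
#: the technical controls from which the noise null is estimated.
SAMPLES = (
    ("ug_s1", UG_SPACE),
    ("ctrl_s1", ONEG_SPACE),
    ("ctrl_s2", ONEG_SPACE),
    ("ctrl_s3", ONEG_SPACE),
    ("ground_s1", ONEG_GROUND),
)

CONTROL_SAMPLES = ("ctrl_s1", "ctrl_s2", "ctrl_s3")


class ConfigError(ValueError):
    """Raised when a configuration field violates its constraints."""


@dataclass
class SimConfig:
    """Parameters of the synthetic peptide-level LC-MS dataset.

    All abundances live on the natural-log scale; ``laplace_scale_b`` is the
    scale of the additive Laplace technical noise applied to each protein in
    each run. Spiked proteins carry a condition effect of
    ``ln(fold_change_over)`` (or ``ln(fold_change_under)``) in the
    microgravity condition only, identically across fractions.
    """

    seed: int = 0
    n_proteins: int = 1500
    frac_over: float = 80 / 1484
    frac_under: float = 69 / 1484
    fold_change_over: float = 2.3
    fold_change_under: float = 1 / 2.1
    laplace_scale_b: float = 0.06
    baseline_mean: float = 10.0
    baseline_sd: float = 1.5
    peptides_per_protein_min: int = 2
    peptides_per_protein_lambda: float = 3.0
    p_missing_id: float = 0.15
    rt_range: Tuple[float, float] = (5.0, 115.0)
    rt_drift_slope: float = 0.05
    rt_drift_intercept: float = 2.0
    rt_jitter_sd: float = 0.1
    decoy_fraction: float = 0.05
    n_fractions: int = 5

    def validate(self) -> None:
        if self.n_proteins < 1:
            raise ConfigError("n_proteins must be >= 1")
        if not (0 <= self.frac_over <= 1 and 0 <= self.frac_under <= 1):
            raise ConfigError("frac_over and frac_under must lie in [0, 1]")
        if self.frac_over + self.frac_under > 1:
            raise ConfigError("frac_over + frac_under must not exceed 1")
        if self.fold_change_over <= 1:
            raise ConfigError("fold_change_over must be > 1")
        if not (0 < self.fold_change_under < 1):
            raise ConfigError("fold_change_under must lie in (0, 1)")
        if self.laplace_scale_b <= 0:
            raise ConfigError("laplace_scale_b must be > 0")
        if self.baseline_sd < 0:
            raise ConfigError("baseline_sd must be >= 0")
        if self.peptides_per_protein_min < 2:
            raise ConfigError("peptides_per_protein_min must be >= 2")
        if self.peptides_per_protein_lambda < 0:
            raise ConfigError("peptides_per_protein_lambda must be >= 0")
        if not (0 <= self.p_missing_id < 1):
            raise ConfigError("p_missing_id must lie in [0, 1)")
        if self.rt_range[0] >= self.rt_range[1]:
            raise ConfigError("rt_range must satisfy low < high")
        if self.rt_jitter_sd < 0:
            raise ConfigError("rt_jitter_sd must be >= 0")
        if not (0 <= self.decoy_fraction < 1):
            raise ConfigError("decoy_fraction must lie in [0, 1)")
        if self.n_fractions < 1:
            raise ConfigError("n_fractions must be >= 1")


@dataclass
class PipelineConfig:
    """End-to-end pipeline configuration.

    Defaults follow the validated workflow thresholds: PSM-level FDR below
    1.3 %, minimum peptide length 8 residues, proteins reported from at
    least two distinct peptides, BH-adjusted significance level 0.05, and a
    +/- 1 minute retention-time window for cross-assignment.
    """

    seed: int = 0
    sim: Optional[SimConfig] = None
    input_dir: Optional[str] = None
    out_dir: str = "gravlfq_out"
    fdr_limit: float = 1.3
    min_peptide_length: int = 8
    min_peptides: int = 2
    alpha: float = 0.05
    rt_tolerance: float = 1.0

    def validate(self) -> None:
        if self.sim is None and self.input_dir is None:
            raise ConfigError(
                "either simulation (sim) or an input_dir with feature/PSM "
                "tables must be provided"
            )
        if not (0 < self.fdr_limit <= 100):
            raise ConfigError("fdr_limit must lie in (0, 100]")
        if self.min_peptide_length < 1:
            raise ConfigError("min_peptide_length must be >= 1")
        if self.min_peptides < 1:
            raise ConfigError("min_peptides must be >= 1")
        if not (0 < self.alpha < 1):
            raise ConfigError("alpha must lie in (0, 1)")
        if self.rt_tolerance <= 0:
            raise ConfigError("rt_tolerance must be > 0")
        if self.sim is not None:
            self.sim.validate()

    def to_dict(self) -> dict:
        d = asdict(self)
        return d
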