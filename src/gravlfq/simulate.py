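"""Synthetic peptide-level LC-MS feature and PSM tables with known truth.

The generator emulates the statistical structure the downstream analysis
assumes: protein log-abundance in each run is a protein baseline plus a
condition effect (non-zero only for spiked proteins in microgravity) plus
Laplace technical noise; peptide XIC areas are the protein's linear
abundance scaled by a peptide-specific ionization factor; retention times
drift affinely between runs; identifications are dropped at random to
exercise cross-assignment; decoy PSMs with stochastically lower scores
exercise target-decoy validation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import CONDITIONS, SAMPLES, ConfigError, SimConfig

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

FEATURE_COLUMNS = [
    "run_id", "condition", "sample", "fraction", "protein_accession",
    "peptide_sequence", "charge", "mz", "rt_observed", "xic_area",
    "identified", "is_decoy", "score",
]

PSM_COLUMNS = [
    "peptide_sequence", "length", "charge", "score", "is_decoy",
    "protein_accession", "run_id",
]

#: Functional categories used for synthetic annotation tables; the list is
#: the union of the category headings of the published over/under tables.
FUNCTIONAL_CATEGORIES = (
    "Signalling", "Miscellaneous", "Lipid metabolism", "Chloroplast",
    "Proteases", "Unknown", "Respiratory chain", "Nucleosome",
    "Cell wall metabolism", "Glycolysis", "Transport", "Cytoskeleton",
    "Oxidoreductases", "Membrane trafficking", "Stress Defence",
    "Amino-acid synthesis", "Tricarboxylic cycle", "Hormone biosynthesis",
    "Protein synthesis", "Transcription", "Oxydoreduction",
)


@dataclass
class Dataset:
    """Bundle returned by :func:`generate_dataset`."""

    features: pd.DataFrame
    psms: pd.DataFrame
    truth: pd.DataFrame
    ms2_events: pd.DataFrame

    def runs(self) -> list[str]:
        return sorted(self.features["run_id"].unique())


def _random_sequences(rng: np.random.Generator, lengths: np.ndarray) -> np.ndarray:
    """Random tryptic-looking peptide sequences, unique by construction."""
    seqs = np.empty(len(lengths), dtype=object)
    seen: set[str] = set()
    for i, ln in enumerate(lengths):
        while True:
            s = "".join(rng.choice(AMINO_ACIDS, size=int(ln) - 1)) + "K"
            if s not in seen:
                seen.add(s)
                seqs[i] = s
                break
    return seqs


def _peptide_mz(lengths: np.ndarray, charges: np.ndarray) -> np.ndarray:
    # crude average-residue mass model; m/z realism is not load-bearing
    mass = 111.1 * lengths + 18.011
    return (mass + charges * 1.00728) / charges


def generate_dataset(config: SimConfig) -> Dataset:
    """Generate per-run peptide-ion feature tables, a PSM table and truth.

    Returns a :class:`Dataset` whose ``features`` frame holds one row per
    peptide ion per run of a fraction where the parent protein is present.
    ``identified`` marks ions with an MS2 identification in that run; the
    XIC area is present for every row (the signal exists in the raw file
    whether or not it was sequenced), which is what makes cross-assignment
    recovery measurable against the truth table.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    (rng_prot, rng_pep, rng_noise, rng_rt, rng_miss,
     rng_ms2, rng_decoy) = [np.random.default_rng(s) for s in ss.spawn(7)]

    n = config.n_proteins
    accessions = np.array([f"P{i:05d}" for i in range(n)])

    # --- truth: spike-in classes and fraction profiles -------------------
    n_over = int(round(config.frac_over * n))
    n_under = int(round(config.frac_under * n))
    classes = np.array(["null"] * n, dtype=object)
    order = rng_prot.permutation(n)
    classes[order[:n_over]] = "over"
    classes[order[n_over:n_over + n_under]] = "under"
    lfc = np.zeros(n)
    lfc[classes == "over"] = np.log(config.fold_change_over)
    lfc[classes == "under"] = np.log(config.fold_change_under)

    nf = config.n_fractions
    if nf >= 5:
        k_probs = np.array([0.35, 0.25, 0.2, 0.1, 0.1] + [0.0] * (nf - 5))
    else:
        k_probs = np.ones(nf)
    k_probs = k_probs / k_probs.sum()
    n_frac_present = rng_prot.choice(np.arange(1, nf + 1), size=n, p=k_probs)
    fraction_profile = [
        np.sort(rng_prot.choice(np.arange(1, nf + 1), size=k, replace=False))
        for k in n_frac_present
    ]

    baseline = rng_prot.normal(config.baseline_mean, config.baseline_sd, size=n)

    truth = pd.DataFrame({
        "protein_accession": accessions,
        "true_log_fold_change": lfc,
        "class": classes,
        "fraction_profile": [",".join(map(str, fp)) for fp in fraction_profile],
        "baseline_log_abundance": baseline,
    })

    # --- peptides --------------------------------------------------------
    n_pep = config.peptides_per_protein_min + rng_pep.poisson(
        config.peptides_per_protein_lambda, size=n)
    pep_protein_idx = np.repeat(np.arange(n), n_pep)
    total_pep = int(n_pep.sum())
    lengths = rng_pep.integers(8, 25, size=total_pep)
    sequences = _random_sequences(rng_pep, lengths)
    charges = rng_pep.choice([2, 3], size=total_pep, p=[0.7, 0.3])
    mz = _peptide_mz(lengths.astype(float), charges.astype(float))
    ion_factor = np.exp(rng_pep.normal(0.0, 0.5, size=total_pep))
    rt_reference = rng_pep.uniform(*config.rt_range, size=total_pep)

    peptides = pd.DataFrame({
        "protein_idx": pep_protein_idx,
        "protein_accession": accessions[pep_protein_idx],
        "peptide_sequence": sequences,
        "charge": charges,
        "mz": mz,
        "length": lengths,
        "ion_factor": ion_factor,
        "rt_reference": rt_reference,
    })

    # --- runs: 5 samples x n_fractions, with per-run affine RT drift -----
    runs = []
    for sample, condition in SAMPLES:
        for f in range(1, nf + 1):
            runs.append((f"{sample}_f{f}", condition, sample, f))
    run_df = pd.DataFrame(runs, columns=["run_id", "condition", "sample", "fraction"])
    n_runs = len(run_df)
    run_slope = 1.0 + config.rt_drift_slope * rng_rt.uniform(-1, 1, size=n_runs)
    run_intercept = config.rt_drift_intercept * rng_rt.uniform(-1, 1, size=n_runs)
    run_df["rt_slope"] = run_slope
    run_df["rt_intercept"] = run_intercept

    # protein x run log-abundance: baseline + effect (ug only) + Laplace
    effect = np.where(run_df["condition"].values[None, :] == CONDITIONS[0],
                      lfc[:, None], 0.0)
    noise = rng_noise.laplace(0.0, config.laplace_scale_b, size=(n, n_runs))
    log_abund = baseline[:, None] + effect + noise

    # presence mask: protein present only in its profile fractions
    present = np.zeros((n, n_runs), dtype=bool)
    frac_by_run = run_df["fraction"].values
    for i, fp in enumerate(fraction_profile):
        present[i] = np.isin(frac_by_run, fp)

    # --- expand to feature rows -----------------------------------------
    prot_idx_grid, run_idx_grid = np.nonzero(present[pep_protein_idx])
    pep_idx = prot_idx_grid  # row index into peptides
    run_idx = run_idx_grid

    feat = pd.DataFrame({
        "run_id": run_df["run_id"].values[run_idx],
        "condition": run_df["condition"].values[run_idx],
        "sample": run_df["sample"].values[run_idx],
        "fraction": frac_by_run[run_idx],
        "protein_accession": peptides["protein_accession"].values[pep_idx],
        "peptide_sequence": peptides["peptide_sequence"].values[pep_idx],
        "charge": peptides["charge"].values[pep_idx],
        "mz": peptides["mz"].values[pep_idx],
    })
    log_a = log_abund[peptides["protein_idx"].values[pep_idx], run_idx]
    feat["xic_area"] = np.exp(log_a) * peptides["ion_factor"].values[pep_idx]

    rt_ref_rows = peptides["rt_reference"].values[pep_idx]
    jitter = (rng_rt.normal(0.0, config.rt_jitter_sd, size=len(feat))
              if config.rt_jitter_sd > 0 else 0.0)
    feat["rt_observed"] = (run_slope[run_idx] * rt_ref_rows
                           + run_intercept[run_idx] + jitter)

    # --- identification missingness --------------------------------------
    identified = rng_miss.random(len(feat)) >= config.p_missing_id
    # never let an ion go fully unidentified within a comparable fraction
    # group (the 5 sample-runs of one fraction): rescue the first row
    grp = pd.Series(
        feat["peptide_sequence"].astype(str) + "/" + feat["charge"].astype(str)
        + "/f" + feat["fraction"].astype(str))
    rescue = (~pd.Series(identified).groupby(grp.values).transform("any")).values
    first_of_group = ~grp.duplicated().values
    identified = identified | (rescue & first_of_group)
    feat["identified"] = identified
    feat["is_decoy"] = False

    # --- MS2 events and observed RT for identified ions ------------------
    id_rows = np.nonzero(identified)[0]
    n_id = len(id_rows)
    best_int = rng_ms2.lognormal(6.0, 1.0, size=n_id)
    other_int = best_int * rng_ms2.uniform(0.05, 0.95, size=n_id)
    dt = rng_ms2.uniform(-0.4, 0.4, size=n_id)
    rt_best = feat["rt_observed"].values[id_rows]
    ms2_events = pd.DataFrame({
        "run_id": np.repeat(feat["run_id"].values[id_rows], 2),
        "peptide_sequence": np.repeat(feat["peptide_sequence"].values[id_rows], 2),
        "charge": np.repeat(feat["charge"].values[id_rows], 2),
        "scan_time": np.column_stack([rt_best, rt_best + dt]).ravel(),
        "precursor_intensity": np.column_stack([best_int, other_int]).ravel(),
    })

    # --- PSM table: one target PSM per identified feature row + decoys ---
    target_scores = np.clip(rng_decoy.normal(45.0, 10.0, size=n_id), 5.0, None)
    psms = pd.DataFrame({
        "peptide_sequence": feat["peptide_sequence"].values[id_rows],
        "length": peptides["length"].values[pep_idx[id_rows]],
        "charge": feat["charge"].values[id_rows],
        "score": target_scores,
        "is_decoy": False,
        "protein_accession": feat["protein_accession"].values[id_rows],
        "run_id": feat["run_id"].values[id_rows],
    })
    feat["score"] = np.nan
    feat.loc[feat.index[id_rows], "score"] = target_scores

    decoys = generate_decoy_psms(config, n_target=n_id, rng=rng_decoy,
                                 run_ids=run_df["run_id"].values)
    if len(decoys):
        psms = pd.concat([psms, decoys], ignore_index=True)

    feat = feat[FEATURE_COLUMNS]
    return Dataset(features=feat, psms=psms[PSM_COLUMNS], truth=truth,
                   ms2_events=ms2_events)


def generate_decoy_psms(config: SimConfig, n_target: int,
                        rng: np.random.Generator | None = None,
                        run_ids: np.ndarray | None = None) -> pd.DataFrame:
    """Decoy PSM rows emulating a search against reversed sequences.

    The decoy count is chosen so decoys make up ``decoy_fraction`` of the
    combined table; decoy scores are drawn from a distribution
    stochastically lower than the target score distribution, and decoy
    peptide lengths include values below 8 residues so the length filter is
    exercised.
    """
    if not (0 <= config.decoy_fraction < 1):
        raise ConfigError("decoy_fraction must lie in [0, 1)")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(7)[6])
    if run_ids is None:
        run_ids = np.array([f"{s}_f{f}" for s, _ in SAMPLES
                            for f in range(1, config.n_fractions + 1)])
    f = config.decoy_fraction
    n_decoy = int(round(f * n_target / (1.0 - f)))
    if n_decoy == 0:
        return pd.DataFrame(columns=PSM_COLUMNS)
    lengths = rng.integers(6, 21, size=n_decoy)
    seqs = _random_sequences(rng, lengths)
    return pd.DataFrame({
        "peptide_sequence": seqs,
        "length": lengths,
        "charge": rng.choice([2, 3], size=n_decoy),
        "score": np.clip(rng.normal(25.0, 8.0, size=n_decoy), 5.0, None),
        "is_decoy": True,
        "protein_accession": np.array(
            [f"DECOY_P{i:05d}" for i in rng.integers(0, config.n_proteins,
                                                     size=n_decoy)]),
        "run_id": rng.choice(run_ids, size=n_decoy),
    })[PSM_COLUMNS]


def generate_annotations(truth: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Synthetic protein annotation table (category, membrane flags).

    Rates follow the composition of a microsome-enriched proteome: roughly
    a third of proteins carry the GO "membrane" annotation and somewhat
    over half have at least one predicted transmembrane segment.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA2]))
    acc = truth["protein_accession"].values
    n = len(acc)
    has_tm = rng.random(n) < 0.566
    n_tm = np.where(has_tm, 1 + rng.poisson(1.5, size=n), 0)
    return pd.DataFrame({
        "protein_accession": acc,
        "agi_locus": [f"AT{rng.integers(1, 6)}G{rng.integers(0, 80000):05d}"
                      for _ in range(n)],
        "functional_category": rng.choice(FUNCTIONAL_CATEGORIES, size=n),
        "is_go_membrane": rng.random(n) < 0.33,
        "n_tm_segments": n_tm,
    })


def difference_of_laplace_mad(b: float) -> float:
    """E|X - Y| for independent X, Y ~ Laplace(0, b) (equals 1.5 b)."""
    return 1.5 * b


def effective_pairwise_scale(b: float, n_fractions,
                             n_mc: int = 200_000, seed: int = 0) -> float:
    """Laplace MLE scale of control-pair log-ratios, by Monte Carlo.

    A control-pair log-ratio is the difference of two sample means, each
    averaging Laplace(0, b) noise over the fractions where the protein is
    present. ``n_fractions`` is either a single count or an array of
    per-protein counts (e.g. from a truth table's fraction profiles), in
    which case the pooled mixture is simulated.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xD1]))
    ks = np.atleast_1d(np.asarray(n_fractions, dtype=int))
    draws = []
    uniq, freq = np.unique(ks, return_counts=True)
    for k, w in zip(uniq, freq):
        m = max(1, int(round(n_mc * w / freq.sum())))
        d = (rng.laplace(0, b, size=(m, k)).mean(axis=1)
             - rng.laplace(0, b, size=(m, k)).mean(axis=1))
        draws.append(d)
    d = np.concatenate(draws)
    return float(np.mean(np.abs(d - np.median(d))))
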