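"""Synthetic matched-trio RNA-seq counts and linked clinical tables.

The generator emulates the study design the screen was built for: eight
patients, each contributing adjacent non-tumor (N), primary tumor (T) and
metastatic lymph-node (LN) bulk RNA-seq samples.  Counts are negative
binomial around gene-level log-normal baseline means, with a per-patient
per-gene random effect (shared by the three sites of a trio, inducing the
matched-design correlation) and a per-sample library-size factor.

A configurable number of genes is "spiked": in each effect-active case
(active with probability ``recurrence_prob``), a spiked-up gene's LN mean
is ``up_fold_ln`` x its N mean and its T mean is ``up_fold_t`` x its N mean
(defaults 4 and 2, so the generating signal sits exactly at the screen's
up rule: LN/T = 2, LN/N = 4, T > N); a spiked-down gene's LN and T means
are ``down_fold_ln_vs_n`` and ``down_fold_t_vs_n`` times its N mean
(defaults 0.25 and 0.7).  The truth labels and per-case active flags are
returned so downstream selection can be benchmarked against ground truth.

A second generator produces clinical tables with the same cohort structure
as the study's validation data: tissue-microarray IHC scores (LN-metastasis
cores stochastically shifted up versus primary-tumor cores), exponential
survival with a group hazard ratio, and positive/examined lymph-node
counts with configurable group fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io_model import (
    ExpressionMatrix,
    IHCRecord,
    LNCountRecord,
    SurvivalRecord,
    ValidationError,
)

LABEL_UP = "up_spiked"
LABEL_DOWN = "down_spiked"
LABEL_NULL = "null"


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the matched-trio count simulation.

    Defaults reproduce the study conditions: 8 cases, 10,000 genes, 100
    spiked-up and 100 spiked-down genes each expressing their effect in a
    given case with probability 0.75 (so true hits typically recur in 4-6
    of 8 cases), fold effects at the screen's thresholds, and negative-
    binomial dispersion 0.2 (typical bulk tissue variability).
    """

    n_cases: int = 8
    n_genes: int = 10_000
    n_up_spiked: int = 100
    n_down_spiked: int = 100
    recurrence_prob: float = 0.75
    up_fold_ln: float = 4.0
    up_fold_t: float = 2.0
    down_fold_ln_vs_n: float = 0.25
    down_fold_t_vs_n: float = 0.7
    nb_dispersion: float = 0.2
    libsize_range: tuple[float, float] = (0.5, 2.0)
    base_mean_log_mean: float = 3.0
    base_mean_log_sd: float = 1.5
    min_spiked_base_mean: float = 10.0
    patient_effect_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_genes < 1:
            raise ValidationError("n_cases and n_genes must be positive")
        if self.n_up_spiked + self.n_down_spiked > self.n_genes:
            raise ValidationError("spiked genes cannot exceed n_genes")
        if not 0 <= self.recurrence_prob <= 1:
            raise ValidationError("recurrence_prob must lie in [0, 1]")
        for fold in (
            self.up_fold_ln,
            self.up_fold_t,
            self.down_fold_ln_vs_n,
            self.down_fold_t_vs_n,
        ):
            if fold <= 0:
                raise ValidationError("fold effects must be positive")
        if self.nb_dispersion < 0:
            raise ValidationError("nb_dispersion must be non-negative")
        lo, hi = self.libsize_range
        if not (0 < lo <= hi):
            raise ValidationError("libsize_range must satisfy 0 < lo <= hi")
        if self.patient_effect_sd < 0 or self.base_mean_log_sd < 0:
            raise ValidationError("scale parameters must be non-negative")


@dataclass
class SimulationTruth:
    """Ground truth of a simulation run.

    ``labels`` maps every gene to up_spiked / down_spiked / null;
    ``active`` is a spiked-gene x case boolean frame of effect-active flags.
    """

    labels: pd.Series
    active: pd.DataFrame

    def genes_with_label(self, label: str) -> list[str]:
        return list(self.labels.index[self.labels == label])

    def to_frame(self) -> pd.DataFrame:
        out = self.labels.rename("label").to_frame()
        out.index.name = "gene_id"
        return out


def _case_ids(n_cases: int) -> list[str]:
    return [f"case{i + 1:02d}" for i in range(n_cases)]


def simulate_trios(
    config: SimulationConfig = SimulationConfig(),
) -> tuple[ExpressionMatrix, pd.DataFrame, SimulationTruth]:
    """Draw a matched-trio count matrix with known spiked genes.

    Returns the count matrix (genes x 3*n_cases samples), the sample
    annotation frame (sample_id, case_id, site) and the simulation truth.
    Fixed seed gives bit-identical output.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    gene_ids = [f"G{i + 1:05d}" for i in range(cfg.n_genes)]
    case_ids = _case_ids(cfg.n_cases)

    base = rng.lognormal(cfg.base_mean_log_mean, cfg.base_mean_log_sd, cfg.n_genes)

    n_spiked = cfg.n_up_spiked + cfg.n_down_spiked
    spiked_idx = rng.choice(cfg.n_genes, size=n_spiked, replace=False)
    up_idx = np.sort(spiked_idx[: cfg.n_up_spiked])
    down_idx = np.sort(spiked_idx[cfg.n_up_spiked:])
    # spiked genes must be expressed to carry an observable signal:
    # rejection-sample their baselines above the floor
    for idx in np.concatenate([up_idx, down_idx]).astype(int):
        while base[idx] < cfg.min_spiked_base_mean:
            base[idx] = rng.lognormal(cfg.base_mean_log_mean, cfg.base_mean_log_sd)

    labels = pd.Series(LABEL_NULL, index=pd.Index(gene_ids, name="gene_id"))
    labels.iloc[up_idx] = LABEL_UP
    labels.iloc[down_idx] = LABEL_DOWN

    spiked_all = np.concatenate([up_idx, down_idx]).astype(int)
    active_flags = rng.random((n_spiked, cfg.n_cases)) < cfg.recurrence_prob
    active = pd.DataFrame(
        active_flags,
        index=pd.Index([gene_ids[i] for i in spiked_all], name="gene_id"),
        columns=case_ids,
    )

    # site fold-effect tensor (gene x case x site), sites ordered N, T, LN
    folds = np.ones((cfg.n_genes, cfg.n_cases, 3))
    up_active = active_flags[: cfg.n_up_spiked]
    down_active = active_flags[cfg.n_up_spiked:]
    folds[up_idx[:, None], np.arange(cfg.n_cases)[None, :], 1] = np.where(
        up_active, cfg.up_fold_t, 1.0
    )
    folds[up_idx[:, None], np.arange(cfg.n_cases)[None, :], 2] = np.where(
        up_active, cfg.up_fold_ln, 1.0
    )
    folds[down_idx[:, None], np.arange(cfg.n_cases)[None, :], 1] = np.where(
        down_active, cfg.down_fold_t_vs_n, 1.0
    )
    folds[down_idx[:, None], np.arange(cfg.n_cases)[None, :], 2] = np.where(
        down_active, cfg.down_fold_ln_vs_n, 1.0
    )

    patient_eff = rng.lognormal(0.0, cfg.patient_effect_sd, (cfg.n_genes, cfg.n_cases))
    lo, hi = cfg.libsize_range
    lib = np.exp(rng.uniform(np.log(lo), np.log(hi), 3 * cfg.n_cases))

    means = base[:, None, None] * patient_eff[:, :, None] * folds
    means = means.reshape(cfg.n_genes, 3 * cfg.n_cases) * lib[None, :]

    if cfg.nb_dispersion > 0:
        r = 1.0 / cfg.nb_dispersion
        counts = rng.negative_binomial(r, r / (r + means))
    else:
        counts = rng.poisson(means)

    sample_ids = [f"{c}_{site}" for c in case_ids for site in ("N", "T", "LN")]
    matrix = ExpressionMatrix(
        pd.DataFrame(
            counts.astype(float),
            index=pd.Index(gene_ids, name="gene_id"),
            columns=sample_ids,
        )
    )
    annot = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "case_id": [s.rsplit("_", 1)[0] for s in sample_ids],
            "site": [s.rsplit("_", 1)[1] for s in sample_ids],
        }
    )
    return matrix, annot, SimulationTruth(labels=labels, active=active)


# ---------------------------------------------------------------------------
# Clinical tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClinicalSimConfig:
    """Parameters of the linked clinical simulation.

    Cohort sizes default to the validation-cohort structure the screen's
    downstream statistics target: a tissue microarray of 179 primary tumors
    and 56 metastatic lymph nodes, and a 415-patient survival cohort.
    ``ihc_shift`` moves the latent staining intensity of LN-metastasis
    cores up before discretization onto the 0-4 half-point grid;
    ``hazard_ratio`` multiplies the exponential event hazard of the
    high-marker group; ``frac_no_ln_met`` / ``frac_high_ratio`` set the
    fractions of patients with no positive nodes and with a positive-node
    ratio above 30%.
    """

    n_primary: int = 179
    n_ln_met: int = 56
    ihc_latent_mean: float = 1.5
    ihc_latent_sd: float = 1.0
    ihc_shift: float = 0.8
    n_patients: int = 415
    hazard_ratio: float = 2.0
    baseline_median_survival: float = 36.0  # months
    followup_max: float = 120.0  # months of administrative censoring
    frac_no_ln_met: float = 0.25
    frac_high_ratio: float = 0.35
    ln_ratio_cutoff: float = 0.30
    marker_log_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_primary, self.n_ln_met, self.n_patients) < 1:
            raise ValidationError("cohort sizes must be positive")
        if self.hazard_ratio <= 0 or self.baseline_median_survival <= 0:
            raise ValidationError("hazard parameters must be positive")
        if not (0 <= self.frac_no_ln_met and 0 <= self.frac_high_ratio
                and self.frac_no_ln_met + self.frac_high_ratio <= 1):
            raise ValidationError("LN-group fractions must form a partition")
        if not 0 < self.ln_ratio_cutoff < 1:
            raise ValidationError("ln_ratio_cutoff must lie in (0, 1)")


def _grid_score(latent: np.ndarray) -> np.ndarray:
    return np.clip(np.round(latent * 2) / 2, 0.0, 4.0)


def simulate_clinical(
    config: ClinicalSimConfig = ClinicalSimConfig(),
    truth: SimulationTruth | None = None,
    marker_gene: str | None = None,
) -> tuple[list[IHCRecord], list[SurvivalRecord], list[LNCountRecord], pd.DataFrame]:
    """Generate IHC, survival and lymph-node tables tied to one marker.

    If ``marker_gene`` is given it must exist in ``truth``.  Returns the
    three record lists plus a per-patient frame with the simulated marker
    expression and the assigned marker group (median split), which is what
    the survival hazard acts on.
    """
    cfg = config
    if marker_gene is not None:
        if truth is None or marker_gene not in truth.labels.index:
            raise ValidationError(f"unknown marker gene {marker_gene!r}")
    rng = np.random.default_rng(cfg.seed)

    # --- IHC: latent intensity, LN cores shifted up, half-point grid ---
    primary_latent = rng.normal(cfg.ihc_latent_mean, cfg.ihc_latent_sd, cfg.n_primary)
    ln_latent = rng.normal(
        cfg.ihc_latent_mean + cfg.ihc_shift, cfg.ihc_latent_sd, cfg.n_ln_met
    )
    ihc = [
        IHCRecord(f"P{i + 1:04d}", "primary", s)
        for i, s in enumerate(_grid_score(primary_latent))
    ] + [
        IHCRecord(f"L{i + 1:04d}", "ln_met", s)
        for i, s in enumerate(_grid_score(ln_latent))
    ]

    # --- survival: exponential hazard scaled by marker group ---
    patient_ids = [f"PT{i + 1:04d}" for i in range(cfg.n_patients)]
    marker = rng.lognormal(0.0, cfg.marker_log_sd, cfg.n_patients)
    median = np.median(marker)
    groups = np.where(marker > median, "high", "low")
    base_rate = np.log(2) / cfg.baseline_median_survival
    rate = base_rate * np.where(groups == "high", cfg.hazard_ratio, 1.0)
    event_time = rng.exponential(1.0 / rate)
    censor_time = rng.uniform(0, cfg.followup_max, cfg.n_patients)
    time = np.minimum(event_time, censor_time)
    event = event_time <= censor_time
    survival = [
        SurvivalRecord(pid, float(t), bool(e), str(g))
        for pid, t, e, g in zip(patient_ids, time, event, groups)
    ]

    # --- positive / examined lymph nodes ---
    examined = rng.integers(8, 41, cfg.n_patients)
    u = rng.random(cfg.n_patients)
    positive = np.zeros(cfg.n_patients, dtype=int)
    for i in range(cfg.n_patients):
        low_max = int(np.floor(cfg.ln_ratio_cutoff * examined[i]))
        if u[i] < cfg.frac_no_ln_met:
            positive[i] = 0
        elif u[i] < cfg.frac_no_ln_met + cfg.frac_high_ratio:
            positive[i] = rng.integers(low_max + 1, examined[i] + 1)
        else:
            positive[i] = rng.integers(1, max(low_max, 1) + 1)
    ln_records = [
        LNCountRecord(pid, int(p), int(e))
        for pid, p, e in zip(patient_ids, positive, examined)
    ]

    patients = pd.DataFrame(
        {
            "patient_id": patient_ids,
            "marker": marker,
            "group": groups,
        }
    )
    if marker_gene is not None:
        patients.insert(1, "marker_gene", marker_gene)
    return ihc, survival, ln_records, patients


def write_truth_table(truth: SimulationTruth, path: str | Path) -> None:
    truth.to_frame().to_csv(path, sep="\t")
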