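"""Synthetic serology cohorts and B-cell repertoires.

These generators produce data with the statistical structure the analysis
assumes, so every downstream stage can be exercised and calibrated
without access to patient data.

Serology model
--------------
Each patient carries latent class-switch processes with exponential
waiting times.  IgM may be present from onset and wanes over time.  IgA
arises from two components: a baseline switch process common to all
patients, and a tumour-driven process active only in ovarian-teratoma
(OT) patients before tumour resection, whose antibody output decays
exponentially after resection while baseline output persists.  The
observed IgA titre is the larger of the two components, snapped down to
the doubling dilution ladder.  Setting the tumour hazard multiplier to 1
switches the tumour component off entirely, giving an exact null in which
OT status is independent of serology.

Repertoire model
----------------
Clones receive power-law base sizes shared between blood and tumour; in
tumour tissue the sizes of multi-cell clones are multiplied by an
expansion factor (a factor of 1 restores exchangeability).  Cells carry a
latent isotype drawn per embedding cluster, a constant-region expression
vector dominated by that isotype, a negative-binomial V-region mutation
count with isotype-dependent mean, 2-D Gaussian cluster coordinates, and
a label-transfer-style prediction-score row summing to 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .enrichment import nearest_centroid_scores
from .repertoire import ISOTYPE_ORDER
from .serology import TITRE_LADDER

__all__ = [
    "ConfigError",
    "CohortConfig",
    "RepertoireConfig",
    "RepertoireData",
    "simulate_serology_cohort",
    "simulate_repertoire",
    "cohort_with_controls",
]


class ConfigError(ValueError):
    """Invalid generator configuration."""


def _check(condition: bool, message: str) -> None:
    if not condition:
        raise ConfigError(message)


# ---------------------------------------------------------------------------
# Serology cohort
# ---------------------------------------------------------------------------


@dataclass
class CohortConfig:
    """Configuration of the synthetic serology cohort.

    Defaults mirror the cohort scale of the study design this package
    models: 108 patients contributing ~285 serum/CSF samples, 27% tumour
    prevalence, 508 control sera, and a doubling titre ladder from 1:20.
    """

    n_patients: int = 108
    samples_per_patient_mean: float = 2.64
    samples_per_patient_max: int = 10
    ot_prevalence: float = 0.27
    titre_ladder: tuple[int, ...] = TITRE_LADDER
    #: per-day hazard multiplier of the tumour-driven IgA switch process
    #: (1 = no tumour effect; the exact serological null)
    iga_switch_hazard_ot: float = 10.0
    iga_base_hazard: float = 0.0015       # per day, all patients
    #: days the tumour-driven switch process runs before symptom onset
    #: (the tumour, and any class switching it drives, predates symptoms)
    tumour_lead_days: float = 120.0
    igg_positive_prob: float = 0.95
    igm_positive_prob: float = 0.55
    igm_half_life: float = 300.0          # days; IgM titre waning
    igm_ladder_index: tuple[float, float] = (2.5, 1.2)   # mean, sd on log2 ladder
    iga_ladder_index: tuple[float, float] = (3.0, 1.5)
    igg_ladder_index: tuple[float, float] = (5.0, 1.5)
    first_sample_day_lognorm: tuple[float, float] = (26.0, 1.1)  # median, sigma
    sample_gap_lognorm: tuple[float, float] = (90.0, 1.0)
    max_day: int = 3000
    resection_day_lognorm: tuple[float, float] = (30.0, 0.5)
    post_resection_iga_decay: float = 20.0   # half-life, days
    csf_fraction: float = 0.17
    control_n: int = 508
    control_signal_median: float = 10.0   # exponential assay signal of controls
    control_positive_rate: float = 0.017
    seed: int | None = None

    def validate(self) -> None:
        _check(self.n_patients > 0 and self.control_n > 0, "counts must be positive")
        for p in (self.ot_prevalence, self.igg_positive_prob, self.igm_positive_prob,
                  self.csf_fraction, self.control_positive_rate):
            _check(0.0 <= p <= 1.0, "probabilities must lie in [0, 1]")
        ladder = self.titre_ladder
        _check(len(ladder) >= 2 and all(b == 2 * a for a, b in zip(ladder, ladder[1:])),
               "titre ladder must be strictly increasing and geometric with ratio 2")
        _check(self.iga_switch_hazard_ot >= 0 and self.iga_base_hazard > 0,
               "hazards must be positive")
        _check(self.post_resection_iga_decay > 0 and self.igm_half_life > 0,
               "half-lives must be positive")
        _check(self.tumour_lead_days >= 0, "tumour lead time must be >= 0")
        _check(self.samples_per_patient_mean >= 1 and self.samples_per_patient_max >= 1,
               "samples per patient must be >= 1")


def _snap_to_ladder(value: float, ladder: tuple[int, ...]) -> int:
    """Largest ladder dilution <= value; 0 (negative) below the ladder."""
    out = 0
    for step in ladder:
        if value >= step:
            out = step
        else:
            break
    return out


def _ladder_titre(rng: np.random.Generator, index_mean: float, index_sd: float,
                  ladder: tuple[int, ...]) -> int:
    idx = int(np.clip(round(rng.normal(index_mean, index_sd)), 0, len(ladder) - 1))
    return ladder[idx]


def simulate_serology_cohort(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a longitudinal serology cohort plus control sera.

    Returns ``(samples, controls)``.  ``samples`` has one row per
    serum/CSF measurement with columns ``patient_id, sample_id, material,
    days_from_onset, ot_status, resection_day, titre_IgM, titre_IgA,
    titre_IgG``; ``controls`` one row per control serum with the assay
    signal and (mostly negative) titres, ``ot_status="control"``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    ladder = config.titre_ladder
    rows = []
    for i in range(config.n_patients):
        pid = f"PT{i:04d}"
        is_ot = rng.random() < config.ot_prevalence
        med, sig = config.resection_day_lognorm
        resection = float(rng.lognormal(np.log(med), sig)) if is_ot else np.nan

        # latent switch processes -------------------------------------------------
        t_base_iga = rng.exponential(1.0 / config.iga_base_hazard)
        extra = config.iga_base_hazard * (config.iga_switch_hazard_ot - 1.0)
        if is_ot and extra > 0:
            # tumour-driven switching runs from `tumour_lead_days` before
            # onset until resection; pre-onset switches surface at day 0
            t_tum = rng.exponential(1.0 / extra) - config.tumour_lead_days
            t_tum_iga = max(t_tum, 0.0) if t_tum <= resection else np.inf
        else:
            t_tum_iga = np.inf
        iga_base_peak = _ladder_titre(rng, *config.iga_ladder_index, ladder)
        iga_tum_peak = _ladder_titre(rng, *config.iga_ladder_index, ladder)
        igm_pos = rng.random() < config.igm_positive_prob
        igm_peak = _ladder_titre(rng, *config.igm_ladder_index, ladder) if igm_pos else 0
        igg_pos = rng.random() < config.igg_positive_prob
        igg_titre = _ladder_titre(rng, *config.igg_ladder_index, ladder) if igg_pos else 0

        n_samples = 1 + rng.poisson(max(config.samples_per_patient_mean - 1.0, 0.0))
        n_samples = int(min(n_samples, config.samples_per_patient_max))
        med0, sig0 = config.first_sample_day_lognorm
        med_gap, sig_gap = config.sample_gap_lognorm
        first = rng.lognormal(np.log(med0), sig0)
        gaps = rng.lognormal(np.log(med_gap), sig_gap, size=n_samples - 1)
        days = np.minimum(first + np.concatenate([[0.0], np.cumsum(gaps)]),
                          config.max_day).astype(int)
        for j, day in enumerate(days):
            igm = _snap_to_ladder(igm_peak * 2.0 ** (-day / config.igm_half_life), ladder)
            base = iga_base_peak if day >= t_base_iga else 0.0
            tum = 0.0
            if day >= t_tum_iga:
                tum = iga_tum_peak
                if day > resection:
                    tum *= 2.0 ** (-(day - resection) / config.post_resection_iga_decay)
            iga = _snap_to_ladder(max(base, tum), ladder)
            rows.append({
                "patient_id": pid,
                "sample_id": f"{pid}-S{j:02d}",
                "material": "csf" if rng.random() < config.csf_fraction else "serum",
                "days_from_onset": int(day),
                "ot_status": "OT" if is_ot else "non-OT",
                "resection_day": resection,
                "titre_IgM": igm,
                "titre_IgA": iga,
                "titre_IgG": igg_titre,
            })
    samples = pd.DataFrame(rows)

    signal = rng.exponential(config.control_signal_median / np.log(2.0),
                             size=config.control_n)
    pos = rng.random(config.control_n) < config.control_positive_rate
    pos_titre = np.where(rng.random(config.control_n) < 0.5, ladder[0], ladder[1])
    controls = pd.DataFrame({
        "patient_id": [f"CT{i:04d}" for i in range(config.control_n)],
        "sample_id": [f"CT{i:04d}-S00" for i in range(config.control_n)],
        "material": "serum",
        "days_from_onset": 0,
        "ot_status": "control",
        "resection_day": np.nan,
        "assay_signal": signal,
        "titre_IgM": np.where(pos, pos_titre, 0).astype(int),
        "titre_IgA": np.where(rng.random(config.control_n) < config.control_positive_rate,
                              pos_titre, 0).astype(int),
        "titre_IgG": 0,
    })
    return samples, controls


def cohort_with_controls(config: CohortConfig) -> pd.DataFrame:
    """Patient samples and control sera stacked into one calls table."""
    samples, controls = simulate_serology_cohort(config)
    return pd.concat([samples, controls.drop(columns=["assay_signal"])],
                     ignore_index=True)


# ---------------------------------------------------------------------------
# BCR repertoire
# ---------------------------------------------------------------------------


def _default_isotype_probs(n_clusters: int) -> dict[int, dict[str, float]]:
    """Cluster-specific isotype usage: naive-like clusters dominated by
    IGHM/IGHD, memory-like clusters by switched isotypes, and the last
    cluster IgA-skewed (the tumour-associated population)."""
    naive = {"IGHM": 0.62, "IGHD": 0.28, "IGHG3": 0.02, "IGHG1": 0.04,
             "IGHA1": 0.02, "IGHG2": 0.01, "IGHG4": 0.0, "IGHE": 0.0, "IGHA2": 0.01}
    memory = {"IGHM": 0.10, "IGHD": 0.02, "IGHG3": 0.08, "IGHG1": 0.40,
              "IGHA1": 0.20, "IGHG2": 0.10, "IGHG4": 0.02, "IGHE": 0.01, "IGHA2": 0.07}
    iga_skewed = {"IGHM": 0.06, "IGHD": 0.01, "IGHG3": 0.04, "IGHG1": 0.14,
                  "IGHA1": 0.45, "IGHG2": 0.05, "IGHG4": 0.01, "IGHE": 0.01,
                  "IGHA2": 0.23}
    out = {}
    for c in range(n_clusters):
        if c == n_clusters - 1:
            out[c] = dict(iga_skewed)
        elif c % 2 == 0:
            out[c] = dict(naive)
        else:
            out[c] = dict(memory)
    return out


@dataclass
class RepertoireConfig:
    """Configuration of the synthetic single-cell BCR repertoire.

    Cell numbers default to an unbalanced blood-heavy design (sorted B
    cells are far more abundant from blood than from dissociated tumour
    tissue), totalling ~10k cells over two patients as in a typical
    two-patient 10x experiment.
    """

    n_cells_per_sample: Mapping[str, int] = field(
        default_factory=lambda: {"tumour": 350, "blood": 4500})
    clone_size_exponent: float = 2.5          # power-law (zeta) exponent, > 1
    expansion_multiplier_tumour: float = 2.2  # size factor for multi-cell clones
    n_clusters: int = 8
    cluster_weights: tuple[float, ...] | None = None
    isotype_probs: Mapping[int, Mapping[str, float]] | None = None
    #: tumour-tissue odds multiplier per cluster (None = last cluster 1.7x)
    cluster_tissue_bias: Mapping[int, float] | None = None
    mutation_mean_per_kb: Mapping[str, float] = field(default_factory=lambda: {
        "IGHM": 12.0, "IGHD": 5.0, "IGHG3": 28.0, "IGHG1": 30.0, "IGHA1": 45.0,
        "IGHG2": 35.0, "IGHG4": 35.0, "IGHE": 35.0, "IGHA2": 48.0})
    mutation_dispersion: float = 2.0          # negative-binomial size parameter
    v_length_mean: float = 330.0
    v_length_sd: float = 25.0
    cluster_sd: float = 0.9                   # spread around cluster centres
    score_temperature: float = 2.0
    sample_prefix: str = "P1"
    seed: int | None = None

    def resolved_isotype_probs(self) -> dict[int, dict[str, float]]:
        probs = self.isotype_probs or _default_isotype_probs(self.n_clusters)
        return {int(c): {g: float(p.get(g, 0.0)) for g in ISOTYPE_ORDER}
                for c, p in probs.items()}

    def validate(self) -> None:
        _check(all(n >= 1 for n in self.n_cells_per_sample.values()),
               "n_cells must be >= 1 for every sample")
        _check(self.clone_size_exponent > 1.0, "power-law exponent must exceed 1")
        _check(self.expansion_multiplier_tumour >= 1.0,
               "expansion multiplier must be >= 1")
        _check(self.n_clusters >= 1, "need at least one cluster")
        for c, probs in self.resolved_isotype_probs().items():
            _check(abs(sum(probs.values()) - 1.0) < 1e-6,
                   f"isotype probabilities for cluster {c} must sum to 1")
        _check(all(m >= 0 for m in self.mutation_mean_per_kb.values()),
               "mutation means must be >= 0")


@dataclass
class RepertoireData:
    """Simulated repertoire: cell table plus prediction-score matrix."""

    cells: pd.DataFrame
    scores: pd.DataFrame            # one row per cell, one column per cluster
    cluster_centres: np.ndarray
    seed: int | None


def _cluster_centres(n_clusters: int, radius: float = 5.0) -> np.ndarray:
    angles = 2 * np.pi * np.arange(n_clusters) / n_clusters
    return radius * np.column_stack([np.cos(angles), np.sin(angles)])


def simulate_repertoire(config: RepertoireConfig) -> RepertoireData:
    """Simulate paired tumour/blood B-cell repertoires for one patient."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    iso_probs = config.resolved_isotype_probs()
    n_clusters = config.n_clusters
    centres = _cluster_centres(n_clusters)
    weights = np.asarray(config.cluster_weights
                         if config.cluster_weights is not None
                         else np.full(n_clusters, 1.0 / n_clusters), dtype=float)
    weights = weights / weights.sum()
    bias = dict(config.cluster_tissue_bias) if config.cluster_tissue_bias is not None \
        else {n_clusters - 1: 1.7}

    # shared clone pool with power-law base sizes
    total_cells = sum(config.n_cells_per_sample.values())
    sizes = rng.zipf(config.clone_size_exponent, size=2 * total_cells)
    sizes = np.minimum(sizes, 500)
    mult = config.expansion_multiplier_tumour
    tumour_sizes = np.where(sizes >= 2, sizes * mult, sizes)

    iso_matrix = np.array([[iso_probs[c][g] for g in ISOTYPE_ORDER]
                           for c in range(n_clusters)])
    frames = []
    all_scores = []
    for tissue, n_cells in config.n_cells_per_sample.items():
        clone_w = tumour_sizes if tissue == "tumour" else sizes
        clone_idx = rng.choice(len(sizes), size=n_cells, p=clone_w / clone_w.sum())
        w = weights.copy()
        for c, fold in bias.items():
            if tissue == "tumour":
                w[int(c)] *= float(fold)
        w = w / w.sum()
        clusters = rng.choice(n_clusters, size=n_cells, p=w)
        iso_idx = np.array([rng.choice(len(ISOTYPE_ORDER), p=iso_matrix[c])
                            for c in clusters])
        # expression: dominant isotype bright, sparse low-level background
        expr = rng.exponential(0.05, size=(n_cells, len(ISOTYPE_ORDER)))
        expr[rng.random(expr.shape) > 0.3] = 0.0
        expr[np.arange(n_cells), iso_idx] = rng.lognormal(1.5, 0.6, size=n_cells) + 0.5
        v_len = np.maximum(rng.normal(config.v_length_mean, config.v_length_sd,
                                      size=n_cells), 250.0).round().astype(int)
        mu = np.array([config.mutation_mean_per_kb[ISOTYPE_ORDER[i]] for i in iso_idx])
        mu = np.maximum(mu * v_len / 1000.0, 1e-9)
        r = config.mutation_dispersion
        mutations = rng.negative_binomial(r, r / (r + mu))
        coords = centres[clusters] + rng.normal(0.0, config.cluster_sd,
                                                size=(n_cells, 2))
        sample_id = f"{config.sample_prefix}-{tissue}"
        frame = pd.DataFrame({
            "cell_id": [f"{sample_id}-C{i:05d}" for i in range(n_cells)],
            "sample_id": sample_id,
            "tissue": tissue,
            "clone_id": [f"clone{k:06d}" for k in clone_idx],
            "c_call": [ISOTYPE_ORDER[i] for i in iso_idx],
            "v_mutation_count": mutations,
            "v_length_nt": v_len,
            "cluster": clusters,
            "umap_1": coords[:, 0],
            "umap_2": coords[:, 1],
        })
        for g_i, gene in enumerate(ISOTYPE_ORDER):
            frame[gene] = expr[:, g_i]
        frames.append(frame)
        all_scores.append(nearest_centroid_scores(coords, centres,
                                                  config.score_temperature))
    cells = pd.concat(frames, ignore_index=True)
    scores = pd.DataFrame(np.vstack(all_scores),
                          columns=[f"cluster_{c}" for c in range(n_clusters)])
    scores.insert(0, "cell_id", cells["cell_id"].to_numpy())
    return RepertoireData(cells, scores, centres, config.seed)
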