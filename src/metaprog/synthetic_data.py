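"""Seeded generators for synthetic study data.

Three generators cover the three data shapes the analysis consumes:

* :func:`simulate_cohort` — a longitudinal lipidomics cohort shaped like the
  female NOD-mouse study arm: 12 progressors and 14 non-progressors sampled
  weekly from age 3 to 36 weeks over a panel of 154 lipid species, with
  progressors censored at a stochastic disease onset.  Every individual
  traverses a shared sequence of progressive metabolic states at its own
  pace; visit profiles are Gaussian per state on the log2 scale, and the
  stored table holds the back-transformed non-negative concentrations.
* :func:`simulate_cross_species_pair` — two matrices that share latent
  factors but live in different feature spaces, with the rows of the second
  randomly permuted; the ground-truth permutation is returned for
  match-recovery tests.
* :func:`simulate_marker_cohort` — per-individual lysoPC component
  concentrations, IAA status and progression outcome, with elevated lysoPC
  in IAA-negative progressors and a protective association for IAA-positive
  individuals with high lysoPC.

True state paths, permutations and outcomes are always returned so that
downstream estimators can be scored against the generating truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .dataio import LongitudinalDataset
from .hmm import ProgressionHMM, left_to_right_mask

LYSOPC_COMPONENTS = ("PC(16:0/0:0)", "PC(18:0/0:0)")


# ---------------------------------------------------------------------------
# longitudinal cohort


def default_truth(
    n_metabolites: int = 154,
    n_states: int = 3,
    group: str = "non-progressor",
    *,
    baseline: float = 5.0,
    noise_sd: float = 0.5,
    stay_prob: float = 2.0 / 3.0,
    state_step: float = 0.25,
) -> ProgressionHMM:
    """Ground-truth progressive HMM for one cohort group.

    Emission means live on the log2 scale around ``baseline`` (raw
    concentrations of order 2**baseline µmol/l).  The progressor profile
    qualitatively mimics the observed pattern: phospholipid-like features
    (the first third of the panel) lowered in the early states, lysoPC-like
    features (the last two panel positions, named after the lysoPC
    components) raised in the final state.  Effect magnitudes are free
    parameters of the generator, not measured values.

    ``stay_prob`` 2/3 gives a mean state dwell of 3 weeks on a weekly grid.
    """
    d, K = n_metabolites, n_states
    # deterministic per-metabolite baselines so the panel is not flat
    offsets = np.sin(np.arange(d)) * 0.5
    M = np.tile(baseline + offsets, (K, 1))
    # global drift across states; state_step in log2 units per state controls
    # how separated adjacent states are relative to noise_sd
    M += (np.arange(K) * state_step)[:, None]
    if group == "progressor":
        n_pl = max(1, d // 3)
        for k in range(min(2, K)):  # early-state phospholipid decrease
            M[k, :n_pl] -= 1.0
        M[K - 1, -2:] += 1.0  # late lysoPC-like increase
    V = np.full((K, d), max(noise_sd, 1e-6) ** 2)
    pi = np.zeros(K)
    pi[0] = 1.0
    A = np.zeros((K, K))
    for k in range(K - 1):
        A[k, k] = stay_prob
        A[k, k + 1] = 1.0 - stay_prob
    A[K - 1, K - 1] = 1.0
    return ProgressionHMM(pi, A, M, V, mask=left_to_right_mask(K))


@dataclass
class GeneratorSpec:
    """Study-design parameters of the synthetic cohort."""

    n_progressors: int = 12
    n_nonprogressors: int = 14
    ages: np.ndarray = field(default_factory=lambda: np.arange(3.0, 37.0))
    n_metabolites: int = 154
    n_states: int = 3
    hmm_truth: Mapping[str, ProgressionHMM] | None = None
    #: weekly probability of diabetes onset for progressors, active after onset_min_age
    dropout_hazard: float = 0.10
    onset_min_age: float = 10.0
    noise_sd: float = 0.5
    seed: int = 0

    def truth(self) -> Mapping[str, ProgressionHMM]:
        if self.hmm_truth is not None:
            return self.hmm_truth
        return {
            g: default_truth(self.n_metabolites, self.n_states, g, noise_sd=self.noise_sd)
            for g in ("progressor", "non-progressor")
        }


def _sample_path(rng: np.random.Generator, model: ProgressionHMM, T: int) -> np.ndarray:
    path = np.empty(T, dtype=int)
    path[0] = rng.choice(model.K, p=model.pi)
    for t in range(1, T):
        path[t] = rng.choice(model.K, p=model.A[path[t - 1]])
    return path


def simulate_cohort(
    spec: GeneratorSpec,
) -> tuple[LongitudinalDataset, dict[str, np.ndarray]]:
    """Simulate a longitudinal cohort; returns (dataset, true state paths).

    State paths are monotone non-decreasing by construction of the truth
    transition matrices.  Emissions are drawn on the log2 scale and stored as
    2**z - 1 (clipped at 0), so applying the default log2(x+1) modelling
    transform recovers the emitted values exactly whenever z >= 0.
    Progressors are truncated at a geometric onset time driven by
    ``dropout_hazard`` after ``onset_min_age``.
    """
    if spec.n_progressors + spec.n_nonprogressors < 1:
        raise ValueError("cohort must contain at least one individual")
    rng = np.random.default_rng(spec.seed)
    truth = spec.truth()
    ages = np.asarray(spec.ages, dtype=float)
    lipid_names = [f"L{j:03d}" for j in range(spec.n_metabolites)]
    # last two panel slots carry the lysoPC component names used by the marker
    if spec.n_metabolites >= 2:
        lipid_names[-2:] = list(LYSOPC_COMPONENTS)

    rows = []
    meta_rows = []
    paths: dict[str, np.ndarray] = {}
    roster = [("progressor", i) for i in range(spec.n_progressors)] + [
        ("non-progressor", i) for i in range(spec.n_nonprogressors)
    ]
    for group, i in roster:
        ind = f"{'P' if group == 'progressor' else 'N'}{i:02d}"
        model = truth[group]
        onset = np.inf
        if group == "progressor" and spec.dropout_hazard > 0:
            eligible = ages[ages >= spec.onset_min_age]
            draws = rng.random(len(eligible))
            hits = np.flatnonzero(draws < spec.dropout_hazard)
            if len(hits):
                onset = eligible[hits[0]]
        visit_ages = ages[ages <= onset]
        T = len(visit_ages)
        path = _sample_path(rng, model, T)
        z = model.means[path] + (
            rng.standard_normal((T, spec.n_metabolites)) * np.sqrt(model.variances[path])
            if np.any(model.variances > 1e-12)
            else 0.0
        )
        conc = np.maximum(np.exp2(z) - 1.0, 0.0)
        for t, age in enumerate(visit_ages):
            for j, lip in enumerate(lipid_names):
                rows.append((ind, age, lip, conc[t, j]))
        paths[ind] = path
        iaa = "positive" if rng.random() < 0.35 else "negative"
        meta_rows.append(
            (ind, group, "F", iaa, float(visit_ages[-1]) if T else float(ages[0]))
        )
    records = pd.DataFrame(rows, columns=["individual", "age", "metabolite", "concentration"])
    meta = pd.DataFrame(
        meta_rows, columns=["individual", "group", "sex", "iaa_status", "followup_end"]
    )
    # panel order matches the truth models' emission columns (L* sorts before PC*)
    dataset = LongitudinalDataset(records, meta, list(lipid_names))
    return dataset, paths


# ---------------------------------------------------------------------------
# cross-species matrix pair


def simulate_cross_species_pair(
    n_rows: int,
    d1: int,
    d2: int,
    shared_rank: int,
    noise_sd: float,
    seed: int = 0,
    *,
    identical_loadings: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Two matrices generated from shared latent factors, second one row-permuted.

    Returns (X, Y, perm) where row i of X corresponds to row perm[i] of Y.
    With ``identical_loadings`` (requires d1 == d2) and noise_sd == 0, Y is
    exactly a row permutation of X.
    """
    if shared_rank > min(d1, d2):
        raise ValueError("shared_rank must not exceed min(d1, d2)")
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((n_rows, shared_rank))
    Lx = rng.standard_normal((d1, shared_rank))
    Ly = Lx if identical_loadings and d1 == d2 else rng.standard_normal((d2, shared_rank))
    X = Z @ Lx.T + noise_sd * rng.standard_normal((n_rows, d1))
    Y_unperm = Z @ Ly.T + noise_sd * rng.standard_normal((n_rows, d2))
    perm = rng.permutation(n_rows)
    Y = np.empty_like(Y_unperm)
    Y[perm] = Y_unperm  # row perm[i] of Y is the partner of row i of X
    return X, Y, perm


# ---------------------------------------------------------------------------
# risk-marker cohort


@dataclass
class MarkerSpec:
    """Parameters of the surrogate-marker cohort generator.

    ``lysopc_shift`` is the additive log2 shift of lysoPC for IAA-negative
    progressors; ``protection_odds`` divides the progression odds of
    IAA-positive individuals with above-median lysoPC (1 = no protection).
    """

    lysopc_shift: float = 1.0
    frac_iaa_pos: float = 0.35
    protection_odds: float = 4.0
    base_prog_prob: float = 12.0 / 26.0
    lysopc_mean: float = 3.0  # log2 µmol/l of the summed components
    noise_sd: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.frac_iaa_pos <= 1.0:
            raise ValueError("frac_iaa_pos must be in [0, 1]")
        if not 0.0 <= self.base_prog_prob <= 1.0:
            raise ValueError("base_prog_prob must be in [0, 1]")


def simulate_marker_cohort(spec: MarkerSpec, n: int) -> pd.DataFrame:
    """Cohort table for the lysoPC + IAA surrogate marker.

    Columns: individual, the two lysoPC component concentrations (µmol/l),
    iaa_status, group.  IAA-negative progressors get a lysoPC shift; among
    IAA-positive individuals high lysoPC lowers the progression odds by
    ``protection_odds``.  With shift 0 and protection_odds 1 the outcome is
    independent of the marker (a null cohort).
    """
    if n < 4:
        raise ValueError("need n >= 4 individuals")
    rng = np.random.default_rng(spec.seed)
    iaa = np.where(rng.random(n) < spec.frac_iaa_pos, "positive", "negative")
    outcome = rng.random(n) < spec.base_prog_prob
    log_lysopc = spec.lysopc_mean + spec.noise_sd * rng.standard_normal(n)
    log_lysopc += spec.lysopc_shift * (outcome & (iaa == "negative"))
    # protection: IAA+ individuals with high lysoPC have reduced progression odds
    high = log_lysopc > np.median(log_lysopc)
    protected = (iaa == "positive") & high
    if spec.protection_odds != 1.0 and protected.any():
        p = spec.base_prog_prob
        odds = p / (1 - p) / spec.protection_odds
        outcome[protected] = rng.random(protected.sum()) < odds / (1 + odds)
    total = np.exp2(log_lysopc)
    split = rng.uniform(0.4, 0.6, size=n)  # PC(16:0/0:0) share of the sum
    return pd.DataFrame(
        {
            "individual": [f"M{i:03d}" for i in range(n)],
            LYSOPC_COMPONENTS[0]: total * split,
            LYSOPC_COMPONENTS[1]: total * (1 - split),
            "iaa_status": iaa,
            "group": np.where(outcome, "progressor", "non-progressor"),
        }
    )
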