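"""Left-to-right Gaussian hidden Markov model of metabolic-state progression.

Each individual's visit sequence is modelled as emissions from a chain of K
latent metabolic states.  The chain is strictly progressive: from state k the
only allowed moves are staying in k or advancing to k+1, so state paths are
monotone non-decreasing and the final state is absorbing.  Emissions are
diagonal-covariance Gaussians over the metabolite panel — with up to 154
metabolites and cohorts of a few dozen individuals a full covariance is not
identifiable.

Individuals are assumed to share the developmental progression while
traversing it at their own pace, so fitting pools all individuals of a cohort
into one model; progressors and non-progressors get separate models whose
per-state emission means are then compared with bootstrap confidence bands.

Fitting is standard Baum-Welch (EM) with all forward/backward arithmetic in
log space.  The structural zeros of the transition matrix are exact at every
iteration: disallowed transitions receive no expected counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .dataio import AnalysisConfig, LongitudinalDataset, modeling_values, to_visit_matrix

LOG_EPS = -1e30  # stand-in for log(0) that survives additions


# ---------------------------------------------------------------------------
# model container


def left_to_right_mask(n_states: int, allow_skips: bool = False) -> np.ndarray:
    """Boolean K x K mask of allowed transitions.

    Default band: self-loops and single forward steps only.  With
    ``allow_skips`` every forward move is allowed (upper triangle) — the
    alternative reading of a purely progressive chain.
    """
    if allow_skips:
        return np.triu(np.ones((n_states, n_states), dtype=bool))
    mask = np.eye(n_states, dtype=bool)
    mask |= np.eye(n_states, k=1, dtype=bool)
    return mask


@dataclass
class ProgressionHMM:
    """K progressive states with diagonal Gaussian emissions.

    pi: initial distribution (K,); A: transition matrix (K, K) honouring
    ``mask``; means/variances: (K, d) emission parameters;
    metabolite_index: column labels for the emission dimensions.
    """

    pi: np.ndarray
    A: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    metabolite_index: list[str] = field(default_factory=list)
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        self.variances = np.atleast_2d(np.asarray(self.variances, dtype=float))
        if self.mask is None:
            self.mask = left_to_right_mask(self.K)
        self.mask = np.asarray(self.mask, dtype=bool)
        if not np.isclose(self.pi.sum(), 1.0):
            raise ValueError("pi must sum to 1")
        if not np.allclose(self.A.sum(axis=1), 1.0):
            raise ValueError("rows of A must sum to 1")
        if np.any(self.A[~self.mask] != 0.0):
            raise ValueError("A has mass on a disallowed (backward) transition")
        if np.any(self.variances <= 0):
            raise ValueError("variances must be positive")

    @property
    def K(self) -> int:
        return len(self.pi)

    @property
    def d(self) -> int:
        return self.means.shape[1]

    def log_emission(self, X: np.ndarray) -> np.ndarray:
        """T x K matrix of per-visit log emission densities."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.d:
            raise ValueError(f"visit matrix has {X.shape[1]} columns, model has {self.d}")
        diff = X[:, None, :] - self.means[None, :, :]  # T x K x d
        return -0.5 * np.sum(
            diff**2 / self.variances[None] + np.log(2 * np.pi * self.variances[None]),
            axis=2,
        )

    def to_json(self, path: str | Path) -> None:
        doc = {
            "pi": self.pi.tolist(),
            "A": self.A.tolist(),
            "means": self.means.tolist(),
            "variances": self.variances.tolist(),
            "metabolite_index": list(self.metabolite_index),
            "mask": self.mask.astype(int).tolist(),
        }
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ProgressionHMM":
        doc = json.loads(Path(path).read_text())
        return cls(
            pi=np.array(doc["pi"]),
            A=np.array(doc["A"]),
            means=np.array(doc["means"]),
            variances=np.array(doc["variances"]),
            metabolite_index=doc.get("metabolite_index", []),
            mask=np.array(doc["mask"], dtype=bool),
        )


@dataclass
class FitResult:
    model: ProgressionHMM
    loglik_trace: np.ndarray
    n_iter: int
    converged: bool


@dataclass
class StateOccupancy:
    """Cohort-average posterior state probability per age bin.

    ``P`` is bins x K; rows sum to 1 except for empty bins, which are NaN.
    ``lower``/``upper`` are bootstrap percentile bands per cell.
    """

    age_bins: np.ndarray
    P: np.ndarray
    lower: np.ndarray | None = None
    upper: np.ndarray | None = None


# ---------------------------------------------------------------------------
# inference on a fixed model


def _log_A(model: ProgressionHMM) -> np.ndarray:
    with np.errstate(divide="ignore"):
        logA = np.log(model.A)
    logA[~model.mask] = LOG_EPS
    logA[np.isneginf(logA)] = LOG_EPS
    return logA


def forward_loglik(model: ProgressionHMM, X: np.ndarray) -> float:
    """Log-likelihood of one visit sequence, summed over allowed state paths."""
    logB = model.log_emission(X)
    logA = _log_A(model)
    with np.errstate(divide="ignore"):
        alpha = np.log(model.pi) + logB[0]
    for t in range(1, len(logB)):
        alpha = logsumexp(alpha[:, None] + logA, axis=0) + logB[t]
    return float(logsumexp(alpha))


def _forward_backward_log(model: ProgressionHMM, X: np.ndarray):
    """Log-space forward-backward; slower but immune to underflow."""
    logB = model.log_emission(X)
    T, K = logB.shape
    logA = _log_A(model)
    with np.errstate(divide="ignore"):
        logpi = np.where(model.pi > 0, np.log(np.maximum(model.pi, 1e-300)), LOG_EPS)
    log_alpha = np.empty((T, K))
    log_alpha[0] = logpi + logB[0]
    for t in range(1, T):
        log_alpha[t] = logsumexp(log_alpha[t - 1][:, None] + logA, axis=0) + logB[t]
    log_beta = np.zeros((T, K))
    for t in range(T - 2, -1, -1):
        log_beta[t] = logsumexp(logA + (logB[t + 1] + log_beta[t + 1])[None, :], axis=1)
    loglik = float(logsumexp(log_alpha[-1]))
    gamma = np.exp(log_alpha + log_beta - loglik)
    gamma /= gamma.sum(axis=1, keepdims=True)
    xi_sum = np.zeros((K, K))
    for t in range(T - 1):
        log_xi = (
            log_alpha[t][:, None]
            + logA
            + (logB[t + 1] + log_beta[t + 1])[None, :]
            - loglik
        )
        xi = np.exp(log_xi)
        xi[~model.mask] = 0.0
        xi_sum += xi
    return gamma, xi_sum, loglik


def _forward_backward(model: ProgressionHMM, X: np.ndarray):
    """Return (gamma, xi_sum, loglik) for one sequence.

    gamma: T x K posterior state probabilities; xi_sum: K x K expected
    transition counts.  Uses the scaled linear-space recursion (each per-visit
    emission row is rescaled by its maximum, each alpha by its sum), falling
    back to log space in the rare case a scaling constant underflows.
    """
    logB = model.log_emission(X)
    T, K = logB.shape
    b_max = logB.max(axis=1)
    B = np.exp(logB - b_max[:, None])
    A = model.A
    alpha = np.empty((T, K))
    c = np.empty(T)
    a = model.pi * B[0]
    c[0] = a.sum()
    if c[0] <= 0 or not np.isfinite(c[0]):
        return _forward_backward_log(model, X)
    alpha[0] = a / c[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ A) * B[t]
        c[t] = a.sum()
        if c[t] <= 0 or not np.isfinite(c[t]):
            return _forward_backward_log(model, X)
        alpha[t] = a / c[t]
    loglik = float(np.log(c).sum() + b_max.sum())
    beta = np.empty((T, K))
    beta[-1] = 1.0
    xi_sum = np.zeros((K, K))
    for t in range(T - 2, -1, -1):
        w = B[t + 1] * beta[t + 1]
        beta[t] = (A @ w) / c[t + 1]
        xi_sum += alpha[t][:, None] * A * w[None, :] / c[t + 1]
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    return gamma, xi_sum, loglik


def posterior_decode(model: ProgressionHMM, X: np.ndarray) -> np.ndarray:
    """T x K posterior state probabilities (forward-backward in log space)."""
    gamma, _, _ = _forward_backward(model, X)
    return gamma


def viterbi_decode(model: ProgressionHMM, X: np.ndarray) -> np.ndarray:
    """Maximum-probability allowed state path; ties resolved toward the lower
    state index at every step of the backward trace."""
    logB = model.log_emission(X)
    T, K = logB.shape
    logA = _log_A(model)
    with np.errstate(divide="ignore"):
        delta = np.where(model.pi > 0, np.log(np.maximum(model.pi, 1e-300)), LOG_EPS) + logB[0]
    back = np.zeros((T, K), dtype=int)
    for t in range(1, T):
        scores = delta[:, None] + logA  # prev x next
        back[t] = np.argmax(scores, axis=0)  # argmax takes the first (lowest) index
        delta = scores[back[t], np.arange(K)] + logB[t]
    path = np.empty(T, dtype=int)
    path[-1] = int(np.argmax(delta))
    for t in range(T - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


# ---------------------------------------------------------------------------
# fitting


def _sequences(dataset: LongitudinalDataset) -> tuple[list[np.ndarray], list[str]]:
    mats, ids = [], []
    for ind in dataset.individuals:
        try:
            _, X = to_visit_matrix(dataset, ind)
        except KeyError:
            continue
        mats.append(X)
        ids.append(ind)
    return mats, ids


#: block-boundary curvatures tried by the deterministic initializer: equal
#: blocks, front-loaded (short early states, as under geometric dwell) and
#: back-loaded.  The candidate with the best final likelihood wins.
INIT_CURVATURES = (1.0, 3.0, 1.0 / 3.0)


def _block_initializer(
    sequences: list[np.ndarray],
    K: int,
    mask: np.ndarray,
    var_floor: np.ndarray,
    curvature: float = 1.0,
) -> ProgressionHMM:
    """Deterministic moment initializer: split each sequence into K contiguous
    time blocks with boundaries at (i/K)**curvature and pool block moments
    across individuals."""
    d = sequences[0].shape[1]
    sums = np.zeros((K, d))
    sqsums = np.zeros((K, d))
    counts = np.zeros(K)
    fractions = (np.arange(K + 1) / K) ** curvature
    for X in sequences:
        edges = np.round(fractions * len(X)).astype(int)
        for k in range(K):
            block = X[edges[k]: edges[k + 1]]
            if len(block) == 0:
                continue
            sums[k] += block.sum(axis=0)
            sqsums[k] += (block**2).sum(axis=0)
            counts[k] += len(block)
    counts = np.maximum(counts, 1)
    M = sums / counts[:, None]
    V = np.maximum(sqsums / counts[:, None] - M**2, var_floor)
    pi = np.zeros(K)
    pi[0] = 1.0
    A = np.zeros((K, K))
    for k in range(K):
        allowed = np.flatnonzero(mask[k])
        if len(allowed) == 1:
            A[k, allowed[0]] = 1.0
        else:
            A[k, k] = 0.8
            others = allowed[allowed != k]
            A[k, others] = 0.2 / len(others)
    return ProgressionHMM(pi, A, M, V, mask=mask.copy())


def fit_baum_welch(
    dataset: LongitudinalDataset,
    config: AnalysisConfig | None = None,
    *,
    n_states: int | None = None,
    allow_skips: bool = False,
    tol: float = 1e-6,
    max_iter: int = 500,
    init: ProgressionHMM | None = None,
) -> FitResult:
    """Fit the progressive HMM to a cohort by Baum-Welch.

    The dataset is moved to the modelling scale (log2(x+1) unless the config
    turns that off) before fitting.  Initialization is deterministic (block
    moments per individual), so refits are reproducible without a seed.
    Variances are floored at 1e-6 of the per-metabolite pooled variance.
    """
    config = config or AnalysisConfig()
    K = n_states if n_states is not None else config.n_states
    work = modeling_values(dataset, config)
    sequences, _ = _sequences(work)
    return fit_baum_welch_sequences(
        sequences, K, allow_skips=allow_skips, tol=tol, max_iter=max_iter, init=init,
        metabolite_index=list(dataset.metabolite_index),
    )


def fit_baum_welch_sequences(
    sequences: list[np.ndarray],
    n_states: int,
    *,
    allow_skips: bool = False,
    tol: float = 1e-6,
    max_iter: int = 500,
    init: ProgressionHMM | None = None,
    metabolite_index: list[str] | None = None,
) -> FitResult:
    """Baum-Welch on pre-extracted visit matrices (one per individual)."""
    if not sequences:
        raise ValueError("no sequences to fit")
    K = n_states
    lengths = [len(X) for X in sequences]
    if K > max(lengths):
        raise ValueError(f"n_states={K} exceeds the longest visit sequence ({max(lengths)})")
    if init is None and sum(1 for L in lengths if L >= K) < 2:
        raise ValueError("need at least 2 individuals with >= n_states visits")
    mask = left_to_right_mask(K, allow_skips)
    stacked = np.vstack(sequences)
    var_floor = 1e-6 * np.maximum(stacked.var(axis=0), 1e-12)
    if init is not None:
        starts = [init]
    else:
        starts = [
            _block_initializer(sequences, K, mask, var_floor, c) for c in INIT_CURVATURES
        ]
    best: FitResult | None = None
    for start in starts:
        result = _run_em(
            sequences, start, mask, var_floor, tol, max_iter, metabolite_index
        )
        if best is None or result.loglik_trace[-1] > best.loglik_trace[-1]:
            best = result
    return best


def _run_em(
    sequences: list[np.ndarray],
    model: ProgressionHMM,
    mask: np.ndarray,
    var_floor: np.ndarray,
    tol: float,
    max_iter: int,
    metabolite_index: list[str] | None,
) -> FitResult:
    K = model.K
    trace: list[float] = []
    converged = False
    for it in range(max_iter):
        gamma_sum = np.zeros((K, model.d))
        gamma_tot = np.zeros(K)
        gamma0 = np.zeros(K)
        xi_tot = np.zeros((K, K))
        wsum = np.zeros((K, model.d))
        wsq = np.zeros((K, model.d))
        loglik = 0.0
        for X in sequences:
            gamma, xi_sum, ll = _forward_backward(model, X)
            loglik += ll
            gamma0 += gamma[0]
            gamma_tot += gamma.sum(axis=0)
            xi_tot += xi_sum
            wsum += gamma.T @ X
            wsq += gamma.T @ (X**2)
        if not np.isfinite(loglik):
            raise FloatingPointError(f"non-finite likelihood at iteration {it}")
        trace.append(loglik)

        pi = gamma0 / gamma0.sum()
        A = np.zeros((K, K))
        for k in range(K):
            row = xi_tot[k] * mask[k]
            total = row.sum()
            if total > 0:
                A[k] = row / total
            else:  # state never left (or never reached): keep it absorbing
                A[k, k] = 1.0
        denom = np.maximum(gamma_tot, 1e-12)[:, None]
        M = wsum / denom
        V = np.maximum(wsq / denom - M**2, var_floor)
        model = ProgressionHMM(pi, A, M, V, metabolite_index or [], mask=mask.copy())

        if len(trace) > 1:
            prev, cur = trace[-2], trace[-1]
            if abs(cur - prev) < tol * (abs(prev) + 1e-12):
                converged = True
                break
    return FitResult(model, np.array(trace), len(trace), converged)


# ---------------------------------------------------------------------------
# state alignment across refits


def align_states(model: ProgressionHMM, reference: ProgressionHMM) -> np.ndarray:
    """Permutation p with p[j] = state of ``model`` matched to reference state j.

    Greedy minimal Euclidean distance between emission-mean rows; ties toward
    the lower index.  Refits initialized at the reference rarely permute, so
    greedy matching is adequate and deterministic.
    """
    K = reference.K
    D = np.linalg.norm(reference.means[:, None, :] - model.means[None, :, :], axis=2)
    perm = np.full(K, -1)
    used_r, used_m = set(), set()
    flat = sorted(
        ((D[i, j], i, j) for i in range(K) for j in range(K)),
        key=lambda t: (t[0], t[1], t[2]),
    )
    for _, i, j in flat:
        if i in used_r or j in used_m:
            continue
        perm[i] = j
        used_r.add(i)
        used_m.add(j)
    return perm


def permute_states(model: ProgressionHMM, perm: np.ndarray) -> ProgressionHMM:
    """Relabel states by ``perm`` (new state j = old state perm[j]).

    Used to compare emission parameters across refits; the permuted
    transition matrix may not honour the progressive band, so the mask is
    recomputed from the permuted support.
    """
    A = model.A[np.ix_(perm, perm)]
    return ProgressionHMM(
        model.pi[perm], A, model.means[perm], model.variances[perm],
        list(model.metabolite_index), mask=A > -1,  # permissive mask
    )


# ---------------------------------------------------------------------------
# bootstrap machinery


def bootstrap_fit(
    dataset: LongitudinalDataset,
    config: AnalysisConfig,
    *,
    reference: FitResult | None = None,
    bootstrap_n: int | None = None,
    seed: int | None = None,
    max_iter: int = 100,
) -> tuple[list[ProgressionHMM], int]:
    """Nonparametric bootstrap of the fitted model.

    The resampling unit is the individual (the whole trajectory).  Each
    replicate is refit starting from the point estimate and its states are
    aligned back to it; replicates whose EM fails numerically are dropped and
    counted, never imputed.  Returns (aligned models, n_dropped).
    """
    B = bootstrap_n if bootstrap_n is not None else config.bootstrap_n
    rng = np.random.default_rng(config.seed if seed is None else seed)
    if reference is None:
        reference = fit_baum_welch(dataset, config)
    work = modeling_values(dataset, config)
    sequences, ids = _sequences(work)
    n = len(sequences)
    models: list[ProgressionHMM] = []
    dropped = 0
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        boot = [sequences[i] for i in idx]
        try:
            fit = fit_baum_welch_sequences(
                boot, reference.model.K, init=reference.model, max_iter=max_iter,
                metabolite_index=list(dataset.metabolite_index),
            )
        except (FloatingPointError, ValueError):
            dropped += 1
            continue
        perm = align_states(fit.model, reference.model)
        models.append(permute_states(fit.model, perm))
    return models, dropped


# ---------------------------------------------------------------------------
# occupancy curves


def occupancy_by_age(
    fit: FitResult,
    dataset: LongitudinalDataset,
    config: AnalysisConfig | None = None,
    *,
    age_bins: np.ndarray | None = None,
    bootstrap_n: int = 0,
    seed: int = 0,
) -> StateOccupancy:
    """Average posterior state probability per age bin for one cohort.

    Per bin: mean posterior over individuals with a visit falling in the bin
    (visit age is assigned to the nearest bin centre; the default grid is the
    native sampling grid).  Bootstrap (over individuals) percentile bands are
    attached when ``bootstrap_n`` > 0.  Empty bins come back as NaN rows, not
    zeros.
    """
    config = config or AnalysisConfig()
    work = modeling_values(dataset, config)
    per_ind: list[tuple[np.ndarray, np.ndarray]] = []  # (ages, gamma)
    for ind in work.individuals:
        try:
            ages, X = to_visit_matrix(work, ind)
        except KeyError:
            continue
        per_ind.append((ages, posterior_decode(fit.model, X)))
    if age_bins is None:
        age_bins = np.unique(np.concatenate([a for a, _ in per_ind]))
    age_bins = np.asarray(age_bins, dtype=float)

    def cohort_occupancy(items: Sequence[tuple[np.ndarray, np.ndarray]]) -> np.ndarray:
        K = fit.model.K
        acc = np.zeros((len(age_bins), K))
        cnt = np.zeros(len(age_bins))
        for ages, gamma in items:
            bins = np.abs(ages[:, None] - age_bins[None, :]).argmin(axis=1)
            for b, g in zip(bins, gamma):
                acc[b] += g
                cnt[b] += 1
        P = np.full((len(age_bins), K), np.nan)
        nz = cnt > 0
        P[nz] = acc[nz] / cnt[nz, None]
        return P

    P = cohort_occupancy(per_ind)
    lower = upper = None
    if bootstrap_n > 0:
        rng = np.random.default_rng(seed)
        reps = np.empty((bootstrap_n,) + P.shape)
        n = len(per_ind)
        for b in range(bootstrap_n):
            idx = rng.integers(0, n, size=n)
            reps[b] = cohort_occupancy([per_ind[i] for i in idx])
        with np.errstate(invalid="ignore"):
            lower = np.nanpercentile(reps, 2.5, axis=0)
            upper = np.nanpercentile(reps, 97.5, axis=0)
    return StateOccupancy(age_bins, P, lower, upper)


# ---------------------------------------------------------------------------
# between-group state differences


@dataclass
class StateDifferenceTable:
    """Per (state, metabolite) difference of emission means, progressor minus
    non-progressor, with a bootstrap confidence-band label per cell.

    ``labels`` values: '<1%' (zero outside the 99% interval), '1-10%' (zero
    outside the 90% interval), 'ns' otherwise.
    """

    metabolite_index: list[str]
    difference: np.ndarray  # K x d
    lower90: np.ndarray
    upper90: np.ndarray
    lower99: np.ndarray
    upper99: np.ndarray
    labels: np.ndarray  # K x d of str


def _symmetric_interval(
    reps: np.ndarray, point: np.ndarray, alpha: float, inflation: float
) -> tuple[np.ndarray, np.ndarray]:
    """Symmetric bootstrap band: point +/- the (1 - alpha) quantile of the
    centered absolute deviations, widened by the finite-sample ``inflation``
    (the bootstrap variance of mean-type statistics is biased low by
    (n - 1)/n)."""
    half = inflation * np.percentile(np.abs(reps - point[None]), 100 * (1 - alpha), axis=0)
    return point - half, point + half


def state_difference_profile(
    dataset: LongitudinalDataset,
    config: AnalysisConfig | None = None,
    *,
    bootstrap_n: int | None = None,
    seed: int | None = None,
    band_edges: tuple[float, float] = (0.01, 0.10),
    fits: tuple[FitResult, FitResult] | None = None,
) -> StateDifferenceTable:
    """Compare per-state emission means between progressors and non-progressors.

    Separate models are fitted per group; the point difference is
    M_P - M_NP per (state, metabolite).  Bands come from bootstrap refits
    (resampling individuals within group, restarting EM from the group point
    estimate, realigning states to it).  Band endpoints are symmetric
    quantiles of the centered bootstrap distribution with a small
    finite-sample inflation — plain percentile endpoints are mildly
    anti-conservative at cohort sizes of a few dozen.
    """
    config = config or AnalysisConfig()
    if band_edges[0] >= band_edges[1]:
        raise ValueError("band_edges must be sorted ascending")
    B = bootstrap_n if bootstrap_n is not None else config.bootstrap_n
    seed = config.seed if seed is None else seed
    ds_p = dataset.subset(dataset.individuals_in_group("progressor"))
    ds_np = dataset.subset(dataset.individuals_in_group("non-progressor"))
    if fits is None:
        fit_p = fit_baum_welch(ds_p, config)
        fit_np = fit_baum_welch(ds_np, config)
    else:
        fit_p, fit_np = fits
    diff = fit_p.model.means - fit_np.model.means

    boot_p, _ = bootstrap_fit(ds_p, config, reference=fit_p, bootstrap_n=B, seed=seed)
    boot_np, _ = bootstrap_fit(ds_np, config, reference=fit_np, bootstrap_n=B, seed=seed + 1)
    n_reps = min(len(boot_p), len(boot_np))
    reps = np.stack(
        [boot_p[i].means - boot_np[i].means for i in range(n_reps)], axis=0
    )
    n_p = len(ds_p.meta)
    n_np = len(ds_np.meta)
    n_h = 2.0 / (1.0 / n_p + 1.0 / n_np)  # harmonic mean of group sizes
    inflation = np.sqrt(n_h / (n_h - 1.0))
    inner, outer = band_edges  # e.g. 0.01 and 0.10 two-sided levels
    lo99, hi99 = _symmetric_interval(reps, diff, inner, inflation)
    lo90, hi90 = _symmetric_interval(reps, diff, outer, inflation)
    labels = np.full(diff.shape, "ns", dtype=object)
    labels[(lo90 > 0) | (hi90 < 0)] = "1-10%"
    labels[(lo99 > 0) | (hi99 < 0)] = "<1%"
    return StateDifferenceTable(
        list(dataset.metabolite_index), diff, lo90, hi90, lo99, hi99, labels.astype(str)
    )
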