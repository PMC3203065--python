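"""Cross-dataset row matching by dependency maximization.

Two data matrices X (Nx x dx) and Y (Ny x dy) measure related objects in
different feature spaces, so rows cannot be matched by distance directly.
Instead, projections Wx, Wy are learned that maximize the statistical
dependency (canonical correlation) between currently matched row pairs, rows
are re-matched in the shared projected subspace by optimal assignment, and
the two steps alternate until the matching stabilizes.

The dependency measure is linear canonical correlation analysis with ridge
regularization on both covariance blocks; the assignment step solves the
linear sum assignment problem (globally optimal, via scipy).  Unequal row
counts are allowed: the smaller side is fully matched.

At desk scale (tens of rows, tens of features) an unregularized or weakly
regularized CCA can reach near-perfect canonical correlations for an
*arbitrary* permutation, so the ridge default is deliberately strong
(0.1 x the mean diagonal covariance) — with it, the summed canonical
correlations cleanly separate correct from incorrect matchings.
Initialization matters for the same reason: candidate starting matchings are
built by aligning the two matrices' top-r left singular vectors (which span
the shared latent subspace) over all axis permutations and sign flips, each
refined by a rigid iterative-closest-point loop (orthogonal Procrustes +
assignment) before the full alternation starts.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh, svd
from scipy.optimize import linear_sum_assignment


#: ridge multiplier (of the mean diagonal covariance) used when none is given
DEFAULT_RIDGE_MULT = 0.1


@dataclass
class MatchResult:
    """Outcome of the alternating projection/assignment iteration.

    ``permutation[i]`` is the row of Y matched to row i of X (full when
    Nx <= Ny).  ``objective_trace`` records the summed canonical
    correlations after each projection fit.
    """

    permutation: np.ndarray
    Wx: np.ndarray
    Wy: np.ndarray
    canonical_correlations: np.ndarray
    objective_trace: np.ndarray
    converged: bool
    n_iter: int


def _center(M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = M.mean(axis=0)
    return M - mu, mu


def _inv_sqrt(C: np.ndarray) -> np.ndarray:
    w, U = eigh(C)
    if np.any(w <= 0):
        raise np.linalg.LinAlgError(
            "singular covariance; pass ridge > 0 to regularize"
        )
    return U @ np.diag(1.0 / np.sqrt(w)) @ U.T


def fit_dependency_projection(
    X: np.ndarray,
    Y: np.ndarray,
    matching: np.ndarray,
    rank: int,
    ridge: float | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Ridge-regularized CCA on the matched row pairs (X[i], Y[matching[i]]).

    Returns (Wx, Wy, canonical_correlations); correlations are clipped to
    [0, 1] and non-increasing.  The sign of each component is fixed by making
    the largest-magnitude loading of Wx positive, so the solution is
    deterministic.  Default ridge: 1e-3 times the mean diagonal covariance of
    each block.
    """
    matching = np.asarray(matching)
    pairs = np.flatnonzero(matching >= 0)
    if len(pairs) < rank + 1:
        raise ValueError("need at least rank + 1 matched pairs")
    Xm, _ = _center(np.asarray(X, dtype=float)[pairs])
    Ym, _ = _center(np.asarray(Y, dtype=float)[matching[pairs]])
    n = len(pairs)
    Cxx = Xm.T @ Xm / n
    Cyy = Ym.T @ Ym / n
    Cxy = Xm.T @ Ym / n
    rx = DEFAULT_RIDGE_MULT * np.mean(np.diag(Cxx)) if ridge is None else ridge
    ry = DEFAULT_RIDGE_MULT * np.mean(np.diag(Cyy)) if ridge is None else ridge
    Cxx = Cxx + rx * np.eye(Cxx.shape[0])
    Cyy = Cyy + ry * np.eye(Cyy.shape[0])
    Kx = _inv_sqrt(Cxx)
    Ky = _inv_sqrt(Cyy)
    U, s, Vt = svd(Kx @ Cxy @ Ky)
    r = min(rank, len(s))
    corr = np.clip(s[:r], 0.0, 1.0)
    Wx = Kx @ U[:, :r]
    Wy = Ky @ Vt.T[:, :r]
    for j in range(r):  # deterministic sign convention
        i = int(np.argmax(np.abs(Wx[:, j])))
        if Wx[i, j] < 0:
            Wx[:, j] *= -1
            Wy[:, j] *= -1
    return Wx, Wy, corr


def match_rows(X_proj: np.ndarray, Y_proj: np.ndarray) -> np.ndarray:
    """Globally optimal assignment minimizing total squared projected distance.

    Returns an array p of length Nx with p[i] the matched row of Y_proj, or
    -1 for X rows left unmatched when Nx > Ny.
    """
    X_proj = np.atleast_2d(X_proj)
    Y_proj = np.atleast_2d(Y_proj)
    if X_proj.size == 0 or Y_proj.size == 0:
        raise ValueError("empty projection matrix")
    if X_proj.shape[1] != Y_proj.shape[1]:
        raise ValueError("projections must share the subspace dimension")
    cost = (
        np.sum(X_proj**2, axis=1)[:, None]
        + np.sum(Y_proj**2, axis=1)[None, :]
        - 2.0 * X_proj @ Y_proj.T
    )
    rows, cols = linear_sum_assignment(cost)
    p = np.full(len(X_proj), -1, dtype=int)
    p[rows] = cols
    return p


def _alignment_inits(
    X: np.ndarray, Y: np.ndarray, rank: int, max_enumeration_rank: int = 4
) -> list[np.ndarray]:
    """Candidate starting matchings from latent-subspace registration.

    The top-r left singular vectors of each (centered) matrix span its
    dominant sample-space subspace; when the matrices share latent factors
    these subspaces agree up to an orthogonal transform.  Axis permutations
    and sign flips are enumerated (r! * 2^r options, so r is capped at
    ``max_enumeration_rank``), each refined by iterative closest point:
    alternate the optimal assignment with the orthogonal Procrustes rotation
    of Y's subspace onto X's.  Candidates are deduplicated and ordered by
    registration cost.
    """
    Xc, _ = _center(X)
    Yc, _ = _center(Y)
    r = min(rank, max_enumeration_rank, min(Xc.shape) - 1, min(Yc.shape) - 1)
    r = max(r, 1)
    Ux = svd(Xc, full_matrices=False)[0][:, :r]
    Uy = svd(Yc, full_matrices=False)[0][:, :r]

    cands: dict[tuple, float] = {}

    def icp(p: np.ndarray) -> None:
        Q = np.eye(r)
        for _ in range(30):  # rigid ICP refinement
            U_, _, Vt_ = svd(Uy[p[p >= 0]].T @ Ux[p >= 0])
            Q = U_ @ Vt_
            p_new = match_rows(Ux, Uy @ Q)
            if np.array_equal(p_new, p):
                break
            p = p_new
        cost = float(np.sum((Ux[p >= 0] - (Uy @ Q)[p[p >= 0]]) ** 2))
        key = tuple(p)
        if key not in cands or cost < cands[key]:
            cands[key] = cost

    # axis permutations and sign flips of the singular components
    for axes in itertools.permutations(range(r)):
        for signs in itertools.product((1.0, -1.0), repeat=r):
            icp(match_rows(Ux, Uy[:, list(axes)] * np.array(signs)))
    # rotation-invariant start: pair rows by rank of whitened-row norm
    nx = np.argsort(np.linalg.norm(Ux, axis=1), kind="stable")
    ny = np.argsort(np.linalg.norm(Uy, axis=1), kind="stable")
    m = min(len(nx), len(ny))
    p_norm = np.full(len(Ux), -1, dtype=int)
    p_norm[nx[:m]] = ny[:m]
    icp(p_norm)
    # seeded random rotations to cover the remaining orientation space
    rot_rng = np.random.default_rng(0)
    for _ in range(24):
        Q0 = np.linalg.qr(rot_rng.standard_normal((r, r)))[0]
        icp(match_rows(Ux, Uy @ Q0))
    ordered = sorted(cands.items(), key=lambda kv: kv[1])
    return [np.array(p, dtype=int) for p, _ in ordered]


def iterate_match(
    X: np.ndarray,
    Y: np.ndarray,
    rank: int = 3,
    ridge: float | None = None,
    max_iter: int = 50,
    n_restarts: int = 48,
    seed: int = 0,
) -> MatchResult:
    """Alternate projection fitting and optimal assignment until the matching
    is a fixed point.

    Starts are the subspace-registration candidates of
    :func:`_alignment_inits`, topped up with seeded random matchings if
    fewer than ``n_restarts`` unique candidates exist.  The iterate with the
    largest dependency objective (sum of canonical correlations) across all
    restarts is returned; ``converged`` reports whether that restart reached
    a fixed point.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    rng = np.random.default_rng(seed)
    n = min(len(X), len(Y))

    inits = _alignment_inits(X, Y, rank)
    while len(inits) < max(n_restarts, 1):
        p = np.full(len(X), -1, dtype=int)
        rows = rng.permutation(len(X))[:n]
        p[rows] = rng.permutation(len(Y))[:n]
        inits.append(p)

    best: MatchResult | None = None
    for p0 in inits[: max(n_restarts, 1)]:
        p = p0.copy()
        trace: list[float] = []
        best_local: tuple[float, np.ndarray, np.ndarray, np.ndarray, np.ndarray] | None = None
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            Wx, Wy, corr = fit_dependency_projection(X, Y, p, rank, ridge)
            obj = float(corr.sum())
            trace.append(obj)
            if best_local is None or obj > best_local[0]:
                best_local = (obj, p.copy(), Wx, Wy, corr)
            Xc, _ = _center(X)
            Yc, _ = _center(Y)
            p_new = match_rows(Xc @ Wx, Yc @ Wy)
            if np.array_equal(p_new, p):
                converged = True
                break
            p = p_new
        obj, p_best, Wx, Wy, corr = best_local
        result = MatchResult(p_best, Wx, Wy, corr, np.array(trace), converged, it)
        if best is None or obj > float(best.canonical_correlations.sum()):
            best = result
    return best
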