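"""Functional distances and nonmetric multidimensional scaling.

Dissimilarity between enzyme product profiles is Bray-Curtis,
``sum|p_i - q_i| / sum(p_i + q_i)`` over a name-union, zero-filled product
vocabulary; on unit-sum compositions this equals half the L1 distance.
The "functional distance" of a variant from its ancestor normalises the
variant-ancestor Bray-Curtis score by the score between the ancestor and a
reference enzyme producing 100% of the focal product (isopimaradiene by
default), so a distance of 1 means "as far from the ancestor as a pure
focal-product producer".

The NMDS embedding minimises Kruskal stress-1,
``sqrt(sum (d_ij - dhat_ij)^2 / sum d_ij^2)``, where d are configuration
distances and dhat are disparities from monotone (pool-adjacent-violators)
regression on the ranked dissimilarities.  Optimisation alternates
isotonic fits with Guttman-transform configuration updates (SMACOF-style),
accepting only stress-decreasing steps, over several random starts plus a
classical-scaling start; everything is driven by one seed sequence so the
result is bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression

from .errors import InputError, UndefinedDistanceError
from .profiling import ProductProfile, aligned_compositions

logger = logging.getLogger(__name__)

#: Default focal product for the pure reference profile.
FOCAL_PRODUCT = "isopimaradiene"


# ---------------------------------------------------------------------------
# Dissimilarities
# ---------------------------------------------------------------------------

def _as_vector_pair(p, q):
    """Align two profiles/dicts/arrays onto a shared zero-filled vocabulary."""
    if isinstance(p, ProductProfile) or isinstance(q, ProductProfile):
        p = p.as_dict() if isinstance(p, ProductProfile) else dict(p)
        q = q.as_dict() if isinstance(q, ProductProfile) else dict(q)
    if isinstance(p, dict) and isinstance(q, dict):
        vocab = tuple(dict.fromkeys(list(p) + list(q)))
        pv = np.array([p.get(k, 0.0) for k in vocab], float)
        qv = np.array([q.get(k, 0.0) for k in vocab], float)
        return pv, qv
    pv, qv = np.asarray(p, float), np.asarray(q, float)
    if pv.shape != qv.shape:
        raise InputError("composition vectors have different shapes; pass "
                         "dicts or profiles to align by product name")
    return pv, qv


def bray_curtis(p, q) -> float:
    """Bray-Curtis dissimilarity between nonnegative abundance vectors."""
    pv, qv = _as_vector_pair(p, q)
    if np.any(pv < 0) or np.any(qv < 0):
        raise InputError("abundances must be nonnegative")
    denom = (pv + qv).sum()
    if denom == 0:
        raise UndefinedDistanceError(
            "Bray-Curtis is undefined for two all-zero profiles "
            "(inactive enzymes are excluded upstream)")
    return float(np.abs(pv - qv).sum() / denom)


def functional_distance(variant, ancestor, reference=None) -> float:
    """Variant-ancestor Bray-Curtis normalised by reference-ancestor Bray-Curtis.

    ``reference`` defaults to a pure 100% isopimaradiene producer.
    """
    if reference is None:
        reference = {FOCAL_PRODUCT: 1.0}
    denom = bray_curtis(reference, ancestor)
    if denom == 0:
        raise UndefinedDistanceError(
            "reference profile is identical to the ancestor; "
            "normalisation is undefined")
    return bray_curtis(variant, ancestor) / denom


@dataclass
class DistanceMatrix:
    """Symmetric Bray-Curtis dissimilarities with zero diagonal."""

    ids: tuple
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, float)
        n = len(self.ids)
        if v.shape != (n, n):
            raise InputError("distance matrix shape does not match ids")
        if not np.allclose(v, v.T, atol=1e-12):
            raise InputError("distance matrix must be symmetric")
        if not np.all(np.diag(v) == 0):
            raise InputError("distance matrix diagonal must be exactly 0")
        if np.any(v < 0) or np.any(v > 1 + 1e-12):
            raise InputError("Bray-Curtis entries must lie in [0, 1]")
        self.values = v
        self.ids = tuple(self.ids)

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.ids), columns=list(self.ids))

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DistanceMatrix":
        return cls(tuple(df.index), df.to_numpy(float))


def distance_matrix(profiles) -> DistanceMatrix:
    """Pairwise Bray-Curtis over the name-union vocabulary of active profiles.

    Inactive profiles are excluded with a logged notice; at least three
    active profiles are required.
    """
    if isinstance(profiles, dict):
        profiles = list(profiles.values())
    active = [p for p in profiles if p.active]
    dropped = [p.enzyme for p in profiles if not p.active]
    if dropped:
        logger.info("excluding inactive enzymes from distance matrix: %s",
                    ", ".join(str(d) for d in dropped))
    if len(active) < 3:
        raise InputError(f"need >= 3 active profiles, got {len(active)}")
    _, mat = aligned_compositions(active)
    n = len(active)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = bray_curtis(mat[i], mat[j])
    return DistanceMatrix(tuple(p.enzyme for p in active), out)


# ---------------------------------------------------------------------------
# Nonmetric MDS
# ---------------------------------------------------------------------------

def isotonic_disparities(dissimilarities, distances) -> np.ndarray:
    """Least-squares monotone fit of distances against dissimilarity rank.

    Pool-adjacent-violators on the configuration distances ordered by
    dissimilarity; ties in the dissimilarities are broken stably (the
    primary, weak-tie approach: tied dissimilarities may receive different
    disparities).  Output is nondecreasing in dissimilarity rank.
    """
    diss = np.asarray(dissimilarities, float)
    dist = np.asarray(distances, float)
    if diss.shape != dist.shape:
        raise InputError("dissimilarities and distances must have equal length")
    order = np.argsort(diss, kind="stable")
    ir = IsotonicRegression(increasing=True)
    fitted = ir.fit_transform(np.arange(len(diss)), dist[order])
    out = np.empty_like(dist)
    out[order] = fitted
    return out


def stress1(dissimilarities, coords) -> float:
    """Kruskal stress-1 of a configuration against target dissimilarities."""
    d = pdist(np.asarray(coords, float))
    dhat = isotonic_disparities(dissimilarities, d)
    denom = (d ** 2).sum()
    if denom == 0:
        return np.inf
    return float(np.sqrt(((d - dhat) ** 2).sum() / denom))


@dataclass
class Embedding:
    """NMDS configuration with its Kruskal stress-1 and provenance."""

    ids: tuple
    coords: np.ndarray  # (n, dims), centred at the origin
    stress: float
    n_starts: int
    seed: int | None
    best_start: int
    converged: bool
    n_iter: int
    stress_history: tuple = ()

    def to_frame(self) -> pd.DataFrame:
        dims = self.coords.shape[1]
        df = pd.DataFrame(self.coords, columns=[f"axis{i+1}" for i in range(dims)])
        df.insert(0, "id", list(self.ids))
        return df


def _classical_scaling(D: np.ndarray, dims: int) -> np.ndarray:
    """Torgerson double-centring start configuration."""
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    evals, evecs = np.linalg.eigh(B)
    idx = np.argsort(evals)[::-1][:dims]
    lam = np.clip(evals[idx], 0.0, None)
    return evecs[:, idx] * np.sqrt(lam)[None, :]


def _smacof_single(delta: np.ndarray, n: int, dims: int, X0: np.ndarray,
                   max_iter: int, tol: float):
    """One optimisation run: isotonic fit alternated with Guttman updates.

    Only stress-decreasing updates are accepted, so the stress trace is
    non-increasing by construction; stalls terminate the run.
    """
    iu = np.triu_indices(n, 1)
    X = X0.copy()
    d = pdist(X)
    dhat = isotonic_disparities(delta, d)
    denom = (d ** 2).sum()
    stress = np.sqrt(((d - dhat) ** 2).sum() / denom) if denom > 0 else np.inf
    history = [stress]
    converged = False
    for _ in range(max_iter):
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(d > 0, dhat / d, 0.0)
        B = np.zeros((n, n))
        B[iu] = -ratio
        B += B.T
        np.fill_diagonal(B, -B.sum(axis=1))
        Xn = B @ X / n
        dn = pdist(Xn)
        dhat_n = isotonic_disparities(delta, dn)
        denom_n = (dn ** 2).sum()
        stress_n = np.sqrt(((dn - dhat_n) ** 2).sum() / denom_n) if denom_n > 0 else np.inf
        if not stress_n < stress:
            converged = True  # no improving step exists: local optimum
            break
        X, d, dhat = Xn, dn, dhat_n
        improvement = stress - stress_n
        stress = stress_n
        history.append(stress)
        if improvement < tol:
            converged = True
            break
    return X, stress, history, converged


def nmds(dm: DistanceMatrix, dims: int = 3, n_starts: int = 20,
         max_iter: int = 500, tol: float = 1e-7,
         seed: int | None = 0) -> Embedding:
    """Nonmetric MDS of a dissimilarity matrix by Kruskal stress-1.

    Runs one classical-scaling start plus ``n_starts - 1`` random starts
    (all drawn from a single seed sequence) and returns the lowest-stress
    configuration, centred at the origin.
    """
    n = len(dm.ids)
    if dims >= n:
        raise InputError(f"dims ({dims}) must be smaller than the number of "
                         f"points ({n})")
    if n_starts < 1:
        raise InputError("n_starts must be >= 1")
    delta = dm.condensed()
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(max(n_starts - 1, 0))
    best = None
    for start in range(n_starts):
        if start == 0:
            X0 = _classical_scaling(dm.values, dims)
            if np.allclose(X0, 0):  # degenerate double-centring; fall back
                X0 = np.random.default_rng(ss.generate_state(1)[0]).standard_normal((n, dims))
        else:
            rng = np.random.default_rng(children[start - 1])
            X0 = rng.standard_normal((n, dims))
        X, stress, history, converged = _smacof_single(delta, n, dims, X0,
                                                       max_iter, tol)
        if best is None or stress < best[1]:
            best = (X, stress, history, converged, start)
    X, stress, history, converged, start = best
    X = X - X.mean(axis=0, keepdims=True)
    return Embedding(ids=dm.ids, coords=X, stress=float(stress),
                     n_starts=n_starts, seed=seed, best_start=start,
                     converged=converged, n_iter=len(history) - 1,
                     stress_history=tuple(history))
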