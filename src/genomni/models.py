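"""Latent-position models and samplers for collections of correlated RDPGs.

A random dot product graph (RDPG) places a latent vector at every vertex and
connects vertex pairs independently with probability equal to the inner
product of their latent vectors.  This module provides

* finite-mixture latent distributions (stochastic blockmodels are the special
  case of finitely many atoms),
* pairwise edge-correlation structures ``R`` together with the two
  constructive families for which exact samplers exist — the forward
  (sequential) chain, where correlation propagates through consecutive
  graphs, and the single-generator model, where every graph is a noisy
  re-sample of one background graph,
* conditional-Bernoulli samplers realising those correlation structures
  while keeping every graph marginally RDPG-distributed.

All randomness flows through :class:`numpy.random.Generator` streams spawned
from a single root seed, so a collection of any size is reproducible from one
integer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "LatentDistribution",
    "LatentPositions",
    "CorrelationMatrix",
    "GraphCollection",
    "build_forward_R",
    "build_generator_R",
    "sample_latent",
    "sample_rdpg",
    "sample_forward_chain",
    "sample_generator_collection",
    "sample_correlated_pair",
]

_WEIGHT_TOL = 1e-12
_PSD_TOL = 1e-10


def _as_rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class LatentDistribution:
    """Finite mixture of point masses in ``d`` dimensions.

    Parameters
    ----------
    atoms
        ``(K, d)`` array, one latent position per mixture component.
    weights
        Probability vector of length ``K``.
    """

    atoms: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        atoms = np.atleast_2d(np.asarray(self.atoms, dtype=float))
        weights = np.asarray(self.weights, dtype=float).ravel()
        object.__setattr__(self, "atoms", atoms)
        object.__setattr__(self, "weights", weights)
        if atoms.shape[0] != weights.shape[0]:
            raise ValueError("number of atoms must match number of weights")
        if np.any(weights < 0) or abs(weights.sum() - 1.0) > _WEIGHT_TOL:
            raise ValueError("weights must be nonnegative and sum to 1")
        gram = atoms @ atoms.T
        if gram.min() < -_WEIGHT_TOL or gram.max() > 1 + 1e-9:
            raise ValueError(
                "pairwise inner products of atoms must lie in [0, 1]; "
                f"found range [{gram.min():.3g}, {gram.max():.3g}]"
            )

    @property
    def n_components(self) -> int:
        return self.atoms.shape[0]

    @property
    def d(self) -> int:
        return self.atoms.shape[1]

    @classmethod
    def from_gram(
        cls,
        B: np.ndarray,
        weights: Sequence[float] | None = None,
        rank_tol: float = 1e-10,
    ) -> "LatentDistribution":
        """Build a blockmodel mixture from a block connection-probability
        (Gram) matrix ``B``.

        ``B`` is factored via its eigendecomposition ``B = V Λ Vᵀ`` and the
        atoms are the rows of ``V Λ^{1/2}``.  Any factorization is equivalent
        under the model's rotational non-identifiability.
        """
        B = np.asarray(B, dtype=float)
        if B.ndim != 2 or B.shape[0] != B.shape[1]:
            raise ValueError("B must be square")
        if not np.allclose(B, B.T, atol=1e-12):
            raise ValueError("B must be symmetric")
        evals, evecs = np.linalg.eigh(B)
        if evals.min() < -1e-8:
            raise ValueError("B must be positive semidefinite")
        keep = evals > rank_tol
        if not keep.any():
            raise ValueError("B has no positive eigenvalues")
        atoms = evecs[:, keep] * np.sqrt(evals[keep])
        K = B.shape[0]
        w = np.full(K, 1.0 / K) if weights is None else np.asarray(weights, float)
        return cls(atoms=atoms, weights=w)


@dataclass(frozen=True)
class LatentPositions:
    """An ``n × d`` matrix of latent positions and the derived edge
    probabilities ``P = X Xᵀ``.

    ``components`` records, when the positions were sampled from a finite
    mixture, the atom index of each row (used to track community labels).
    """

    X: np.ndarray
    components: np.ndarray | None = field(default=None)

    def __post_init__(self):
        X = np.atleast_2d(np.asarray(self.X, dtype=float))
        object.__setattr__(self, "X", X)
        P = X @ X.T
        if P.min() < -1e-9 or P.max() > 1 + 1e-9:
            raise ValueError("entries of X Xᵀ must lie in [0, 1]")
        if self.components is not None:
            comp = np.asarray(self.components, dtype=int)
            if comp.shape[0] != X.shape[0]:
                raise ValueError("components must have one entry per row of X")
            object.__setattr__(self, "components", comp)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]

    @property
    def P(self) -> np.ndarray:
        return np.clip(self.X @ self.X.T, 0.0, 1.0)


@dataclass(frozen=True)
class CorrelationMatrix:
    """Symmetric ``m × m`` pairwise edge-correlation structure with unit
    diagonal and nonnegative off-diagonal entries."""

    R: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.R, dtype=float)
        object.__setattr__(self, "R", R)
        if R.ndim != 2 or R.shape[0] != R.shape[1]:
            raise ValueError("R must be square")
        if not np.allclose(R, R.T, atol=1e-12):
            raise ValueError("R must be symmetric")
        if not np.allclose(np.diag(R), 1.0, atol=1e-12):
            raise ValueError("R must have unit diagonal")
        off = R[~np.eye(R.shape[0], dtype=bool)]
        if off.size and (off.min() < 0 or off.max() > 1 + 1e-12):
            raise ValueError("off-diagonal correlations must lie in [0, 1]")

    @property
    def m(self) -> int:
        return self.R.shape[0]

    def is_psd(self, tol: float = _PSD_TOL) -> bool:
        return np.linalg.eigvalsh(self.R).min() >= -tol


@dataclass(frozen=True)
class GraphCollection:
    """``m`` symmetric hollow binary adjacency matrices on a common aligned
    vertex set, stored as an ``(m, n, n)`` array."""

    adjacency: np.ndarray

    def __post_init__(self):
        A = np.asarray(self.adjacency)
        if A.ndim == 2:
            A = A[None]
        if A.ndim != 3 or A.shape[1] != A.shape[2]:
            raise ValueError("adjacency must be (m, n, n)")
        A = A.astype(np.int8, copy=False)
        for k in range(A.shape[0]):
            _check_adjacency(A[k])
        object.__setattr__(self, "adjacency", A)

    @property
    def m(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n(self) -> int:
        return self.adjacency.shape[1]

    @property
    def graphs(self) -> list[np.ndarray]:
        return [self.adjacency[k] for k in range(self.m)]

    def __getitem__(self, k: int) -> np.ndarray:
        return self.adjacency[k]

    def mean_adjacency(self) -> np.ndarray:
        return self.adjacency.mean(axis=0)


def _check_adjacency(A: np.ndarray) -> None:
    if not np.array_equal(A, A.T):
        raise ValueError("adjacency must be symmetric")
    if np.any(np.diag(A) != 0):
        raise ValueError("adjacency must be hollow")
    vals = np.unique(A)
    if not np.isin(vals, [0, 1]).all():
        raise ValueError("adjacency entries must be 0/1")


# ---------------------------------------------------------------------------
# Correlation-structure builders
# ---------------------------------------------------------------------------

def build_forward_R(rho_steps: Sequence[float]) -> CorrelationMatrix:
    """Correlation matrix of the forward (sequential) chain.

    ``rho_steps[k]`` is the step correlation between consecutive graphs
    ``k`` and ``k+1``; the correlation between graphs ``k1 < k2`` is the
    product of the intervening step correlations.
    """
    steps = np.asarray(rho_steps, dtype=float).ravel()
    if steps.size == 0:
        raise ValueError("rho_steps must be nonempty")
    if steps.min() < 0 or steps.max() > 1:
        raise ValueError("step correlations must lie in [0, 1]")
    m = steps.size + 1
    R = np.eye(m)
    for k1 in range(m):
        for k2 in range(k1 + 1, m):
            R[k1, k2] = R[k2, k1] = np.prod(steps[k1:k2])
    return CorrelationMatrix(R)


def build_generator_R(nu: Sequence[float]) -> CorrelationMatrix:
    """Correlation matrix of the single-generator model:
    ``R = ν νᵀ + diag(I − ν νᵀ)``, i.e. ``ρ_{k1,k2} = ν_{k1} ν_{k2}``."""
    v = np.asarray(nu, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("nu must be nonempty")
    if v.min() < 0 or v.max() > 1:
        raise ValueError("generator entries must lie in [0, 1]")
    R = np.outer(v, v)
    np.fill_diagonal(R, 1.0)
    return CorrelationMatrix(R)


# ---------------------------------------------------------------------------
# Samplers
# ---------------------------------------------------------------------------

def sample_latent(
    F: LatentDistribution,
    n: int,
    seed: int | np.random.Generator | None = None,
    deterministic_blocks: bool = False,
) -> LatentPositions:
    """Draw ``n`` latent positions i.i.d. from the mixture ``F``.

    With ``deterministic_blocks=True`` the component memberships are fixed
    rather than sampled: component ``k`` receives a contiguous block of
    ``round(n · w_k)`` vertices (largest-remainder apportionment), with the
    first block assigned to atom 0.  This pins vertex 0 to the first atom,
    which is convenient when tracking the estimate of a known latent
    position across Monte-Carlo replicates.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _as_rng(seed)
    if deterministic_blocks:
        counts = np.floor(F.weights * n).astype(int)
        rem = n - counts.sum()
        order = np.argsort(-(F.weights * n - counts))
        counts[order[:rem]] += 1
        comp = np.repeat(np.arange(F.n_components), counts)
    else:
        comp = rng.choice(F.n_components, size=n, p=F.weights)
    return LatentPositions(X=F.atoms[comp], components=comp)


def _bernoulli_symmetric(P: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    n = P.shape[0]
    iu = np.triu_indices(n, k=1)
    draws = (rng.random(iu[0].size) < P[iu]).astype(np.int8)
    A = np.zeros((n, n), dtype=np.int8)
    A[iu] = draws
    return A + A.T


def sample_rdpg(
    X: LatentPositions, seed: int | np.random.Generator | None = None
) -> GraphCollection:
    """Sample one graph: upper-triangle entries independent Bernoulli(P_ij)."""
    rng = _as_rng(seed)
    P = X.P
    return GraphCollection(_bernoulli_symmetric(P, rng)[None])


def _resample_conditional(
    A_prev: np.ndarray, P: np.ndarray, rho: float, rng: np.random.Generator
) -> np.ndarray:
    """One conditional step: given the previous graph, each edge is redrawn
    Bernoulli(P + ρ(1−P)) where the previous edge is present and
    Bernoulli(P(1−ρ)) where it is absent.  Preserves the RDPG marginal and
    yields per-edge correlation ρ with the conditioning graph."""
    n = P.shape[0]
    iu = np.triu_indices(n, k=1)
    p = P[iu]
    prev = A_prev[iu].astype(bool)
    prob = np.where(prev, p + rho * (1.0 - p), p * (1.0 - rho))
    draws = (rng.random(p.size) < prob).astype(np.int8)
    A = np.zeros((n, n), dtype=np.int8)
    A[iu] = draws
    return A + A.T


def sample_forward_chain(
    X: LatentPositions,
    rho_steps: Sequence[float],
    seed: int | np.random.Generator | None = None,
) -> GraphCollection:
    """Sample a forward (sequential) chain of ``m = len(rho_steps) + 1``
    graphs with prescribed consecutive step correlations."""
    steps = np.asarray(rho_steps, dtype=float).ravel()
    if steps.size == 0:
        raise ValueError("rho_steps must be nonempty")
    if steps.min() < 0 or steps.max() > 1:
        raise ValueError("step correlations must lie in [0, 1]")
    root = _as_rng(seed)
    streams = root.spawn(steps.size + 1)
    P = X.P
    graphs = [_bernoulli_symmetric(P, streams[0])]
    for ell, rho in enumerate(steps):
        graphs.append(_resample_conditional(graphs[-1], P, rho, streams[ell + 1]))
    return GraphCollection(np.stack(graphs))


def sample_generator_collection(
    X: LatentPositions,
    nu: Sequence[float],
    seed: int | np.random.Generator | None = None,
) -> tuple[np.ndarray, GraphCollection]:
    """Sample the single-generator model: a background graph ``A^(0)`` and
    ``m`` children, child ``ℓ`` re-sampled edgewise from ``A^(0)`` with
    retention parameter ``ν_ℓ``.  Cross-child correlation is ``ν_{ℓ1}ν_{ℓ2}``.

    Returns ``(A0, children)``.
    """
    v = np.asarray(nu, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("nu must be nonempty")
    if v.min() < 0 or v.max() > 1:
        raise ValueError("generator entries must lie in [0, 1]")
    root = _as_rng(seed)
    streams = root.spawn(v.size + 1)
    P = X.P
    A0 = _bernoulli_symmetric(P, streams[0])
    children = [
        _resample_conditional(A0, P, rho, streams[ell + 1])
        for ell, rho in enumerate(v)
    ]
    return A0, GraphCollection(np.stack(children))


def sample_correlated_pair(
    X: LatentPositions,
    rho: float,
    seed: int | np.random.Generator | None = None,
) -> GraphCollection:
    """Sample a pair of graphs with per-edge correlation ``rho`` (a single
    forward step)."""
    if not 0 <= rho <= 1:
        raise ValueError("rho must lie in [0, 1]")
    return sample_forward_chain(X, [rho], seed=seed)
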