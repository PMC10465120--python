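"""Empirical estimation of edge probabilities and cross-graph correlation.

Two edge-level estimators are provided: a plug-in estimator that
standardises each edge indicator by an estimated (or known) Bernoulli
probability matrix, and the plain Pearson correlation over the vectorised
upper triangles (exact for homogeneous Erdős–Rényi pairs).  A Monte-Carlo
driver measures the correlation realised between embedded latent-position
estimates, the empirical counterpart of the limiting correlation calculus
in :mod:`genomni.theory`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .models import (
    GraphCollection,
    LatentDistribution,
    sample_correlated_pair,
    sample_forward_chain,
    sample_generator_collection,
    sample_latent,
    sample_rdpg,
)
from .omnibus import (
    OmnibusCoefficients,
    ase,
    omni_embed,
    procrustes_align,
)

__all__ = [
    "TrimmedProbabilityEstimate",
    "estimate_edge_probability",
    "plugin_edge_correlation",
    "pearson_graph_correlation",
    "embedded_correlation_mc",
    "aligned_difference_covariance_mc",
    "EmbeddedCorrelationResult",
]


@dataclass(frozen=True)
class TrimmedProbabilityEstimate:
    """Spectral edge-probability estimate with entries trimmed to
    ``[ε, 1−ε]`` so that Bernoulli variances are bounded away from zero."""

    Phat: np.ndarray
    epsilon: float

    def __post_init__(self):
        P = np.asarray(self.Phat, dtype=float)
        object.__setattr__(self, "Phat", P)
        eps = self.epsilon
        if P.min() < eps - 1e-12 or P.max() > 1 - eps + 1e-12:
            raise ValueError("entries must lie in [ε, 1−ε]")
        if not np.allclose(P, P.T, atol=1e-10):
            raise ValueError("Phat must be symmetric")


def estimate_edge_probability(
    A: np.ndarray, d: int, epsilon: float = 1e-4
) -> TrimmedProbabilityEstimate:
    """Estimate the edge-probability matrix of one graph from its spectral
    embedding: ``P̃ = X̂ D̂ X̂ᵀ`` where ``X̂`` is the ``d``-dimensional ASE and
    ``D̂`` carries the signs of the top-``d`` eigenvalues (by magnitude);
    entries are then trimmed to ``[ε, 1−ε]``."""
    if not 0 < epsilon < 0.5:
        raise ValueError("epsilon must lie in (0, 1/2)")
    A = np.asarray(A, dtype=float)
    n = A.shape[0]
    if n <= 400 or d >= n - 1:
        evals, evecs = np.linalg.eigh(A)
    else:
        import scipy.sparse.linalg

        evals, evecs = scipy.sparse.linalg.eigsh(A, k=d, which="LM")
    order = np.argsort(-np.abs(evals), kind="stable")[:d]
    lam = evals[order]
    U = evecs[:, order]
    Ptilde = (U * lam) @ U.T
    Phat = np.clip(Ptilde, epsilon, 1.0 - epsilon)
    Phat = (Phat + Phat.T) / 2.0
    return TrimmedProbabilityEstimate(Phat=Phat, epsilon=epsilon)


def plugin_edge_correlation(
    A1: np.ndarray, A2: np.ndarray, P1hat: np.ndarray, P2hat: np.ndarray
) -> float:
    """Plug-in estimator of the per-edge correlation between two graphs on
    aligned vertices:

    ``ρ̂ = (2/(n(n−1))) Σ_{i<j} (A_ij − P̂_ij)(A'_ij − P̂'_ij)
    / [P̂_ij(1−P̂_ij) P̂'_ij(1−P̂'_ij)]^{1/2}``.

    The probability matrices may be estimates or the true ``P``; entries at
    exactly 0 or 1 are rejected (zero Bernoulli variance).
    """
    A1, A2 = np.asarray(A1, float), np.asarray(A2, float)
    P1, P2 = np.asarray(P1hat, float), np.asarray(P2hat, float)
    if not (A1.shape == A2.shape == P1.shape == P2.shape):
        raise ValueError("all four matrices must share a shape")
    n = A1.shape[0]
    iu = np.triu_indices(n, k=1)
    p1, p2 = P1[iu], P2[iu]
    if np.any((p1 <= 0) | (p1 >= 1) | (p2 <= 0) | (p2 >= 1)):
        raise ValueError("probability entries must lie strictly in (0, 1)")
    num = (A1[iu] - p1) * (A2[iu] - p2)
    den = np.sqrt(p1 * (1 - p1) * p2 * (1 - p2))
    return float(2.0 / (n * (n - 1)) * np.sum(num / den))


def pearson_graph_correlation(A1: np.ndarray, A2: np.ndarray) -> float:
    """Pearson correlation of the vectorised off-diagonal entries; the edge
    correlation under a correlated homogeneous Erdős–Rényi model."""
    A1, A2 = np.asarray(A1, float), np.asarray(A2, float)
    if A1.shape != A2.shape:
        raise ValueError("shapes must match")
    iu = np.triu_indices(A1.shape[0], k=1)
    a, b = A1[iu], A2[iu]
    ca, cb = a - a.mean(), b - b.mean()
    va, vb = np.sum(ca**2), np.sum(cb**2)
    if va == 0 or vb == 0:
        raise ValueError("constant adjacency: Pearson correlation undefined")
    return float(np.sum(ca * cb) / np.sqrt(va * vb))


# ---------------------------------------------------------------------------
# Monte-Carlo embedded-space correlation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EmbeddedCorrelationResult:
    correlation: float
    se: float
    per_coordinate: np.ndarray
    pearson: float
    reps: int


def _sample_collection(
    X, model: str, rng: np.random.Generator, *, m: int | None = None,
    rho: float | None = None, rho_steps=None, nu=None,
) -> GraphCollection:
    if model == "iid":
        if m is None:
            raise ValueError("model 'iid' requires m")
        graphs = [sample_rdpg(X, rng)[0] for _ in range(m)]
        return GraphCollection(np.stack(graphs))
    if model == "pair":
        return sample_correlated_pair(X, 0.0 if rho is None else rho, rng)
    if model == "forward":
        return sample_forward_chain(X, rho_steps, rng)
    if model == "generator":
        _, coll = sample_generator_collection(X, nu, rng)
        return coll
    raise ValueError(f"unknown model {model!r}")


def embedded_correlation_mc(
    F: LatentDistribution,
    coeffs: OmnibusCoefficients,
    pair: tuple[int, int],
    n: int,
    reps: int,
    seed: int | np.random.Generator | None = None,
    *,
    model: str = "iid",
    rho: float | None = None,
    rho_steps=None,
    nu=None,
    tracked_vertex: int = 0,
    align: str = "truth",
    n_boot: int = 200,
) -> EmbeddedCorrelationResult:
    """Measure, by Monte Carlo, the correlation between the embedded
    estimates of one tracked latent position in omnibus blocks ``s1`` and
    ``s2``.

    Each replicate samples fresh latent positions (deterministic block
    memberships, so the tracked vertex keeps the same latent position),
    draws a graph collection under ``model``, embeds the omnibus matrix,
    aligns the stacked embedding to the true positions by orthogonal
    Procrustes (``align='truth'``), and records the residuals of the
    tracked vertex in both blocks.

    The correlation is measured on the scale on which the limit theory
    states it: the across-replicate variance of each coordinate of
    ``√n (r_{s1} − r_{s2})`` is compared with the single-graph kernel via
    ``ρ̂_j = 1 − Var_j / (2 Σ(x)_{jj})`` — two estimates of the same latent
    position behave like ρ-correlated Gaussians with marginal kernel
    ``Σ(x)``.  Coordinates are averaged into one scalar; a bootstrap over
    replicates gives its standard error.  The raw across-replicate Pearson
    correlation of the residual coordinates (normalised by the block
    variances rather than ``Σ(x)``) is also reported for reference.
    """
    from .theory import sigma_x
    s1, s2 = pair
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    d = F.d
    res1 = np.empty((reps, d))
    res2 = np.empty((reps, d))
    for r in range(reps):
        sub = rng.spawn(1)[0]
        X = sample_latent(F, n, sub, deterministic_blocks=True)
        coll = _sample_collection(X, model, sub, m=coeffs.m, rho=rho,
                                  rho_steps=rho_steps, nu=nu)
        blocks = omni_embed(coeffs, coll, d)
        if align == "truth":
            Z = np.tile(X.X, (coeffs.m, 1))
            W, _ = procrustes_align(blocks.stacked, Z)
            aligned = blocks.stacked @ W
        elif align == "none":
            aligned = blocks.stacked
        else:
            raise ValueError(f"unknown alignment {align!r}")
        i = tracked_vertex
        res1[r] = aligned[s1 * n + i] - X.X[i]
        res2[r] = aligned[s2 * n + i] - X.X[i]
    if s1 == s2:
        return EmbeddedCorrelationResult(1.0, 0.0, np.ones(d), 1.0, reps)

    x_track = F.atoms[0] if tracked_vertex == 0 else None
    if x_track is None:
        raise ValueError("tracked vertex must be 0 (deterministic first atom)")
    sig_diag = np.diag(sigma_x(F, x_track))
    diffs = np.sqrt(n) * (res1 - res2)

    def _rho(dd: np.ndarray) -> np.ndarray:
        return 1.0 - dd.var(axis=0, ddof=1) / (2.0 * sig_diag)

    per_coord = _rho(diffs)
    point = float(per_coord.mean())
    boots = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, reps, size=reps)
        boots[b] = _rho(diffs[idx]).mean()

    c1, c2 = res1 - res1.mean(axis=0), res2 - res2.mean(axis=0)
    pearson = float(np.mean(
        np.sum(c1 * c2, axis=0)
        / np.sqrt(np.sum(c1**2, axis=0) * np.sum(c2**2, axis=0))
    ))
    return EmbeddedCorrelationResult(
        correlation=point, se=float(boots.std(ddof=1)), per_coordinate=per_coord,
        pearson=pearson, reps=reps,
    )


def aligned_difference_covariance_mc(
    F: LatentDistribution,
    rho: float,
    n: int,
    reps: int,
    seed: int | np.random.Generator | None = None,
    tracked_vertex: int = 0,
) -> np.ndarray:
    """Empirical covariance of the ``√n``-scaled difference of the two
    separately-embedded, Procrustes-aligned estimates of one tracked latent
    position, over ``reps`` correlated pairs.  The limit is
    ``2(1−ρ)·Σ(x)``."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    d = F.d
    diffs = np.empty((reps, d))
    for r in range(reps):
        sub = rng.spawn(1)[0]
        X = sample_latent(F, n, sub, deterministic_blocks=True)
        pair = sample_correlated_pair(X, rho, sub)
        aligned = []
        for k in range(2):
            Xhat = ase(pair[k].astype(float), d)
            W, _ = procrustes_align(Xhat, X.X)
            aligned.append(Xhat @ W)
        i = tracked_vertex
        diffs[r] = np.sqrt(n) * (aligned[0][i] - aligned[1][i])
    return np.cov(diffs, rowvar=False)
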