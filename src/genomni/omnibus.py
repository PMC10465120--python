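"""Generalized omnibus matrices and their spectral embeddings.

An omnibus matrix stacks ``m`` aligned ``n × n`` adjacency matrices into one
``mn × mn`` block matrix whose ``(k, ℓ)`` block is a convex combination
``Σ_q c_q^{(k,ℓ)} A^{(q)}`` of the input graphs.  Embedding the omnibus
matrix once yields ``m`` latent-position estimates per vertex that live in a
common subspace — no pairwise Procrustes alignment is needed — at the price
of correlation induced across the per-graph estimates.  The choice of block
coefficients governs that induced correlation; this module provides the
standard designs (classical pairwise average, total average, weighted
pairwise average, dampened, forward, pair-preserving) plus validation of the
defining constraints:

1. every block is a convex combination of the graphs,
2. in block-row ``k`` the cumulative weight of graph ``k`` strictly
   dominates that of every other graph,
3. the assembled matrix is symmetric.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.linalg
import scipy.sparse.linalg

from .models import GraphCollection

__all__ = [
    "OmnibusCoefficients",
    "WeightProfile",
    "EmbeddingBlocks",
    "ValidationReport",
    "ase",
    "classical_coefficients",
    "total_average_coefficients",
    "weighted_pairwise_coefficients",
    "dampened_coefficients",
    "forward_coefficients",
    "pair_preserving_coefficients",
    "coefficients_for_design",
    "validate_coefficients",
    "assemble_omnibus",
    "weight_profile",
    "omni_embed",
    "procrustes_align",
]

_CONVEX_TOL = 1e-10


@dataclass(frozen=True)
class OmnibusCoefficients:
    """Convex-combination weights ``c[k, ℓ, q]`` of graph ``q`` in block
    ``(k, ℓ)`` of an ``m``-graph omnibus matrix."""

    c: np.ndarray
    design: str = field(default="custom", compare=False)

    def __post_init__(self):
        c = np.asarray(self.c, dtype=float)
        if c.ndim != 3 or len(set(c.shape)) != 1:
            raise ValueError("c must be an m×m×m array")
        object.__setattr__(self, "c", c)

    @property
    def m(self) -> int:
        return self.c.shape[0]

    def weight_profile(self) -> "WeightProfile":
        return weight_profile(self)

    def validate(self) -> "ValidationReport":
        return validate_coefficients(self)


@dataclass(frozen=True)
class WeightProfile:
    """Row-aggregated weights ``α[k, q] = Σ_ℓ c[k, ℓ, q]``: the cumulative
    weight of graph ``q`` across block-row ``k``.  Every row sums to ``m``
    and the diagonal strictly dominates its row."""

    alpha: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.alpha, dtype=float)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("alpha must be square")
        object.__setattr__(self, "alpha", a)

    @property
    def m(self) -> int:
        return self.alpha.shape[0]

    def row_sums_ok(self, tol: float = 1e-9) -> bool:
        return bool(np.allclose(self.alpha.sum(axis=1), self.m, atol=tol))

    def dominance_ok(self) -> bool:
        a = self.alpha
        return all(a[k, k] > np.max(np.delete(a[k], k)) for k in range(self.m))


@dataclass(frozen=True)
class ValidationReport:
    passed: bool
    first_violation: str | None
    checks: dict


@dataclass(frozen=True)
class EmbeddingBlocks:
    """Stacked ``mn × d`` omnibus embedding split into ``m`` blocks of ``n``
    rows; block ``s`` estimates the latent positions as seen by graph ``s``."""

    stacked: np.ndarray
    m: int

    def __post_init__(self):
        Z = np.asarray(self.stacked, dtype=float)
        if Z.ndim != 2 or Z.shape[0] % self.m != 0:
            raise ValueError("stacked must be (m·n) × d")
        object.__setattr__(self, "stacked", Z)

    @property
    def n(self) -> int:
        return self.stacked.shape[0] // self.m

    @property
    def d(self) -> int:
        return self.stacked.shape[1]

    @property
    def blocks(self) -> list[np.ndarray]:
        return [self.block(s) for s in range(self.m)]

    def block(self, s: int) -> np.ndarray:
        n = self.n
        return self.stacked[s * n:(s + 1) * n]

    def mean_block(self) -> np.ndarray:
        return self.stacked.reshape(self.m, self.n, self.d).mean(axis=0)


# ---------------------------------------------------------------------------
# Adjacency spectral embedding
# ---------------------------------------------------------------------------

def ase(A: np.ndarray, d: int) -> np.ndarray:
    """Adjacency spectral embedding: ``X̂ = U |S|^{1/2}`` from the ``d``
    largest-magnitude eigenpairs of the symmetric matrix ``A``.

    Eigenvalue magnitudes order the spectrum and scale the eigenvectors;
    negative eigenvalues among the retained ones are flagged with a warning,
    as are (near-)ties between the ``d``-th and ``(d+1)``-th magnitudes.
    Column signs follow the convention that each eigenvector's
    largest-magnitude entry is positive.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("A must be square")
    if not np.allclose(A, A.T, atol=1e-10):
        raise ValueError("A must be symmetric")
    n = A.shape[0]
    if not 1 <= d <= n:
        raise ValueError(f"d must satisfy 1 <= d <= {n}")

    k_probe = min(d + 1, n)
    if n <= 400 or k_probe >= n - 1:
        evals, evecs = np.linalg.eigh(A)
    else:
        evals, evecs = scipy.sparse.linalg.eigsh(A, k=k_probe, which="LM")
    order = np.argsort(-np.abs(evals), kind="stable")
    evals, evecs = evals[order], evecs[:, order]

    if k_probe > d and np.isclose(abs(evals[d - 1]), abs(evals[d]), rtol=1e-8, atol=1e-12):
        warnings.warn(
            f"eigenvalue magnitude tie at position {d}; embedding dimension ambiguous",
            RuntimeWarning,
        )
    top = evals[:d]
    if np.allclose(top, 0.0):
        warnings.warn("matrix has (numerically) zero leading spectrum; "
                      "returning zero embedding", RuntimeWarning)
    elif (top < 0).any():
        warnings.warn("negative eigenvalue among the top-d magnitudes",
                      RuntimeWarning)
    U = evecs[:, :d]
    # deterministic sign convention
    flip = np.sign(U[np.argmax(np.abs(U), axis=0), np.arange(d)])
    flip[flip == 0] = 1.0
    U = U * flip
    return U * np.sqrt(np.abs(top))


# ---------------------------------------------------------------------------
# Coefficient designs
# ---------------------------------------------------------------------------

def classical_coefficients(m: int) -> OmnibusCoefficients:
    """Classical omnibus: diagonal blocks ``A^{(k)}``, off-diagonal blocks
    the plain pairwise average ``(A^{(k)}+A^{(ℓ)})/2``."""
    _require_m(m)
    c = np.zeros((m, m, m))
    for k in range(m):
        c[k, k, k] = 1.0
        for ell in range(m):
            if ell != k:
                c[k, ell, k] = c[k, ell, ell] = 0.5
    return OmnibusCoefficients(c, design="classical")


def total_average_coefficients(m: int) -> OmnibusCoefficients:
    """Total-average omnibus: every off-diagonal block is the sample mean
    graph ``Ā``."""
    _require_m(m)
    c = np.zeros((m, m, m))
    for k in range(m):
        for ell in range(m):
            if k == ell:
                c[k, k, k] = 1.0
            else:
                c[k, ell, :] = 1.0 / m
    return OmnibusCoefficients(c, design="totalavg")


def weighted_pairwise_coefficients(w: Sequence[float]) -> OmnibusCoefficients:
    """Weighted pairwise-average omnibus:
    block ``(k, ℓ) = (w_k A^{(k)} + w_ℓ A^{(ℓ)})/(w_k + w_ℓ)``."""
    w = np.asarray(w, dtype=float).ravel()
    m = w.size
    _require_m(m)
    if (w <= 0).any():
        raise ValueError("weights must be strictly positive")
    c = np.zeros((m, m, m))
    for k in range(m):
        c[k, k, k] = 1.0
        for ell in range(m):
            if ell != k:
                c[k, ell, k] = w[k] / (w[k] + w[ell])
                c[k, ell, ell] = w[ell] / (w[k] + w[ell])
    return OmnibusCoefficients(c, design="weighted")


def dampened_coefficients(w: Sequence[float]) -> OmnibusCoefficients:
    """Dampened omnibus for a strictly increasing positive weight vector:
    below-diagonal block ``(k, ℓ), k > ℓ`` is ``(w_k A^{(k)} + A^{(ℓ)})/(w_k+1)``
    (mirrored above the diagonal), so later graphs increasingly dominate and
    the induced correlation decays along the sequence."""
    w = np.asarray(w, dtype=float).ravel()
    m = w.size
    _require_m(m)
    if (w <= 0).any() or (np.diff(w) <= 0).any():
        raise ValueError("weights must be positive and strictly increasing")
    c = np.zeros((m, m, m))
    for k in range(m):
        c[k, k, k] = 1.0
        for ell in range(m):
            if k > ell:
                c[k, ell, k] = w[k] / (w[k] + 1.0)
                c[k, ell, ell] = 1.0 / (w[k] + 1.0)
            elif k < ell:
                c[k, ell, k] = 1.0 / (w[ell] + 1.0)
                c[k, ell, ell] = w[ell] / (w[ell] + 1.0)
    _assert_block_symmetry(c)
    return OmnibusCoefficients(c, design="dampened")


def forward_coefficients(m: int) -> OmnibusCoefficients:
    """Forward omnibus: with 1-based indices ``i > j`` the block is
    ``((i−1) A^{(j)} + A^{(i)})/i``, so correlation grows along the
    sequence (the mirror image of the dampened design)."""
    _require_m(m)
    c = np.zeros((m, m, m))
    for k in range(m):          # 0-based; i = k + 1
        c[k, k, k] = 1.0
        for ell in range(m):
            if k > ell:
                c[k, ell, ell] = k / (k + 1.0)
                c[k, ell, k] = 1.0 / (k + 1.0)
            elif k < ell:
                c[k, ell, k] = ell / (ell + 1.0)
                c[k, ell, ell] = 1.0 / (ell + 1.0)
    _assert_block_symmetry(c)
    return OmnibusCoefficients(c, design="forward")


def pair_preserving_coefficients(m: int) -> OmnibusCoefficients:
    """Pair-preserving omnibus (even ``m``): consecutive pairs
    ``(2t, 2t+1)`` are averaged in their cross blocks; every other
    off-diagonal block passes through the smaller-index graph.  Preserves
    the inherent correlation of each consecutive pair in the embedded space
    up to a ``O(1/m)`` induced term."""
    _require_m(m)
    if m % 2 != 0:
        raise ValueError("m must be even for the pair-preserving design")
    c = np.zeros((m, m, m))
    for k in range(m):
        for ell in range(m):
            if k == ell:
                c[k, k, k] = 1.0
            elif k // 2 == ell // 2:
                c[k, ell, k] = c[k, ell, ell] = 0.5
            else:
                c[k, ell, min(k, ell)] = 1.0
    _assert_block_symmetry(c)
    return OmnibusCoefficients(c, design="pair12")


_DESIGN_BUILDERS = {
    "classical": classical_coefficients,
    "totalavg": total_average_coefficients,
    "weighted": weighted_pairwise_coefficients,
    "dampened": dampened_coefficients,
    "forward": forward_coefficients,
    "pair12": pair_preserving_coefficients,
}


def coefficients_for_design(
    design: str, m: int | None = None, weights: Sequence[float] | None = None
) -> OmnibusCoefficients:
    """Dispatch a named design to its builder.  ``weighted`` and ``dampened``
    take a weight vector; the rest take the graph count ``m``."""
    if design not in _DESIGN_BUILDERS:
        raise ValueError(f"unknown design {design!r}; choose from {sorted(_DESIGN_BUILDERS)}")
    if design in ("weighted", "dampened"):
        if weights is None:
            raise ValueError(f"design {design!r} requires a weight vector")
        return _DESIGN_BUILDERS[design](weights)
    if m is None:
        raise ValueError(f"design {design!r} requires m")
    return _DESIGN_BUILDERS[design](m)


def _require_m(m: int) -> None:
    if m < 2:
        raise ValueError("at least two graphs are required")


def _assert_block_symmetry(c: np.ndarray) -> None:
    if not np.allclose(c, np.swapaxes(c, 0, 1), atol=1e-12):
        raise AssertionError("block coefficients are not symmetric in (k, ℓ)")


# ---------------------------------------------------------------------------
# Validation, assembly, embedding
# ---------------------------------------------------------------------------

def weight_profile(coeffs: OmnibusCoefficients) -> WeightProfile:
    """Aggregate the coefficient tensor over block columns:
    ``α[k, q] = Σ_ℓ c[k, ℓ, q]``."""
    return WeightProfile(coeffs.c.sum(axis=1))


def validate_coefficients(coeffs: OmnibusCoefficients) -> ValidationReport:
    """Check the three defining constraints (convexity of every block,
    symmetry of the assembled matrix, strict diagonal dominance of the
    weight profile) and report the first violation, if any."""
    c = coeffs.c
    m = coeffs.m
    checks: dict[str, bool] = {}
    first = None

    nonneg = bool((c >= -_CONVEX_TOL).all())
    sums_one = bool(np.allclose(c.sum(axis=2), 1.0, atol=_CONVEX_TOL))
    checks["convexity"] = nonneg and sums_one
    if not checks["convexity"] and first is None:
        first = "convexity"

    checks["symmetry"] = bool(np.allclose(c, np.swapaxes(c, 0, 1), atol=1e-10))
    if not checks["symmetry"] and first is None:
        first = "symmetry"

    alpha = c.sum(axis=1)
    dom = all(
        alpha[k, k] > alpha[k, q] for k in range(m) for q in range(m) if q != k
    )
    checks["dominance"] = bool(dom)
    if not checks["dominance"] and first is None:
        first = "dominance"

    checks["row_sums"] = bool(np.allclose(alpha.sum(axis=1), m, atol=1e-9))
    if not checks["row_sums"] and first is None:
        first = "row_sums"

    return ValidationReport(passed=first is None, first_violation=first, checks=checks)


def assemble_omnibus(
    coeffs: OmnibusCoefficients, graphs: GraphCollection | np.ndarray
) -> np.ndarray:
    """Build the dense ``mn × mn`` omnibus matrix
    ``𝔐(k,ℓ) = Σ_q c_q^{(k,ℓ)} A^{(q)}``."""
    A = graphs.adjacency if isinstance(graphs, GraphCollection) else np.asarray(graphs, float)
    m = coeffs.m
    if A.shape[0] != m:
        raise ValueError(f"expected {m} graphs, got {A.shape[0]}")
    n = A.shape[1]
    blocks = (coeffs.c.reshape(m * m, m) @ A.reshape(m, n * n)).reshape(m, m, n, n)
    M = blocks.swapaxes(1, 2).reshape(m * n, m * n)
    if not np.allclose(M, M.T, atol=1e-10):
        raise AssertionError("assembled omnibus matrix is not symmetric")
    return M


def omni_embed(
    coeffs: OmnibusCoefficients, graphs: GraphCollection | np.ndarray, d: int
) -> EmbeddingBlocks:
    """Assemble the omnibus matrix and embed it, returning the ``m`` blocks
    of estimated latent positions in block-row order."""
    M = assemble_omnibus(coeffs, graphs)
    return EmbeddingBlocks(stacked=ase(M, d), m=coeffs.m)


def procrustes_align(
    Xhat: np.ndarray, target: np.ndarray
) -> tuple[np.ndarray, float]:
    """Solve the orthogonal Procrustes problem
    ``min_{W orthogonal} ‖X̂ W − target‖_F``.

    Returns the optimal ``W`` and the minimal residual norm.
    """
    Xhat = np.asarray(Xhat, float)
    target = np.asarray(target, float)
    if Xhat.shape != target.shape:
        raise ValueError("shapes must match")
    W, _ = scipy.linalg.orthogonal_procrustes(Xhat, target)
    residual = float(np.linalg.norm(Xhat @ W - target))
    return W, residual
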