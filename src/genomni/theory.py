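"""Closed-form limit theory for generalized omnibus embeddings.

For an ``m``-graph omnibus design with weight profile ``α`` applied to
pairwise edge-correlated RDPGs with correlation matrix ``R``, the
``√n``-scaled row residuals of the embedding are asymptotically Gaussian.
This module evaluates the limiting covariances and the induced/inherent
correlation calculus exactly for finite-mixture latent distributions:

* ``Σ(x)`` — the single-graph ASE covariance kernel,
* the per-block covariance ``(1/m²)[Σ_q α(s,q)² + 2Σ_{q<l} α(s,q)α(s,l)ρ_{q,l}]·Σ(x)``,
* the cross-block difference covariance and the limiting correlation
  ``ρ(s1,s2) = 1 − Σ_q d_q²/(2m²) − Σ_{q<l} d_q d_l ρ_{q,l}/m²`` with
  ``d_q = α(s1,q) − α(s2,q)``, split into its *method* (induced) and
  *model* (inherent) parts,
* the printed closed forms for the named designs,
* the effective sample size ``m/(1+ρ(m−1))`` and the covariance of the
  averaged latent-position estimator.

Expectations over the latent distribution are exact finite sums over the
mixture atoms.  All indices are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .models import CorrelationMatrix, LatentDistribution
from .omnibus import WeightProfile

__all__ = [
    "SecondMoment",
    "CorrelationParts",
    "second_moment",
    "sigma_x",
    "block_covariance",
    "difference_covariance",
    "limiting_correlation",
    "closed_form_correlation",
    "effective_sample_size",
    "averaged_estimator_covariance",
]


@dataclass(frozen=True)
class SecondMoment:
    """``Δ = E[X₁X₁ᵀ]``, required to be full rank ``d``."""

    Delta: np.ndarray
    condition_number: float


class CorrelationParts(NamedTuple):
    total: float
    method: float
    model: float


class CovarianceParts(NamedTuple):
    matrix: np.ndarray
    method_coefficient: float
    model_coefficient: float


def second_moment(F: LatentDistribution) -> SecondMoment:
    """Exact mixture second moment ``Δ = Σ_k π_k ξ_k ξ_kᵀ``; raises if
    ``Δ`` is rank-deficient (every limit theorem requires full rank)."""
    Delta = np.einsum("k,ki,kj->ij", F.weights, F.atoms, F.atoms)
    evals = np.linalg.eigvalsh(Delta)
    if evals.min() <= 1e-12 * max(evals.max(), 1.0):
        raise ValueError("second moment Δ is rank deficient")
    return SecondMoment(Delta=Delta, condition_number=float(evals.max() / evals.min()))


def sigma_x(F: LatentDistribution, x: np.ndarray) -> np.ndarray:
    """Single-graph covariance kernel
    ``Σ(x) = Δ⁻¹ E[(xᵀX₁ − (xᵀX₁)²) X₁X₁ᵀ] Δ⁻¹`` evaluated exactly over the
    mixture atoms.  ``xᵀξ_k`` must lie in ``[0, 1]`` for every atom."""
    x = np.asarray(x, dtype=float).ravel()
    if x.size != F.d:
        raise ValueError(f"x must have dimension {F.d}")
    Delta = second_moment(F).Delta
    p = F.atoms @ x
    if p.min() < -1e-9 or p.max() > 1 + 1e-9:
        raise ValueError("xᵀξ_k must lie in [0, 1] for all atoms")
    var = p - p**2
    E = np.einsum("k,k,ki,kj->ij", F.weights, var, F.atoms, F.atoms)
    Dinv = np.linalg.inv(Delta)
    return Dinv @ E @ Dinv


def _alpha_and_R(alpha, R) -> tuple[np.ndarray, np.ndarray]:
    a = alpha.alpha if isinstance(alpha, WeightProfile) else np.asarray(alpha, float)
    r = R.R if isinstance(R, CorrelationMatrix) else np.asarray(R, float)
    if a.shape != r.shape:
        raise ValueError("alpha and R must both be m×m")
    return a, r


def block_covariance(
    alpha: WeightProfile | np.ndarray,
    R: CorrelationMatrix | np.ndarray,
    s: int,
    F: LatentDistribution,
    x: np.ndarray,
) -> CovarianceParts:
    """Limiting covariance of the ``√n``-scaled residual of block ``s``:
    a scalar coefficient times ``Σ(x)``, returned with the coefficient's
    method-induced and model-inherent parts."""
    a, r = _alpha_and_R(alpha, R)
    m = a.shape[0]
    if not 0 <= s < m:
        raise IndexError(f"block index {s} out of range for m={m}")
    row = a[s]
    method = float(row @ row) / m**2
    model = float(row @ r @ row - row @ row) / m**2
    return CovarianceParts(
        matrix=(method + model) * sigma_x(F, x),
        method_coefficient=method,
        model_coefficient=model,
    )


def difference_covariance(
    alpha: WeightProfile | np.ndarray,
    R: CorrelationMatrix | np.ndarray,
    s1: int,
    s2: int,
    F: LatentDistribution,
    x: np.ndarray,
) -> np.ndarray:
    """Limiting covariance of the ``√n``-scaled difference between blocks
    ``s1`` and ``s2``.  Both printed algebraic forms of the coefficient are
    evaluated and asserted to agree (they coincide because each α row sums
    to ``m``); the result equals ``2(1 − ρ(s1,s2))·Σ(x)``."""
    a, r = _alpha_and_R(alpha, R)
    m = a.shape[0]
    for s in (s1, s2):
        if not 0 <= s < m:
            raise IndexError(f"block index {s} out of range for m={m}")
    d = a[s1] - a[s2]
    form1 = float(d @ r @ d) / m**2
    cross = sum(
        d[q] * d[l] * (r[q, l] - 1.0) for q in range(m) for l in range(q + 1, m)
    )
    form2 = 2.0 * cross / m**2
    if not np.isclose(form1, form2, atol=1e-8, rtol=1e-8):
        raise AssertionError(
            "the two algebraic forms of the difference covariance disagree; "
            "the weight profile rows do not sum to m"
        )
    return form1 * sigma_x(F, x)


def limiting_correlation(
    alpha: WeightProfile | np.ndarray,
    R: CorrelationMatrix | np.ndarray,
    s1: int,
    s2: int,
) -> CorrelationParts:
    """Limiting correlation between the embedded estimates of a common
    latent position in blocks ``s1`` and ``s2``, with its method-induced
    and model-inherent parts.  With ``d_q = α(s1,q) − α(s2,q)``:

    ``method = 1 − Σ_q d_q² / (2m²)``,
    ``model  = − Σ_{q<l} d_q d_l ρ_{q,l} / m²``.
    """
    a, r = _alpha_and_R(alpha, R)
    m = a.shape[0]
    for s in (s1, s2):
        if not 0 <= s < m:
            raise IndexError(f"block index {s} out of range for m={m}")
    d = a[s1] - a[s2]
    method = 1.0 - float(d @ d) / (2.0 * m**2)
    model = -float(d @ r @ d - d @ d) / (2.0 * m**2)
    return CorrelationParts(total=method + model, method=method, model=model)


def closed_form_correlation(design: str, **params) -> float:
    """Printed closed forms of the limiting correlation for the named
    design families.

    - ``classical``: ``3/4 + ρ_in/4`` (any m).
    - ``totalavg``: ``1 − 1/m² + ρ_in/m²``.
    - ``weighted_equal_pair``: the pair carries weight ``w`` and all other
      graphs weight 1: ``1 − ((m−1)w+1)²/(m²(1+w)²)·(1 − ρ_in)``.
    - ``pair12``: ``1 − (1 − ρ_in)(m−1)²/m²`` for the preserved pair.
    """
    rho_in = float(params.get("rho_in", 0.0))
    if design == "classical":
        return 0.75 + rho_in / 4.0
    m = params.get("m")
    if m is None:
        raise ValueError(f"design {design!r} requires m")
    m = int(m)
    if design == "totalavg":
        return 1.0 - 1.0 / m**2 + rho_in / m**2
    if design == "weighted_equal_pair":
        w = float(params["w"])
        factor = ((m - 1) * w + 1.0) ** 2 / (m**2 * (1.0 + w) ** 2)
        return 1.0 - factor * (1.0 - rho_in)
    if design == "pair12":
        return 1.0 - (1.0 - rho_in) * (m - 1) ** 2 / m**2
    raise ValueError(f"unknown design family {design!r}")


def effective_sample_size(m: int, rho: float) -> float:
    """Effective sample size of ``m`` flat-``ρ`` correlated graphs:
    ``m / (1 + ρ(m−1))`` — equals ``m`` at independence and 1 at ``ρ=1``."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0 <= rho <= 1:
        raise ValueError("rho must lie in [0, 1]")
    return m / (1.0 + rho * (m - 1))


def averaged_estimator_covariance(
    m: int, rho: float, F: LatentDistribution, x: np.ndarray
) -> np.ndarray:
    """Limiting covariance of the ``√n``-scaled residual of the averaged
    latent-position estimator over ``m`` flat-``ρ`` correlated graphs
    (separately embedded + aligned, or omnibus-block averaged):

    ``[(1−ρ)/m + ρ] · Σ(x) = Σ(x) / m_eff``,

    the network analogue of the classical covariance of the sample mean of
    ρ-correlated observations.  At ``ρ=0`` the averaging contributes the
    full factor ``1/m``; at ``ρ=1`` the average is no better than a single
    graph.  ``m = 1`` is rejected — use the single-graph kernel ``Σ(x)``
    directly for one graph.
    """
    if m < 2:
        raise ValueError("m must be >= 2; use sigma_x directly for one graph")
    if not 0 <= rho <= 1:
        raise ValueError("rho must lie in [0, 1]")
    rho_eff = (1.0 - rho) / m + rho
    return rho_eff * sigma_x(F, x)
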