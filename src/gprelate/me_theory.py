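"""Theoretical effective number of chromosome segments (Me).

Me measures how many independent genomic segments effectively segregate in
a population: the fewer the segments, the fewer parameters genomic
prediction must estimate and the higher its accuracy at a given discovery
sample size.  Under a standard neutral model the expected squared
correlation (LD) between two loci at recombination distance ``c`` Morgan is
``r2 = 1/(1 + 4*Ne*c)``, or ``1/(2 + 4*Ne*c)`` when historical mutation is
accounted for.

Three estimators are provided, all derived from the M x M matrix S of
pairwise squared correlations among equally spaced SNPs:

* ``me_from_weights`` — Me as the sum of SNP weights solving ``S w = e``;
* ``me_matrix_mean`` — the approximation ``1/Me = mean(S)``;
* ``me_closed_form_single`` / ``me_closed_form_genome`` — the M -> infinity
  limit of the matrix mean, evaluated in closed form, with a
  between-chromosome relationship covariance of ``1/(3*Ne)`` for the
  multi-chromosome genome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.linalg import solve, toeplitz

__all__ = [
    "PopulationGenomeSpec",
    "SnpCorrelationMatrix",
    "MeEstimate",
    "expected_r2",
    "build_snp_correlation_matrix",
    "me_from_weights",
    "me_matrix_mean",
    "me_closed_form_single",
    "me_closed_form_genome",
]


@dataclass(frozen=True)
class PopulationGenomeSpec:
    """Effective population size plus genome layout.

    Attributes
    ----------
    Ne : float
        Effective population size (>= 1).
    n_chr : int
        Number of chromosomes, all of equal length.
    chr_length : float
        Genomic length per chromosome in Morgan.
    mutation_correction : bool
        If True use ``r2 = 1/(2 + 4*Ne*c)`` (accounts for historical
        mutation), else ``1/(1 + 4*Ne*c)``.
    """

    Ne: float
    n_chr: int = 1
    chr_length: float = 1.0
    mutation_correction: bool = True

    def __post_init__(self) -> None:
        if self.Ne < 1:
            raise ValueError(f"Ne must be >= 1, got {self.Ne}")
        if self.n_chr < 1:
            raise ValueError(f"n_chr must be >= 1, got {self.n_chr}")
        if self.chr_length <= 0:
            raise ValueError(f"chr_length must be > 0, got {self.chr_length}")


@dataclass(frozen=True)
class SnpCorrelationMatrix:
    """Toeplitz matrix of expected squared correlations between SNPs."""

    values: np.ndarray
    spacing: float  # Morgan between adjacent SNPs

    @property
    def order(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class MeEstimate:
    """An Me value tagged with the method that produced it."""

    value: float
    method: str  # weights | matrix_mean | closed_form | grm_variance
    spec: Any = field(default=None, compare=False)

    def __float__(self) -> float:
        return float(self.value)


def expected_r2(c: np.ndarray | float, Ne: float, mutation_correction: bool = True):
    """Expected squared LD correlation at recombination distance ``c`` Morgan."""
    alpha = 2.0 if mutation_correction else 1.0
    return 1.0 / (alpha + 4.0 * Ne * np.asarray(c, dtype=float))


def build_snp_correlation_matrix(spec: PopulationGenomeSpec, M: int) -> SnpCorrelationMatrix:
    """Expected r2 matrix for M equally spaced SNPs on one chromosome.

    SNPs span the chromosome with the endpoints included, so adjacent SNPs
    are ``chr_length / (M - 1)`` Morgan apart.
    """
    if spec.n_chr != 1:
        raise ValueError("the SNP correlation matrix is built per chromosome (n_chr=1)")
    if M < 2:
        raise ValueError(f"need at least 2 SNPs, got {M}")
    spacing = spec.chr_length / (M - 1)
    dist = np.arange(M, dtype=float) * spacing
    first_row = expected_r2(dist, spec.Ne, spec.mutation_correction)
    first_row[0] = 1.0  # a SNP is perfectly correlated with itself
    return SnpCorrelationMatrix(values=toeplitz(first_row), spacing=spacing)


def me_from_weights(S: SnpCorrelationMatrix | np.ndarray) -> MeEstimate:
    """Me as the sum of SNP weights ``w`` solving ``S w = e``.

    Each SNP is down-weighted by how strongly it is correlated with the
    others; independent SNPs get weight 1, perfectly correlated SNPs share
    a single unit of weight.  Near-singular matrices (long stretches of
    near-perfect LD) are ridge-regularised with 1e-8 on the diagonal.
    """
    A = S.values if isinstance(S, SnpCorrelationMatrix) else np.asarray(S, dtype=float)
    M = A.shape[0]
    e = np.ones(M)
    if np.linalg.cond(A) > 1e12:
        warnings.warn(
            "SNP correlation matrix is near-singular; adding ridge 1e-8",
            RuntimeWarning,
            stacklevel=2,
        )
        w, *_ = np.linalg.lstsq(A + 1e-8 * np.eye(M), e, rcond=None)
    else:
        w = solve(A, e, assume_a="sym")
    return MeEstimate(value=float(w.sum()), method="weights", spec=S)


def me_matrix_mean(S: SnpCorrelationMatrix | np.ndarray) -> MeEstimate:
    """Me from the approximation ``1/Me = mean of all M^2 entries of S``."""
    A = S.values if isinstance(S, SnpCorrelationMatrix) else np.asarray(S, dtype=float)
    return MeEstimate(value=float(1.0 / A.mean()), method="matrix_mean", spec=S)


def _inv_me_single(Ne: float, L: float, mutation_correction: bool) -> float:
    """Closed-form ``1/Me`` for one chromosome of length L Morgan.

    This is the M -> infinity limit of mean(S): with x the scaled distance,
    ``1/Me = 2 * integral_0^1 (1 - x) r2(x L) dx``, which integrates to
    ``2[(a + alpha) ln(1 + a/alpha) - a] / a^2`` with ``a = 4 Ne L`` and
    ``alpha`` the 1 or 2 in the r2 denominator.
    """
    a = 4.0 * Ne * L
    alpha = 2.0 if mutation_correction else 1.0
    if a == 0.0:
        # all loci in perfect linkage: a single segment
        return 1.0
    return 2.0 * ((a + alpha) * np.log1p(a / alpha) - a) / (a * a)


def me_closed_form_single(spec: PopulationGenomeSpec) -> MeEstimate:
    """Closed-form Me for a single chromosome."""
    if spec.n_chr != 1:
        raise ValueError("use me_closed_form_genome for multi-chromosome genomes")
    inv = _inv_me_single(spec.Ne, spec.chr_length, spec.mutation_correction)
    return MeEstimate(value=1.0 / inv, method="closed_form", spec=spec)


def me_closed_form_genome(spec: PopulationGenomeSpec) -> MeEstimate:
    """Closed-form Me for a genome of ``n_chr`` equal-length chromosomes.

    Relationships at different chromosomes are not independent: drift makes
    a pair of individuals similarly related everywhere, giving a
    between-chromosome covariance of ``1/(3*Ne)``.  The genome-wide
    ``1/Me`` is the mean of the n_chr x n_chr covariance matrix with
    diagonal ``1/Me_single`` and off-diagonal ``1/(3*Ne)``:

        1/Me_genome = [n * (1/Me_single) + n*(n-1)/(3*Ne)] / n^2
    """
    n = spec.n_chr
    inv_single = _inv_me_single(spec.Ne, spec.chr_length, spec.mutation_correction)
    inv_genome = (n * inv_single + n * (n - 1) / (3.0 * spec.Ne)) / (n * n)
    return MeEstimate(value=1.0 / inv_genome, method="closed_form", spec=spec)
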