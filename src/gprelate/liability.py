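"""Truncated standard-normal machinery for the liability threshold model.

Disease status is modelled as an unobserved standard-normal liability
exceeding a threshold ``t`` chosen so that a fraction ``K`` (the population
prevalence) of individuals lies above it.  The same truncation algebra is
reused for percentile strata of ranked genetic profile scores: the top
``q`` fraction of a standard-normal score distribution has mean
``phi(t_q)/q`` and a reduced within-stratum variance.

All quantities are in standard-deviation units of the underlying normal;
scaling to a particular trait is left to callers.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

__all__ = [
    "LiabilityModel",
    "PercentileContrast",
    "liability_quantities",
    "percentile_quantities",
]

_norm = stats.norm


@dataclass(frozen=True)
class LiabilityModel:
    """Threshold-model quantities implied by a population prevalence.

    Attributes
    ----------
    K : float
        Population prevalence of the disease, in (0, 1).
    t : float
        Liability threshold: the upper-``K`` quantile of N(0, 1).
    z : float
        Standard-normal density at ``t``.
    i_case : float
        Mean liability of affected individuals, ``z / K`` (> 0).
    i_control : float
        Mean liability of unaffected individuals, ``-z / (1 - K)`` (< 0).
    """

    K: float
    t: float
    z: float
    i_case: float
    i_control: float


@dataclass(frozen=True)
class PercentileContrast:
    """Thresholds and conditional means for tail strata of ranked scores.

    The top stratum is the upper ``top_fraction`` tail of a standard-normal
    score distribution, the bottom stratum the lower ``bottom_fraction``
    tail.  ``var_top``/``var_bottom`` are the truncated-normal variances
    within each stratum, needed when propagating a stratum mean through a
    liability calculation.
    """

    top_fraction: float
    bottom_fraction: float
    t_top: float
    t_bottom: float
    i_top: float
    i_bottom: float
    var_top: float
    var_bottom: float


def liability_quantities(K: float) -> LiabilityModel:
    """Compute threshold, density and case/control mean liabilities.

    Parameters
    ----------
    K : float
        Population prevalence, strictly between 0 and 1.

    Returns
    -------
    LiabilityModel

    Examples
    --------
    >>> m = liability_quantities(0.1)
    >>> round(m.t, 5), round(m.i_case, 5)
    (1.28155, 1.75498)
    """
    if not 0.0 < K < 1.0:
        raise ValueError(f"prevalence K must be in (0, 1), got {K}")
    t = _norm.isf(K)
    z = _norm.pdf(t)
    return LiabilityModel(K=K, t=t, z=z, i_case=z / K, i_control=-z / (1.0 - K))


def _upper_tail_moments(fraction: float) -> tuple[float, float, float]:
    """Threshold, mean and variance of the upper-``fraction`` tail of N(0,1)."""
    t = _norm.isf(fraction)
    m = _norm.pdf(t) / fraction
    # Var(X | X > t) = 1 + t*m - m^2 for a standard normal.
    v = 1.0 + t * m - m * m
    return t, m, v


def percentile_quantities(
    top_fraction: float, bottom_fraction: float | None = None
) -> PercentileContrast:
    """Thresholds and stratum means for top/bottom score percentiles.

    The bottom stratum is constructed by symmetry from the lower tail:
    ``i_bottom = -phi(t)/bottom_fraction`` with ``t`` the lower-tail
    threshold.  If ``bottom_fraction`` is omitted it defaults to
    ``top_fraction`` (the usual symmetric contrast).

    Examples
    --------
    >>> c = percentile_quantities(0.2)
    >>> round(c.i_top, 5)
    1.39981
    """
    if bottom_fraction is None:
        bottom_fraction = top_fraction
    for name, q in (("top_fraction", top_fraction), ("bottom_fraction", bottom_fraction)):
        if not 0.0 < q < 1.0:
            raise ValueError(f"{name} must be in (0, 1), got {q}")
    if top_fraction + bottom_fraction > 1.0:
        raise ValueError("top and bottom strata overlap: fractions sum above 1")
    t_top, i_top, var_top = _upper_tail_moments(top_fraction)
    t_low, m_low, var_bottom = _upper_tail_moments(bottom_fraction)
    return PercentileContrast(
        top_fraction=top_fraction,
        bottom_fraction=bottom_fraction,
        t_top=t_top,
        t_bottom=-t_low,
        i_top=i_top,
        i_bottom=-m_low,
        var_top=var_top,
        var_bottom=var_bottom,
    )
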