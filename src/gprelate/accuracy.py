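"""Expected genomic-prediction accuracy, AUC and percentile odds ratios.

For a quantitative trait the expected correlation between true and
estimated genetic profile scores follows the classical information
argument: N phenotypic records each carrying h² of signal must estimate
the effects of Me independent segments,

    r(g, ghat) = sqrt( N h² b / (N h² b + Me) ),

with b the fraction of genetic variance captured by the M observed
markers.  The phenotype-score correlation is h times that.

For case-control designs the discovery information is expressed on the
observed 0/1 disease scale.  With prevalence K (liability threshold t,
density z) and case proportion P in the discovery sample, the
heritability on the ascertained observed scale is
h²_01 = h² z² P(1-P) / (K²(1-K)²), and the score accuracy on that scale is

    rho_01 = sqrt( N h²_01 / (N h²_01 + Me) ).

Expected AUC and odds ratios follow by propagating the score-liability
correlation rho_01 * h through truncated-normal algebra (cases are the
upper-K tail of liability; score percentiles are tails of the score
distribution).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import norm

from .liability import LiabilityModel, PercentileContrast
from .me_theory import MeEstimate

__all__ = [
    "TraitDesign",
    "PredictionAccuracy",
    "captured_fraction",
    "accuracy_quantitative",
    "accuracy_phenotypic",
    "accuracy_case_control",
    "expected_auc",
    "expected_or",
]


@dataclass(frozen=True)
class TraitDesign:
    """Discovery-design parameters for an accuracy calculation.

    Attributes
    ----------
    h2 : float
        Heritability of the trait; on the liability scale for diseases.
    N : int
        Number of phenotyped individuals in the discovery sample.
    P : float | None
        Proportion of cases among discovery individuals (case-control only).
    M : int | None
        Number of observed markers; when given, the captured-variance
        fraction b = M/(M+Me) is applied, otherwise b = 1.
    """

    h2: float
    N: int
    P: float | None = None
    M: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.h2 <= 1.0:
            raise ValueError(f"h2 must be in (0, 1], got {self.h2}")
        if self.N < 1:
            raise ValueError(f"N must be >= 1, got {self.N}")
        if self.P is not None and not 0.0 < self.P < 1.0:
            raise ValueError(f"P must be in (0, 1), got {self.P}")


@dataclass(frozen=True)
class PredictionAccuracy:
    """Bundle of expected performance measures for one design."""

    r_true: float
    r_pheno: float | None = None
    rho_01: float | None = None
    auc: float | None = None
    or_contrast: float | None = None


def _me_value(Me: MeEstimate | float) -> float:
    v = float(Me)
    if v <= 0:
        raise ValueError(f"Me must be positive, got {v}")
    return v


def captured_fraction(M: int, Me: MeEstimate | float) -> float:
    """Fraction of genetic variance captured by M observed markers.

    b = M / (M + Me); tends to 1 with dense markers.
    """
    if M < 1:
        raise ValueError(f"M must be >= 1, got {M}")
    me = _me_value(Me)
    return M / (M + me)


def _b(design: TraitDesign, me: float) -> float:
    return captured_fraction(design.M, me) if design.M is not None else 1.0


def accuracy_quantitative(design: TraitDesign, Me: MeEstimate | float) -> float:
    """Expected correlation between true and estimated genetic scores."""
    me = _me_value(Me)
    info = design.N * design.h2 * _b(design, me)
    return math.sqrt(info / (info + me))


def accuracy_phenotypic(design: TraitDesign, Me: MeEstimate | float) -> float:
    """Expected correlation between phenotypes and estimated scores.

    The phenotype only correlates with its genetic part, so this is
    sqrt(h2) times the score accuracy.
    """
    return math.sqrt(design.h2) * accuracy_quantitative(design, Me)


def accuracy_case_control(
    design: TraitDesign, Me: MeEstimate | float, lia: LiabilityModel
) -> float:
    """Expected score accuracy on the 0/1 disease scale (rho_01).

    Combines the liability-to-observed-scale variance transform with the
    case ascertainment of the discovery sample (P cases at prevalence K).
    """
    if design.P is None:
        raise ValueError("case-control accuracy requires design.P")
    me = _me_value(Me)
    K, z, P = lia.K, lia.z, design.P
    h2_01 = design.h2 * z * z * P * (1.0 - P) / (K * K * (1.0 - K) ** 2)
    info = design.N * h2_01 * _b(design, me)
    return math.sqrt(info / (info + me))


def _score_liability_corr(design: TraitDesign, Me, lia: LiabilityModel) -> float:
    """Correlation between the estimated score and the total liability."""
    return accuracy_case_control(design, Me, lia) * math.sqrt(design.h2)


def expected_auc(
    design: TraitDesign, Me: MeEstimate | float, lia: LiabilityModel
) -> float:
    """Expected AUC of the genetic score in an unselected target sample.

    AUC is the probability that a random case outscores a random control.
    Conditional on status, the standardized score is normal with mean
    rho*i (cases) or rho*i2 (controls) and variance reduced by the
    truncation, giving

        AUC = Phi( rho (i - i2) / sqrt(2 - rho² [i(i-t) + i2(i2-t)]) )

    with rho the score-liability correlation rho_01 * h.
    """
    rho = _score_liability_corr(design, Me, lia)
    i, i2, t = lia.i_case, lia.i_control, lia.t
    num = rho * (i - i2)
    den = math.sqrt(2.0 - rho * rho * (i * (i - t) + i2 * (i2 - t)))
    return float(norm.cdf(num / den))


def _stratum_disease_prob(rho: float, mean: float, var: float, t: float) -> float:
    """P(liability > t) for a score stratum with given mean and variance.

    Liability given the score s is N(rho*s, 1-rho²); mixing over the
    truncated-normal score distribution within the stratum gives liability
    mean rho*mean and variance (1-rho²) + rho²*var.
    """
    sd = math.sqrt(1.0 - rho * rho + rho * rho * var)
    return float(norm.sf((t - rho * mean) / sd))


def expected_or(
    design: TraitDesign,
    Me: MeEstimate | float,
    lia: LiabilityModel,
    contrast: PercentileContrast,
    mode: str = "top_vs_bottom",
) -> float:
    """Expected odds ratio of disease between score strata.

    ``mode='top_vs_bottom'`` contrasts the top stratum against the bottom
    stratum; ``mode='top_vs_population'`` contrasts it against the whole
    (unselected) population, whose disease odds are K/(1-K).
    """
    if mode not in ("top_vs_bottom", "top_vs_population"):
        raise ValueError(f"unknown mode {mode!r}")
    rho = _score_liability_corr(design, Me, lia)
    p_top = _stratum_disease_prob(rho, contrast.i_top, contrast.var_top, lia.t)
    if mode == "top_vs_bottom":
        p_ref = _stratum_disease_prob(rho, contrast.i_bottom, contrast.var_bottom, lia.t)
    else:
        p_ref = lia.K
    return (p_top / (1.0 - p_top)) / (p_ref / (1.0 - p_ref))
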