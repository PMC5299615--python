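"""Genetic profile scores by GBLUP and its SNP-BLUP (ridge) equivalent.

GBLUP treats individual genetic values as a random effect with covariance
proportional to the GRM.  With discovery phenotypes y (centered) and
shrinkage ratio lambda = (1 - h²)/h², the predicted genetic profile
scores of target individuals are

    ghat_target = G_td (G_dd + lambda I)^-1 y_d.

The identical predictions arise from ridge regression on standardized
SNP dosages (SNP-BLUP) when the GRM is built from the same dosages; the
two routes serve as mutual numerical checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .grm import GenotypeMatrix, Grm, standardize_dosages

__all__ = ["GblupConfig", "ProfileScoreSet", "gblup_predict", "snp_blup_predict"]


@dataclass(frozen=True)
class GblupConfig:
    """Shrinkage configuration for (G)BLUP.

    ``h2_assumed`` sets lambda = (1 - h²)/h² on the standardized-GRM
    scale; it is supplied by the user, not estimated.  ``jitter`` is added
    to the diagonal before factorization for numerical stability.
    """

    h2_assumed: float
    jitter: float = 1e-8

    def __post_init__(self) -> None:
        if not 0.0 < self.h2_assumed < 1.0:
            raise ValueError(f"h2_assumed must be in (0, 1), got {self.h2_assumed}")

    @property
    def lam(self) -> float:
        return (1.0 - self.h2_assumed) / self.h2_assumed


@dataclass
class ProfileScoreSet:
    """Estimated genetic profile scores for a set of individuals."""

    individual_ids: list[str]
    scores: np.ndarray
    true_values: np.ndarray | None = None
    phenotypes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(set(self.individual_ids)) != len(self.individual_ids):
            raise ValueError("duplicate individual ids")
        if self.scores.shape != (len(self.individual_ids),):
            raise ValueError("scores length does not match ids")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("non-finite scores")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"id": self.individual_ids, "score": self.scores})
        if self.true_values is not None:
            df["true_value"] = self.true_values
        if self.phenotypes is not None:
            df["phenotype"] = self.phenotypes
        return df


def _gls_mean(chol, y: np.ndarray) -> float:
    """Generalized-least-squares estimate of the overall mean.

    mu = (1' V^-1 y) / (1' V^-1 1) with V the shrunken relationship
    matrix.  A plain arithmetic mean is biased in ascertained samples,
    where genotype means are shifted toward risk alleles; the GLS mean
    absorbs that shift into the fixed intercept.
    """
    ones = np.ones_like(y)
    vi1 = cho_solve(chol, ones)
    return float((vi1 @ y) / (vi1 @ ones))


def gblup_predict(
    G: Grm,
    y_discovery: np.ndarray,
    discovery_ids: list[str],
    target_ids: list[str],
    cfg: GblupConfig,
) -> ProfileScoreSet:
    """Predict target genetic profile scores from discovery phenotypes.

    An overall mean is fitted by GLS and removed; predictions are
    deterministic given the inputs.
    """
    y = np.asarray(y_discovery, dtype=float)
    if y.shape != (len(discovery_ids),):
        raise ValueError("phenotype length does not match discovery ids")
    di = G.indices(discovery_ids)
    ti = G.indices(target_ids)
    Gdd = G.values[np.ix_(di, di)].copy()
    Gdd[np.diag_indices_from(Gdd)] += cfg.lam + cfg.jitter
    try:
        c = cho_factor(Gdd, lower=True)
    except np.linalg.LinAlgError as err:  # pragma: no cover - defensive
        raise np.linalg.LinAlgError(
            "GBLUP system not positive definite after jitter"
        ) from err
    alpha = cho_solve(c, y - _gls_mean(c, y))
    scores = G.values[np.ix_(ti, di)] @ alpha
    return ProfileScoreSet(individual_ids=list(target_ids), scores=scores)


def snp_blup_predict(
    X_discovery: GenotypeMatrix,
    y_discovery: np.ndarray,
    X_target: GenotypeMatrix,
    cfg: GblupConfig,
) -> ProfileScoreSet:
    """Ridge regression on standardized dosages, projected onto targets.

    SNP effects beta = Z'(Z Z'/m + lambda I)^-1 y / m are estimated in the
    discovery set and applied to target rows standardized with the joint
    allele frequencies, matching :func:`gblup_predict` on the same data.
    """
    y = np.asarray(y_discovery, dtype=float)
    nd = X_discovery.n_individuals
    if y.shape != (nd,):
        raise ValueError("phenotype length does not match discovery individuals")
    joint = GenotypeMatrix(
        dosages=np.vstack([X_discovery.dosages, X_target.dosages]),
        individual_ids=list(X_discovery.individual_ids) + list(X_target.individual_ids),
        snp_ids=list(X_discovery.snp_ids),
    )
    Z, _ = standardize_dosages(joint)
    Zd, Zt = Z[:nd], Z[nd:]
    m = Z.shape[1]
    Kdd = Zd @ Zd.T / m
    Kdd[np.diag_indices_from(Kdd)] += cfg.lam + cfg.jitter
    c = cho_factor(Kdd, lower=True)
    alpha = cho_solve(c, y - _gls_mean(c, y))
    beta = Zd.T @ alpha / m
    return ProfileScoreSet(
        individual_ids=list(X_target.individual_ids), scores=Zt @ beta
    )
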