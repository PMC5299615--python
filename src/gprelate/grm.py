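"""Genomic relationship matrices and empirical Me.

The GRM between individuals i and j is the covariance of their
standardized SNP dosages, A = Z Z' / m with Z the column-standardized
dosage matrix (VanRaden/GCTA scaling with observed allele frequencies).
The variance of relationships between a target and a discovery sample
measures how concentrated that relatedness is, and its reciprocal is an
empirical estimate of the effective number of chromosome segments:

    Me = 1 / var(A_ij),   i in target, j in discovery.

Design utilities used in the relatedness experiments live here too:
ranking target individuals by their relationship variance with the
discovery set, and greedy pruning of pairs above a relatedness cut-off.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .me_theory import MeEstimate

__all__ = [
    "GenotypeMatrix",
    "Grm",
    "build_grm",
    "standardize_dosages",
    "me_from_grm",
    "target_variance_ranking",
    "prune_relatedness",
    "read_grm",
    "write_grm",
    "read_dosage_table",
]


@dataclass
class GenotypeMatrix:
    """Dosage matrix (individuals x SNPs) with ids and allele frequencies."""

    dosages: np.ndarray  # float, entries 0/1/2, NaN for missing
    individual_ids: list[str]
    snp_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-dimensional")
        if len(self.individual_ids) != self.dosages.shape[0]:
            raise ValueError("individual_ids length does not match dosage rows")
        if not self.snp_ids:
            self.snp_ids = [f"snp{k + 1}" for k in range(self.dosages.shape[1])]
        if len(self.snp_ids) != self.dosages.shape[1]:
            raise ValueError("snp_ids length does not match dosage columns")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def allele_frequencies(self) -> np.ndarray:
        """Observed allele frequency per SNP (half the mean dosage)."""
        return np.nanmean(self.dosages, axis=0) / 2.0


@dataclass
class Grm:
    """Square symmetric genomic relationship matrix with individual ids."""

    values: np.ndarray
    individual_ids: list[str]
    n_snps: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.individual_ids)
        if self.values.shape != (n, n):
            raise ValueError("GRM shape does not match number of ids")
        self._index = {iid: k for k, iid in enumerate(self.individual_ids)}

    def indices(self, ids: Sequence[str]) -> np.ndarray:
        try:
            return np.array([self._index[i] for i in ids], dtype=int)
        except KeyError as err:
            raise KeyError(f"individual {err.args[0]!r} not in GRM") from None


def standardize_dosages(
    X: GenotypeMatrix, freqs: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Column-standardize dosages; returns (Z, kept column indices).

    Each SNP column has its mean 2p subtracted and is divided by
    sqrt(2p(1-p)) with p the observed allele frequency.  Missing dosages
    are mean-imputed first; monomorphic SNPs are dropped.
    """
    D = X.dosages.copy()
    if freqs is None:
        freqs = X.allele_frequencies()
    col_mean = 2.0 * freqs
    nan_mask = np.isnan(D)
    if nan_mask.any():
        D[nan_mask] = np.broadcast_to(col_mean, D.shape)[nan_mask]
    keep = (freqs > 0.0) & (freqs < 1.0)
    if not keep.any():
        raise ValueError("all SNPs are monomorphic; cannot build a GRM")
    p = freqs[keep]
    Z = (D[:, keep] - col_mean[keep]) / np.sqrt(2.0 * p * (1.0 - p))
    return Z, np.flatnonzero(keep)


def build_grm(X: GenotypeMatrix) -> Grm:
    """GRM A = Z Z' / m from column-standardized dosages."""
    if X.n_individuals < 2:
        raise ValueError("need at least 2 individuals")
    Z, kept = standardize_dosages(X)
    m = kept.size
    if m < X.n_snps:
        import warnings

        warnings.warn(
            f"dropped {X.n_snps - m} monomorphic SNPs", RuntimeWarning, stacklevel=2
        )
    A = Z @ Z.T / m
    return Grm(values=A, individual_ids=list(X.individual_ids), n_snps=m)


def discovery_target_block(
    G: Grm, discovery_ids: Sequence[str], target_ids: Sequence[str]
) -> np.ndarray:
    """The target x discovery off-diagonal block of relationships."""
    d = set(discovery_ids)
    if d & set(target_ids):
        raise ValueError("discovery and target id sets overlap")
    if not discovery_ids or not target_ids:
        raise ValueError("discovery and target sets must be nonempty")
    return G.values[np.ix_(G.indices(target_ids), G.indices(discovery_ids))]


def me_from_grm(
    G: Grm,
    discovery_ids: Sequence[str],
    target_ids: Sequence[str],
    per_target: bool = False,
) -> tuple[MeEstimate, np.ndarray]:
    """Empirical Me from the variance of target-discovery relationships.

    Me = 1/var(A_ij) over the pooled off-diagonal block (population 1/n
    denominator).  With ``per_target=True`` the Me is instead the
    reciprocal of the mean per-target-individual variance.  Also returns
    the per-target variance vector (a diagnostic for subset selection).
    """
    block = discovery_target_block(G, discovery_ids, target_ids)
    per_var = block.var(axis=1)
    v = per_var.mean() if per_target else block.var()
    if v <= 0.0:
        raise ValueError("Me undefined: zero variance of relationships")
    return MeEstimate(value=1.0 / v, method="grm_variance", spec=None), per_var


def target_variance_ranking(
    G: Grm,
    discovery_ids: Sequence[str],
    target_ids: Sequence[str],
    top_fraction: float,
) -> list[str]:
    """Target ids in the top fraction by relationship variance with discovery.

    Higher variance means more close relatives in the discovery set, hence
    a smaller effective Me and better expected prediction for those
    individuals.  Ties are broken by position in ``target_ids``.
    """
    if not 0.0 < top_fraction <= 1.0:
        raise ValueError("top_fraction must be in (0, 1]")
    block = discovery_target_block(G, discovery_ids, target_ids)
    per_var = block.var(axis=1)
    n_keep = max(1, int(round(top_fraction * len(target_ids))))
    order = np.argsort(-per_var, kind="stable")[:n_keep]
    return [target_ids[k] for k in sorted(order)]


def prune_relatedness(G: Grm, threshold: float) -> list[str]:
    """Ids remaining after greedily breaking all pairs with A_ij > threshold.

    Repeatedly removes the individual involved in the most offending
    pairs (ties broken by id order) until no pair exceeds the cut-off.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    A = G.values.copy()
    np.fill_diagonal(A, 0.0)
    active = np.ones(len(G.individual_ids), dtype=bool)
    order = np.argsort(np.asarray(G.individual_ids, dtype=object), kind="stable")
    rank = np.empty_like(order)
    rank[order] = np.arange(order.size)
    while True:
        over = (A > threshold) & active[:, None] & active[None, :]
        deg = over.sum(axis=1)
        if deg.max(initial=0) == 0:
            break
        worst = np.flatnonzero(deg == deg.max())
        victim = worst[np.argmin(rank[worst])]
        active[victim] = False
    return [iid for iid, keep in zip(G.individual_ids, active) if keep]


# ---------------------------------------------------------------------------
# I/O: GCTA-style text GRM and plain dosage tables


def write_grm(G: Grm, prefix: str | Path) -> None:
    """Write ``<prefix>.grm`` (lower-triangle text) and ``<prefix>.grm.id``."""
    prefix = Path(prefix)
    n = len(G.individual_ids)
    with open(f"{prefix}.grm", "w") as fh:
        for i in range(n):
            for j in range(i + 1):
                fh.write(f"{i + 1}\t{j + 1}\t{G.n_snps}\t{G.values[i, j]:.10g}\n")
    with open(f"{prefix}.grm.id", "w") as fh:
        for iid in G.individual_ids:
            fh.write(f"{iid}\t{iid}\n")


def read_grm(prefix: str | Path) -> Grm:
    """Read a GCTA-style text GRM written by :func:`write_grm`."""
    prefix = Path(prefix)
    ids = [line.split()[1] for line in open(f"{prefix}.grm.id") if line.strip()]
    n = len(ids)
    A = np.full((n, n), np.nan)
    n_snps = 0
    with open(f"{prefix}.grm") as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 4:
                raise ValueError(
                    f"{prefix}.grm line {lineno}: expected 4 fields, got {len(fields)}"
                )
            i, j = int(fields[0]) - 1, int(fields[1]) - 1
            if not (0 <= j <= i < n):
                raise ValueError(f"{prefix}.grm line {lineno}: index out of range")
            if not np.isnan(A[i, j]):
                raise ValueError(f"{prefix}.grm line {lineno}: duplicate entry")
            n_snps = int(fields[2])
            A[i, j] = A[j, i] = float(fields[3])
    if np.isnan(A).any():
        raise ValueError(f"{prefix}.grm: missing lower-triangle entries")
    return Grm(values=A, individual_ids=ids, n_snps=n_snps)


def read_dosage_table(path: str | Path) -> GenotypeMatrix:
    """Read a tab-delimited dosage table (PLINK .raw compatible).

    First two columns are family id and individual id; any of the PLINK
    header columns PAT/MAT/SEX/PHENOTYPE are skipped if present; remaining
    columns are per-SNP dosages in {0, 1, 2} (NA allowed).
    """
    df = pd.read_csv(path, sep=r"\s+")
    cols = list(df.columns)
    skip = {"PAT", "MAT", "SEX", "PHENOTYPE"}
    snp_cols = [c for c in cols[2:] if c.upper() not in skip]
    ids = df.iloc[:, 1].astype(str).tolist()
    return GenotypeMatrix(
        dosages=df[snp_cols].to_numpy(dtype=float),
        individual_ids=ids,
        snp_ids=snp_cols,
    )
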