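"""Liability-threshold case-control simulator with independent SNPs.

Each individual carries ``m_snps`` independent biallelic SNPs (allele
frequencies uniform on (0.05, 0.95), Hardy-Weinberg genotypes).  SNP
effects on the liability scale are normal, scaled so the genetic variance
is ``h2``; liability adds a normal residual, and an individual is a case
iff liability exceeds the prevalence-K threshold.  The discovery set is
case-enriched to a proportion P by rejection sampling from the
prevalence-K population; the target set is an unascertained population
sample.

Design utilities used in the relatedness experiments are included:
dichotomizing a quantitative phenotype into an ascertained case-control
subset, and family-wise versus within-family discovery/target splits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grm import GenotypeMatrix
from .liability import liability_quantities

__all__ = [
    "CaseControlSimConfig",
    "CaseControlResult",
    "simulate_case_control",
    "dichotomize_phenotype",
    "split_family_wise",
    "split_within_family",
]


@dataclass(frozen=True)
class CaseControlSimConfig:
    m_snps: int = 254  # typically set to a target Me
    h2: float = 0.5
    K: float = 0.1
    P: float = 0.5
    n_discovery: int = 3000
    n_target: int = 30000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m_snps < 1:
            raise ValueError("m_snps must be >= 1")
        if not 0.0 < self.h2 < 1.0:
            raise ValueError("h2 must be in (0, 1)")
        if not 0.0 < self.K < 1.0 or not 0.0 < self.P < 1.0:
            raise ValueError("K and P must be in (0, 1)")


@dataclass
class CaseControlResult:
    discovery: GenotypeMatrix
    discovery_status: np.ndarray  # 0/1
    target: GenotypeMatrix
    target_status: np.ndarray
    g_true_discovery: np.ndarray  # genetic liabilities
    g_true_target: np.ndarray
    snp_effects: np.ndarray
    allele_freqs: np.ndarray


def _population(
    n: int,
    freqs: np.ndarray,
    beta: np.ndarray,
    h2: float,
    threshold: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Genotypes, genetic liabilities and status for n population draws."""
    dos = rng.binomial(2, freqs, size=(n, freqs.size)).astype(float)
    Z = (dos - 2.0 * freqs) / np.sqrt(2.0 * freqs * (1.0 - freqs))
    g = Z @ beta
    liab = g + rng.standard_normal(n) * np.sqrt(1.0 - h2)
    return dos, g, (liab > threshold).astype(int)


def simulate_case_control(
    cfg: CaseControlSimConfig, rng: np.random.Generator | None = None
) -> CaseControlResult:
    """Simulate an ascertained discovery set and a population target set."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    t = liability_quantities(cfg.K).t
    freqs = rng.uniform(0.05, 0.95, size=cfg.m_snps)
    beta = rng.standard_normal(cfg.m_snps)
    beta *= np.sqrt(cfg.h2 / cfg.m_snps)  # standardized SNPs: var(g) = h2

    n_cases = int(round(cfg.n_discovery * cfg.P))
    n_controls = cfg.n_discovery - n_cases
    cases_d, cases_g, ctrls_d, ctrls_g = [], [], [], []
    have_cases = have_ctrls = 0
    drawn, cap = 0, int(50 * cfg.n_discovery / cfg.K)
    while have_cases < n_cases or have_ctrls < n_controls:
        if drawn >= cap:
            raise RuntimeError(
                f"could not ascertain {n_cases} cases within {cap} draws; "
                "increase the cap or lower P"
            )
        chunk = min(cap - drawn, max(1000, int(n_cases / max(cfg.K, 1e-6))))
        dos, g, status = _population(chunk, freqs, beta, cfg.h2, t, rng)
        drawn += chunk
        case_idx = np.flatnonzero(status == 1)[: n_cases - have_cases]
        ctrl_idx = np.flatnonzero(status == 0)[: n_controls - have_ctrls]
        cases_d.append(dos[case_idx]), cases_g.append(g[case_idx])
        ctrls_d.append(dos[ctrl_idx]), ctrls_g.append(g[ctrl_idx])
        have_cases += case_idx.size
        have_ctrls += ctrl_idx.size
    disc_dos = np.vstack(cases_d + ctrls_d)
    disc_g = np.concatenate(cases_g + ctrls_g)
    disc_status = np.concatenate([np.ones(n_cases, int), np.zeros(n_controls, int)])
    perm = rng.permutation(cfg.n_discovery)
    disc_dos, disc_g, disc_status = disc_dos[perm], disc_g[perm], disc_status[perm]

    targ_dos, targ_g, targ_status = _population(
        cfg.n_target, freqs, beta, cfg.h2, t, rng
    )

    snp_ids = [f"snp{k + 1}" for k in range(cfg.m_snps)]
    disc_ids = [f"d{k + 1}" for k in range(cfg.n_discovery)]
    targ_ids = [f"t{k + 1}" for k in range(cfg.n_target)]
    return CaseControlResult(
        discovery=GenotypeMatrix(disc_dos, disc_ids, snp_ids),
        discovery_status=disc_status,
        target=GenotypeMatrix(targ_dos, targ_ids, snp_ids),
        target_status=targ_status,
        g_true_discovery=disc_g,
        g_true_target=targ_g,
        snp_effects=beta,
        allele_freqs=freqs,
    )


def dichotomize_phenotype(
    values: np.ndarray,
    K: float,
    P: float,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Turn a quantitative phenotype into an ascertained case-control subset.

    The top-K fraction of values become cases; controls are sampled from
    the remainder so the selected subset has case proportion P.  Returns
    (status, selected_indices); status is aligned with selected_indices.
    Ties at the cut are broken by stable sort order.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    values = np.asarray(values, dtype=float)
    n = values.size
    if not 0.0 < K < 1.0:
        raise ValueError("K must be in (0, 1)")
    if np.ptp(values) == 0.0:
        raise ValueError("constant phenotype vector cannot be dichotomized")
    n_cases = int(round(n * K))
    order = np.argsort(-values, kind="stable")
    case_idx = order[:n_cases]
    rest = order[n_cases:]
    n_controls = int(round(n_cases * (1.0 - P) / P))
    if n_controls > rest.size:
        raise ValueError(
            f"case proportion P={P} infeasible: needs {n_controls} controls, "
            f"only {rest.size} available"
        )
    ctrl_idx = rng.choice(rest, size=n_controls, replace=False)
    selected = np.concatenate([case_idx, ctrl_idx])
    status = np.concatenate([np.ones(n_cases, int), np.zeros(n_controls, int)])
    return status, selected


def _split(
    family_ids: np.ndarray, fraction: float, seed: int, family_wise: bool
) -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng(seed)
    family_ids = np.asarray(family_ids)
    n = family_ids.size
    for _ in range(2):  # one resample if a side comes out empty
        if family_wise:
            fams = np.unique(family_ids)
            in_disc = np.isin(family_ids, fams[rng.random(fams.size) < fraction])
        else:
            in_disc = rng.random(n) < fraction
        if in_disc.any() and not in_disc.all():
            return np.flatnonzero(in_disc), np.flatnonzero(~in_disc)
    raise ValueError("split produced an empty discovery or target side")


def split_family_wise(
    family_ids: np.ndarray, fraction: float = 0.8, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Assign whole families to discovery (probability ``fraction``) or target.

    Discovery and target then share only distant ancestry: a large
    effective Ne/Me design.  Returns (discovery_indices, target_indices).
    """
    return _split(family_ids, fraction, seed, family_wise=True)


def split_within_family(
    family_ids: np.ndarray, fraction: float = 0.8, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Assign each individual independently, splitting inside families.

    Close relatives end up on both sides: a small effective Ne/Me design.
    """
    return _split(family_ids, fraction, seed, family_wise=False)
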