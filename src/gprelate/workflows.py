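"""High-level workflows binding theory, simulators and predictors together.

Two entry points mirror the study design: an analytic sweep of expected
performance over a grid of effective population sizes, and
simulation-based validation runs that compare observed statistics against
their theoretical expectations over replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import metrics
from .accuracy import (
    TraitDesign,
    accuracy_case_control,
    accuracy_phenotypic,
    accuracy_quantitative,
    expected_auc,
    expected_or,
)
from .gblup import GblupConfig, snp_blup_predict
from .grm import build_grm, me_from_grm
from .liability import liability_quantities, percentile_quantities
from .me_theory import PopulationGenomeSpec, me_closed_form_genome, me_closed_form_single
from .sim_casecontrol import CaseControlSimConfig, simulate_case_control
from .sim_genedrop import GenedropConfig, simulate_genedrop

__all__ = ["run_theory_curves", "run_validation_genedrop", "run_validation_casecontrol"]


def run_theory_curves(
    ne_grid: list[float],
    n_chr: int = 30,
    chr_length: float = 1.0,
    h2: float = 0.5,
    N: int = 3000,
    K: float = 0.1,
    P: float = 0.5,
    top_fraction: float = 0.2,
    top_fraction_pop: float = 0.01,
    mutation_correction: bool = True,
) -> pd.DataFrame:
    """Expected Me, accuracy, AUC and ORs over a grid of Ne values.

    Deterministic: the analytic twin of the simulation experiments.
    """
    lia = liability_quantities(K)
    design_q = TraitDesign(h2=h2, N=N)
    design_cc = TraitDesign(h2=h2, N=N, P=P)
    c_tb = percentile_quantities(top_fraction)
    c_pop = percentile_quantities(top_fraction_pop, top_fraction_pop)
    rows = []
    for ne in ne_grid:
        spec = PopulationGenomeSpec(
            Ne=ne, n_chr=n_chr, chr_length=chr_length, mutation_correction=mutation_correction
        )
        me = me_closed_form_genome(spec)
        rows.append(
            {
                "Ne": ne,
                "Me": me.value,
                "r_true": accuracy_quantitative(design_q, me),
                "r_pheno": accuracy_phenotypic(design_q, me),
                "rho_01": accuracy_case_control(design_cc, me, lia),
                "auc": expected_auc(design_cc, me, lia),
                "or_top_bottom": expected_or(design_cc, me, lia, c_tb, "top_vs_bottom"),
                "or_top_population": expected_or(
                    design_cc, me, lia, c_pop, "top_vs_population"
                ),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class ValidationReport:
    """Observed-vs-expected comparison over simulation replicates."""

    table: pd.DataFrame  # one row per replicate
    expected: dict[str, float]
    coverage: dict[str, bool]  # expected inside the empirical 95% interval
    n_replicates: int

    def summary(self) -> pd.DataFrame:
        rows = []
        for name, exp in self.expected.items():
            obs = self.table[name]
            lo, hi = np.percentile(obs, [2.5, 97.5]) if len(obs) > 1 else (np.nan, np.nan)
            rows.append(
                {
                    "quantity": name,
                    "expected": exp,
                    "observed_mean": obs.mean(),
                    "observed_sd": obs.std(ddof=1) if len(obs) > 1 else np.nan,
                    "ci95_low": lo,
                    "ci95_high": hi,
                    "covered": self.coverage[name],
                }
            )
        return pd.DataFrame(rows)


def _coverage(table: pd.DataFrame, expected: dict[str, float]) -> dict[str, bool]:
    out = {}
    for name, exp in expected.items():
        obs = table[name].to_numpy()
        if obs.size < 2:
            out[name] = False  # undefined interval
        else:
            lo, hi = np.percentile(obs, [2.5, 97.5])
            out[name] = bool(lo <= exp <= hi)
    return out


def run_validation_genedrop(
    cfg: GenedropConfig, n_replicates: int = 20, seed: int = 0
) -> ValidationReport:
    """Gene-dropping validation: empirical Me and observed GBLUP accuracy.

    Per replicate: simulate, estimate Me from the discovery-target GRM
    block, and correlate GBLUP scores with true genetic values in the
    target set.  Expected values come from the closed-form Me and the
    accuracy formula evaluated at it.
    """
    spec = PopulationGenomeSpec(
        Ne=cfg.Ne, n_chr=1, chr_length=cfg.chr_length, mutation_correction=True
    )
    me_exp = (
        me_closed_form_single(spec).value
        if cfg.n_chr == 1
        else me_closed_form_genome(replace(spec, n_chr=cfg.n_chr)).value
    )
    design = TraitDesign(h2=cfg.h2_sim, N=cfg.n_discovery)
    acc_exp = accuracy_quantitative(design, me_exp)
    rows = []
    for rep in range(n_replicates):
        rng = np.random.default_rng((seed + rep) % 2**31)
        res = simulate_genedrop(replace(cfg, seed=(seed + rep) % 2**31), rng)
        all_dos = np.vstack([res.discovery.dosages, res.target.dosages])
        ids = res.discovery.individual_ids + res.target.individual_ids
        from .grm import GenotypeMatrix

        G = build_grm(GenotypeMatrix(all_dos, ids, res.discovery.snp_ids))
        me_obs, _ = me_from_grm(G, res.discovery.individual_ids, res.target.individual_ids)
        scores = snp_blup_predict(
            res.discovery,
            res.phenotypes,
            res.target,
            GblupConfig(h2_assumed=cfg.h2_sim),
        )
        acc_obs = float(np.corrcoef(scores.scores, res.g_true_target)[0, 1])
        rows.append({"replicate": rep, "me": me_obs.value, "accuracy": acc_obs})
    table = pd.DataFrame(rows)
    expected = {"me": me_exp, "accuracy": acc_exp}
    return ValidationReport(
        table=table,
        expected=expected,
        coverage=_coverage(table, expected),
        n_replicates=n_replicates,
    )


def run_validation_casecontrol(
    cfg: CaseControlSimConfig,
    n_replicates: int = 10,
    seed: int = 0,
    top_fraction: float = 0.2,
    top_fraction_pop: float = 0.01,
) -> ValidationReport:
    """Case-control validation: observed AUC and percentile ORs vs theory.

    GBLUP is run on the 0/1 status with shrinkage set from the
    observed-scale heritability of the ascertained sample; AUC and ORs
    are measured in the unascertained target sample.
    """
    lia = liability_quantities(cfg.K)
    design = TraitDesign(h2=cfg.h2, N=cfg.n_discovery, P=cfg.P)
    c_tb = percentile_quantities(top_fraction)
    c_pop = percentile_quantities(top_fraction_pop, top_fraction_pop)
    expected = {
        "auc": expected_auc(design, cfg.m_snps, lia),
        "or_top_bottom": expected_or(design, cfg.m_snps, lia, c_tb, "top_vs_bottom"),
        "or_top_population": expected_or(
            design, cfg.m_snps, lia, c_pop, "top_vs_population"
        ),
    }
    h2_01 = (
        cfg.h2 * lia.z**2 * cfg.P * (1 - cfg.P) / (cfg.K**2 * (1 - cfg.K) ** 2)
    )
    gb_cfg = GblupConfig(h2_assumed=min(h2_01, 0.99))
    rows = []
    for rep in range(n_replicates):
        rng = np.random.default_rng((seed + rep) % 2**31)
        res = simulate_case_control(replace(cfg, seed=(seed + rep) % 2**31), rng)
        scores = snp_blup_predict(
            res.discovery, res.discovery_status.astype(float), res.target, gb_cfg
        )
        rows.append(
            {
                "replicate": rep,
                "auc": metrics.observed_auc(scores.scores, res.target_status),
                "or_top_bottom": metrics.observed_or(
                    scores.scores, res.target_status, top_fraction, "bottom"
                ).odds_ratio,
                "or_top_population": metrics.observed_or(
                    scores.scores, res.target_status, top_fraction_pop, "population"
                ).odds_ratio,
            }
        )
    table = pd.DataFrame(rows)
    return ValidationReport(
        table=table,
        expected=expected,
        coverage=_coverage(table, expected),
        n_replicates=n_replicates,
    )
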