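"""Observed performance of genetic profile scores: AUC and percentile ORs.

These estimators mirror the expected quantities in :mod:`gprelate.accuracy`
so theory and simulation can be compared directly.  AUC is the normalized
Mann-Whitney U statistic (ties count one half); odds ratios come from the
2x2 contingency cross-product over rank-defined score strata.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

__all__ = ["ContrastResult", "observed_auc", "observed_or", "decile_or_profile"]


@dataclass(frozen=True)
class ContrastResult:
    """A 2x2 stratum-by-status table and its odds ratio."""

    stratum: str
    reference: str
    cases_stratum: float
    controls_stratum: float
    cases_reference: float
    controls_reference: float
    odds_ratio: float
    log_or_se: float
    corrected: bool = False  # Haldane-Anscombe 0.5 applied to a zero cell


def _check_scores_status(scores, status) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    status = np.asarray(status, dtype=int)
    if scores.shape != status.shape or scores.ndim != 1:
        raise ValueError("scores and status must be 1-d arrays of equal length")
    if not set(np.unique(status)) <= {0, 1}:
        raise ValueError("status must be 0/1")
    return scores, status


def observed_auc(scores, status) -> float:
    """Probability that a random case outscores a random control.

    Computed as the rank-sum (Mann-Whitney U) statistic normalized by
    n_cases * n_controls; tied scores contribute 1/2.
    """
    scores, status = _check_scores_status(scores, status)
    n1 = int(status.sum())
    n0 = status.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both cases and controls are required for AUC")
    ranks = rankdata(scores)  # average ranks handle ties
    u = ranks[status == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def _table_or(a: float, b: float, c: float, d: float) -> tuple[float, float, bool]:
    """Cross-product OR for table [[a, b], [c, d]]; 0.5 correction on zeros."""
    corrected = 0.0 in (a, b, c, d)
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (b * c)
    se = float(np.sqrt(1 / a + 1 / b + 1 / c + 1 / d))
    return float(or_), se, corrected


def _tail_indices(scores: np.ndarray, fraction: float, top: bool) -> np.ndarray:
    n = scores.size
    k = int(np.floor(n * fraction))
    if k < 1:
        raise ValueError(f"fraction {fraction} selects no individuals (n={n})")
    order = np.argsort(scores, kind="stable")
    return order[-k:] if top else order[:k]


def observed_or(
    scores, status, top_fraction: float, reference: str = "bottom", bottom_fraction: float | None = None
) -> ContrastResult:
    """Odds ratio of case status for the top score stratum vs a reference.

    ``reference='bottom'`` contrasts against the bottom ``bottom_fraction``
    (default: same as top); ``reference='population'`` contrasts against
    the full sample.
    """
    scores, status = _check_scores_status(scores, status)
    if reference not in ("bottom", "population"):
        raise ValueError("reference must be 'bottom' or 'population'")
    top_idx = _tail_indices(scores, top_fraction, top=True)
    a = status[top_idx].sum()
    b = top_idx.size - a
    if reference == "bottom":
        bot_idx = _tail_indices(scores, bottom_fraction or top_fraction, top=False)
        c = status[bot_idx].sum()
        d = bot_idx.size - c
        ref_name = f"bottom {100 * (bottom_fraction or top_fraction):g}%"
    else:
        c = status.sum()
        d = status.size - c
        ref_name = "population"
    or_, se, corrected = _table_or(a, b, c, d)
    return ContrastResult(
        stratum=f"top {100 * top_fraction:g}%",
        reference=ref_name,
        cases_stratum=float(a),
        controls_stratum=float(b),
        cases_reference=float(c),
        controls_reference=float(d),
        odds_ratio=or_,
        log_or_se=se,
        corrected=corrected,
    )


def decile_or_profile(scores, status, bin_fraction: float = 0.2) -> list[ContrastResult]:
    """OR of each consecutive score bin against the bottom bin.

    Scores are ranked and cut into bins of ``bin_fraction`` each (bin
    boundaries at floor(n * q), stable tie order); the bottom bin versus
    itself is reported as OR = 1 for completeness.
    """
    scores, status = _check_scores_status(scores, status)
    n = scores.size
    n_bins = int(round(1.0 / bin_fraction))
    order = np.argsort(scores, kind="stable")
    edges = [int(np.floor(n * k * bin_fraction)) for k in range(n_bins)] + [n]
    bins = [order[edges[k] : edges[k + 1]] for k in range(n_bins)]
    c_ref = status[bins[0]].sum()
    d_ref = bins[0].size - c_ref
    out = []
    for k, idx in enumerate(bins):
        a = status[idx].sum()
        b = idx.size - a
        if k == 0:
            out.append(
                ContrastResult(
                    stratum="bin 1",
                    reference="bin 1",
                    cases_stratum=float(a),
                    controls_stratum=float(b),
                    cases_reference=float(c_ref),
                    controls_reference=float(d_ref),
                    odds_ratio=1.0,
                    log_or_se=0.0,
                )
            )
            continue
        or_, se, corrected = _table_or(a, b, c_ref, d_ref)
        out.append(
            ContrastResult(
                stratum=f"bin {k + 1}",
                reference="bin 1",
                cases_stratum=float(a),
                controls_stratum=float(b),
                cases_reference=float(c_ref),
                controls_reference=float(d_ref),
                odds_ratio=or_,
                log_or_se=se,
                corrected=corrected,
            )
        )
    return out
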