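"""Differential peptide-marker screening.

Consensus peptides pass a detection-frequency filter (>= 70% in at least one
diagnostic group), are tested with a two-sided Wilcoxon rank-sum test (exact
permutation distribution for small groups, tie-corrected normal approximation
otherwise), adjusted with the Benjamini-Hochberg step-up procedure, and called
significant at adjusted p < alpha with regulation from group mean amplitudes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .featmatch import ConsensusPeptide

logger = logging.getLogger(__name__)

EXACT_MAX_N = 8  # exact branch when min(n, m) <= this


@dataclass
class MarkerResult:
    cluster_id: int
    frequency_case: float
    frequency_control: float
    p_raw: float
    p_adjusted: float
    mean_amp_case: float
    mean_amp_control: float
    regulation: Optional[str]  # "up" / "down"; None = exact mean tie, excluded
    significant: bool


def frequency_filter(
    peptides: Sequence[ConsensusPeptide],
    case_group: str,
    control_group: str,
    threshold: float = 0.70,
) -> List[ConsensusPeptide]:
    """Retain peptides detected in >= threshold of at least one group."""
    return [
        p
        for p in peptides
        if max(
            p.frequencies.get(case_group, 0.0), p.frequencies.get(control_group, 0.0)
        )
        >= threshold
    ]


def _midranks(values: np.ndarray) -> np.ndarray:
    return stats.rankdata(values, method="average")


def _exact_ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided rank-sum p by full permutation of group labels.

    Mid-ranks handle ties. The distribution of the case-group rank sum over
    all C(n+m, n) label assignments is computed by subset-sum dynamic
    programming over the (doubled, hence integral) ranks; two-sided
    p = min(1, 2 * min(P(W <= w), P(W >= w))).
    """
    n = len(x)
    combined = np.concatenate([x, y])
    ranks2 = np.rint(2.0 * _midranks(combined)).astype(np.int64)  # integral
    w2 = int(ranks2[:n].sum())

    # dp[k] maps achievable rank-sum -> number of k-subsets achieving it
    dp: List[Dict[int, int]] = [dict() for _ in range(n + 1)]
    dp[0][0] = 1
    for r in ranks2:
        r = int(r)
        for k in range(n - 1, -1, -1):
            if not dp[k]:
                continue
            tgt = dp[k + 1]
            for s, c in dp[k].items():
                tgt[s + r] = tgt.get(s + r, 0) + c
    dist = dp[n]
    n_total = sum(dist.values())
    p_le = sum(c for s, c in dist.items() if s <= w2) / n_total
    p_ge = sum(c for s, c in dist.items() if s >= w2) / n_total
    return min(1.0, 2.0 * min(p_le, p_ge))


def ranksum_test(
    case_amplitudes: Sequence[float], control_amplitudes: Sequence[float]
) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact permutation distribution when min(n, m) <= 8 (cohort sizes of 7-10
    make the normal approximation marginal); tie- and continuity-corrected
    normal approximation otherwise.
    """
    x = np.asarray(case_amplitudes, dtype=float)
    y = np.asarray(control_amplitudes, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups need at least one observation")
    if min(len(x), len(y)) <= EXACT_MAX_N:
        return _exact_ranksum_p(x, y)
    return float(
        stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
    )


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, returned in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m, dtype=float)
    out[order] = adjusted
    return out


def amplitude_matrix(
    peptide: ConsensusPeptide,
    groups: Mapping[str, str],
    case_group: str,
    control_group: str,
    zero_fill: bool = True,
) -> Tuple[np.ndarray, np.ndarray]:
    """Per-group amplitude vectors for one peptide.

    With ``zero_fill`` (default) a sample in which the peptide was not
    detected contributes amplitude 0, preserving the presence/absence signal;
    otherwise missing samples are dropped.
    """
    case, control = [], []
    for sample_id, group in groups.items():
        amp = peptide.amplitudes.get(sample_id)
        if amp is None:
            if not zero_fill:
                continue
            amp = 0.0
        if group == case_group:
            case.append(amp)
        elif group == control_group:
            control.append(amp)
    return np.asarray(case), np.asarray(control)


def call_markers(
    peptides: Sequence[ConsensusPeptide],
    groups: Mapping[str, str],
    case_group: str,
    control_group: str,
    alpha: float = 0.05,
    zero_fill: bool = True,
) -> List[MarkerResult]:
    """Test filtered peptides and call significance at adjusted p < alpha.

    Peptides whose group means tie exactly get ``regulation=None`` and are
    excluded from the downstream orthology/protease stages by their callers;
    peptides with an empty group (only possible with ``zero_fill=False``)
    are skipped with a log entry.
    """
    tested: List[Tuple[ConsensusPeptide, float, float, float]] = []
    for pep in peptides:
        case, control = amplitude_matrix(
            pep, groups, case_group, control_group, zero_fill=zero_fill
        )
        if len(case) == 0 or len(control) == 0:
            logger.warning("cluster %s: empty group, skipped", pep.cluster_id)
            continue
        p = ranksum_test(case, control)
        tested.append((pep, p, float(np.mean(case)), float(np.mean(control))))

    adjusted = bh_adjust([t[1] for t in tested])
    results: List[MarkerResult] = []
    for (pep, p_raw, mc, mctl), p_adj in zip(tested, adjusted):
        if mc > mctl:
            regulation: Optional[str] = "up"
        elif mc < mctl:
            regulation = "down"
        else:
            regulation = None
            logger.info("cluster %s: tied group means, flagged unregulated", pep.cluster_id)
        results.append(
            MarkerResult(
                cluster_id=pep.cluster_id,
                frequency_case=pep.frequencies.get(case_group, 0.0),
                frequency_control=pep.frequencies.get(control_group, 0.0),
                p_raw=p_raw,
                p_adjusted=float(p_adj),
                mean_amp_case=mc,
                mean_amp_control=mctl,
                regulation=regulation,
                significant=bool(p_adj < alpha),
            )
        )
    results.sort(key=lambda r: (r.p_adjusted, r.cluster_id))
    return results
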