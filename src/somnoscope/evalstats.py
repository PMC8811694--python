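"""Quantitative evaluation statistics for sleep-staging studies.

Per-segment macro-F1 against ground truth, pairwise Cohen kappa between
raters under the same scoring setting, a Wilcoxon signed-rank test for
clustered paired data (scores contributed by the same rater are correlated),
and correction-rate metrics for AI-incorrect epochs.

The clustered test is a moment-based signed-rank construction: the statistic
is the total signed rank T = sum_ij s_ij R_ij, and its null variance adds to
the independent-pairs term sum R^2 a within-cluster cross term
rho_c * [(sum_j R_cj)^2 - sum_j R_cj^2], where rho_c is a sign-concordance
estimate of the within-cluster correlation of signed ranks computed from
the *other* clusters (leave-one-cluster-out, which decouples a cluster's
score from its own variance weight).  With singleton clusters the cross
terms vanish and the test reduces exactly to the normal-approximation
Wilcoxon signed-rank test (including the tie correction), which is the
oracle the test suite checks against.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import NamedTuple

import numpy as np
from scipy import stats as _stats
from sklearn.metrics import cohen_kappa_score, f1_score

from .synthetic import STAGES
from .templates import ValidationError

__all__ = [
    "ScoringRecord",
    "PairedComparison",
    "TestResult",
    "CorrectionRates",
    "macro_f1",
    "cohen_kappa",
    "pairwise_kappa",
    "clustered_wilcoxon",
    "correction_rates",
]


@dataclass(frozen=True)
class ScoringRecord:
    """One rater's stage sequence for one segment under one scoring setting."""

    segment_id: str
    rater_id: str
    setting: str  # cdss | ai_only | conventional
    stages: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.setting not in ("cdss", "ai_only", "conventional"):
            raise ValidationError(f"unknown setting {self.setting!r}")
        if not self.stages:
            raise ValidationError("stages must be non-empty")
        bad = [s for s in self.stages if s not in STAGES]
        if bad:
            raise ValidationError(f"unknown stage labels {sorted(set(bad))}")
        object.__setattr__(self, "stages", tuple(self.stages))


@dataclass(frozen=True)
class PairedComparison:
    """Per-unit score pairs with a cluster id per pair (typically the rater)."""

    score1: np.ndarray
    score2: np.ndarray
    cluster_ids: np.ndarray

    def __post_init__(self) -> None:
        s1 = np.asarray(self.score1, dtype=float)
        s2 = np.asarray(self.score2, dtype=float)
        cid = np.asarray(self.cluster_ids)
        if not (s1.shape == s2.shape == cid.shape) or s1.ndim != 1 or s1.size == 0:
            raise ValidationError("score1, score2 and cluster_ids must be equal-length 1-D arrays")
        object.__setattr__(self, "score1", s1)
        object.__setattr__(self, "score2", s2)
        object.__setattr__(self, "cluster_ids", cid)


@dataclass(frozen=True)
class TestResult:
    p_value: float
    z_statistic: float
    n: int
    n_clusters: int
    effect_size_r: float


def _check_sequences(a, b) -> tuple[list, list]:
    a, b = list(a), list(b)
    if len(a) != len(b):
        raise ValidationError(f"sequence lengths differ: {len(a)} vs {len(b)}")
    if not a:
        raise ValidationError("sequences must be non-empty")
    return a, b


def macro_f1(predicted, truth) -> float:
    """Unweighted mean of per-class F1 over the classes present in truth.

    A class present in truth but never predicted contributes F1 = 0; classes
    absent from truth are not averaged (short segments rarely contain all
    five stages).
    """
    predicted, truth = _check_sequences(predicted, truth)
    labels = sorted(set(truth))
    return float(f1_score(truth, predicted, labels=labels, average="macro", zero_division=0))


def cohen_kappa(stages_a, stages_b) -> float:
    """Unweighted Cohen kappa; defined as 1 when both raters agree perfectly
    on a single constant label (p_e = p_o = 1)."""
    stages_a, stages_b = _check_sequences(stages_a, stages_b)
    if stages_a == stages_b and len(set(stages_a)) == 1:
        return 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return float(cohen_kappa_score(stages_a, stages_b))


def pairwise_kappa(
    records: list[ScoringRecord], setting: str
) -> list[tuple[tuple[str, str], str, float]]:
    """Kappa for every unordered rater pair on every shared segment under
    one setting; ((rater_a, rater_b), segment_id, kappa) tuples."""
    by_segment: dict[str, dict[str, ScoringRecord]] = {}
    for rec in records:
        if rec.setting != setting:
            continue
        by_segment.setdefault(rec.segment_id, {})[rec.rater_id] = rec
    out: list[tuple[tuple[str, str], str, float]] = []
    for segment_id in sorted(by_segment):
        raters = sorted(by_segment[segment_id])
        for ra, rb in combinations(raters, 2):
            out.append(
                (
                    (ra, rb),
                    segment_id,
                    cohen_kappa(by_segment[segment_id][ra].stages, by_segment[segment_id][rb].stages),
                )
            )
    if not out:
        warnings.warn(f"no rater pair shares a segment under setting {setting!r}")
    return out


def clustered_wilcoxon(pairs: PairedComparison, alternative: str = "greater") -> TestResult:
    """Wilcoxon signed-rank test with cluster-robust variance.

    Differences are score2 - score1 (alternative='greater' tests that
    score2 tends to exceed score1); zero differences are dropped by the
    usual Wilcoxon convention.
    """
    if alternative not in ("greater", "two-sided"):
        raise ValidationError("alternative must be 'greater' or 'two-sided'")
    d = pairs.score2 - pairs.score1
    keep = d != 0
    if not keep.any():
        raise ValidationError("all paired differences are zero; the test is undefined")
    d = d[keep]
    clusters = pairs.cluster_ids[keep]
    ranks = _stats.rankdata(np.abs(d))
    signs = np.sign(d)
    total = float((signs * ranks).sum())
    uniq = list(np.unique(clusters))
    concordant, pair_count, cross_rank = {}, {}, {}
    for c in uniq:
        member = clusters == c
        r_c, s_c = ranks[member], signs[member]
        n_pos = int((s_c > 0).sum())
        n_neg = int((s_c < 0).sum())
        g = r_c.size
        concordant[c] = n_pos * (n_pos - 1) + n_neg * (n_neg - 1)
        pair_count[c] = g * (g - 1)
        cross_rank[c] = float(r_c.sum() ** 2 - (r_c**2).sum())
    base = float((ranks**2).sum())
    variance = base
    for c in uniq:
        other_conc = sum(concordant[o] for o in uniq if o != c)
        other_pairs = sum(pair_count[o] for o in uniq if o != c)
        if other_pairs > 0:
            # leave-one-cluster-out sign-concordance estimate of the
            # within-cluster correlation of signed ranks
            rho = 2.0 * other_conc / other_pairs - 1.0
            variance += rho * cross_rank[c]
    variance = max(variance, 0.1 * base)
    z = total / np.sqrt(variance)
    if alternative == "greater":
        p = float(_stats.norm.sf(z))
    else:
        p = float(2.0 * _stats.norm.sf(abs(z)))
    n = int(d.size)
    return TestResult(
        p_value=p,
        z_statistic=float(z),
        n=n,
        n_clusters=len(uniq),
        effect_size_r=float(z / np.sqrt(n)),
    )


class CorrectionRates(NamedTuple):
    """Revision statistics over epochs the AI staged incorrectly.

    ``frac_revised_correct`` uses all AI-incorrect epochs as denominator;
    ``frac_revised_correct_among_revised`` conditions on the epochs the
    technician actually changed (both readings of the rate are reported).
    """

    frac_revised: float
    frac_revised_correct: float
    frac_revised_correct_among_revised: float


def correction_rates(ai_stages, revised_stages, truth_stages) -> CorrectionRates:
    ai, revised = _check_sequences(ai_stages, revised_stages)
    _, truth = _check_sequences(ai_stages, truth_stages)
    incorrect = [i for i in range(len(ai)) if ai[i] != truth[i]]
    if not incorrect:
        raise ValidationError("no incorrectly predicted epochs; correction rates are undefined")
    revised_idx = [i for i in incorrect if revised[i] != ai[i]]
    corrected_idx = [i for i in incorrect if revised[i] == truth[i]]
    n_inc = len(incorrect)
    n_rev = len(revised_idx)
    return CorrectionRates(
        frac_revised=n_rev / n_inc,
        frac_revised_correct=len(corrected_idx) / n_inc,
        frac_revised_correct_among_revised=(len(corrected_idx) / n_rev) if n_rev else 0.0,
    )
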