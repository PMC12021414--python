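"""Group-comparison statistics with the conventions used throughout the pipeline.

Medians are reported with percentile-bootstrap 95% confidence intervals
(1000 resamples).  Group differences use the two-sided Wilcoxon rank-sum
test, with the critical p-value Sidak-corrected for the number of parameter
comparisons in the dataset.  Effect size is the condition-minus-control
difference relative to a reference (the control value by default; the
control fast-bin slope for fin-slope comparisons, to avoid inflating changes
relative to small control values).  A difference is called significant only
when p < p_critical AND |effect size| >= 15% — both criteria together.
Outliers are flagged beyond three scaled median absolute deviations
(scale factor 1.4826, consistent with z-scores at the normal).  Activated-
cell counts are compared with Fisher's exact test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

logger = logging.getLogger(__name__)

MAD_SCALE = 1.4826
MAD_THRESHOLD = 3.0
EFFECT_SIZE_MIN_PCT = 15.0
N_BOOT_MEDIAN = 1000


def median_ci(
    values: np.ndarray, n_boot: int = N_BOOT_MEDIAN, seed: int = 0
) -> tuple[float, float, float]:
    """(median, lo95, hi95): percentile bootstrap of the sample median."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    boot = np.median(values[idx], axis=1)
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return float(np.median(values)), float(lo), float(hi)


def wilcoxon_rank_sum(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact enumeration when the combined sample is small (<= 20) and tie-free;
    otherwise the normal approximation with tie and continuity corrections.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (pooled.size <= 20 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                           use_continuity=True)
    return float(res.pvalue)


def sidak_critical(m_tests: int, alpha: float = 0.05) -> float:
    """Sidak critical p-value: 1 - (1 - alpha)^(1/m)."""
    if m_tests < 1:
        raise ValueError("m_tests must be >= 1")
    return float(1.0 - (1.0 - alpha) ** (1.0 / m_tests))


def effect_size(
    control_value: float, condition_value: float, reference: float | None = None
) -> float:
    """Signed effect size in percent: 100 * (condition - control) / reference.

    ``reference`` defaults to the control value.  For fin-slope comparisons
    pass the control fast-bin slope instead.  The convention is asymmetric:
    swapping groups negates the effect only when the reference is the
    control value.
    """
    if reference is None:
        reference = control_value
    if reference == 0:
        raise ValueError("reference value must be nonzero")
    return 100.0 * (condition_value - control_value) / reference


def effect_size_rounded(
    control_value: float, condition_value: float, reference: float | None = None
) -> int:
    """Effect size rounded to integer percent, the reporting convention."""
    return int(round(effect_size(control_value, condition_value, reference)))


def relative_change(pre_value: float, post_value: float) -> float:
    """Percent change from pre to post, normalized to the pre value."""
    if pre_value == 0:
        raise ValueError("pre value must be nonzero")
    return 100.0 * (post_value - pre_value) / pre_value


def detect_outliers(values: np.ndarray) -> np.ndarray:
    """Boolean mask of values beyond 3 scaled MADs from the median.

    Outlier iff |x - median| > 3 * 1.4826 * MAD.  When MAD is zero there is
    no finite threshold; the documented degenerate rule flags any value not
    equal to the median, with a log entry.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValueError("need at least 3 values")
    med = np.median(values)
    dev = np.abs(values - med)
    mad = np.median(dev)
    if mad == 0:
        logger.warning("MAD is zero; flagging all values differing from the median")
        return dev > 0
    return dev > MAD_THRESHOLD * MAD_SCALE * mad


def fisher_exact(table) -> float:
    """Two-sided Fisher exact p for a 2x2 count table.

    Sums hypergeometric probabilities of all tables (at fixed margins) no
    more probable than the observed one.
    """
    table = np.asarray(table, dtype=int)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("table must be 2x2 with non-negative integer cells")
    return float(sps.fisher_exact(table, alternative="two-sided")[1])


def classify_activated(F: float, F0: float) -> bool:
    """A cell counts as activated iff F/F0 > 2 (strict)."""
    if F0 <= 0:
        raise ValueError("baseline fluorescence F0 must be positive")
    return F / F0 > 2.0


@dataclass
class GroupComparison:
    """One parameter's control-vs-condition comparison row."""

    parameter: str
    control_median: float
    control_ci: tuple[float, float]
    condition_median: float
    condition_ci: tuple[float, float]
    p: float
    p_critical: float
    effect_size_pct: float
    significant: bool

    @property
    def effect_size_pct_rounded(self) -> int:
        return int(round(self.effect_size_pct))


def compare_groups(
    parameter: str,
    control: np.ndarray,
    condition: np.ndarray,
    m_tests: int = 1,
    alpha: float = 0.05,
    effect_reference: float | None = None,
    n_boot: int = N_BOOT_MEDIAN,
    seed: int = 0,
) -> GroupComparison:
    """Full comparison of one kinematic parameter between two groups.

    ``m_tests`` is the number of parameter comparisons in the dataset family
    (it sets the Sidak-corrected critical p).  Significance requires both
    p < p_critical and |effect size| >= 15%.
    """
    cm, clo, chi = median_ci(control, n_boot=n_boot, seed=seed)
    xm, xlo, xhi = median_ci(condition, n_boot=n_boot, seed=seed + 1)
    p = wilcoxon_rank_sum(control, condition)
    p_crit = sidak_critical(m_tests, alpha=alpha)
    eff = effect_size(cm, xm, reference=effect_reference)
    return GroupComparison(
        parameter=parameter,
        control_median=cm,
        control_ci=(clo, chi),
        condition_median=xm,
        condition_ci=(xlo, xhi),
        p=p,
        p_critical=p_crit,
        effect_size_pct=eff,
        significant=bool(p < p_crit and abs(eff) >= EFFECT_SIZE_MIN_PCT),
    )
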