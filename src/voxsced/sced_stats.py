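"""Single-case experimental design statistics.

Tau-U nonoverlap between a baseline phase (A) and a comparison phase (B),
with optional baseline-trend correction; exact permutation p-values for the
tiny samples typical of single-subject designs; and two-way mixed-effects
intraclass correlation for interrater reliability.

Conventions
-----------
- S_AB counts signed A-vs-B pairs: #(b > a) - #(b < a); ties contribute 0.
- Baseline-trend correction subtracts the Kendall S of the baseline
  (all ordered pairs i < i') from S_AB while keeping the denominator
  n_a·n_b, so corrected tau can exceed 1 in magnitude only transiently at
  extreme trends; it is not renormalized.
- Var(S) = n_a·n_b·(n_a + n_b + 1)/3 (Mann-Whitney-equivalent, no tie
  correction). For the sample sizes this design produces (3 baseline
  visits), the exact permutation p is the authoritative result and is
  computed whenever n_a + n_b <= 12; the normal approximation is reported
  alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.stats import norm

__all__ = [
    "PhaseSeries",
    "TauUResult",
    "IccResult",
    "MeasureUndefined",
    "tau_u",
    "exact_permutation_p",
    "icc",
    "significance_flag",
    "bh_adjust",
]

EXACT_ENUMERATION_LIMIT = 12


class MeasureUndefined(ValueError):
    """A statistic or measure that cannot be computed; carries a reason code."""

    def __init__(self, reason: str, detail: str = ""):
        self.reason = reason
        super().__init__(f"{reason}{': ' + detail if detail else ''}")


@dataclass
class PhaseSeries:
    """Ordered measurements of one measure within one study phase."""

    participant_id: str
    measure_name: str
    task_label: str
    phase: str
    values: list[float]

    def __post_init__(self) -> None:
        self.values = [float(v) for v in self.values]
        if len(self.values) < 1:
            raise ValueError("PhaseSeries requires at least one value")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class TauUResult:
    s_ab: int
    s_trend_a: int
    s_corrected: int
    tau: float
    variance_s: float
    z: float
    p_two_sided: float
    p_exact: float | None
    corrected: bool
    n_a: int
    n_b: int

    @property
    def p(self) -> float:
        """The p-value to report: exact when available, else normal."""
        return self.p_exact if self.p_exact is not None else self.p_two_sided


@dataclass
class IccResult:
    icc_value: float
    model: str
    n_subjects: int
    n_raters: int


def _values(x) -> np.ndarray:
    if isinstance(x, PhaseSeries):
        return np.asarray(x.values, dtype=float)
    return np.asarray(x, dtype=float)


def _s_ab(a: np.ndarray, b: np.ndarray) -> int:
    diff = b[None, :] - a[:, None]
    return int(np.sign(diff).sum())


def _kendall_s(a: np.ndarray) -> int:
    diff = a[None, :] - a[:, None]
    return int(np.sign(np.triu(diff, 1)).sum())


def tau_u(a, b, correct_baseline: bool = False,
          exact_p: bool = True, seed: int | None = None) -> TauUResult:
    """Tau-U between baseline phase ``a`` and comparison phase ``b``.

    With ``correct_baseline`` the baseline Kendall S is subtracted from the
    A-vs-B pair count before forming tau. The exact permutation p (over all
    assignments of the pooled values to phases, when n_a + n_b <= 12, else
    a seeded sample of 10000 assignments) accompanies the normal
    approximation whenever ``exact_p`` is true.
    """
    av, bv = _values(a), _values(b)
    if av.size < 2:
        raise ValueError("baseline phase needs >= 2 values")
    if bv.size < 1:
        raise ValueError("comparison phase needs >= 1 value")
    n_a, n_b = av.size, bv.size
    s_ab = _s_ab(av, bv)
    s_trend = _kendall_s(av)
    s_corr = s_ab - s_trend
    s_used = s_corr if correct_baseline else s_ab
    tau = s_used / (n_a * n_b)
    var_s = n_a * n_b * (n_a + n_b + 1) / 3.0
    z = s_used / math.sqrt(var_s)
    p_norm = float(2.0 * norm.sf(abs(z)))
    p_ex = None
    if exact_p:
        p_ex = exact_permutation_p(
            av, bv,
            statistic="tau_corrected" if correct_baseline else "tau",
            seed=seed)
    return TauUResult(s_ab=s_ab, s_trend_a=s_trend, s_corrected=s_corr,
                      tau=float(tau), variance_s=var_s, z=float(z),
                      p_two_sided=p_norm, p_exact=p_ex,
                      corrected=correct_baseline, n_a=n_a, n_b=n_b)


def _stat(av: np.ndarray, bv: np.ndarray, statistic: str) -> float:
    s = _s_ab(av, bv)
    if statistic == "tau_corrected":
        s -= _kendall_s(av)
    return s / (av.size * bv.size)


def exact_permutation_p(a, b, statistic: str = "tau",
                        n_samples: int = 10000,
                        seed: int | None = None) -> float:
    """Permutation p-value for |tau| under phase-label exchange.

    The pooled series keeps its temporal order; each assignment chooses
    which n_a positions belong to the baseline. Full enumeration when
    n_a + n_b <= 12; otherwise a seeded random sample of assignments
    (the observed assignment is always included).
    """
    av, bv = _values(a), _values(b)
    pooled = np.concatenate([av, bv])
    n, n_a = pooled.size, av.size
    observed = abs(_stat(av, bv, statistic))
    count = 0
    total = 0
    if n <= EXACT_ENUMERATION_LIMIT:
        for idx_a in combinations(range(n), n_a):
            mask = np.zeros(n, dtype=bool)
            mask[list(idx_a)] = True
            stat = abs(_stat(pooled[mask], pooled[~mask], statistic))
            total += 1
            if stat >= observed - 1e-12:
                count += 1
        return count / total
    rng = np.random.default_rng(seed)
    count = 1  # the observed assignment
    for _ in range(n_samples):
        idx = rng.permutation(n)
        mask = np.zeros(n, dtype=bool)
        mask[np.sort(idx[:n_a])] = True
        stat = abs(_stat(pooled[mask], pooled[~mask], statistic))
        if stat >= observed - 1e-12:
            count += 1
    return count / (n_samples + 1)


def icc(ratings, model: str = "two_way_mixed_single") -> IccResult:
    """Two-way mixed-effects consistency ICC from the ANOVA mean squares.

    ``ratings`` is a subjects × raters matrix with no missing cells.
    single: (MS_R - MS_E) / (MS_R + (k-1)·MS_E); average: (MS_R - MS_E)/MS_R.
    """
    y = np.asarray(ratings, dtype=float)
    if y.ndim != 2 or y.shape[0] < 2 or y.shape[1] < 2:
        raise ValueError("ratings must be an n>=2 subjects x k>=2 raters matrix")
    if np.isnan(y).any():
        raise ValueError("ratings matrix must have no missing cells")
    n, k = y.shape
    grand = y.mean()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((y - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    if ms_r <= 0 and ms_e <= 0:
        raise MeasureUndefined("zero_variance", "constant ratings matrix")
    if model == "two_way_mixed_single":
        val = (ms_r - ms_e) / (ms_r + (k - 1) * ms_e)
    elif model == "two_way_mixed_average":
        if ms_r == 0:
            raise MeasureUndefined("zero_variance", "no between-subject variance")
        val = (ms_r - ms_e) / ms_r
    else:
        raise ValueError(f"unknown ICC model {model!r}")
    return IccResult(icc_value=float(val), model=model, n_subjects=n, n_raters=k)


def significance_flag(result: TauUResult, alpha: float = 0.05) -> bool:
    """True when the reported p (exact if available) is <= alpha (inclusive)."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    return result.p <= alpha


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (optional multiplicity control)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    return multipletests(p, method="fdr_bh")[1]
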