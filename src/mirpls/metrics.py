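"""Validation statistics: errors, determination, spike recovery, paired comparison.

Conventions:

* RMSE family — sqrt(sum(e_i^2)/n); RMSEE on calibration fits, RMSECV on
  out-of-fold predictions, RMSEP on an external set.
* SEC/SECV/SEP — degrees-of-freedom-corrected analogues,
  sqrt(sum(e_i^2)/(n - n_lv - 1)); converge to the RMSE as n grows.
* Recovery — 100 * (spiked - unspiked)/added, the standard spike-recovery
  accuracy measure for matrix effects.
* Method comparison — two-sided paired t-test on per-sample differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import DegenerateDataError, DomainError


def _paired(predicted, reference) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(predicted, dtype=float).ravel()
    r = np.asarray(reference, dtype=float).ravel()
    if p.size != r.size:
        raise ValueError(f"length mismatch: {p.size} predicted vs {r.size} reference")
    if p.size == 0:
        raise ValueError("empty input")
    return p, r


def rmse(predicted, reference) -> float:
    p, r = _paired(predicted, reference)
    return float(np.sqrt(np.mean((p - r) ** 2)))


def standard_error(predicted, reference, n_lv: int) -> float:
    """sqrt(sum(residual^2)/(n - n_lv - 1)) — SEC/SECV/SEP depending on source."""
    p, r = _paired(predicted, reference)
    n = p.size
    if n <= n_lv + 1:
        raise ValueError(f"need n > n_lv + 1 (= {n_lv + 1}), got n = {n}")
    return float(np.sqrt(np.sum((p - r) ** 2) / (n - n_lv - 1)))


def r_squared(predicted, reference) -> float:
    """Coefficient of determination 1 - SSres/SStot."""
    p, r = _paired(predicted, reference)
    ss_tot = float(np.sum((r - r.mean()) ** 2))
    if ss_tot == 0:
        raise DegenerateDataError("reference has zero variance; R^2 undefined")
    return 1.0 - float(np.sum((p - r) ** 2)) / ss_tot


@dataclass(frozen=True)
class RecoveryResult:
    """One spike-recovery experiment, concentrations in % w/w."""

    unspiked_conc: float
    spiked_conc: float
    amount_added: float
    percent_recovery: float

    def rounded(self, sig_figs: int = 3) -> float:
        """Presentation rounding (3 s.f. by convention in recovery tables)."""
        return round_sig(self.percent_recovery, sig_figs)


def round_sig(x: float, sig_figs: int = 3) -> float:
    if x == 0:
        return 0.0
    return float(f"{x:.{sig_figs}g}")


def recovery(unspiked: float, spiked: float, added: float) -> RecoveryResult:
    if added <= 0:
        raise DomainError(f"amount added must be positive, got {added}")
    pct = 100.0 * (spiked - unspiked) / added
    return RecoveryResult(
        unspiked_conc=float(unspiked),
        spiked_conc=float(spiked),
        amount_added=float(added),
        percent_recovery=pct,
    )


@dataclass(frozen=True)
class PairedComparison:
    statistic: float
    p_value: float
    significant: bool
    alpha: float
    n: int
    mean_difference: float


def paired_method_comparison(values_a, values_b, alpha: float = 0.05) -> PairedComparison:
    """Two-sided paired t-test; significant when p < alpha.

    Identical vectors (zero difference variance and zero mean difference)
    return p = 1 by convention rather than the undefined 0/0 statistic.
    """
    a, b = _paired(values_a, values_b)
    if a.size < 3:
        raise ValueError("paired comparison needs at least 3 pairs")
    d = a - b
    if np.allclose(d, 0.0):
        return PairedComparison(0.0, 1.0, False, alpha, a.size, 0.0)
    t_stat, p_val = stats.ttest_rel(a, b)
    if not np.isfinite(p_val):  # zero spread, non-zero offset: maximally significant
        t_stat, p_val = np.sign(d.mean()) * np.inf, 0.0
    return PairedComparison(
        float(t_stat), float(p_val), bool(p_val < alpha), alpha, a.size, float(d.mean())
    )
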