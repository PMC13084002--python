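"""Bulk culture phenotypes: OD600 growth-rate fitting with paired scaling,
the 60-min lag readout, and the ordinal acquired-stress-resistance score.

Growth rates come from log-linear OLS on a fixed post-stress window (default
75-225 min, the exponential regrowth regime after 0.7 M NaCl addition).
Acquired resistance is read from colony viability over an 11-dose H2O2 series
(0-20 mM): each dose is graded 0-3 and the grades summed into a survival
score in [0, 33] per pretreatment time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


class PhenotypeError(ValueError):
    pass


@dataclass
class ODCurve:
    """One optical-density time series; ``times`` are minutes relative to
    stress addition (negative = pre-stress)."""

    times: np.ndarray
    od: np.ndarray
    strain: str = ""
    replicate: str = ""
    treated: bool = True

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.times.shape != self.od.shape or self.times.ndim != 1:
            raise PhenotypeError("times and od must be matching 1-D arrays")
        if not np.all(np.diff(self.times) > 0):
            raise PhenotypeError("times must be strictly increasing")
        if np.any(self.od <= 0):
            raise PhenotypeError("od values must be positive")
        spacing = np.diff(self.times)
        if spacing.size and not np.allclose(spacing, spacing[0]):
            warnings.warn("irregular OD sampling interval", stacklevel=2)


@dataclass(frozen=True)
class GrowthRateResult:
    rate: float  # per-minute exponential rate (slope of ln OD vs t)
    window: tuple[float, float]
    r_squared: float
    scaled_rate: float | None = None


def fit_growth_rate(
    curve: ODCurve, window: tuple[float, float] = (75.0, 225.0)
) -> GrowthRateResult:
    """Exponential rate by OLS of ln(OD) against time inside the closed window."""
    lo, hi = window
    mask = (curve.times >= lo) & (curve.times <= hi)
    if mask.sum() < 4:
        raise PhenotypeError(
            f"need >= 4 points in window [{lo}, {hi}], got {int(mask.sum())}"
        )
    t = curve.times[mask]
    y = np.log(curve.od[mask])
    res = stats.linregress(t, y)
    return GrowthRateResult(
        rate=float(res.slope),
        window=(float(lo), float(hi)),
        r_squared=float(res.rvalue**2),
    )


def scale_rates(
    mutant_rates: list[float],
    paired_wt_post: list[float],
    wt_pre: list[float],
    wt_post: list[float],
) -> np.ndarray:
    """Paired normalization of mutant rates.

    Each mutant rate is divided by its same-day wild-type post-stress rate,
    then multiplied by the average wild-type post/pre-stress relative rate, so
    the result is on the "fraction of unstressed wild-type growth" scale.
    """
    mutant_rates = np.asarray(mutant_rates, dtype=float)
    paired_wt_post = np.asarray(paired_wt_post, dtype=float)
    wt_pre = np.asarray(wt_pre, dtype=float)
    wt_post = np.asarray(wt_post, dtype=float)
    if mutant_rates.shape != paired_wt_post.shape or wt_pre.shape != wt_post.shape:
        raise PhenotypeError("replicate-paired lists must have equal lengths")
    zero = np.flatnonzero(paired_wt_post == 0)
    if zero.size:
        raise PhenotypeError(f"zero paired wild-type rate at replicate index {zero[0]}")
    if np.any(wt_pre == 0):
        raise PhenotypeError("zero pre-stress wild-type rate")
    return mutant_rates / paired_wt_post * np.mean(wt_post / wt_pre)


def percent_change_lag(curve: ODCurve, span: float = 60.0) -> float:
    """Percent change in OD from t=0 to t=span minutes (linear interpolation
    to the exact endpoints); a lagging culture scores lower."""
    if curve.times[0] > 0 or curve.times[-1] < span:
        raise PhenotypeError(
            f"curve [{curve.times[0]}, {curve.times[-1]}] does not cover [0, {span}]"
        )
    od0 = float(np.interp(0.0, curve.times, curve.od))
    od1 = float(np.interp(span, curve.times, curve.od))
    return 100.0 * (od1 - od0) / od0


# ---------------------------------------------------------------------------
# acquired stress resistance scoring

#: closed-below viability grade bins: complete, majority, partial, none
SCORE_EDGES = (0.995, 0.5, 0.1)


def score_viability(fraction: float) -> int:
    """Grade a survival fraction on the four-point colony-viability scale:
    indistinguishable-from-complete survival scores 3, 50-100% scores 2,
    10-50% scores 1, below 10% scores 0."""
    if not 0.0 <= fraction <= 1.0:
        raise PhenotypeError(f"survival fraction {fraction} outside [0, 1]")
    if fraction >= SCORE_EDGES[0]:
        return 3
    if fraction >= SCORE_EDGES[1]:
        return 2
    if fraction >= SCORE_EDGES[2]:
        return 1
    return 0


@dataclass
class ViabilityPanel:
    """Survival fractions over an ordered H2O2 dose series, one row per
    NaCl pretreatment time. ``survival`` is (n_times, n_doses), already
    normalized to the no-peroxide control."""

    pretreat_times: np.ndarray
    doses: np.ndarray
    survival: np.ndarray
    strain: str = ""
    replicate: str = ""

    def __post_init__(self) -> None:
        self.pretreat_times = np.asarray(self.pretreat_times, dtype=float)
        self.doses = np.asarray(self.doses, dtype=float)
        self.survival = np.asarray(self.survival, dtype=float)
        if self.survival.shape != (self.pretreat_times.size, self.doses.size):
            raise PhenotypeError("survival must be (n_times, n_doses)")
        if np.any((self.survival < 0) | (self.survival > 1)):
            raise PhenotypeError("survival fractions must lie in [0, 1]")


@dataclass(frozen=True)
class SurvivalScoreSeries:
    pretreat_times: np.ndarray
    scores: np.ndarray  # integer 0-33 per pretreatment time
    delta_scores: np.ndarray  # score minus the time-0 score


def survival_score(panel: ViabilityPanel, n_doses: int = 11) -> SurvivalScoreSeries:
    """Sum the 0-3 viability grade over the peroxide dose series for each
    pretreatment time; the delta series is relative to the unstressed t=0
    aliquot of the same panel."""
    if panel.doses.size != n_doses:
        raise PhenotypeError(
            f"expected {n_doses} peroxide doses, got {panel.doses.size}"
        )
    scores = np.array(
        [sum(score_viability(f) for f in row) for row in panel.survival], dtype=int
    )
    if 0.0 not in panel.pretreat_times:
        raise PhenotypeError("panel lacks the t=0 (unstressed) reference time")
    t0 = int(np.flatnonzero(panel.pretreat_times == 0.0)[0])
    return SurvivalScoreSeries(
        pretreat_times=panel.pretreat_times.copy(),
        scores=scores,
        delta_scores=scores - scores[t0],
    )


def panel_from_frame(df: pd.DataFrame, strain: str = "", replicate: str = "") -> ViabilityPanel:
    """Build a panel from a tidy frame with columns pretreat_min plus
    ``dose_<mM>`` columns; ``dose_0`` is the reference and is dropped after
    normalization (rows are assumed pre-normalized if already in [0, 1])."""
    if "dose_0" not in df.columns:
        raise PhenotypeError("missing reference column dose_0")
    dose_cols = [c for c in df.columns if c.startswith("dose_")]
    doses = sorted(float(c.split("_", 1)[1]) for c in dose_cols)
    sub = df[[f"dose_{d:g}" for d in doses]].to_numpy(dtype=float)
    ref = sub[:, 0][:, None]
    if np.any(ref <= 0):
        raise PhenotypeError("dose_0 reference counts must be positive")
    frac = np.clip(sub / ref, 0.0, 1.0)
    return ViabilityPanel(
        pretreat_times=df["pretreat_min"].to_numpy(dtype=float),
        doses=np.asarray(doses),
        survival=frac,
        strain=strain,
        replicate=replicate,
    )


# ---------------------------------------------------------------------------
# group comparisons

PAIRED_T_TWO_SIDED = "paired_t_two_sided"
PAIRED_T_ONE_SIDED = "paired_t_one_sided"
WILCOXON_RANK_SUM = "wilcoxon_rank_sum"


def compare_groups(
    a,
    b,
    mode: str = PAIRED_T_TWO_SIDED,
    *,
    alternative: str = "less",
) -> tuple[float, float]:
    """Replicate-paired t tests and the (Mann-Whitney) rank-sum test.

    Returns ``(statistic, p_value)``. For the one-sided paired t the
    ``alternative`` declares the tested direction of ``a`` relative to ``b``
    (default ``"less"``: first group scores lower). The rank-sum test is
    computed exactly for n <= 25 per group when there are no ties.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise PhenotypeError("need at least 2 observations per group")
    if mode in (PAIRED_T_TWO_SIDED, PAIRED_T_ONE_SIDED):
        if a.size != b.size:
            raise PhenotypeError("paired modes require equal-length samples")
        alt = "two-sided" if mode == PAIRED_T_TWO_SIDED else alternative
        if np.all(a == b):  # zero-variance differences: no evidence either way
            return 0.0, 1.0
        res = stats.ttest_rel(a, b, alternative=alt)
    elif mode == WILCOXON_RANK_SUM:
        pooled = np.concatenate([a, b])
        no_ties = np.unique(pooled).size == pooled.size
        method = "exact" if (max(a.size, b.size) <= 25 and no_ties) else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    else:
        raise PhenotypeError(f"unknown comparison mode {mode!r}")
    return float(res.statistic), float(res.pvalue)
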