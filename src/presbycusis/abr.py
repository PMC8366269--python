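"""ABR threshold cohorts: reference distributions, quartile classification, shifts.

The auditory brainstem response (ABR) threshold of a subject-ear is the lowest
stimulus level with an identifiable evoked response, measured here on a fixed
tone grid of 10 frequencies (2.0-45.2 kHz, 2 steps per octave) at levels
10-100 dB SPL in 3 dB steps.  A cohort of such grids defines, per age group, a
reference distribution against which individual animals are classified into
lower / normal / upper quartiles, and a juvenile reference against which
threshold *shifts* are computed.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

#: Standard test frequencies in kHz, 2 steps/octave from 2.0 to 45.2.
STANDARD_FREQUENCIES_KHZ: tuple[float, ...] = (
    2.0, 2.83, 4.0, 5.66, 8.0, 11.3, 16.0, 22.6, 32.0, 45.2)

#: Stimulus level grid (dB SPL).
LEVEL_MIN_DB = 10.0
LEVEL_MAX_DB = 100.0
LEVEL_STEP_DB = 3.0

#: Band split: 8 kHz belongs to the low band.
LOW_BAND_MAX_KHZ = 8.0

AGE_GROUPS = ("juvenile", "young_adult", "adult")


def quantize_level(x: np.ndarray | float) -> np.ndarray:
    """Snap dB values to the instrument's 3 dB grid anchored at 10 dB SPL,
    then clip to [10, 100]."""
    x = np.asarray(x, dtype=float)
    q = LEVEL_MIN_DB + LEVEL_STEP_DB * np.round((x - LEVEL_MIN_DB) / LEVEL_STEP_DB)
    return np.clip(q, LEVEL_MIN_DB, LEVEL_MAX_DB)


@dataclass
class ThresholdGrid:
    """One subject-ear's ABR thresholds across the standard frequency grid.

    ``thresholds_db`` holds dB SPL per frequency; NaN marks a frequency that
    was not measured.  ``no_response`` flags ceiling hits where no response was
    identified; per the default policy those are stored as 100 dB SPL and
    participate in means.
    """

    subject_id: str
    ear: str
    age_days: float
    age_group: str
    thresholds_db: np.ndarray
    no_response: np.ndarray | None = None
    frequencies_khz: np.ndarray = field(
        default_factory=lambda: np.array(STANDARD_FREQUENCIES_KHZ))

    def __post_init__(self) -> None:
        self.frequencies_khz = np.asarray(self.frequencies_khz, dtype=float)
        self.thresholds_db = np.asarray(self.thresholds_db, dtype=float)
        if self.no_response is None:
            self.no_response = np.zeros(self.frequencies_khz.size, dtype=bool)
        self.no_response = np.asarray(self.no_response, dtype=bool)
        if self.thresholds_db.shape != self.frequencies_khz.shape:
            raise ValueError("thresholds and frequencies differ in length")
        if np.any(np.diff(self.frequencies_khz) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        present = np.isfinite(self.thresholds_db)
        if np.any((self.thresholds_db[present] < LEVEL_MIN_DB)
                  | (self.thresholds_db[present] > LEVEL_MAX_DB)):
            raise ValueError("thresholds outside [10, 100] dB SPL")
        if self.ear not in ("left", "right", "both"):
            raise ValueError(f"unknown ear {self.ear!r}")

    @property
    def n_present(self) -> int:
        return int(np.isfinite(self.thresholds_db).sum())

    def mean_threshold(self) -> float:
        """Subject-mean threshold over measured frequencies (NR counted at 100)."""
        return float(np.nanmean(self.thresholds_db))

    def is_standard(self) -> bool:
        return (self.frequencies_khz.size == len(STANDARD_FREQUENCIES_KHZ)
                and np.allclose(self.frequencies_khz, STANDARD_FREQUENCIES_KHZ))


def low_band_mask(frequencies_khz: np.ndarray) -> np.ndarray:
    return np.asarray(frequencies_khz) <= LOW_BAND_MAX_KHZ


def collapse_ears(grids: list[ThresholdGrid]) -> list[ThresholdGrid]:
    """One grid per subject: where both ears were measured, average them.

    Cohort statistics use one value per animal; averaging is elementwise over
    frequencies, with NR flags kept only where both ears were at ceiling.
    """
    by_subject: dict[str, list[ThresholdGrid]] = {}
    for g in grids:
        by_subject.setdefault(g.subject_id, []).append(g)
    out = []
    for sid, ears in by_subject.items():
        if len(ears) == 1:
            out.append(ears[0])
            continue
        thr = np.nanmean(np.stack([g.thresholds_db for g in ears]), axis=0)
        nr = np.logical_and.reduce([g.no_response for g in ears])
        g0 = ears[0]
        out.append(ThresholdGrid(sid, "both", g0.age_days, g0.age_group,
                                 thr, nr, g0.frequencies_khz))
    return out


@dataclass
class ReferenceDistribution:
    """Per-age-group reference statistics of a cohort of threshold grids."""

    age_group: str
    frequencies_khz: np.ndarray
    mean: np.ndarray          # per frequency, dB SPL
    sd: np.ndarray            # per frequency, dB (ddof=1)
    p25: np.ndarray           # per frequency
    p75: np.ndarray
    subject_means: np.ndarray  # one value per subject
    subject_mean_p25: float
    subject_mean_p75: float
    n: int

    def __post_init__(self) -> None:
        if np.any(self.p25 > self.p75 + 1e-12):
            raise ValueError("P25 exceeds P75")


def build_reference(grids: list[ThresholdGrid], age_group: str | None = None,
                    ears: str = "average") -> ReferenceDistribution:
    """Build the reference distribution for one age group.

    Percentiles use linear interpolation between closest order statistics (the
    spreadsheet / NumPy-default convention).  Requires at least 4 subjects.
    """
    if age_group is not None:
        grids = [g for g in grids if g.age_group == age_group]
    else:
        groups = {g.age_group for g in grids}
        if len(groups) != 1:
            raise ValueError("grids span multiple age groups; pass age_group")
        age_group = groups.pop()
    if ears == "average":
        grids = collapse_ears(grids)
    if any(not g.is_standard() for g in grids):
        raise ValueError("mixed or non-standard frequency lists")
    if len(grids) < 4:
        raise ValueError(f"need >=4 subjects for percentiles, got {len(grids)}")
    thr = np.stack([g.thresholds_db for g in grids])  # (n, 10)
    subject_means = np.array([g.mean_threshold() for g in grids])
    return ReferenceDistribution(
        age_group=age_group,
        frequencies_khz=grids[0].frequencies_khz.copy(),
        mean=np.nanmean(thr, axis=0),
        sd=np.nanstd(thr, axis=0, ddof=1),
        p25=np.nanpercentile(thr, 25, axis=0),
        p75=np.nanpercentile(thr, 75, axis=0),
        subject_means=subject_means,
        subject_mean_p25=float(np.percentile(subject_means, 25)),
        subject_mean_p75=float(np.percentile(subject_means, 75)),
        n=len(grids),
    )


@dataclass
class QuartileLabel:
    """Classification outcome relative to the reference interquartile band."""

    label: str            # lower | normal | upper
    score: float          # the statistic compared against the band
    rule: str

    def __post_init__(self) -> None:
        if self.label not in ("lower", "normal", "upper"):
            raise ValueError(f"bad label {self.label!r}")


def classify_quartile(grid: ThresholdGrid, ref: ReferenceDistribution,
                      rule: str = "subject_mean",
                      outside_fraction: float = 0.8) -> QuartileLabel:
    """Assign lower/normal/upper relative to the reference cohort.

    Default rule compares the subject-mean threshold to the 25th/75th
    percentiles of the reference distribution of subject means: strictly below
    P25 -> lower, strictly above P75 -> upper, otherwise normal.  The
    alternative ``per_frequency`` rule labels a subject whose thresholds lie
    outside the per-frequency interquartile band at >= ``outside_fraction`` of
    measured frequencies.
    """
    if grid.age_group != ref.age_group:
        raise ValueError(
            f"grid age group {grid.age_group!r} != reference {ref.age_group!r}")
    present = np.isfinite(grid.thresholds_db)
    if present.sum() < 0.5 * grid.frequencies_khz.size:
        raise ValueError("more than 50% of frequencies missing; refusing to classify")
    if rule == "subject_mean":
        score = grid.mean_threshold()
        if score < ref.subject_mean_p25:
            label = "lower"
        elif score > ref.subject_mean_p75:
            label = "upper"
        else:
            label = "normal"
        return QuartileLabel(label, score, rule)
    if rule == "per_frequency":
        thr = grid.thresholds_db[present]
        below = np.mean(thr < ref.p25[present])
        above = np.mean(thr > ref.p75[present])
        if above >= outside_fraction:
            return QuartileLabel("upper", float(above), rule)
        if below >= outside_fraction:
            return QuartileLabel("lower", float(below), rule)
        return QuartileLabel("normal", float(max(above, below)), rule)
    raise ValueError(f"unknown rule {rule!r}")


@dataclass
class ShiftGrid:
    """Per-frequency threshold shift against the juvenile reference mean."""

    subject_id: str
    age_days: float
    frequencies_khz: np.ndarray
    shift_db: np.ndarray
    censored: np.ndarray      # NR thresholds: shift is a lower bound
    low_band_mean: float
    high_band_mean: float


def threshold_shift(grid: ThresholdGrid,
                    juvenile_ref: ReferenceDistribution) -> ShiftGrid:
    """shift[f] = threshold[f] - juvenile reference mean[f].

    No-response thresholds yield flagged (censored) shifts that are excluded
    from the band means.  Band means split at 8 kHz, inclusive in the low band.
    """
    if not np.allclose(grid.frequencies_khz, juvenile_ref.frequencies_khz):
        raise ValueError("reference does not cover the grid's frequencies")
    shift = grid.thresholds_db - juvenile_ref.mean
    valid = np.isfinite(shift) & ~grid.no_response
    low = low_band_mask(grid.frequencies_khz)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        low_mean = float(np.mean(shift[valid & low])) if np.any(valid & low) else math.nan
        high_mean = float(np.mean(shift[valid & ~low])) if np.any(valid & ~low) else math.nan
    return ShiftGrid(grid.subject_id, grid.age_days, grid.frequencies_khz.copy(),
                     shift, grid.no_response.copy(), low_mean, high_mean)


def summarize_groups(grids: list[ThresholdGrid]):
    """Per-frequency mean / SD / SEM table over a group of grids.

    SD uses the n-1 denominator; SEM = SD / sqrt(n).  Returns a DataFrame with
    one row per frequency.
    """
    import pandas as pd

    if len(grids) < 1:
        raise ValueError("no grids")
    if any(not g.is_standard() for g in grids):
        raise ValueError("non-standard frequency list")
    thr = np.stack([g.thresholds_db for g in grids])
    n = np.isfinite(thr).sum(axis=0)
    mean = np.nanmean(thr, axis=0)
    if len(grids) >= 2:
        sd = np.nanstd(thr, axis=0, ddof=1)
        sem = sd / np.sqrt(np.maximum(n, 1))
    else:
        sd = np.full(mean.shape, np.nan)
        sem = np.full(mean.shape, np.nan)
    return pd.DataFrame({
        "frequency_khz": grids[0].frequencies_khz,
        "n": n, "mean_db": mean, "sd_db": sd, "sem_db": sem,
    })


# ---------------------------------------------------------------------------
# Nonparametric group comparisons
# ---------------------------------------------------------------------------

@dataclass
class GroupTestResult:
    method: str               # mann_whitney_exact | mann_whitney_asymptotic |
                              # mann_whitney_permutation | kruskal_wallis
    statistic: float
    p_value: float
    shapiro: list[tuple[float, float]]   # (W, p) per sample, NaN if n < 3
    significant: bool
    highly_significant: bool
    warning: str | None = None


_EXACT_PRODUCT_LIMIT = 400
_ENUMERATION_LIMIT = 200_000


def _mwu_enumerate(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p by enumerating all group assignments.

    Handles ties via midranks; two-sided p is the fraction of assignments whose
    U deviates from the null mean n1*n2/2 at least as much as observed.
    """
    n1, n2 = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    mu = n1 * n2 / 2.0
    r1_obs = ranks[:n1].sum()
    u_obs = r1_obs - n1 * (n1 + 1) / 2.0
    dev_obs = abs(u_obs - mu)
    count = total = 0
    for idx in itertools.combinations(range(n1 + n2), n1):
        u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2.0
        if abs(u - mu) >= dev_obs - 1e-9:
            count += 1
        total += 1
    return u_obs, count / total


def mann_whitney(a, b) -> tuple[float, float, str, str | None]:
    """Two-sided Mann-Whitney U with the exact null where tractable.

    Tie-free samples with n1*n2 <= 400 use the exact U distribution; tied
    samples small enough to enumerate use a full-assignment permutation null;
    everything else falls back to the normal approximation with tie correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = len(a), len(b)
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return n1 * n2 / 2.0, 1.0, "mann_whitney_exact", "all observations tied"
    has_ties = len(np.unique(pooled)) < len(pooled)
    if not has_ties and n1 * n2 <= _EXACT_PRODUCT_LIMIT:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        return float(res.statistic), float(res.pvalue), "mann_whitney_exact", None
    if has_ties and math.comb(n1 + n2, n1) <= _ENUMERATION_LIMIT:
        u, p = _mwu_enumerate(a, b)
        return float(u), float(p), "mann_whitney_permutation", None
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue), "mann_whitney_asymptotic", None


def compare_groups(*samples) -> GroupTestResult:
    """Two samples -> Mann-Whitney U; three or more -> Kruskal-Wallis.

    A Shapiro-Wilk normality report per sample is attached but does not gate
    the rank tests.  Significance flags at 0.05 and 0.001 are reported only as
    presentation-layer booleans.
    """
    if len(samples) < 2:
        raise ValueError("need at least two samples")
    samples = [np.asarray(s, dtype=float) for s in samples]
    if any(len(s) < 3 for s in samples):
        raise ValueError("each sample needs n >= 3")
    shapiro = []
    for s in samples:
        if len(s) >= 3 and np.ptp(s) > 0:
            w = stats.shapiro(s)
            shapiro.append((float(w.statistic), float(w.pvalue)))
        else:
            shapiro.append((math.nan, math.nan))
    warning = None
    if len(samples) == 2:
        stat, p, method, warning = mann_whitney(samples[0], samples[1])
    else:
        pooled = np.concatenate(samples)
        if np.ptp(pooled) == 0:
            stat, p, warning = 0.0, 1.0, "all observations tied"
        else:
            res = stats.kruskal(*samples)
            stat, p = float(res.statistic), float(res.pvalue)
        method = "kruskal_wallis"
    if warning:
        warnings.warn(warning, stacklevel=2)
    return GroupTestResult(method, stat, p, shapiro,
                           significant=p < 0.05, highly_significant=p < 0.001,
                           warning=warning)
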