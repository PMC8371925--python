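"""ROI-averaged coherence and the pairwise / interaction contrasts.

Z-scored coherence maps are reduced to one scalar per subject by averaging
over an a-priori region of interest (a set of channels) and a frequency
band (filter-bank bins whose centers fall in the band, endpoints
inclusive; the default 0.5-2 Hz range selects 5 of the 11 default bins).
The scalars then enter Welch t tests: per-group paired stimulus
contrasts, one-sample above-chance tests, between-group comparisons per
stimulus, and the expertise interaction as a two-sample Welch t on
per-subject difference scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .coherence import CoherenceMap
from .containers import InputError

DEFAULT_FREQ_RANGE_HZ = (0.5, 2.0)


@dataclass
class ROIDefinition:
    """A named set of channels plus a frequency band of interest."""

    name: str
    channel_labels: list[str]
    freq_range_hz: tuple[float, float] = DEFAULT_FREQ_RANGE_HZ

    def __post_init__(self) -> None:
        self.channel_labels = list(self.channel_labels)
        lo, hi = self.freq_range_hz
        if not self.channel_labels:
            raise InputError("ROI must contain at least one channel")
        if not lo < hi:
            raise InputError("freq range must have low < high")


@dataclass
class TTestReport:
    """One t contrast: statistic, df, p, Cohen's d with a 95% CI."""

    name: str
    t: float
    df: float
    p: float
    d: float
    d_ci: tuple[float, float]
    n: tuple[int, ...]


@dataclass
class ContrastReport:
    """All ROI-level contrasts for one 2x2 cohort.

    ``extras`` is an open slot for bolt-on statistics (ANOVA, mixed
    models, Bayesian estimates) computed by external packages.
    """

    roi: str
    tests: dict[str, TTestReport]
    interaction_direction: float  # mean(group1 A-B) - mean(group2 A-B)
    extras: dict = field(default_factory=dict)


def roi_average(zmap: CoherenceMap, roi: ROIDefinition) -> float:
    """Mean z-scored coherence over the ROI's channels and frequency bins."""
    if zmap.kind != "zscored":
        raise InputError("roi_average expects a z-scored map")
    if zmap.channel_labels is None:
        raise InputError("map carries no channel labels")
    lo, hi = roi.freq_range_hz
    bin_sel = (zmap.bin_centers_hz >= lo) & (zmap.bin_centers_hz <= hi)
    missing = set(roi.channel_labels) - set(zmap.channel_labels)
    if missing:
        raise InputError(f"ROI channels not in map: {sorted(missing)}")
    ch_sel = [zmap.channel_labels.index(c) for c in roi.channel_labels]
    if not bin_sel.any():
        raise InputError("no frequency bins inside the ROI range")
    return float(zmap.values[np.ix_(ch_sel, np.flatnonzero(bin_sel))].mean())


def _cohens_d_ci(d: float, n1: int, n2: int | None = None) -> tuple[float, float]:
    """Approximate 95% CI for Cohen's d via its large-sample SE."""
    if n2 is None:  # one-sample / paired
        se = math.sqrt(1.0 / n1 + d**2 / (2.0 * n1))
    else:
        nh = n1 + n2
        se = math.sqrt((n1 + n2) / (n1 * n2) + d**2 / (2.0 * nh))
    return (d - 1.96 * se, d + 1.96 * se)


def _one_sample_report(name: str, x: np.ndarray, popmean: float = 0.0) -> TTestReport:
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2:
        raise InputError(f"{name}: need >= 2 observations")
    sd = x.std(ddof=1)
    if sd == 0:
        # degenerate: all values identical
        t = 0.0 if x.mean() == popmean else math.inf
        p = 1.0 if t == 0.0 else 0.0
        d = 0.0 if t == 0.0 else math.inf
        return TTestReport(name, t, n - 1, p, d, (d, d), (n,))
    res = stats.ttest_1samp(x, popmean)
    d = float((x.mean() - popmean) / sd)
    return TTestReport(
        name, float(res.statistic), float(n - 1), float(res.pvalue), d,
        _cohens_d_ci(d, n), (n,),
    )


def _welch_report(name: str, a: np.ndarray, b: np.ndarray) -> TTestReport:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InputError(f"{name}: need >= 2 observations per group")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        equal = a.mean() == b.mean()
        t = 0.0 if equal else math.inf
        p = 1.0 if equal else 0.0
        d = 0.0 if equal else math.inf
        return TTestReport(name, t, a.size + b.size - 2, p, d, (d, d), (a.size, b.size))
    res = stats.ttest_ind(a, b, equal_var=False)
    # Welch-Satterthwaite df
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    df = (va + vb) ** 2 / (
        va**2 / (a.size - 1) + vb**2 / (b.size - 1)
    )
    sp = math.sqrt(
        ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1))
        / (a.size + b.size - 2)
    )
    d = float((a.mean() - b.mean()) / sp) if sp > 0 else math.inf
    return TTestReport(
        name, float(res.statistic), float(df), float(res.pvalue), d,
        _cohens_d_ci(d, a.size, b.size), (a.size, b.size),
    )


def expertise_contrast(
    group1_scalars_by_stim: dict[str, np.ndarray],
    group2_scalars_by_stim: dict[str, np.ndarray],
    roi_name: str = "roi",
    group_names: tuple[str, str] = ("group1", "group2"),
    stim_names: tuple[str, str] | None = None,
) -> ContrastReport:
    """Full ROI contrast report for a 2 (group) x 2 (stimulus) design.

    Each ``*_scalars_by_stim`` maps the two stimulus labels to per-subject
    ROI scalars, paired across stimuli within group.  The interaction is a
    two-sample Welch t on per-subject (A - B) difference scores, which is
    invariant to per-group constants added to both stimuli (main effects
    cancel).
    """
    stims1 = list(group1_scalars_by_stim)
    stims2 = list(group2_scalars_by_stim)
    if len(stims1) != 2 or stims1 != stims2:
        raise InputError("both groups need the same two stimulus labels")
    sa, sb = stim_names if stim_names is not None else stims1
    g1a = np.asarray(group1_scalars_by_stim[sa], dtype=float)
    g1b = np.asarray(group1_scalars_by_stim[sb], dtype=float)
    g2a = np.asarray(group2_scalars_by_stim[sa], dtype=float)
    g2b = np.asarray(group2_scalars_by_stim[sb], dtype=float)
    if g1a.shape != g1b.shape or g2a.shape != g2b.shape:
        raise InputError("within-group scalars must be paired across stimuli")
    gn1, gn2 = group_names

    tests: dict[str, TTestReport] = {}
    # paired stimulus contrast per group (one-sample t on differences)
    tests[f"{gn1}:{sa}-{sb}"] = _one_sample_report(f"{gn1}:{sa}-{sb}", g1a - g1b)
    tests[f"{gn2}:{sa}-{sb}"] = _one_sample_report(f"{gn2}:{sa}-{sb}", g2a - g2b)
    # above-chance coherence per cell
    for gname, cells in ((gn1, (g1a, g1b)), (gn2, (g2a, g2b))):
        for sname, x in zip((sa, sb), cells):
            tests[f"{gname}:{sname}>0"] = _one_sample_report(
                f"{gname}:{sname}>0", x
            )
    # between-group comparison per stimulus
    tests[f"{sa}:{gn1}-{gn2}"] = _welch_report(f"{sa}:{gn1}-{gn2}", g1a, g2a)
    tests[f"{sb}:{gn1}-{gn2}"] = _welch_report(f"{sb}:{gn1}-{gn2}", g1b, g2b)
    # the expertise interaction: Welch t on difference scores
    tests["interaction"] = _welch_report("interaction", g1a - g1b, g2a - g2b)

    return ContrastReport(
        roi=roi_name,
        tests=tests,
        interaction_direction=float((g1a - g1b).mean() - (g2a - g2b).mean()),
    )
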