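"""GC-FAME fatty-acid profiling: retention-time identification, calibration-
curve quantification, and group comparison (one-way ANOVA + Fisher's LSD).

GC of fatty acid methyl esters quantifies total fatty acids after
transesterification; it resolves positional / cis-trans isomers (carried
here as an opaque name suffix such as ``n-9c``) but is blind to which intact
lipid a chain came from and loses short-chain FAs (< 10 carbons) to
evaporation during derivatization. Inputs are integrated peak tables
(retention time, area); chromatogram signal processing is out of scope.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "GcPeak",
    "FameName",
    "CalibrationCurve",
    "fit_calibration",
    "identify_fames",
    "fa_percentages",
    "anova_fisher_lsd",
    "AnovaResult",
    "GC_RUN_TIME_MIN",
]

GC_RUN_TIME_MIN = 58.0


@dataclass(frozen=True)
class GcPeak:
    rt_min: float
    area: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.rt_min <= GC_RUN_TIME_MIN:
            raise ValueError(f"retention time {self.rt_min} outside 0-{GC_RUN_TIME_MIN} min")
        if self.area < 0:
            raise ValueError("peak area must be >= 0")


_FAME_RE = re.compile(r"^FA\s+(\d+):(\d+)(.*)$")


@dataclass(frozen=True, order=True)
class FameName:
    """A FAME identity: carbons:double_bonds plus an opaque positional tag."""

    carbons: int
    double_bonds: int
    suffix: str = ""  # e.g. "n-9c", "n6c"; carried verbatim, never parsed

    def __post_init__(self) -> None:
        if not 4 <= self.carbons <= 24:
            raise ValueError(f"FAME carbon number {self.carbons} outside 4-24")

    @classmethod
    def parse(cls, text: str) -> "FameName":
        m = _FAME_RE.match(text.strip())
        if not m:
            raise ValueError(f"malformed FAME name {text!r} (expected 'FA C:D[suffix]')")
        return cls(int(m.group(1)), int(m.group(2)), m.group(3).strip())

    @property
    def key(self) -> tuple[int, int]:
        """(carbons, double_bonds): the resolution MS and GC share."""
        return (self.carbons, self.double_bonds)

    def __str__(self) -> str:
        return f"FA {self.carbons}:{self.double_bonds}{self.suffix}"


@dataclass(frozen=True)
class CalibrationCurve:
    """Amount-vs-area OLS line for one FAME, with its fitted area range."""

    fame: FameName
    slope: float
    intercept: float
    area_min: float
    area_max: float
    residuals: tuple[float, ...] = ()

    def amount(self, area: float) -> float:
        if not self.area_min <= area <= self.area_max:
            logger.warning(
                "%s: area %.4g extrapolates beyond fit range [%.4g, %.4g]",
                self.fame, area, self.area_min, self.area_max,
            )
        return self.slope * area + self.intercept


def fit_calibration(fame: FameName, points: list[tuple[float, float]]) -> CalibrationCurve:
    """Ordinary least squares of amount on area over (area, amount) points."""
    areas = np.array([a for a, _ in points], dtype=float)
    amounts = np.array([m for _, m in points], dtype=float)
    if len(np.unique(areas)) < 2:
        raise ValueError("calibration needs >= 2 distinct area points")
    fit = stats.linregress(areas, amounts)
    if fit.slope <= 0:
        raise ValueError(f"non-positive calibration slope {fit.slope:g} for {fame}")
    resid = amounts - (fit.slope * areas + fit.intercept)
    return CalibrationCurve(
        fame, float(fit.slope), float(fit.intercept),
        float(areas.min()), float(areas.max()), tuple(float(r) for r in resid),
    )


def identify_fames(
    peaks: list[GcPeak],
    rt_library: dict[FameName, float],
    window: float = 0.1,
) -> dict[FameName, float]:
    """Assign peaks to library FAMEs by retention time; areas summed per FAME.

    Each peak goes to the nearest library entry within +/- window minutes
    (exact ties break to the lower library RT, logged); peaks outside every
    window stay unassigned (logged). Library RTs must be unique within
    2 x window, otherwise assignment would be ambiguous.
    """
    entries = sorted(rt_library.items(), key=lambda kv: (kv[1], kv[0]))
    for (f1, rt1), (f2, rt2) in zip(entries, entries[1:]):
        if abs(rt2 - rt1) < 2 * window:
            raise ValueError(
                f"retention-time collision: {f1} at {rt1} vs {f2} at {rt2} "
                f"(closer than {2 * window} min)"
            )
    out: dict[FameName, float] = {}
    for peak in peaks:
        best = None
        for fame, rt in entries:  # entries RT-ascending: ties keep lower RT
            d = abs(peak.rt_min - rt)
            if d <= window and (best is None or d < best[0]):
                best = (d, fame, rt)
            elif best is not None and d == best[0]:
                logger.info(
                    "peak at %.3f min equidistant; keeping lower-RT %s", peak.rt_min, best[1]
                )
        if best is None:
            logger.info("peak at %.3f min matches no library FAME", peak.rt_min)
            continue
        out[best[1]] = out.get(best[1], 0.0) + peak.area
    return out


def fa_percentages(
    fame_areas: dict[FameName, float],
    curves: dict[FameName, CalibrationCurve],
) -> tuple[dict[FameName, float], dict[FameName, float], dict[str, float]]:
    """Quantify assigned FAMEs and normalize to percentages.

    Returns (percentages, amounts, totals) where totals holds the saturated
    (double_bonds == 0) and unsaturated shares, summing to 100.
    """
    amounts = {}
    for fame, area in fame_areas.items():
        if fame not in curves:
            raise ValueError(f"no calibration curve for {fame}")
        amounts[fame] = curves[fame].amount(area)
    total = sum(amounts.values())
    if total <= 0:
        raise ValueError("total quantified FAME amount is zero")
    pct = {fame: 100.0 * amt / total for fame, amt in amounts.items()}
    saturated = sum(p for f, p in pct.items() if f.double_bonds == 0)
    totals = {"saturated": saturated, "unsaturated": 100.0 - saturated}
    return pct, amounts, totals


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    p_value: float
    df_between: int
    df_within: int
    mse: float
    pairwise: dict[tuple[str, str], tuple[float, float, bool]]
    """(group_i, group_j) -> (t statistic, p value, significant at alpha)."""

    def significant_pairs(self) -> list[tuple[str, str]]:
        return [pair for pair, (_, _, sig) in self.pairwise.items() if sig]


def anova_fisher_lsd(
    groups: dict[str, list[float]], alpha: float = 0.01
) -> AnovaResult:
    """One-way ANOVA with Fisher's LSD pairwise t-tests on the pooled MSE.

    Sums of squares are computed explicitly; the F and t distributions come
    from scipy. Every group needs >= 2 replicates.
    """
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two groups")
    for name, values in groups.items():
        if len(values) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 replicates")
    names = list(groups)
    data = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    n_total = sum(len(v) for v in data.values())
    grand = sum(v.sum() for v in data.values()) / n_total
    ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in data.values())
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in data.values())
    df_between = len(groups) - 1
    df_within = n_total - len(groups)
    ms_between = ss_between / df_between
    mse = ss_within / df_within
    if mse == 0.0:
        f_stat = 0.0 if ms_between == 0.0 else float("inf")
    else:
        f_stat = ms_between / mse
    p_value = float(stats.f.sf(f_stat, df_between, df_within)) if np.isfinite(f_stat) else 0.0

    pairwise = {}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            va, vb = data[a], data[b]
            diff = va.mean() - vb.mean()
            se = np.sqrt(mse * (1 / len(va) + 1 / len(vb)))
            if se == 0.0:
                t = 0.0 if diff == 0.0 else np.sign(diff) * float("inf")
            else:
                t = diff / se
            p = float(2 * stats.t.sf(abs(t), df_within)) if np.isfinite(t) else 0.0
            if not np.isfinite(t) and diff == 0.0:
                p = 1.0
            pairwise[(a, b)] = (float(t), p, p <= alpha and diff != 0.0)
    return AnovaResult(float(f_stat), p_value, df_between, df_within, float(mse), pairwise)
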