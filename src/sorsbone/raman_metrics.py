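"""Band-level biochemical metrics for bone Raman spectra.

Bone quality is summarized by five quantities per spectrum:

* PO4/CO3 — phosphate-to-carbonate ratio (mineral quality; carbonate
  substitution into the apatite lattice lowers it),
* PO4/AmideIII, PO4/CH2, PO4/AmideI — mineral-to-matrix ratios, and
* CH2 FWHM — full width at half maximum of the ~1450 cm⁻¹ CH2 deformation
  band, an organic-matrix heterogeneity marker.

Band values are computed above a local linear baseline drawn through the
band-window endpoints, either as peak height or as the trapezoidal area
(the default: more robust to noise).  Group summaries report per-class
mean ± SEM where SEM = SD/√N, aggregating to one value per subject before
any class statistic.  Between-class comparisons default to an exact
two-sided Mann-Whitney test (mid-rank treatment of ties) suited to the
small group sizes typical of cadaveric cohorts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._exceptions import MetricError, StatTestError
from .spectra_io import Spectrum

logger = logging.getLogger(__name__)

BAND_NAMES = ("PO4", "CO3", "AmideIII", "CH2", "AmideI")


@dataclass(frozen=True)
class BandDefinition:
    """A named Raman band with its integration window (cm⁻¹)."""

    name: str
    center: float
    lo: float
    hi: float
    mode: Literal["height", "area"] = "area"

    def __post_init__(self) -> None:
        if not self.lo < self.center < self.hi:
            raise ValueError(
                f"band {self.name}: need lo < center < hi, got "
                f"({self.lo}, {self.center}, {self.hi})"
            )

    @property
    def window(self) -> tuple[float, float]:
        return (self.lo, self.hi)


def default_bands(mode: Literal["height", "area"] = "area") -> dict[str, BandDefinition]:
    """Standard bone-Raman band assignments (windows in cm⁻¹)."""
    table = {
        "PO4": (960.0, 930.0, 980.0),
        "CO3": (1070.0, 1050.0, 1100.0),
        "AmideIII": (1250.0, 1215.0, 1300.0),
        "CH2": (1450.0, 1400.0, 1500.0),
        "AmideI": (1665.0, 1595.0, 1720.0),
    }
    return {
        name: BandDefinition(name, c, lo, hi, mode)
        for name, (c, lo, hi) in table.items()
    }


@dataclass(frozen=True)
class RamanMetricSet:
    """The four band ratios plus CH2 FWHM for one spectrum."""

    po4_co3: float
    po4_amideIII: float
    po4_ch2: float
    po4_amideI: float
    ch2_fwhm: float

    RATIO_FIELDS = ("po4_co3", "po4_amideIII", "po4_ch2", "po4_amideI")

    def as_dict(self) -> dict[str, float]:
        return {
            "po4_co3": self.po4_co3,
            "po4_amideIII": self.po4_amideIII,
            "po4_ch2": self.po4_ch2,
            "po4_amideI": self.po4_amideI,
            "ch2_fwhm": self.ch2_fwhm,
        }


@dataclass
class GroupSummary:
    """Per-class (optionally per-position) mean/SD/SEM/N table."""

    table: pd.DataFrame  # columns: class, [position,] metric, mean, sd, sem, n


def _local_baseline(s: Spectrum, band: BandDefinition) -> tuple[np.ndarray, np.ndarray]:
    """Band-window intensities above a linear baseline through the endpoints."""
    mask = s.axis.window_mask(band.lo, band.hi)
    if mask.sum() < 3:
        raise MetricError(
            f"band {band.name} window [{band.lo}, {band.hi}] covers fewer "
            "than 3 axis points"
        )
    x = s.axis.values[mask]
    y = s.intensities[mask]
    # linear baseline through the window-edge intensities
    base = y[0] + (y[-1] - y[0]) * (x - x[0]) / (x[-1] - x[0])
    return x, y - base


def band_value(s: Spectrum, band: BandDefinition) -> float:
    """Height or integrated area of a band above its local linear baseline."""
    x, y = _local_baseline(s, band)
    if band.mode == "height":
        return float(y.max())
    return float(np.trapezoid(y, x))


def fwhm(s: Spectrum, band: BandDefinition) -> float:
    """Full width at half maximum of the band's peak, in cm⁻¹.

    After local linear baseline removal, the half-maximum level is crossed
    once on each side of the peak apex; crossing positions are located by
    linear interpolation between grid points.
    """
    x, y = _local_baseline(s, band)
    i_max = int(np.argmax(y))
    peak = y[i_max]
    if peak <= 0:
        raise MetricError(f"band {band.name}: no peak above local baseline")
    half = peak / 2.0

    def cross(idx_range: Iterable[int], right_of: bool) -> float | None:
        for i in idx_range:
            j = i + 1
            if (y[i] - half) * (y[j] - half) <= 0 and y[i] != y[j]:
                return float(x[i] + (half - y[i]) * (x[j] - x[i]) / (y[j] - y[i]))
        return None

    left = cross(range(i_max - 1, -1, -1), False)
    right = cross(range(i_max, len(y) - 1), True)
    if left is None or right is None:
        raise MetricError(
            f"band {band.name}: half-maximum not crossed inside the window "
            "(window too narrow)"
        )
    return right - left


def compute_metrics(
    s: Spectrum, bands: Mapping[str, BandDefinition] | None = None
) -> RamanMetricSet:
    """Compute the four ratios and CH2 FWHM for one spectrum."""
    if bands is None:
        bands = default_bands()
    missing = [n for n in BAND_NAMES if n not in bands]
    if missing:
        raise MetricError(f"missing band definition(s): {', '.join(missing)}")
    po4 = band_value(s, bands["PO4"])
    ratios = {}
    for name in ("CO3", "AmideIII", "CH2", "AmideI"):
        denom = band_value(s, bands[name])
        if denom <= 0:
            raise MetricError(
                f"band {name}: non-positive denominator ({denom:.4g})"
            )
        ratios[name] = po4 / denom
    return RamanMetricSet(
        po4_co3=ratios["CO3"],
        po4_amideIII=ratios["AmideIII"],
        po4_ch2=ratios["CH2"],
        po4_amideI=ratios["AmideI"],
        ch2_fwhm=fwhm(s, bands["CH2"]),
    )


# ---------------------------------------------------------------------------
# Group summaries and significance
# ---------------------------------------------------------------------------

def metrics_frame(
    metrics: Mapping[str, RamanMetricSet] | pd.DataFrame,
) -> pd.DataFrame:
    """Normalize per-subject metrics into a DataFrame indexed by subject."""
    if isinstance(metrics, pd.DataFrame):
        return metrics
    return pd.DataFrame({k: m.as_dict() for k, m in metrics.items()}).T


def summarize_groups(
    metrics: pd.DataFrame,
    classes: Mapping[str, str],
    positions: Mapping[str, float] | None = None,
) -> GroupSummary:
    """Per-class mean/SD/SEM/N, one aggregated value per subject first.

    ``metrics`` rows may repeat a subject (several sites); rows are averaged
    per subject before class statistics.  ``classes`` maps subject → WHO
    class.  If ``positions`` is given (row label → signed mm), summaries are
    additionally stratified by position.  SD uses the ddof=1 convention; a
    single-subject class reports SD = SEM = 0.
    """
    df = metrics.copy()
    df["subject"] = [str(i) for i in df.index] if "subject" not in df else df["subject"]
    value_cols = [c for c in df.columns if c != "subject"]
    if positions is not None:
        df["position"] = [positions[i] for i in df.index]
        value_cols = [c for c in value_cols if c != "position"]
        group_keys = ["who_class", "position"]
        per_subject = df.groupby(["subject", "position"], as_index=False)[
            value_cols
        ].mean()
        per_subject["who_class"] = per_subject["subject"].map(classes)
    else:
        group_keys = ["who_class"]
        per_subject = df.groupby("subject", as_index=False)[value_cols].mean()
        per_subject["who_class"] = per_subject["subject"].map(classes)
    if per_subject["who_class"].isna().any():
        raise MetricError("every subject must have a WHO class")

    rows = []
    for keys, grp in per_subject.groupby(group_keys):
        if not isinstance(keys, tuple):
            keys = (keys,)
        n = len(grp)
        for col in value_cols:
            sd = float(grp[col].std(ddof=1)) if n > 1 else 0.0
            rows.append(
                {
                    **dict(zip(group_keys, keys)),
                    "metric": col,
                    "mean": float(grp[col].mean()),
                    "sd": sd,
                    "sem": sd / math.sqrt(n),
                    "n": n,
                }
            )
    return GroupSummary(table=pd.DataFrame(rows))


def _mannwhitney_exact_midrank(a: np.ndarray, b: np.ndarray) -> float:
    """Exact two-sided Mann-Whitney p-value with mid-rank tie handling.

    Enumerates every assignment of the pooled values to the two groups and
    counts assignments whose U statistic deviates from its null mean at
    least as much as the observed one.  Valid with ties (mid-ranks make U
    well defined); cost is C(n1+n2, n1) evaluations.
    """
    pooled = np.concatenate([a, b])
    n1, n2 = len(a), len(b)
    ranks = stats.rankdata(pooled)  # mid-ranks
    mu = n1 * n2 / 2.0

    def u_of(idx: tuple[int, ...]) -> float:
        r1 = ranks[list(idx)].sum()
        return r1 - n1 * (n1 + 1) / 2.0

    obs_dev = abs(u_of(tuple(range(n1))) - mu)
    total = 0
    extreme = 0
    for idx in combinations(range(n1 + n2), n1):
        total += 1
        if abs(u_of(idx) - mu) >= obs_dev - 1e-12:
            extreme += 1
    return extreme / total


def compare_classes(
    values_a: Sequence[float],
    values_b: Sequence[float],
    test: Literal["mannwhitney", "welch"] = "mannwhitney",
    exact_limit: int = 20000,
) -> float:
    """Two-sided p-value comparing per-subject metric values of two classes.

    Default is the Mann-Whitney U test, computed exactly by enumeration
    when C(n1+n2, n1) ≤ ``exact_limit`` (it always is for the cadaveric
    group sizes here) and by the tie-corrected normal approximation
    otherwise.  ``welch`` selects Welch's unequal-variance t-test.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise StatTestError("each class needs at least 2 subjects")
    if test == "welch":
        return float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    if test != "mannwhitney":
        raise ValueError(f"unknown test: {test!r}")
    if math.comb(len(a) + len(b), len(a)) <= exact_limit:
        return _mannwhitney_exact_midrank(a, b)
    return float(
        stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
    )
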