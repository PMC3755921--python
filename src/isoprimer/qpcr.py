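"""qPCR run evaluation: standard curves, acceptance criteria, melt peaks,
and reference-normalized knockdown quantification.

Standard (dilution) curves: mean Cq is regressed on log10(relative input)
for a serial dilution (default: five points, four-fold steps).  The slope
gives the amplification efficiency E% = (10^(-1/slope) - 1) * 100; perfect
doubling yields slope -1/log10(2) ~ -3.32 and 100%.  A primer pair passes
QC when efficiency is in 90-120%, the regression R^2 exceeds 0.995, adjacent
dilution points are evenly spaced (|spacing - log2(factor)| <= 0.5 cycles,
i.e. two cycles apart at four-fold dilution), the most dilute point crosses
threshold before cycle 30, and the no-template control is at least five
cycles away (or undetected).  Melt curves must show a single peak in -dF/dT.

Knockdown: Cq of the query gene is normalized to the arithmetic mean Cq of
the reference genes per condition (equivalent to the geometric mean of their
quantities), and relative expression is 2^(-ddCq) assuming 100%
amplification efficiency; knockdown% = (1 - relative expression) * 100.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal, stats


class QpcrInputError(ValueError):
    """Typed error for malformed qPCR inputs."""


@dataclass
class DilutionSeries:
    """Replicate Cq values over a serial dilution.

    ``cq[i]`` holds the replicate Cqs of dilution point ``i``; the relative
    input at point i is ``dilution_factor ** -i``.
    """

    cq: list[list[float]]
    dilution_factor: float = 4.0
    ntc_cq: float | None = None

    def __post_init__(self) -> None:
        if self.dilution_factor <= 1:
            raise QpcrInputError("dilution_factor must be > 1")
        if len(self.cq) < 3:
            raise QpcrInputError("need >= 3 dilution points")
        arr = [np.asarray(row, dtype=float) for row in self.cq]
        if any(not np.isfinite(row).all() for row in arr):
            raise QpcrInputError("non-finite Cq value")

    @property
    def n_points(self) -> int:
        return len(self.cq)

    @property
    def mean_cq(self) -> np.ndarray:
        return np.array([float(np.mean(row)) for row in self.cq])

    @property
    def log_input(self) -> np.ndarray:
        return -np.arange(self.n_points) * math.log10(self.dilution_factor)


@dataclass
class DilutionFit:
    slope: float
    intercept: float
    r_squared: float
    efficiency_pct: float
    spacing: float
    max_cq: float
    ntc_distance: float | None
    replicate_sd: float


@dataclass
class QcCriteria:
    efficiency_min: float = 90.0
    efficiency_max: float = 120.0
    r_squared_min: float = 0.995
    spacing_tol: float = 0.5
    max_cq_limit: float = 30.0
    ntc_min_distance: float = 5.0


@dataclass
class QcVerdict:
    passed: bool
    flags: dict[str, bool] = field(default_factory=dict)


@dataclass
class KnockdownResult:
    query_gene: str
    rel_expr: float
    knockdown_pct: float
    n_refs: int


def fit_dilution(series: DilutionSeries) -> DilutionFit:
    """Least-squares fit of mean Cq vs log10 relative input."""
    x = series.log_input
    y = series.mean_cq
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise QpcrInputError("zero-variance dilution input")
    res = stats.linregress(x, y)
    spacing = float(np.mean(np.diff(y)))
    max_cq = float(y.max())
    ntc_distance = None if series.ntc_cq is None else float(series.ntc_cq - max_cq)
    rep_sd = float(np.mean([np.std(row, ddof=0) for row in series.cq]))
    return DilutionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        efficiency_pct=float((10.0 ** (-1.0 / res.slope) - 1.0) * 100.0),
        spacing=spacing,
        max_cq=max_cq,
        ntc_distance=ntc_distance,
        replicate_sd=rep_sd,
    )


def qc_verdict(fit: DilutionFit, criteria: QcCriteria | None = None,
               dilution_factor: float = 4.0,
               melt_peak_count: int | None = None) -> QcVerdict:
    """Apply the acceptance criteria to a dilution fit (melt peak optional)."""
    c = criteria or QcCriteria()
    expected_spacing = math.log2(dilution_factor)
    flags = {
        "efficiency": c.efficiency_min <= fit.efficiency_pct <= c.efficiency_max,
        "r_squared": fit.r_squared > c.r_squared_min,
        "spacing": abs(fit.spacing - expected_spacing) <= c.spacing_tol,
        "max_cq": fit.max_cq < c.max_cq_limit,
        "ntc": fit.ntc_distance is None or fit.ntc_distance >= c.ntc_min_distance,
    }
    if melt_peak_count is not None:
        flags["single_melt_peak"] = melt_peak_count == 1
    return QcVerdict(passed=all(flags.values()), flags=flags)


def melt_peak_count(temperatures, fluorescence,
                    prominence_frac: float = 0.2) -> int:
    """Number of melt peaks: local maxima of -dF/dT (3-point smoothed)
    exceeding ``prominence_frac`` of the global maximum."""
    t = np.asarray(temperatures, dtype=float)
    f = np.asarray(fluorescence, dtype=float)
    if t.size < 5 or f.size != t.size:
        raise QpcrInputError("melt curve needs >= 5 matched points")
    if np.any(np.diff(t) <= 0):
        raise QpcrInputError("temperature grid must be strictly increasing")
    d = -np.gradient(f, t)
    smoothed = np.convolve(d, np.ones(3) / 3.0, mode="same")
    height = prominence_frac * smoothed.max()
    peaks, _ = signal.find_peaks(smoothed, height=height)
    return int(len(peaks))


def _mean(values) -> float:
    return float(np.mean(np.asarray(values, dtype=float)))


def knockdown(
    query_cq_treated,
    query_cq_control,
    ref_cqs_treated,
    ref_cqs_control,
    query_gene: str = "query",
) -> KnockdownResult:
    """Reference-normalized relative expression by 2^(-ddCq).

    Reference Cqs may be dicts (gene -> replicate Cqs) or sequences; the
    reference sets must agree between conditions.  Replicates are averaged
    first; references are combined by arithmetic mean of Cq (the geometric
    mean of their quantities).
    """
    if isinstance(ref_cqs_treated, dict) != isinstance(ref_cqs_control, dict):
        raise QpcrInputError("reference sets differ in structure between conditions")
    if isinstance(ref_cqs_treated, dict):
        if set(ref_cqs_treated) != set(ref_cqs_control):
            raise QpcrInputError(
                f"mismatched reference genes: {sorted(ref_cqs_treated)} vs "
                f"{sorted(ref_cqs_control)}"
            )
        refs_t = [_mean(ref_cqs_treated[g]) for g in sorted(ref_cqs_treated)]
        refs_c = [_mean(ref_cqs_control[g]) for g in sorted(ref_cqs_control)]
    else:
        refs_t = [_mean(v) for v in ref_cqs_treated]
        refs_c = [_mean(v) for v in ref_cqs_control]
        if len(refs_t) != len(refs_c):
            raise QpcrInputError("mismatched number of reference genes")
    if not refs_t:
        raise QpcrInputError("need >= 1 reference gene")
    dcq_t = _mean(query_cq_treated) - float(np.mean(refs_t))
    dcq_c = _mean(query_cq_control) - float(np.mean(refs_c))
    ddcq = dcq_t - dcq_c
    rel = 2.0 ** (-ddcq)
    return KnockdownResult(
        query_gene=query_gene,
        rel_expr=rel,
        knockdown_pct=(1.0 - rel) * 100.0,
        n_refs=len(refs_t),
    )
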