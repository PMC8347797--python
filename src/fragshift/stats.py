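"""Ensemble averaging and mutant-series statistics.

Snapshot ensembles are reduced to per-variant means (excitation energies in
eV, wavelengths in nm — converted per snapshot and then averaged — and
projected fields per charge model).  Series of variants are compared to
experiment with deviations, the mean unsigned error (MUE), the sample
Pearson correlation, and ordinary least-squares regression, via
scipy.stats behind this module's surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _sps

from .assembly import AssemblyReport
from .errors import DegenerateDataError, FragshiftError
from .fields import FieldResult
from .fragments import GmfccConfig


@dataclass
class VariantSummary:
    """Per-variant ensemble means over snapshots."""

    variant: str
    mean_omega_1b: float
    mean_omega_2b: float
    mean_lambda_1b: float
    mean_lambda_2b: float
    n_snapshots: int
    exp_nm: float | None = None
    mean_field_by_model: dict[str, float] = field(default_factory=dict)


@dataclass
class RegressionStats:
    """Pearson R, OLS fit, and error summary of a calc-vs-reference series."""

    r: float
    slope: float
    intercept: float
    mue: float
    mean_deviation: float
    deviations: list[float]


def summarize_variant(
    snapshot_reports: list[AssemblyReport],
    fields: list[FieldResult] | None = None,
    exp_nm: float | None = None,
    variant: str = "",
    hc_ev_nm: float = GmfccConfig().hc_ev_nm,
) -> VariantSummary:
    """Arithmetic snapshot means of a variant's ensemble.

    Wavelengths are converted per snapshot and then averaged, matching the
    observation that the most probable and the average absorption wavelength
    of a thermal ensemble nearly coincide.
    """
    if not snapshot_reports:
        raise FragshiftError("summarize_variant: empty snapshot list")
    w1 = np.array([r.omega_1b for r in snapshot_reports])
    w2 = np.array([r.omega_total for r in snapshot_reports])
    by_model: dict[str, list[float]] = {}
    for f in fields or []:
        by_model.setdefault(f.charge_model or "default", []).append(f.field)
    return VariantSummary(
        variant=variant,
        mean_omega_1b=float(w1.mean()),
        mean_omega_2b=float(w2.mean()),
        mean_lambda_1b=float((hc_ev_nm / w1).mean()),
        mean_lambda_2b=float((hc_ev_nm / w2).mean()),
        n_snapshots=len(snapshot_reports),
        exp_nm=exp_nm,
        mean_field_by_model={k: float(np.mean(v)) for k, v in by_model.items()},
    )


def _check_xy(xs, ys) -> tuple[np.ndarray, np.ndarray]:
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.shape != ys.shape:
        raise FragshiftError(f"length mismatch: {xs.shape} vs {ys.shape}")
    if xs.size < 3:
        raise DegenerateDataError("need at least 3 points")
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        raise DegenerateDataError("zero variance in one of the variables")
    return xs, ys


def pearson_r(xs, ys) -> float:
    """Sample Pearson correlation coefficient."""
    xs, ys = _check_xy(xs, ys)
    return float(_sps.pearsonr(xs, ys).statistic)


def linear_fit(xs, ys) -> tuple[float, float]:
    """Ordinary least squares of y on x → (slope, intercept)."""
    xs, ys = _check_xy(xs, ys)
    res = _sps.linregress(xs, ys)
    return float(res.slope), float(res.intercept)


def mue_and_deviations(calc, ref) -> tuple[float, float, list[float]]:
    """(MUE, mean deviation, per-item deviations) of calc − ref."""
    calc = np.asarray(calc, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if calc.shape != ref.shape:
        raise FragshiftError(f"length mismatch: {calc.shape} vs {ref.shape}")
    dev = calc - ref
    return float(np.abs(dev).mean()), float(dev.mean()), [float(d) for d in dev]


def regression_stats(calc, ref) -> RegressionStats:
    """Full calc-vs-reference statistics: R, OLS fit of calc on ref, errors."""
    mue, mean_dev, devs = mue_and_deviations(calc, ref)
    r = pearson_r(ref, calc)
    slope, intercept = linear_fit(ref, calc)
    return RegressionStats(
        r=r, slope=slope, intercept=intercept, mue=mue, mean_deviation=mean_dev, deviations=devs
    )


def wavelength_histogram(
    values, bin_width: float = 2.0
) -> tuple[np.ndarray, np.ndarray, float]:
    """Histogram of absorption wavelengths → (bin edges, counts, mean).

    Bin edges start at the floor of the minimum and cover all values; counts
    sum to the number of inputs.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise FragshiftError("wavelength_histogram: empty input")
    if bin_width <= 0:
        raise FragshiftError("bin width must be positive")
    lo = np.floor(values.min() / bin_width) * bin_width
    nbins = max(1, int(np.ceil((values.max() - lo) / bin_width)) or 1)
    edges = lo + bin_width * np.arange(nbins + 1)
    if edges[-1] <= values.max():
        edges = np.append(edges, edges[-1] + bin_width)
    counts, edges = np.histogram(values, bins=edges)
    return edges, counts, float(values.mean())
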