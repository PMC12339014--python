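"""Ion-count estimation, per-scan isotopologue ratios, outlier rejection,
and counting-statistics uncertainty.

An Orbitrap reports each centroid with a signal intensity S and a noise
figure N.  The number of charges behind a peak is estimated as

    count = (S / N) * c * (Rn / r)**a * mu**b

with the noise-equivalent-charge constant c (default 3, experimentally
determined at the reference resolution Rn = 240,000), the working resolution
r and the number of microscans mu.  The default exponents a = b = 0.5 follow
the square-root transient-averaging convention; set both to 1 for the
flattened linear reading.  Isotopologue ratios are ratios of ion counts, so
every factor except S/N cancels between species acquired in the same scan.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .scandata import RunTable

__all__ = [
    "IonCountConfig",
    "OutlierPolicy",
    "RatioSeries",
    "RatioSummary",
    "ion_count",
    "scan_ratio",
    "ratio_series",
    "filter_outlier_scans",
    "aggregate_ratio",
]


@dataclass(frozen=True)
class IonCountConfig:
    noise_charges: float = 3.0          # charges per noise unit at Rn
    reference_resolution: float = 240_000.0
    resolution_exponent: float = 0.5
    microscan_exponent: float = 0.5

    def __post_init__(self):
        if self.noise_charges <= 0 or self.reference_resolution <= 0:
            raise ValueError("constants must be positive")
        for e in (self.resolution_exponent, self.microscan_exponent):
            if not 0.0 <= e <= 1.0:
                raise ValueError("exponents must lie in [0, 1]")

    def scale(self, resolution: float, microscans: int) -> float:
        """Multiplier turning S/N into an ion count at the given settings."""
        if resolution <= 0:
            raise ValueError("resolution must be positive")
        if microscans < 1:
            raise ValueError("microscans must be >= 1")
        return (
            self.noise_charges
            * (self.reference_resolution / resolution) ** self.resolution_exponent
            * microscans ** self.microscan_exponent
        )


def ion_count(S, N, resolution: float, microscans: int, cfg: IonCountConfig | None = None):
    """Estimated charges behind a centroid; linear in S and in 1/N."""
    cfg = cfg or IonCountConfig()
    S = np.asarray(S, float)
    N = np.asarray(N, float)
    if (N <= 0).any():
        raise ValueError("noise must be positive")
    return S / N * cfg.scale(resolution, microscans)


def scan_ratio(scan, numerator: str, denominator: str) -> float:
    """Per-scan isotopologue ratio (S_num/N_num)/(S_den/N_den).

    The instrument constants cancel exactly, so no IonCountConfig is needed.
    Raises on a zero denominator signal; batch processing masks such scans
    instead (see :func:`ratio_series`).
    """
    s_num, n_num = scan.readings[numerator]
    s_den, n_den = scan.readings[denominator]
    if s_den == 0:
        raise ZeroDivisionError(f"scan {scan.scan}: zero denominator signal")
    return (s_num / n_num) / (s_den / n_den)


@dataclass
class RatioSeries:
    """Per-scan ratios with the ion counts behind them and a retained mask."""

    ratios: np.ndarray
    counts_num: np.ndarray
    counts_den: np.ndarray
    retained: np.ndarray
    tic: np.ndarray
    exclusions: dict[int, str] = field(default_factory=dict)
    numerator: str = ""
    denominator: str = ""

    def __post_init__(self):
        n = len(self.ratios)
        if not (len(self.retained) == len(self.counts_num) == len(self.counts_den) == n):
            raise ValueError("inconsistent series lengths")

    @property
    def n_retained(self) -> int:
        return int(self.retained.sum())


def ratio_series(
    run: RunTable,
    numerator: str = "13C1",
    denominator: str = "M0",
    cfg: IonCountConfig | None = None,
) -> RatioSeries:
    """Build the per-scan ratio series of a run.

    Scans with a zero denominator signal are masked out with reason
    ``zero_base_peak`` rather than raising.
    """
    cfg = cfg or IonCountConfig()
    s_num, n_num = run.signal(numerator), run.noise(numerator)
    s_den, n_den = run.signal(denominator), run.noise(denominator)
    counts_num = ion_count(s_num, n_num, run.resolution, run.microscans, cfg)
    counts_den = ion_count(s_den, n_den, run.resolution, run.microscans, cfg)
    retained = s_den > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.where(retained, (s_num / n_num) / np.where(retained, s_den / n_den, 1.0), np.nan)
    exclusions = {
        int(run.frame["scan"].iloc[i]): "zero_base_peak"
        for i in np.flatnonzero(~retained)
    }
    return RatioSeries(
        ratios=ratios,
        counts_num=counts_num,
        counts_den=counts_den,
        retained=retained,
        tic=run.tic,
        exclusions=exclusions,
        numerator=numerator,
        denominator=denominator,
    )


@dataclass(frozen=True)
class OutlierPolicy:
    """Single-pass robust screen on TIC and on the per-scan ratio.

    A retained scan is dropped when its TIC deviates from the median by more
    than ``k_tic`` MAD-scaled robust standard deviations, or its ratio by
    more than ``k_ratio``.  Defaults are conservative; ``math.inf`` disables
    a component.
    """

    k_tic: float = 5.0
    k_ratio: float = 3.0
    min_scans: int = 5


def _robust_outliers(values: np.ndarray, k: float) -> np.ndarray:
    if not math.isfinite(k):
        return np.zeros(len(values), bool)
    med = np.median(values)
    dev = np.abs(values - med)
    scale = 1.4826 * np.median(dev)
    return dev > k * scale


def filter_outlier_scans(series: RatioSeries, policy: OutlierPolicy | None = None) -> RatioSeries:
    """Apply the outlier policy once, returning a series with an updated mask
    and per-scan exclusion reasons."""
    policy = policy or OutlierPolicy()
    idx = np.flatnonzero(series.retained)
    if len(idx) < policy.min_scans:
        raise ValueError(f"need >= {policy.min_scans} retained scans, have {len(idx)}")
    bad_tic = _robust_outliers(series.tic[idx], policy.k_tic)
    bad_ratio = _robust_outliers(series.ratios[idx], policy.k_ratio)
    retained = series.retained.copy()
    exclusions = dict(series.exclusions)
    for pos, (bt, br) in zip(idx, zip(bad_tic, bad_ratio)):
        if bt or br:
            retained[pos] = False
            exclusions[int(pos)] = "tic_outlier" if bt else "ratio_outlier"
    if not retained.any():
        raise ValueError("outlier policy excluded every scan")
    return RatioSeries(
        ratios=series.ratios,
        counts_num=series.counts_num,
        counts_den=series.counts_den,
        retained=retained,
        tic=series.tic,
        exclusions=exclusions,
        numerator=series.numerator,
        denominator=series.denominator,
    )


@dataclass
class RatioSummary:
    """Aggregated isotopologue ratio of a block of scans."""

    ratio: float
    sd: float
    se: float
    n: int
    n_excluded: int
    shot_noise_rel: float   # predicted relative error from counting statistics
    method: str

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("need at least one retained scan")


def aggregate_ratio(series: RatioSeries, method: str = "ratio_of_sums") -> RatioSummary:
    """Aggregate a scan-ratio series.

    ``ratio_of_sums`` divides the summed ion counts (lower bias at small
    counts, the default); ``mean_of_ratios`` averages per-scan ratios.  The
    two coincide exactly when per-scan counts are proportional.  Dispersion
    is always computed from the retained per-scan ratios; the shot-noise
    relative error is sqrt(1/sum_num + 1/sum_den).
    """
    keep = series.retained
    n = int(keep.sum())
    if n < 1:
        raise ValueError("no retained scans")
    r = series.ratios[keep]
    if method == "mean_of_ratios":
        est = float(np.mean(r))
    elif method == "ratio_of_sums":
        den = float(series.counts_den[keep].sum())
        if den == 0:
            raise ValueError("zero total denominator count")
        est = float(series.counts_num[keep].sum()) / den
    else:
        raise ValueError(f"unknown aggregation method {method!r}")
    sd = float(np.std(r, ddof=1)) if n > 1 else 0.0
    se = sd / math.sqrt(n)
    c_num = float(series.counts_num[keep].sum())
    c_den = float(series.counts_den[keep].sum())
    shot = math.sqrt(1.0 / c_num + 1.0 / c_den) if c_num > 0 and c_den > 0 else math.inf
    return RatioSummary(
        ratio=est,
        sd=sd,
        se=se,
        n=n,
        n_excluded=int((~keep).sum()),
        shot_noise_rel=shot,
        method=method,
    )
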