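"""Session structure, sample-standard bracketing, and delta calibration.

A bracketed session alternates reference (R) and sample (S) segments: the
dual-inlet design uses seven 5-minute valve blocks (R,S,R,S,R,S,R over
35 min); the flow-injection design alternates 15-minute injections whose
plateau (nominally 10 min) supplies the usable scans.  Each sample segment
is referenced to the mean (or time interpolation) of its two neighbouring
reference segments, cancelling source drift common to both isotopologues:

    delta_i = (R_sample,i / R_ref,i - 1) * 1000            [permil]

Values measured against the working standard are placed on the VPDB scale
with the exact multiplicative composition

    delta_s/VPDB = delta_s/std + delta_std/VPDB
                   + delta_s/std * delta_std/VPDB / 1000.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .ratios import IonCountConfig, OutlierPolicy, RatioSummary, aggregate_ratio, filter_outlier_scans, ratio_series
from .scandata import RunTable

__all__ = [
    "SessionLayout",
    "Block",
    "CalibrationConfig",
    "DeltaResult",
    "EvaluationReport",
    "segment_blocks",
    "detect_plateau",
    "bracket_delta",
    "to_vpdb",
    "from_vpdb",
    "mae",
    "combine_replicates",
    "compare_groups",
    "process_session",
    "load_standards",
]


@dataclass(frozen=True)
class SessionLayout:
    """Block schedule of a bracketed session.

    Roles must alternate, starting and ending with a reference, so every
    sample segment is bracketed.  Dual-inlet default: 7 x 5 min blocks.
    Flow-injection (hplc) default: 15 min per injection with a ~10 min
    plateau.
    """

    mode: str = "dual_inlet"
    roles: tuple[str, ...] = ("R", "S", "R", "S", "R", "S", "R")
    block_minutes: float = 5.0
    injection_minutes: float = 15.0

    def __post_init__(self):
        if self.mode not in ("dual_inlet", "hplc"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.roles[0] != "R" or self.roles[-1] != "R":
            raise ValueError("role sequence must start and end with a reference")
        if any(a == b for a, b in zip(self.roles, self.roles[1:])):
            raise ValueError("roles must alternate")
        if self.roles.count("R") < 2:
            raise ValueError("need at least two reference blocks")

    @property
    def segment_minutes(self) -> float:
        return self.block_minutes if self.mode == "dual_inlet" else self.injection_minutes

    @property
    def total_minutes(self) -> float:
        return len(self.roles) * self.segment_minutes


@dataclass
class Block:
    """One reference-or-sample segment with its aggregated ratio."""

    role: str
    t_start: float
    t_end: float
    summary: RatioSummary
    trim_seconds: float = 0.0
    n_scans: int = 0


@dataclass(frozen=True)
class CalibrationConfig:
    """delta 13C of the working standard vs VPDB, in permil (with its SD)."""

    delta_std_vpdb: float = -27.8
    sd: float = 0.4

    def __post_init__(self):
        if not math.isfinite(self.delta_std_vpdb):
            raise ValueError("calibration value must be finite")
        if self.sd < 0:
            raise ValueError("calibration SD must be >= 0")


@dataclass
class DeltaResult:
    """Calibrated session result in permil."""

    delta_vs_std: float
    delta_vpdb: float
    sd: float
    n: int
    ci95_half_width: float
    per_block: list[float] = field(default_factory=list)
    flags: dict = field(default_factory=dict)


def segment_blocks(
    run: RunTable,
    layout: SessionLayout | None = None,
    trim_seconds: float = 30.0,
    numerator: str = "13C1",
    denominator: str = "M0",
    cfg: IonCountConfig | None = None,
    policy: OutlierPolicy | None = None,
    method: str = "ratio_of_sums",
    min_scans: int = 10,
    plateau_threshold: float | None = None,
) -> list[Block]:
    """Assign scans to layout segments and aggregate each segment's ratio.

    Segments are half-open time intervals [start, end): a scan exactly at a
    boundary belongs to the later block.  The first and last *trim_seconds*
    of each segment are discarded (valve-switch / injection transients).  In
    hplc mode each injection is additionally restricted to its TIC plateau
    before trimming (see :func:`detect_plateau`).
    """
    layout = layout or SessionLayout()
    if trim_seconds < 0 or trim_seconds >= layout.segment_minutes * 30:
        raise ValueError("trim must be non-negative and < half the segment length")
    t = run.time_min
    if len(t) == 0 or t.max() < layout.total_minutes - layout.segment_minutes * 0.5:
        raise ValueError("run shorter than the session layout")
    trim_min = trim_seconds / 60.0
    blocks: list[Block] = []
    for i, role in enumerate(layout.roles):
        t0 = i * layout.segment_minutes
        t1 = t0 + layout.segment_minutes
        if layout.mode == "hplc":
            seg = run.window(t0, t1)
            lo, hi = detect_plateau(
                seg,
                threshold=plateau_threshold if plateau_threshold is not None else 0.5,
                min_duration_min=1.0,
                trim_seconds=trim_seconds,
            )
            sub = seg.window(lo, hi)
        else:
            sub = run.window(t0 + trim_min, t1 - trim_min)
        if len(sub) < min_scans:
            raise ValueError(
                f"block {i} ({role}) retains {len(sub)} scans, fewer than {min_scans}"
            )
        series = ratio_series(sub, numerator, denominator, cfg)
        series = filter_outlier_scans(series, policy)
        summary = aggregate_ratio(series, method)
        blocks.append(
            Block(
                role="reference" if role == "R" else "sample",
                t_start=t0,
                t_end=t1,
                summary=summary,
                trim_seconds=trim_seconds,
                n_scans=len(sub),
            )
        )
    return blocks


def detect_plateau(
    run: RunTable,
    threshold: float = 0.5,
    min_duration_min: float = 1.0,
    trim_seconds: float = 30.0,
) -> tuple[float, float]:
    """Locate the usable TIC plateau of a flow-injection segment.

    The plateau is the longest contiguous scan window whose TIC stays at or
    above ``threshold`` times the median TIC of the top-half scans; the
    returned time window is additionally edge-trimmed.  Raises when no
    window meets the minimum duration.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    tic = run.tic
    t = run.time_min
    if len(tic) == 0 or np.nanmax(tic) <= 0:
        raise ValueError("no usable TIC signal")
    top_half = tic[tic >= np.median(tic)]
    ref = float(np.median(top_half))
    above = tic >= threshold * ref
    runs: list[tuple[int, int]] = []
    start = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(above) - 1))
    if not runs:
        raise ValueError("no plateau found")
    lo_i, hi_i = max(runs, key=lambda r: r[1] - r[0])
    lo, hi = float(t[lo_i]), float(t[hi_i])
    if hi - lo < min_duration_min:
        raise ValueError(f"plateau of {hi - lo:.2f} min shorter than {min_duration_min} min")
    trim = trim_seconds / 60.0
    return lo + trim, hi - trim + 1e-9


def bracket_delta(blocks: list[Block], bracketing: str = "adjacent_mean") -> DeltaResult:
    """Per-sample-block deltas vs the working standard, in permil.

    Each sample block's reference ratio is the mean (``adjacent_mean``) or
    time-linear interpolation (``interpolate``) of its two neighbouring
    reference blocks.  The session estimate is the mean over sample blocks
    with SD and a t-based 95% half-width across them.
    """
    if bracketing not in ("adjacent_mean", "interpolate"):
        raise ValueError(f"unknown bracketing {bracketing!r}")
    deltas = []
    for i, blk in enumerate(blocks):
        if blk.role != "sample":
            continue
        prev = next((b for b in reversed(blocks[:i]) if b.role == "reference"), None)
        nxt = next((b for b in blocks[i + 1:] if b.role == "reference"), None)
        if prev is None or nxt is None:
            raise ValueError(f"sample block at {blk.t_start} min is not bracketed")
        if bracketing == "adjacent_mean":
            r_ref = 0.5 * (prev.summary.ratio + nxt.summary.ratio)
        else:
            tm = 0.5 * (blk.t_start + blk.t_end)
            tp = 0.5 * (prev.t_start + prev.t_end)
            tn = 0.5 * (nxt.t_start + nxt.t_end)
            w = (tm - tp) / (tn - tp)
            r_ref = (1 - w) * prev.summary.ratio + w * nxt.summary.ratio
        deltas.append((blk.summary.ratio / r_ref - 1.0) * 1000.0)
    if not deltas:
        raise ValueError("no sample blocks")
    arr = np.asarray(deltas)
    n = len(arr)
    sd = float(np.std(arr, ddof=1)) if n > 1 else 0.0
    ci = float(stats.t.ppf(0.975, n - 1) * sd / math.sqrt(n)) if n > 1 else math.nan
    return DeltaResult(
        delta_vs_std=float(arr.mean()),
        delta_vpdb=math.nan,
        sd=sd,
        n=n,
        ci95_half_width=ci,
        per_block=list(map(float, arr)),
    )


def to_vpdb(delta_vs_std: float, cal: CalibrationConfig) -> float:
    """Place a delta measured against the working standard on the VPDB
    scale (exact multiplicative composition, permil in and out)."""
    if not math.isfinite(delta_vs_std):
        raise ValueError("delta must be finite")
    ds, dr = delta_vs_std, cal.delta_std_vpdb
    return ds + dr + ds * dr / 1000.0


def from_vpdb(delta_vpdb: float, cal: CalibrationConfig) -> float:
    """Inverse of :func:`to_vpdb`: express a VPDB-scale delta against the
    working standard."""
    if not math.isfinite(delta_vpdb):
        raise ValueError("delta must be finite")
    dr = cal.delta_std_vpdb
    return (delta_vpdb - dr) / (1.0 + dr / 1000.0)


@dataclass
class EvaluationReport:
    """Measured-vs-expected delta comparison for a standard set."""

    measured: np.ndarray
    expected: np.ndarray
    residues: np.ndarray
    mae: float
    n: int

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "measured": self.measured,
                "expected": self.expected,
                "residue": self.residues,
            }
        )


def mae(measured, expected) -> EvaluationReport:
    """Mean absolute error between measured and expected delta values:
    MAE = (1/n) sum |measured_i - expected_i|."""
    m = np.asarray(measured, float)
    e = np.asarray(expected, float)
    if m.shape != e.shape:
        raise ValueError("measured and expected must have the same length")
    if m.size < 1:
        raise ValueError("need at least one value")
    res = m - e
    return EvaluationReport(
        measured=m, expected=e, residues=res, mae=float(np.mean(np.abs(res))), n=m.size
    )


def combine_replicates(deltas, confidence: float = 0.95):
    """Mean, SD (ddof=1) and t-based confidence half-width of replicate
    deltas: half-width = t(1-alpha/2, n-1) * SD / sqrt(n)."""
    arr = np.asarray(deltas, float)
    n = arr.size
    if n < 2:
        raise ValueError("need at least two replicates")
    sd = float(np.std(arr, ddof=1))
    tq = float(stats.t.ppf(0.5 + confidence / 2.0, n - 1))
    return float(arr.mean()), sd, tq * sd / math.sqrt(n)


def compare_groups(a, b):
    """Two-sided Welch's t test on replicate deltas of two groups.

    Degenerate zero-variance groups with equal means give (0, nan, 1) by
    convention.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two replicates")
    if np.std(a) == 0 and np.std(b) == 0 and a.mean() == b.mean():
        return 0.0, math.nan, 1.0
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def process_session(
    run: RunTable,
    layout: SessionLayout | None = None,
    cal: CalibrationConfig | None = None,
    bracketing: str = "adjacent_mean",
    trim_seconds: float = 30.0,
    numerator: str = "13C1",
    denominator: str = "M0",
    cfg: IonCountConfig | None = None,
    policy: OutlierPolicy | None = None,
    method: str = "ratio_of_sums",
) -> DeltaResult:
    """End-to-end session processing: segment, aggregate, bracket, calibrate."""
    cal = cal or CalibrationConfig()
    blocks = segment_blocks(
        run,
        layout,
        trim_seconds=trim_seconds,
        numerator=numerator,
        denominator=denominator,
        cfg=cfg,
        policy=policy,
        method=method,
    )
    result = bracket_delta(blocks, bracketing)
    result.delta_vpdb = to_vpdb(result.delta_vs_std, cal)
    low = [b for b in blocks if b.summary.n < 10]
    if low:
        result.flags["low_scan_count_blocks"] = len(low)
    return result


def load_standards() -> pd.DataFrame:
    """Bundled methyl stearate standards validation set: per standard,
    introduction method and adduct, the Orbitrap delta 13C (vs VPDB), its
    SD, the GC-C-IRMS expected value and the residue as published."""
    ref = resources.files("orbidelta.data") / "fame_standards.tsv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", comment="#")
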