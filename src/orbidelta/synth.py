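"""Seeded synthetic-session generator with known ground truth.

Forward model: each scan delivers a Poisson-distributed number of ions per
monitored isotopologue with expectation

    E[count] = flux * abundance(species) * drift(t) * plateau(t)

where abundance is recomputed from the isotope table after shifting the
13C/12C ratio to realise the configured delta value (18O and 2H stay at
reference composition), drift models slow source intensity changes common
to all species, and plateau models the flow-injection profile.  Realised
counts are inverted through the same signal-to-noise ion-count relation the
analysis uses, so a noise-free simulation recovers the configured delta
exactly.  The noise column is an arbitrary-unit scale with log-normal
jitter; it cancels from every ratio.

Defaults mirror the validated acquisition: resolution 60,000, two
microscans, AGC target 5e5 ions per scan, 1 s scan period, sodiated methyl
stearate with a 7-block dual-inlet schedule, working standard at
-27.8 permil vs VPDB.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import chem
from .chem import IsotopeTable, TargetIon, default_isotope_table, make_target
from .scandata import CentroidSpectrum, RunTable
from .ratios import IonCountConfig
from .session import CalibrationConfig, SessionLayout, from_vpdb

__all__ = ["SimConfig", "simulate_session", "simulate_spectra", "predict_precision"]

#: 13C/12C atomic ratio of the VPDB scale anchor.
R13_VPDB = 0.0111802


@dataclass(frozen=True)
class SimConfig:
    """Full parameterisation of one synthetic bracketed session."""

    delta_sample_vpdb: float = -30.0     # true delta 13C of the sample, permil vs VPDB
    delta_reference_vpdb: float = -27.8  # working standard, permil vs VPDB
    formula: str = "C19H38O2"
    adduct: str = "sodium"
    charge: int = 1
    species_labels: tuple[str, ...] = ("M0", "13C1", "13C2", "18O1")
    flux: float = 5e5                    # mean total ions per scan (AGC-limited)
    resolution: float = 60_000.0
    microscans: int = 2
    scan_period_s: float = 1.0
    layout: SessionLayout = field(default_factory=SessionLayout)
    drift: str = "none"                  # none | linear | exponential
    drift_rate_per_hour: float = 0.0     # fractional flux change per hour
    adduct_ratio: float = 10.0           # [M+Na]+ : [M+H]+ intensity ratio
    contamination: float = 0.0           # fraction of window intensity
    plateau_ramp_min: float = 1.0        # hplc ramp up/down time
    noise_base: float = 1.0              # arbitrary-unit noise scale
    noise_sigma: float = 0.1             # log-normal jitter of the noise scale
    poisson: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.flux <= 0:
            raise ValueError("flux must be positive")
        if not 0.0 <= self.contamination < 1.0:
            raise ValueError("contamination must be in [0, 1)")
        if self.adduct_ratio <= 0:
            raise ValueError("adduct ratio must be positive")
        if self.drift not in ("none", "linear", "exponential"):
            raise ValueError(f"unknown drift model {self.drift!r}")

    @property
    def delta_sample_vs_std(self) -> float:
        """Ground-truth delta of the sample against the working standard."""
        return from_vpdb(
            self.delta_sample_vpdb, CalibrationConfig(self.delta_reference_vpdb, 0.0)
        )


def _shifted_table(delta_vpdb: float, base: IsotopeTable) -> IsotopeTable:
    """Isotope table whose 13C/12C ratio realises *delta_vpdb*."""
    r13 = R13_VPDB * (1.0 + delta_vpdb / 1000.0)
    return base.with_ratio("C", 13, r13)


def _species_abundances(cfg: SimConfig, delta_vpdb: float, base: IsotopeTable) -> dict[str, float]:
    table = _shifted_table(delta_vpdb, base)
    formula = chem.parse_formula(cfg.formula, table)
    structure = {
        s.label: s.abundance
        for s in chem.fine_structure(formula, cfg.adduct, cfg.charge, 1e-9, table)
    }
    return {lb: structure[lb] for lb in cfg.species_labels}


def _drift_factor(cfg: SimConfig, t_min: np.ndarray) -> np.ndarray:
    hours = t_min / 60.0
    if cfg.drift == "none" or cfg.drift_rate_per_hour == 0.0:
        return np.ones_like(t_min)
    if cfg.drift == "linear":
        return 1.0 + cfg.drift_rate_per_hour * hours
    return np.exp(cfg.drift_rate_per_hour * hours)


def _plateau_factor(cfg: SimConfig, t_min: np.ndarray) -> np.ndarray:
    """Trapezoidal injection profile inside each hplc segment; unity for
    the dual-inlet mode (continuous infusion)."""
    if cfg.layout.mode != "hplc":
        return np.ones_like(t_min)
    seg = cfg.layout.injection_minutes
    ramp = cfg.plateau_ramp_min
    local = np.mod(t_min, seg)
    up = np.clip(local / ramp, 0.0, 1.0)
    down = np.clip((seg - local) / ramp, 0.0, 1.0)
    return np.minimum(up, down)


def simulate_session(cfg: SimConfig) -> RunTable:
    """Generate the scan table of one synthetic session.

    Deterministic given (config, seed): identical inputs give bit-identical
    tables.  Raises when the flux is so low that the expected base-peak
    count per scan falls below one ion.
    """
    rng = np.random.default_rng(cfg.seed)
    base = default_isotope_table()
    ab_ref = _species_abundances(cfg, cfg.delta_reference_vpdb, base)
    ab_sam = _species_abundances(cfg, cfg.delta_sample_vpdb, base)
    if cfg.flux * ab_ref["M0"] < 1.0:
        raise ValueError("expected base-peak count per scan is below one ion")

    layout = cfg.layout
    total_min = layout.total_minutes
    n_scans = int(total_min * 60.0 / cfg.scan_period_s)
    t_min = np.arange(n_scans) * cfg.scan_period_s / 60.0
    seg_idx = np.minimum((t_min // layout.segment_minutes).astype(int), len(layout.roles) - 1)
    is_sample = np.array([layout.roles[i] == "S" for i in seg_idx])
    drift = _drift_factor(cfg, t_min)
    plateau = _plateau_factor(cfg, t_min)
    scale = IonCountConfig().scale(cfg.resolution, cfg.microscans)

    frame = {"scan": np.arange(n_scans), "time_min": t_min}
    tic = np.zeros(n_scans)
    for label in cfg.species_labels:
        ab = np.where(is_sample, ab_sam[label], ab_ref[label])
        expected = cfg.flux * ab * drift * plateau
        counts = rng.poisson(expected).astype(float) if cfg.poisson else expected
        noise = cfg.noise_base * np.exp(rng.normal(0.0, cfg.noise_sigma, n_scans))
        signal = counts * noise / scale
        frame[f"S_{label}"] = signal
        frame[f"N_{label}"] = noise
        tic += signal
    frame["tic"] = tic
    metadata = {
        "formula": cfg.formula,
        "adduct": cfg.adduct,
        "charge": cfg.charge,
        "resolution": cfg.resolution,
        "microscans": cfg.microscans,
        "mode": layout.mode,
        "seed": cfg.seed,
        "true_delta_sample_vpdb": cfg.delta_sample_vpdb,
        "true_delta_reference_vpdb": cfg.delta_reference_vpdb,
    }
    cols = ["scan", "time_min", "tic"]
    for lb in cfg.species_labels:
        cols += [f"S_{lb}", f"N_{lb}"]
    return RunTable(pd.DataFrame(frame)[cols], metadata)


def simulate_spectra(cfg: SimConfig, target: TargetIon | None = None) -> list[CentroidSpectrum]:
    """Generate centroided spectra for the session, including an optional
    coisolated contaminant peak carrying the configured fraction of the
    window intensity (placed 0.5 Da above the base peak, mass-resolved from
    every monitored species)."""
    run = simulate_session(cfg)
    target = target or make_target(
        cfg.formula, cfg.adduct, cfg.charge, labels=cfg.species_labels
    )
    mz_by_label = {s.label: s.mz for s in target.species}
    contam_mz = mz_by_label["M0"] + 0.5
    f = cfg.contamination
    spectra = []
    for rec in run.scans():
        mzs, intens, noises = [], [], []
        for label, (s, n) in rec.readings.items():
            mzs.append(mz_by_label[label])
            intens.append(s)
            noises.append(n)
        if f > 0.0:
            total = float(sum(intens))
            mzs.append(contam_mz)
            intens.append(total * f / (1.0 - f))
            noises.append(float(np.median(noises)))
        order = np.argsort(mzs)
        spectra.append(
            CentroidSpectrum(
                scan=rec.scan,
                time_min=rec.time_min,
                mz=np.asarray(mzs)[order],
                intensity=np.asarray(intens)[order],
                noise=np.asarray(noises)[order],
            )
        )
    return spectra


def predict_precision(cfg: SimConfig, trim_seconds: float = 30.0) -> float:
    """Counting-statistics prediction of the session delta standard error
    (permil): SE = 1000 * sqrt(2) * sqrt(1/C_minor + 1/C_major) / sqrt(n_S),
    with C the retained ions per block per species and n_S the number of
    sample blocks.  The sqrt(2) accounts for reference-and-sample noise."""
    base = default_isotope_table()
    ab = _species_abundances(cfg, cfg.delta_reference_vpdb, base)
    layout = cfg.layout
    usable_s = layout.segment_minutes * 60.0 - 2.0 * trim_seconds
    n_scans = usable_s / cfg.scan_period_s
    c_major = n_scans * cfg.flux * ab["M0"]
    c_minor = n_scans * cfg.flux * ab["13C1"]
    n_sample = sum(1 for r in layout.roles if r == "S")
    return 1000.0 * math.sqrt(2.0) * math.sqrt(1.0 / c_minor + 1.0 / c_major) / math.sqrt(n_sample)
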