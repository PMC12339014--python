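"""Per-scan signal data model and I/O.

The primary exchange format is an open, tab-delimited scan table: one row
per Orbitrap scan with signal (S) and noise (N) columns per monitored
isotopologue, plus a ``#``-prefixed metadata block.  Centroided mzML (or
in-memory centroid spectra) can be reduced to the same table by matching
peaks to the monitored species' m/z windows.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .chem import TargetIon

__all__ = [
    "ScanRecord",
    "RunTable",
    "CentroidSpectrum",
    "read_scan_table",
    "write_scan_table",
    "read_mzml",
    "write_mzml",
    "extract_signals",
    "contamination_fraction",
    "ContaminationReport",
]

_META_KEYS = ("formula", "adduct", "charge", "resolution", "microscans", "mode")


@dataclass
class ScanRecord:
    """One scan's extracted readings: per-species (S, N) plus the
    acquisition parameters entering the ion-count estimate."""

    scan: int
    time_min: float
    readings: dict[str, tuple[float, float]]  # label -> (S, N)
    resolution: float
    microscans: int
    tic: float = math.nan

    def __post_init__(self):
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if self.microscans < 1:
            raise ValueError("microscans must be >= 1")
        for label, (s, n) in self.readings.items():
            if s < 0:
                raise ValueError(f"scan {self.scan}: negative S for {label}")
            if n <= 0:
                raise ValueError(f"scan {self.scan}: non-positive N for {label}")


class RunTable:
    """Ordered scans of one acquisition run.

    Wraps a DataFrame with columns ``scan, time_min, tic, S_<label>,
    N_<label>, ...`` and a metadata mapping (formula, adduct, charge,
    resolution, microscans, mode).  All scans of a run share the resolution
    and microscan settings.
    """

    def __init__(self, frame: pd.DataFrame, metadata: dict, flags: dict | None = None):
        required = {"scan", "time_min", "tic"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"scan table missing columns: {sorted(missing)}")
        labels = sorted(
            c[2:] for c in frame.columns if c.startswith("S_")
        )
        for lb in labels:
            if f"N_{lb}" not in frame.columns:
                raise ValueError(f"species {lb} has S column but no N column")
        if not labels:
            raise ValueError("scan table has no species columns")
        frame = frame.sort_values("scan", kind="stable").reset_index(drop=True)
        if not frame["time_min"].is_monotonic_increasing:
            # tolerated with a flag; order by scan index is authoritative
            flags = dict(flags or {})
            flags["non_monotone_time"] = True
        for lb in labels:
            n = frame[f"N_{lb}"].to_numpy(float)
            s = frame[f"S_{lb}"].to_numpy(float)
            if (n <= 0).any():
                bad = int(frame["scan"].to_numpy()[np.flatnonzero(n <= 0)[0]])
                raise ValueError(f"non-positive noise for {lb} at scan {bad}")
            if (s < 0).any():
                bad = int(frame["scan"].to_numpy()[np.flatnonzero(s < 0)[0]])
                raise ValueError(f"negative signal for {lb} at scan {bad}")
        self.frame = frame
        self.metadata = dict(metadata)
        self.labels = labels
        self.flags = dict(flags or {})

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def resolution(self) -> float:
        return float(self.metadata.get("resolution", math.nan))

    @property
    def microscans(self) -> int:
        return int(self.metadata.get("microscans", 1))

    def scans(self):
        res, mu = self.resolution, self.microscans
        for row in self.frame.itertuples(index=False):
            yield ScanRecord(
                scan=int(row.scan),
                time_min=float(row.time_min),
                readings={
                    lb: (getattr(row, f"S_{lb}"), getattr(row, f"N_{lb}"))
                    for lb in self.labels
                },
                resolution=res,
                microscans=mu,
                tic=float(row.tic),
            )

    def signal(self, label: str) -> np.ndarray:
        return self.frame[f"S_{label}"].to_numpy(float)

    def noise(self, label: str) -> np.ndarray:
        return self.frame[f"N_{label}"].to_numpy(float)

    @property
    def time_min(self) -> np.ndarray:
        return self.frame["time_min"].to_numpy(float)

    @property
    def tic(self) -> np.ndarray:
        return self.frame["tic"].to_numpy(float)

    def window(self, t0: float, t1: float) -> "RunTable":
        """Scans with time in the half-open interval [t0, t1)."""
        t = self.time_min
        sel = (t >= t0) & (t < t1)
        return RunTable(self.frame[sel].copy(), self.metadata, self.flags)

    def equals(self, other: "RunTable") -> bool:
        if self.labels != other.labels or self.metadata != other.metadata:
            return False
        cols = ["scan", "time_min", "tic"]
        for lb in self.labels:
            cols += [f"S_{lb}", f"N_{lb}"]
        a = self.frame[cols].to_numpy(float)
        b = other.frame[cols].to_numpy(float)
        return a.shape == b.shape and bool(np.array_equal(a, b))


def write_scan_table(run: RunTable, path) -> None:
    """Write the tab-delimited scan table with its ``#`` metadata block."""
    with open(path, "w", encoding="utf-8") as fh:
        for key in _META_KEYS:
            if key in run.metadata:
                fh.write(f"# {key}: {run.metadata[key]}\n")
        for key, value in run.metadata.items():
            if key not in _META_KEYS:
                fh.write(f"# {key}: {value}\n")
        cols = ["scan", "time_min", "tic"]
        for lb in run.labels:
            cols += [f"S_{lb}", f"N_{lb}"]
        fh.write("\t".join(cols) + "\n")
        run.frame[cols].to_csv(fh, sep="\t", header=False, index=False, float_format="%.17g")


def read_scan_table(path) -> RunTable:
    """Read a scan table written by :func:`write_scan_table` (or any file
    conforming to the documented schema)."""
    metadata: dict[str, object] = {}
    header_line = None
    body = io.StringIO()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                text = line[1:].strip()
                if ":" in text:
                    key, _, value = text.partition(":")
                    metadata[key.strip()] = _coerce(value.strip())
                continue
            if header_line is None:
                header_line = line
                if not line.startswith("scan\ttime_min"):
                    raise ValueError(f"malformed scan table header: {line.strip()!r}")
            body.write(line)
    if header_line is None:
        raise ValueError(f"no header in scan table {path}")
    body.seek(0)
    frame = pd.read_csv(body, sep="\t", float_precision="round_trip")
    return RunTable(frame, metadata)


def _coerce(value: str):
    for cast in (int, float):
        try:
            return cast(value)
        except ValueError:
            pass
    return value


@dataclass
class CentroidSpectrum:
    """A centroided scan: parallel peak arrays, with per-peak noise where
    the acquisition exported one (otherwise ``noise`` is None and a
    spectrum-level fallback applies downstream, flagged)."""

    scan: int
    time_min: float
    mz: np.ndarray
    intensity: np.ndarray
    noise: np.ndarray | None = None

    def __post_init__(self):
        self.mz = np.asarray(self.mz, float)
        self.intensity = np.asarray(self.intensity, float)
        if self.noise is not None:
            self.noise = np.asarray(self.noise, float)
            if (self.noise <= 0).any():
                raise ValueError(f"scan {self.scan}: non-positive noise value")
        # canonical peak order: strictly increasing m/z
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]
        if self.noise is not None:
            self.noise = self.noise[order]
        if len(self.mz) > 1 and (np.diff(self.mz) <= 0).any():
            raise ValueError(f"scan {self.scan}: duplicate m/z values")


_MZML_NS = "{http://psi.hupo.org/ms/mzml}"


def _decode_binary_array(elem) -> tuple[str | None, np.ndarray]:
    """Decode one mzML <binaryDataArray>: returns (kind, values) where kind
    is "mz", "intensity", a non-standard array name, or None."""
    import base64
    import zlib

    dtype = np.float64
    compressed = False
    kind = None
    for cv in elem.iter(f"{_MZML_NS}cvParam"):
        acc = cv.get("accession", "")
        if acc == "MS:1000521":
            dtype = np.float32
        elif acc == "MS:1000523":
            dtype = np.float64
        elif acc == "MS:1000574":
            compressed = True
        elif acc == "MS:1000514":
            kind = "mz"
        elif acc == "MS:1000515":
            kind = "intensity"
        elif acc == "MS:1000786":
            kind = (cv.get("value") or "non-standard").strip().lower()
    node = elem.find(f"{_MZML_NS}binary")
    raw = base64.b64decode(node.text or "")
    if compressed:
        raw = zlib.decompress(raw)
    return kind, np.frombuffer(raw, dtype=dtype).astype(float)


def read_mzml(path) -> list[CentroidSpectrum]:
    """Read centroided spectra from mzML, consuming only m/z, intensity and
    (where present) noise arrays.

    Noise is taken from a non-standard binary data array whose name contains
    "noise" (the convention vendor converters use); spectra without one get
    ``noise=None``.  Only MS1 spectra are returned.
    """
    from lxml import etree

    spectra = []
    for idx, (_, spec) in enumerate(
        etree.iterparse(str(path), tag=f"{_MZML_NS}spectrum")
    ):
        level = None
        for cv in spec.iter(f"{_MZML_NS}cvParam"):
            if cv.get("accession") == "MS:1000511":
                level = int(cv.get("value"))
        if level not in (None, 1):
            spec.clear()
            continue
        time = 0.0
        for scan in spec.iter(f"{_MZML_NS}scan"):
            for cv in scan.iter(f"{_MZML_NS}cvParam"):
                if cv.get("accession") == "MS:1000016":
                    time = float(cv.get("value"))
                    if cv.get("unitName", "minute").startswith("second"):
                        time /= 60.0
            break
        mz = intensity = noise = None
        for arr in spec.iter(f"{_MZML_NS}binaryDataArray"):
            kind, values = _decode_binary_array(arr)
            if kind == "mz":
                mz = values
            elif kind == "intensity":
                intensity = values
            elif kind and "noise" in kind:
                noise = values
        if mz is None or intensity is None:
            raise ValueError(f"spectrum {idx}: missing m/z or intensity array")
        spectra.append(
            CentroidSpectrum(scan=idx, time_min=time, mz=mz, intensity=intensity, noise=noise)
        )
        spec.clear()
    return spectra


def write_mzml(spectra: list[CentroidSpectrum], path) -> None:
    """Write centroid spectra as minimal mzML (64-bit, uncompressed), with
    per-peak noise carried in a non-standard "noise array"."""
    import base64

    def b64(arr):
        return base64.b64encode(np.asarray(arr, "<f8").tobytes()).decode()

    def array_xml(kind_cv, payload):
        return (
            f'<binaryDataArray encodedLength="{len(payload)}">'
            '<cvParam cvRef="MS" accession="MS:1000523" name="64-bit float"/>'
            '<cvParam cvRef="MS" accession="MS:1000576" name="no compression"/>'
            f"{kind_cv}<binary>{payload}</binary></binaryDataArray>"
        )

    chunks = []
    for spec in spectra:
        arrays = [
            array_xml('<cvParam cvRef="MS" accession="MS:1000514" name="m/z array"/>', b64(spec.mz)),
            array_xml('<cvParam cvRef="MS" accession="MS:1000515" name="intensity array"/>', b64(spec.intensity)),
        ]
        if spec.noise is not None:
            arrays.append(
                array_xml(
                    '<cvParam cvRef="MS" accession="MS:1000786" name="non-standard data array" value="noise array"/>',
                    b64(spec.noise),
                )
            )
        chunks.append(
            f'<spectrum index="{spec.scan}" id="scan={spec.scan + 1}" defaultArrayLength="{len(spec.mz)}">'
            '<cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>'
            '<cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum"/>'
            '<scanList count="1"><cvParam cvRef="MS" accession="MS:1000795" name="no combination"/>'
            f'<scan><cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{spec.time_min!r}" '
            'unitCvRef="UO" unitAccession="UO:0000031" unitName="minute"/></scan></scanList>'
            f'<binaryDataArrayList count="{len(arrays)}">{"".join(arrays)}</binaryDataArrayList>'
            "</spectrum>"
        )
    doc = (
        '<?xml version="1.0" encoding="utf-8"?>'
        '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">'
        '<cvList count="2"><cv id="MS" fullName="PSI-MS" URI="https://raw.githubusercontent.com/'
        'HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>'
        '<cv id="UO" fullName="UO" URI="http://purl.obolibrary.org/obo/uo.obo"/></cvList>'
        f'<run id="run"><spectrumList count="{len(spectra)}" defaultDataProcessingRef="dp">'
        f"{''.join(chunks)}</spectrumList></run></mzML>"
    )
    Path(path).write_text(doc, encoding="utf-8")


def extract_signals(
    spectra: list[CentroidSpectrum],
    target: TargetIon,
    resolution: float = 60000,
    microscans: int = 2,
    ppm: float | None = None,
    default_noise: float | None = None,
) -> RunTable:
    """Reduce centroid spectra to a scan table for the monitored species.

    For each scan and species the most intense peak within +-ppm of the
    species m/z supplies (S, N).  An absent peak yields S = 0 with N set to
    the median noise of the scan (flagged); two or more candidate peaks set a
    multiplicity flag.  Species windows must be disjoint at the configured
    tolerance.
    """
    ppm = target.ppm_tolerance if ppm is None else ppm
    mzs = [(s.label, s.mz) for s in target.species]
    ordered = sorted(mzs, key=lambda t: t[1])
    for (la, ma), (lb, mb) in zip(ordered, ordered[1:]):
        if ma * (1 + ppm * 1e-6) >= mb * (1 - ppm * 1e-6):
            raise ValueError(f"species windows overlap at {ppm} ppm: {la}, {lb}")

    rows = []
    flags: dict[str, object] = {}
    for spec in spectra:
        if spec.noise is None:
            if default_noise is None:
                raise ValueError(
                    f"scan {spec.scan}: no noise array and no default_noise given"
                )
            noise = np.full_like(spec.intensity, float(default_noise))
            flags["spectrum_level_noise"] = True
        else:
            noise = spec.noise
        row = {"scan": spec.scan, "time_min": spec.time_min, "tic": float(spec.intensity.sum())}
        scan_median_noise = float(np.median(noise)) if len(noise) else (default_noise or 1.0)
        for label, mz0 in mzs:
            tol = mz0 * ppm * 1e-6
            sel = np.flatnonzero(np.abs(spec.mz - mz0) <= tol)
            if len(sel) == 0:
                row[f"S_{label}"] = 0.0
                row[f"N_{label}"] = scan_median_noise
                flags.setdefault("missing_peaks", []).append((spec.scan, label))
            else:
                if len(sel) > 1:
                    flags.setdefault("multiple_peaks", []).append((spec.scan, label))
                best = sel[np.argmax(spec.intensity[sel])]
                row[f"S_{label}"] = float(spec.intensity[best])
                row[f"N_{label}"] = float(noise[best])
        rows.append(row)
    frame = pd.DataFrame(rows)
    metadata = {
        "adduct": target.adduct,
        "charge": target.charge,
        "resolution": resolution,
        "microscans": microscans,
    }
    return RunTable(frame, metadata, flags)


@dataclass
class ContaminationReport:
    """Per-scan unassigned-intensity fraction inside a monitored window,
    with run-level median/max and a screening flag (default threshold 10%)."""

    per_scan: np.ndarray
    median: float
    max: float
    threshold: float
    flagged: bool


def contamination_fraction(
    spectra: list[CentroidSpectrum],
    target: TargetIon,
    window: tuple[float, float],
    threshold: float = 0.10,
    ppm: float | None = None,
) -> ContaminationReport:
    """Fraction of window intensity not assigned to monitored species.

    Runs exceeding the threshold (median or max of per-scan fractions >=
    threshold) are flagged for review, never rejected automatically.
    """
    lo, hi = window
    if not hi > lo:
        raise ValueError("empty m/z window")
    ppm = target.ppm_tolerance if ppm is None else ppm
    for s in target.species:
        if not lo <= s.mz <= hi:
            raise ValueError(f"window does not cover species {s.label} at m/z {s.mz:.4f}")
    fractions = []
    for spec in spectra:
        in_window = (spec.mz >= lo) & (spec.mz <= hi)
        total = float(spec.intensity[in_window].sum())
        if total == 0.0:
            fractions.append(0.0)
            continue
        assigned = np.zeros(len(spec.mz), bool)
        for s in target.species:
            tol = s.mz * ppm * 1e-6
            assigned |= np.abs(spec.mz - s.mz) <= tol
        contam = float(spec.intensity[in_window & ~assigned].sum())
        fractions.append(contam / total)
    per_scan = np.asarray(fractions)
    med = float(np.median(per_scan)) if len(per_scan) else 0.0
    mx = float(per_scan.max()) if len(per_scan) else 0.0
    return ContaminationReport(
        per_scan=per_scan,
        median=med,
        max=mx,
        threshold=threshold,
        flagged=med >= threshold or mx >= threshold,
    )
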