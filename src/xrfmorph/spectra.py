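"""Reading, calibration, formatting and landmarking of micro-XRF spectra.

A per-zone mean spectrum (photon counts per pixel vs emission energy in keV)
is turned into a fixed-length *landmark vector*: the continuous spectrum is
reconstructed by linear interpolation, subset to the reliable 1.7-18.3 keV
window, log10-transformed and standardised (mean 0, population sd 1), then
sampled every 0.02 keV.  The resulting 831 values are homologous across
spectra and form the rows of a :class:`LandmarkMatrix`, the morphometric data
object all downstream analyses operate on.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# The landmark grid: 1.7 + 0.02 k keV for k = 0..830.
GRID_LO = 1.7
GRID_HI = 18.3
GRID_STEP = 0.02
N_LANDMARKS = 831
LANDMARK_GRID = np.linspace(GRID_LO, GRID_HI, N_LANDMARKS)

MANIFEST_COLUMNS = ("zone_id", "specimen_id", "site", "clade", "zone_type", "session", "mineralogy")
ZONE_TYPES = ("fossil", "sediment")


@dataclass(frozen=True)
class Spectrum:
    """One analysed zone: strictly increasing energies (keV) and mean counts.

    Counts are mean photon counts per pixel over the zone and may be
    fractional; they must be non-negative.
    """

    zone_id: str
    energy: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.energy, dtype=float)
        c = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "energy", e)
        object.__setattr__(self, "counts", c)
        if e.ndim != 1 or c.ndim != 1 or e.size != c.size:
            raise ValueError("energy and counts must be 1-D vectors of equal length")
        if e.size < 2:
            raise ValueError("a spectrum needs at least 2 points")
        d = np.diff(e)
        if np.any(d <= 0):
            row = int(np.argmax(d <= 0)) + 1
            raise ValueError(f"non-monotone energy at row {row} (E={e[row]:g} keV)")
        if np.any(c < 0):
            row = int(np.argmax(c < 0))
            raise ValueError(f"negative counts at row {row}")

    @property
    def support(self) -> tuple[float, float]:
        return float(self.energy[0]), float(self.energy[-1])


_NUM_RE = re.compile(r"^[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$")


def _split_row(line: str) -> list[str]:
    for sep in (",", ";", "\t"):
        if sep in line:
            return [f.strip() for f in line.split(sep) if f.strip()]
    return line.split()


def read_spectrum(path: str | Path, format: str = "auto") -> Spectrum:
    """Read one spectrum from a two-column delimited file or an EMSA/MAS file.

    ``format`` is ``delimited``, ``emsa`` or ``auto`` (sniffed: EMSA files
    start with ``#FORMAT``).  Comment lines (``#``) and an optional header
    row are ignored in delimited files.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text(encoding="utf-8")
    if format == "auto":
        head = text.lstrip()[:40].upper()
        format = "emsa" if head.startswith("#FORMAT") else "delimited"
    if format == "emsa":
        energy, counts = _parse_emsa(text, path)
    elif format == "delimited":
        energy, counts = _parse_delimited(text, path)
    else:
        raise ValueError(f"unknown spectrum format {format!r}")
    if len(energy) < 2:
        raise ValueError(f"{path}: fewer than 2 data rows")
    return Spectrum(zone_id=path.stem, energy=np.array(energy), counts=np.array(counts))


def _parse_delimited(text: str, path: Path) -> tuple[list[float], list[float]]:
    energy: list[float] = []
    counts: list[float] = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = _split_row(line)
        if len(fields) < 2:
            raise ValueError(f"{path}: expected two columns, got {line!r}")
        if not (_NUM_RE.match(fields[0]) and _NUM_RE.match(fields[1])):
            if not energy:  # header row
                continue
            raise ValueError(f"{path}: unparseable row {line!r}")
        energy.append(float(fields[0]))
        counts.append(float(fields[1]))
    return energy, counts


def _parse_emsa(text: str, path: Path) -> tuple[list[float], list[float]]:
    """EMSA/MAS 1.0 keyword-header file, XY data mode only."""
    energy: list[float] = []
    counts: list[float] = []
    in_data = False
    datatype = "XY"
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            key, _, value = line[1:].partition(":")
            key = key.strip().upper()
            value = value.strip()
            if key == "DATATYPE":
                datatype = value.upper()
            elif key == "SPECTRUM":
                if datatype != "XY":
                    raise ValueError(f"{path}: only XY-mode EMSA files are supported")
                in_data = True
            elif key == "ENDOFDATA":
                in_data = False
            continue
        if in_data:
            fields = _split_row(line)
            if len(fields) < 2:
                raise ValueError(f"{path}: malformed EMSA data row {line!r}")
            energy.append(float(fields[0]))
            counts.append(float(fields[1]))
    return energy, counts


def write_spectrum(spectrum: Spectrum, path: str | Path) -> Path:
    """Write a delimited two-column spectrum file (round-trips exactly)."""
    path = Path(path)
    lines = [f"# zone_id: {spectrum.zone_id}", "energy_keV,counts"]
    lines += [f"{float(e)!r},{float(c)!r}" for e, c in zip(spectrum.energy, spectrum.counts)]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read and validate the zone manifest.

    Required columns: zone_id, specimen_id, site, clade, zone_type, session,
    mineralogy; an optional ``file`` column points at the spectrum files.
    ``zone_id`` identifies the physical zone (specimen + zone index) and is
    repeated across sessions for control specimens; (zone_id, session) pairs
    must be unique.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty manifest") from None
    return validate_manifest(df, name=str(path))


def validate_manifest(df: pd.DataFrame, name: str = "manifest") -> pd.DataFrame:
    if df.empty:
        raise ValueError(f"{name}: empty manifest")
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{name}: missing required column(s) {', '.join(missing)}")
    bad = set(df["zone_type"].unique()) - set(ZONE_TYPES)
    if bad:
        raise ValueError(f"{name}: unknown zone_type value(s) {sorted(bad)}")
    dup = df.duplicated(subset=["zone_id", "session"])
    if dup.any():
        pairs = df.loc[dup, ["zone_id", "session"]].to_records(index=False).tolist()
        raise ValueError(f"{name}: duplicate (zone_id, session) pairs {pairs[:5]}")
    return df.reset_index(drop=True)


@dataclass(frozen=True)
class EnergyCalibration:
    """Affine (optionally quadratic) channel -> keV calibration.

    ``energy = offset + gain * channel + quad * channel**2``.
    """

    gain: float
    offset: float
    quad: float = 0.0
    residuals: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ValueError("calibration gain must be positive")

    def apply(self, channels: np.ndarray) -> np.ndarray:
        ch = np.asarray(channels, dtype=float)
        return self.offset + self.gain * ch + self.quad * ch**2

    def apply_spectrum(self, raw: Spectrum) -> Spectrum:
        return Spectrum(raw.zone_id, self.apply(raw.energy), raw.counts)

    @property
    def max_residual(self) -> float:
        return float(np.max(np.abs(self.residuals))) if self.residuals.size else 0.0


def calibrate_energy(
    reference_lines: Sequence[tuple[float, float]], quadratic: bool = False
) -> EnergyCalibration:
    """Least-squares fit of the channel -> keV axis from reference peaks.

    ``reference_lines`` are (channel, energy_keV) pairs, e.g. the Ca, Fe and Y
    Ka1 peaks at 3.692, 6.405 and 14.958 keV.  At least 2 distinct channels
    are required; the quadratic term needs >= 3 pairs and ``quadratic=True``.
    """
    pairs = np.asarray(reference_lines, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2 or pairs.shape[0] < 2:
        raise ValueError("need at least 2 (channel, energy) reference pairs")
    ch, en = pairs[:, 0], pairs[:, 1]
    if np.unique(ch).size < ch.size:
        raise ValueError("coincident reference channels")
    degree = 2 if (quadratic and len(ch) >= 3) else 1
    design = np.vander(ch, degree + 1, increasing=True)
    coef, *_ = np.linalg.lstsq(design, en, rcond=None)
    resid = design @ coef - en
    quad = float(coef[2]) if degree == 2 else 0.0
    return EnergyCalibration(gain=float(coef[1]), offset=float(coef[0]), quad=quad, residuals=resid)


def reconstruct_continuous(spectrum: Spectrum) -> Callable[[np.ndarray], np.ndarray]:
    """Continuous spectrum: linear interpolation between the exported points.

    The returned evaluator is exact at the points and raises on queries
    outside the spectrum's support.
    """
    lo, hi = spectrum.support
    e, c = spectrum.energy, spectrum.counts

    def evaluate(energy):
        q = np.asarray(energy, dtype=float)
        if np.any(q < lo) or np.any(q > hi):
            raise ValueError(f"query outside spectrum support [{lo:g}, {hi:g}] keV")
        out = np.interp(q, e, c)
        return out if q.ndim else float(out)

    return evaluate


def subset_energy(spectrum: Spectrum, lo: float = GRID_LO, hi: float = GRID_HI) -> Spectrum:
    """Restrict a spectrum to [lo, hi] keV, synthesising exact endpoints.

    Every retained channel satisfies lo <= E <= hi; if no exported point falls
    exactly on a bound, a sample is interpolated there so all subset spectra
    share identical support.
    """
    slo, shi = spectrum.support
    if slo > lo or shi < hi:
        raise ValueError(
            f"spectrum support [{slo:g}, {shi:g}] keV does not cover [{lo:g}, {hi:g}] keV"
        )
    inside = (spectrum.energy >= lo) & (spectrum.energy <= hi)
    e = spectrum.energy[inside]
    c = spectrum.counts[inside]
    evaluate = reconstruct_continuous(spectrum)
    if e.size == 0 or e[0] > lo:
        e = np.concatenate(([lo], e))
        c = np.concatenate(([evaluate(lo)], c))
    if e[-1] < hi:
        e = np.concatenate((e, [hi]))
        c = np.concatenate((c, [evaluate(hi)]))
    return Spectrum(spectrum.zone_id, e, c)


def log_standardize(spectrum: Spectrum) -> Spectrum:
    """log10(counts + 1), then z-score with the population standard deviation.

    The +1 offset keeps zero-count channels defined while leaving large counts
    essentially untouched.  Output has mean 0 and population sd 1 over the
    spectrum's channels; a constant spectrum is rejected.
    """
    v = np.log10(spectrum.counts + 1.0)
    sd = float(np.std(v))  # population (divide-by-n) sd
    if np.ptp(v) == 0.0 or sd == 0.0 or not np.isfinite(sd):
        raise ValueError(f"degenerate spectrum {spectrum.zone_id}: zero variance")
    z = (v - v.mean()) / sd
    return _unchecked(spectrum.zone_id, spectrum.energy, z)


def _unchecked(zone_id: str, energy: np.ndarray, values: np.ndarray) -> Spectrum:
    """Build a Spectrum bypassing the counts >= 0 check (standardised values)."""
    obj = object.__new__(Spectrum)
    object.__setattr__(obj, "zone_id", zone_id)
    object.__setattr__(obj, "energy", np.asarray(energy, dtype=float))
    object.__setattr__(obj, "counts", np.asarray(values, dtype=float))
    return obj


def extract_landmarks(spectrum: Spectrum) -> np.ndarray:
    """Sample the (processed) continuous spectrum at the 831 grid energies."""
    lo, hi = spectrum.support
    if lo > GRID_LO or hi < GRID_HI:
        raise ValueError(
            f"spectrum support [{lo:g}, {hi:g}] keV insufficient for the landmark grid"
        )
    return np.interp(LANDMARK_GRID, spectrum.energy, spectrum.counts)


def landmark_vector(spectrum: Spectrum) -> np.ndarray:
    """Full formatting chain: subset -> log10 + standardise -> 831 landmarks."""
    return extract_landmarks(log_standardize(subset_energy(spectrum)))


@dataclass
class LandmarkMatrix:
    """Rows of landmark vectors with their zone metadata.

    ``values`` is (n_rows, 831); ``meta`` is the manifest slice describing
    each row (same order); ``aligned`` records whether session realignment has
    been applied.
    """

    values: np.ndarray
    meta: pd.DataFrame
    grid: np.ndarray = field(default_factory=lambda: LANDMARK_GRID.copy())
    aligned: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != self.grid.size:
            raise ValueError("landmark matrix shape does not match the grid")
        if len(self.meta) != self.values.shape[0]:
            raise ValueError("metadata row count does not match matrix row count")
        self.meta = self.meta.reset_index(drop=True)

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    def select(self, mask: np.ndarray) -> "LandmarkMatrix":
        mask = np.asarray(mask)
        return LandmarkMatrix(
            self.values[mask], self.meta.loc[mask].reset_index(drop=True), self.grid, self.aligned
        )

    def to_csv(self, values_path: str | Path, meta_path: str | Path | None = None) -> None:
        """Delimited export: first row = grid energies, one row per spectrum."""
        df = pd.DataFrame(self.values, columns=[f"{e:.2f}" for e in self.grid])
        df.insert(0, "zone_id", self.meta["zone_id"].to_numpy())
        df.insert(1, "session", self.meta["session"].to_numpy())
        df.to_csv(values_path, index=False)
        if meta_path is not None:
            self.meta.to_csv(meta_path, index=False)


def build_landmark_matrix(
    spectra: Iterable[Spectrum], meta: pd.DataFrame
) -> LandmarkMatrix:
    """Format spectra (in manifest row order) into a LandmarkMatrix."""
    rows = [landmark_vector(s) for s in spectra]
    if not rows:
        raise ValueError("no spectra supplied")
    return LandmarkMatrix(np.vstack(rows), meta)


def load_landmark_matrix(manifest: pd.DataFrame, spectra_dir: str | Path) -> LandmarkMatrix:
    """Read every spectrum file referenced by the manifest and landmark it."""
    if "file" not in manifest.columns:
        raise ValueError("manifest has no 'file' column; cannot locate spectrum files")
    spectra_dir = Path(spectra_dir)
    spectra = (read_spectrum(spectra_dir / f) for f in manifest["file"])
    return build_landmark_matrix(spectra, manifest)
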