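"""Spectral data model, file I/O and generic preprocessing.

A :class:`Spectrum` is one Raman measurement on a shared wavenumber axis,
carrying acquisition metadata (subject, digit/phalanx, position along the
bone, lateral collection offset, tissue kind).  A :class:`PairedDataset`
holds row-aligned predictor/response matrices: transcutaneous spectra
acquired at a 6-mm lateral offset (X) and exposed-bone spectra at a 3-mm
offset (Y), with subject labels for leakage-safe cross-validation.

Position codes follow the phalangeal convention: ``MM00`` is the midpoint,
``MPxx`` is xx mm proximal (negative signed position) and ``MDxx`` is xx mm
distal (positive).  Codes are case-insensitive.

Preprocessing here is deliberately generic: an iteratively-reweighted
polynomial baseline (fluorescence removal) and band normalization, which is
used for visualization only — modelling operates on unnormalized spectra.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from ._exceptions import (
    FormatError,
    MetadataError,
    NormalizationError,
    PairingError,
)

logger = logging.getLogger(__name__)

#: Default working axis: fingerprint region, 499 evenly spaced points.
DEFAULT_AXIS_RANGE = (800.0, 1800.0)
DEFAULT_AXIS_POINTS = 499

Dialect = Literal["long_csv", "wide_csv", "json"]

_POSITION_RE = re.compile(r"^(MM|MP|MD)(\d{2})$", re.IGNORECASE)


def parse_position(code: str) -> float:
    """Convert a position code (MM00/MPxx/MDxx) to signed millimetres.

    Proximal (MP) is negative, distal (MD) positive, MM00 is zero.
    """
    m = _POSITION_RE.match(code.strip())
    if m is None:
        raise MetadataError(f"unknown position code: {code!r}")
    kind, mm = m.group(1).upper(), int(m.group(2))
    if kind == "MM":
        if mm != 0:
            raise MetadataError(f"midpoint code must be MM00, got {code!r}")
        return 0.0
    return -float(mm) if kind == "MP" else float(mm)


def format_position(position_mm: float) -> str:
    """Render signed millimetres as a position code; zero is ``MM00``."""
    mm = int(round(abs(position_mm)))
    if mm == 0:
        return "MM00"
    return f"{'MP' if position_mm < 0 else 'MD'}{mm:02d}"


@dataclass(frozen=True)
class WavenumberAxis:
    """A strictly increasing Raman-shift axis in cm^-1."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size < 8:
            raise FormatError("axis must be 1-D with at least 8 points")
        if not np.all(np.diff(values) > 0):
            raise FormatError("axis must be strictly increasing")
        object.__setattr__(self, "values", values)
        self.values.setflags(write=False)

    def __len__(self) -> int:
        return self.values.size

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavenumberAxis):
            return NotImplemented
        return self.values.shape == other.values.shape and bool(
            np.array_equal(self.values, other.values)
        )

    def __hash__(self) -> int:
        return hash(self.values.tobytes())

    @classmethod
    def default(cls) -> "WavenumberAxis":
        lo, hi = DEFAULT_AXIS_RANGE
        return cls(np.linspace(lo, hi, DEFAULT_AXIS_POINTS))

    def window_mask(self, lo: float, hi: float) -> np.ndarray:
        return (self.values >= lo) & (self.values <= hi)


@dataclass(frozen=True)
class AcquisitionMeta:
    """Where and how one spectrum was acquired."""

    subject_id: str
    digit_phalanx: str = "D2P1"
    position_mm: float = 0.0
    offset_mm: int = 6
    tissue: Literal["transcutaneous", "exposed_bone"] = "transcutaneous"

    def __post_init__(self) -> None:
        if self.offset_mm not in (0, 3, 6):
            raise MetadataError(
                f"offset_mm must be one of 0, 3, 6; got {self.offset_mm}"
            )
        if self.tissue not in ("transcutaneous", "exposed_bone"):
            raise MetadataError(f"unknown tissue kind: {self.tissue!r}")

    @property
    def position_code(self) -> str:
        return format_position(self.position_mm)

    @property
    def site(self) -> tuple[str, float]:
        return (self.digit_phalanx, self.position_mm)


@dataclass(frozen=True)
class Spectrum:
    """One Raman spectrum: intensities on an axis plus acquisition metadata."""

    axis: WavenumberAxis
    intensities: np.ndarray
    meta: AcquisitionMeta

    def __post_init__(self) -> None:
        y = np.asarray(self.intensities, dtype=float)
        if y.shape != (len(self.axis),):
            raise FormatError(
                f"intensity length {y.shape} does not match axis length "
                f"{len(self.axis)}"
            )
        if not np.all(np.isfinite(y)):
            raise ValueError("spectrum contains non-finite intensities")
        object.__setattr__(self, "intensities", y)
        self.intensities.setflags(write=False)

    def with_intensities(self, y: np.ndarray) -> "Spectrum":
        return replace(self, intensities=np.asarray(y, dtype=float))


@dataclass
class PairedDataset:
    """Row-aligned transcutaneous (X) / exposed-bone (Y) matrices.

    Row i of X and row i of Y come from the same subject and the same
    anatomical site; ``subjects`` and ``sites`` carry the grouping needed
    for subject-wise cross-validation.
    """

    axis: WavenumberAxis
    X: np.ndarray
    Y: np.ndarray
    subjects: list[str]
    sites: list[tuple[str, float]]
    unmatched: list[AcquisitionMeta] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        n = self.X.shape[0]
        if self.Y.shape[0] != n or len(self.subjects) != n or len(self.sites) != n:
            raise FormatError("X, Y, subjects and sites must be row-aligned")
        if self.X.shape[1] != len(self.axis) or self.Y.shape[1] != len(self.axis):
            raise FormatError("matrix width must match axis length")

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]

    @property
    def subject_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.subjects:
            seen.setdefault(s)
        return list(seen)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_META_COLUMNS = ("subject_id", "digit_phalanx", "position", "offset_mm", "tissue")


def _meta_to_row(meta: AcquisitionMeta) -> dict:
    return {
        "subject_id": meta.subject_id,
        "digit_phalanx": meta.digit_phalanx,
        "position": meta.position_code,
        "offset_mm": meta.offset_mm,
        "tissue": meta.tissue,
    }


def _meta_from_row(row: dict) -> AcquisitionMeta:
    return AcquisitionMeta(
        subject_id=str(row["subject_id"]),
        digit_phalanx=str(row.get("digit_phalanx", "D2P1")),
        position_mm=parse_position(str(row.get("position", "MM00"))),
        offset_mm=int(row.get("offset_mm", 6)),
        tissue=str(row.get("tissue", "transcutaneous")),
    )


def write_spectra(
    spectra: Sequence[Spectrum], path: str | Path, dialect: Dialect = "wide_csv"
) -> None:
    """Write spectra to disk in one of the supported text dialects.

    wide_csv: one row per spectrum, metadata columns then one column per
    wavenumber.  long_csv: tidy (one row per point).  json: axis + records.
    """
    path = Path(path)
    if not spectra:
        raise FormatError("no spectra to write")
    axis = spectra[0].axis
    for s in spectra:
        if s.axis != axis:
            raise FormatError("all spectra must share one axis")

    if dialect == "wide_csv":
        rows = []
        for s in spectra:
            row = _meta_to_row(s.meta)
            row.update(
                {repr(float(w)): v for w, v in zip(axis.values, s.intensities)}
            )
            rows.append(row)
        pd.DataFrame(rows).to_csv(path, index=False)
    elif dialect == "long_csv":
        frames = []
        for i, s in enumerate(spectra):
            df = pd.DataFrame(
                {"spectrum_index": i, "wavenumber": axis.values,
                 "intensity": s.intensities}
            )
            for k, v in _meta_to_row(s.meta).items():
                df[k] = v
            frames.append(df)
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    elif dialect == "json":
        payload = {
            "wavenumber": axis.values.tolist(),
            "spectra": [
                {**_meta_to_row(s.meta), "intensity": s.intensities.tolist()}
                for s in spectra
            ],
        }
        path.write_text(json.dumps(payload))
    else:
        raise FormatError(f"unknown dialect: {dialect!r}")


def read_spectra(path: str | Path, dialect: Dialect = "wide_csv") -> list[Spectrum]:
    """Read spectra from a text file; every spectrum shares one axis.

    Raises :class:`FormatError` on axis-length mismatches and
    :class:`MetadataError` on unparseable position codes.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    if dialect == "wide_csv":
        df = pd.read_csv(path, float_precision="round_trip")
        meta_cols = [c for c in df.columns if c in _META_COLUMNS]
        wn_cols = [c for c in df.columns if c not in _META_COLUMNS]
        try:
            axis = WavenumberAxis(np.array([float(c) for c in wn_cols]))
        except ValueError as exc:
            raise FormatError(f"non-numeric wavenumber column: {exc}") from exc
        out = []
        for _, row in df.iterrows():
            meta = _meta_from_row({c: row[c] for c in meta_cols})
            out.append(Spectrum(axis, row[wn_cols].to_numpy(dtype=float), meta))
        return out

    if dialect == "long_csv":
        df = pd.read_csv(path, float_precision="round_trip")
        if "wavenumber" not in df.columns:
            raise FormatError("long CSV must declare a 'wavenumber' column")
        out = []
        axis: WavenumberAxis | None = None
        for _, grp in df.groupby("spectrum_index", sort=True):
            wn = grp["wavenumber"].to_numpy(dtype=float)
            if axis is None:
                axis = WavenumberAxis(wn)
            elif wn.shape != axis.values.shape or not np.array_equal(
                wn, axis.values
            ):
                raise FormatError("spectra do not share one wavenumber axis")
            meta = _meta_from_row(grp.iloc[0].to_dict())
            out.append(Spectrum(axis, grp["intensity"].to_numpy(dtype=float), meta))
        if not out:
            raise FormatError("empty long CSV")
        return out

    if dialect == "json":
        payload = json.loads(Path(path).read_text())
        axis = WavenumberAxis(np.asarray(payload["wavenumber"], dtype=float))
        out = []
        for rec in payload["spectra"]:
            y = np.asarray(rec["intensity"], dtype=float)
            if y.shape != (len(axis),):
                raise FormatError(
                    f"spectrum length {y.size} does not match axis {len(axis)}"
                )
            out.append(Spectrum(axis, y, _meta_from_row(rec)))
        return out

    raise FormatError(f"unknown dialect: {dialect!r}")


# ---------------------------------------------------------------------------
# Pairing
# ---------------------------------------------------------------------------

def pair_by_site(
    trans: Iterable[Spectrum],
    bone: Iterable[Spectrum],
    window: tuple[float, float] = (-5.0, 5.0),
) -> PairedDataset:
    """Pair transcutaneous and exposed-bone spectra by (subject, site).

    Only sites whose position falls inside ``window`` (signed mm around the
    phalangeal midpoint; the default is the stable MP05-MD05 region) are
    kept.  Rows are sorted canonically by (subject, digit_phalanx, position)
    so the result is independent of input ordering.  Unmatched spectra are
    reported on the result and logged.
    """
    trans = list(trans)
    bone = list(bone)
    if not trans or not bone:
        raise PairingError("both spectrum collections must be non-empty")
    axis = trans[0].axis
    for s in [*trans, *bone]:
        if s.axis != axis:
            raise FormatError("all spectra must share one axis")

    lo, hi = window

    def key(s: Spectrum) -> tuple[str, str, float]:
        return (s.meta.subject_id, s.meta.digit_phalanx, s.meta.position_mm)

    tmap = {key(s): s for s in trans}
    bmap = {key(s): s for s in bone}
    common = sorted(
        k for k in tmap.keys() & bmap.keys() if lo <= k[2] <= hi
    )
    if not common:
        raise PairingError(
            f"no (subject, site) pairs inside window [{lo}, {hi}] mm"
        )

    unmatched = [
        m.meta
        for k, m in {**tmap, **bmap}.items()
        if k not in set(common)
    ]
    for m in unmatched:
        logger.info(
            "unmatched spectrum: subject=%s site=%s/%s tissue=%s",
            m.subject_id, m.digit_phalanx, m.position_code, m.tissue,
        )

    X = np.vstack([tmap[k].intensities for k in common])
    Y = np.vstack([bmap[k].intensities for k in common])
    subjects = [k[0] for k in common]
    sites = [(k[1], k[2]) for k in common]
    return PairedDataset(axis, X, Y, subjects, sites, unmatched=unmatched)


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def subtract_baseline(
    s: Spectrum, degree: int = 5, n_iter: int = 20
) -> Spectrum:
    """Remove a smooth fluorescence background.

    Fits a polynomial of the given degree by iteratively reweighted least
    squares in which points above the current fit are clipped to it
    (modified polyfit of Lieber & Mahadevan-Jansen), so the fit hugs local
    minima and Raman peaks are left intact.  Idempotent within tolerance.
    """
    if degree < 0 or degree >= len(s.axis) / 10:
        raise ValueError(f"degree {degree} out of range for axis length {len(s.axis)}")
    if not np.all(np.isfinite(s.intensities)):
        raise ValueError("non-finite intensities")
    x = s.axis.values
    # centre/scale the abscissa for numerical conditioning
    xs = (x - x.mean()) / (np.ptp(x) / 2)
    target = s.intensities.astype(float).copy()
    fit = target
    for _ in range(n_iter):
        coeffs = np.polynomial.polynomial.polyfit(xs, target, degree)
        fit = np.polynomial.polynomial.polyval(xs, coeffs)
        target = np.minimum(target, fit)
    return s.with_intensities(s.intensities - fit)


def normalize_to_band(
    s: Spectrum, window: tuple[float, float]
) -> tuple[Spectrum, float]:
    """Scale a spectrum so its maximum inside the band window equals 1.

    Returns the scaled spectrum and the scale factor applied.  Used for
    visualization only (e.g. phosphate-band normalization of class-mean
    spectra); modelling operates on unnormalized intensities.
    """
    mask = s.axis.window_mask(*window)
    if not mask.any():
        raise NormalizationError(
            f"band window {window} does not intersect the axis"
        )
    peak = float(s.intensities[mask].max())
    if peak <= 0:
        raise NormalizationError(
            f"band maximum {peak} is not positive; cannot normalize"
        )
    return s.with_intensities(s.intensities / peak), 1.0 / peak
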