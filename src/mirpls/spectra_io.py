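"""Spectral data containers and I/O.

The central container is :class:`SpectrumSet`: a set of absorbance spectra
sharing one uniform, strictly increasing wavenumber grid.  Mid-IR
instruments commonly export grids in descending wavenumber order; readers
accept either direction and canonicalise to ascending, reversing the
absorbance columns consistently, so that downstream derivative filters have
an unambiguous sign.

Supported formats:

* CSV — header row required, wavenumber column named ``wavenumber_cm-1``,
  one additional column per sample ("columns" orientation) or the transpose
  ("rows" orientation).  Comma separator, ``.`` decimal.
* JCAMP-DX — single-spectrum ``##XYDATA=(X++(Y..Y))`` (AFFN numbers) and
  ``##XYPOINTS=(XY..XY)`` records, with XFACTOR/YFACTOR scaling and
  transmittance-to-absorbance conversion when YUNITS declares transmittance.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import (
    FormatError,
    GridError,
    IdentityError,
    RegionError,
    SpectraParseError,
    StateError,
)

WAVENUMBER_COLUMN = "wavenumber_cm-1"

#: Relative tolerance for the uniform-spacing invariant, required by
#: Savitzky-Golay derivative filters which assume equidistant abscissae.
_SPACING_RTOL = 1e-6


@dataclass(frozen=True)
class WavenumberGrid:
    """Uniform, strictly increasing wavenumber axis in cm^-1."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size < 2:
            raise GridError("grid needs at least two wavenumber points")
        diffs = np.diff(values)
        if not np.all(diffs > 0):
            raise GridError("grid must be strictly increasing")
        spacing = diffs[0]
        if not np.allclose(diffs, spacing, rtol=_SPACING_RTOL, atol=0.0):
            raise GridError(
                "grid spacing is not uniform (relative tolerance 1e-6); "
                f"spacings range {diffs.min():g}..{diffs.max():g} cm-1"
            )

    @classmethod
    def from_range(cls, low_cm: float, high_cm: float, spacing: float = 1.0) -> "WavenumberGrid":
        n = int(round((high_cm - low_cm) / spacing)) + 1
        return cls(low_cm + spacing * np.arange(n))

    @property
    def spacing(self) -> float:
        return float(self.values[1] - self.values[0])

    def __len__(self) -> int:
        return int(self.values.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavenumberGrid):
            return NotImplemented
        return self.values.shape == other.values.shape and np.allclose(
            self.values, other.values, rtol=1e-9, atol=0.0
        )


@dataclass
class SpectrumSet:
    """Absorbance matrix (samples x grid points) on a shared grid.

    ``replicate_of`` optionally maps a sample id to the parent sample it
    replicates; instruments typically record each standard in triplicate.
    """

    grid: WavenumberGrid
    absorbance: np.ndarray
    sample_ids: list[str]
    replicate_of: dict[str, str] | None = field(default=None)

    def __post_init__(self) -> None:
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        if self.absorbance.shape[1] != len(self.grid):
            raise GridError(
                f"absorbance has {self.absorbance.shape[1]} columns but grid has "
                f"{len(self.grid)} points"
            )
        if self.absorbance.shape[0] != len(self.sample_ids):
            raise IdentityError("one sample id required per spectrum")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = sorted({s for s in self.sample_ids if self.sample_ids.count(s) > 1})
            raise IdentityError(f"duplicate sample ids: {dupes}")
        if not np.all(np.isfinite(self.absorbance)):
            raise SpectraParseError("absorbance contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    def __len__(self) -> int:
        return self.n_samples


def _canonicalise(wavenumbers: np.ndarray, absorbance: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flip a descending grid (and its columns) to ascending."""
    if wavenumbers.size >= 2 and wavenumbers[0] > wavenumbers[-1]:
        return wavenumbers[::-1].copy(), absorbance[:, ::-1].copy()
    return wavenumbers, absorbance


def read_spectra_csv(path, orientation: str = "columns") -> SpectrumSet:
    """Read a spectra CSV.

    orientation="columns": first column is ``wavenumber_cm-1``, each further
    column one sample.  orientation="rows": the transpose (first row is the
    grid, each further row one sample).
    """
    if orientation not in ("columns", "rows"):
        raise ValueError(f"orientation must be 'columns' or 'rows', got {orientation!r}")
    if orientation == "columns":
        # pandas silently mangles duplicate headers; check the raw header row
        with open(path) as fh:
            header = [h.strip() for h in fh.readline().rstrip("\n").split(",")]
        if len(set(header)) != len(header):
            dupes = sorted({h for h in header if header.count(h) > 1})
            raise IdentityError(f"duplicate sample ids in {path}: {dupes}")
    df = pd.read_csv(path, header=0, index_col=None)
    if orientation == "rows":
        df = df.set_index(df.columns[0]).T.reset_index(names=WAVENUMBER_COLUMN)
    if WAVENUMBER_COLUMN not in df.columns:
        raise SpectraParseError(
            f"wavenumber column {WAVENUMBER_COLUMN!r} not found in {path} "
            f"(columns: {list(df.columns)[:5]}...)"
        )
    sample_ids = [str(c) for c in df.columns if c != WAVENUMBER_COLUMN]
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any() or df[col].isna().any():
            row = int(np.flatnonzero(coerced.isna().to_numpy())[0])
            raise SpectraParseError(
                f"non-numeric or missing cell at row {row}, column {col!r} in {path}"
            )
        df[col] = coerced
    wavenumbers = df[WAVENUMBER_COLUMN].to_numpy(dtype=float)
    absorbance = df[sample_ids].to_numpy(dtype=float).T
    wavenumbers, absorbance = _canonicalise(wavenumbers, absorbance)
    try:
        grid = WavenumberGrid(wavenumbers)
    except GridError as exc:
        raise GridError(f"{path}: {exc}") from exc
    return SpectrumSet(grid=grid, absorbance=absorbance, sample_ids=sample_ids)


def write_spectra_csv(sset: SpectrumSet, path, orientation: str = "columns") -> None:
    df = pd.DataFrame(
        {WAVENUMBER_COLUMN: sset.grid.values}
        | {sid: sset.absorbance[i] for i, sid in enumerate(sset.sample_ids)}
    )
    if orientation == "rows":
        df = df.set_index(WAVENUMBER_COLUMN).T.reset_index(names="sample_id")
    df.to_csv(path, index=False)


_JCAMP_LABEL = re.compile(r"^\s*##\s*([^=]+?)\s*=\s*(.*)\s*$")


def _jcamp_records(text: str) -> dict[str, str]:
    """Collect labelled-data-records; multi-line values are joined with newlines."""
    records: dict[str, str] = {}
    current: str | None = None
    for line in text.splitlines():
        line = line.split("$$")[0]  # strip comments
        m = _JCAMP_LABEL.match(line)
        if m:
            current = m.group(1).upper().replace(" ", "").replace("-", "").replace("_", "")
            records[current] = m.group(2)
        elif current is not None and line.strip():
            records[current] += "\n" + line.strip()
    return records


def read_jcampdx(path) -> SpectrumSet:
    """Read a single-spectrum JCAMP-DX file (AFFN XYDATA or XYPOINTS)."""
    with open(path) as fh:
        text = fh.read()
    records = _jcamp_records(text)
    if "END" not in records:
        raise FormatError(f"{path}: no ##END= record; file truncated?")

    xfactor = float(records.get("XFACTOR", 1.0))
    yfactor = float(records.get("YFACTOR", 1.0))

    if "XYDATA" in records:
        body = records["XYDATA"].split("\n")
        if not body or "X++" not in body[0].replace(" ", ""):
            raise FormatError(f"{path}: only (X++(Y..Y)) XYDATA tables are supported")
        step = _xydata_step(records)
        xs: list[float] = []
        ys: list[float] = []
        for line in body[1:]:
            nums = [float(tok) for tok in re.split(r"[,\s]+", line.strip()) if tok]
            if len(nums) < 2:
                raise FormatError(f"{path}: XYDATA line with fewer than two numbers")
            x0 = nums[0] * xfactor  # line abscissa belongs to the first y
            yvals = [v * yfactor for v in nums[1:]]
            xs.extend(x0 + i * step for i in range(len(yvals)))
            ys.extend(yvals)
        wavenumbers = np.asarray(xs)
        intensity = np.asarray(ys)
    elif "XYPOINTS" in records:
        body = records["XYPOINTS"].split("\n")[1:]
        pairs = [float(tok) for line in body for tok in re.split(r"[,;\s]+", line.strip()) if tok]
        if len(pairs) < 4 or len(pairs) % 2:
            raise FormatError(f"{path}: malformed XYPOINTS table")
        arr = np.asarray(pairs).reshape(-1, 2)
        wavenumbers = arr[:, 0] * xfactor
        intensity = arr[:, 1] * yfactor
    else:
        raise FormatError(f"{path}: no ##XYDATA= or ##XYPOINTS= record")

    yunits = records.get("YUNITS", "ABSORBANCE").upper()
    if "TRANSMITTANCE" in yunits:
        if yunits.startswith("%") or "PERCENT" in yunits:
            intensity = intensity / 100.0
        if np.any(intensity <= 0):
            raise FormatError(f"{path}: non-positive transmittance cannot be converted")
        intensity = -np.log10(intensity)

    title = records.get("TITLE", "spectrum") or "spectrum"
    absorbance = intensity[np.newaxis, :]
    wavenumbers, absorbance = _canonicalise(wavenumbers, absorbance)
    return SpectrumSet(
        grid=WavenumberGrid(wavenumbers), absorbance=absorbance, sample_ids=[title]
    )


def _xydata_step(records: dict[str, str]) -> float:
    """Abscissa increment in actual X units (DELTAX, or from FIRSTX/LASTX)."""
    if "DELTAX" in records:
        return float(records["DELTAX"])
    try:
        first = float(records["FIRSTX"])
        last = float(records["LASTX"])
        npoints = int(float(records["NPOINTS"]))
    except KeyError as exc:
        raise FormatError(f"XYDATA without DELTAX or FIRSTX/LASTX/NPOINTS: {exc}") from exc
    if npoints < 2:
        raise FormatError("XYDATA with NPOINTS < 2")
    return (last - first) / (npoints - 1)


def select_region(sset: SpectrumSet, low_cm: float, high_cm: float) -> SpectrumSet:
    """Restrict to the inclusive wavenumber window [low_cm, high_cm]."""
    if low_cm >= high_cm:
        raise RegionError(f"low_cm ({low_cm}) must be below high_cm ({high_cm})")
    mask = (sset.grid.values >= low_cm) & (sset.grid.values <= high_cm)
    if not mask.any():
        raise RegionError(
            f"region {low_cm}-{high_cm} cm-1 does not intersect grid "
            f"{sset.grid.values[0]:g}-{sset.grid.values[-1]:g} cm-1"
        )
    return SpectrumSet(
        grid=WavenumberGrid(sset.grid.values[mask]),
        absorbance=sset.absorbance[:, mask],
        sample_ids=list(sset.sample_ids),
        replicate_of=dict(sset.replicate_of) if sset.replicate_of else None,
    )


def average_replicates(sset: SpectrumSet) -> SpectrumSet:
    """Collapse replicate spectra to their pointwise mean, one per parent.

    Samples absent from ``replicate_of`` are their own parent (singletons
    pass through unchanged).  Parent order follows first appearance.
    """
    if sset.replicate_of is None:
        raise StateError("average_replicates requires a replicate_of mapping")
    parents: list[str] = []
    groups: dict[str, list[int]] = {}
    for i, sid in enumerate(sset.sample_ids):
        parent = sset.replicate_of.get(sid, sid)
        if parent not in groups:
            parents.append(parent)
            groups[parent] = []
        groups[parent].append(i)
    averaged = np.vstack([sset.absorbance[groups[p]].mean(axis=0) for p in parents])
    return SpectrumSet(grid=sset.grid, absorbance=averaged, sample_ids=parents)
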