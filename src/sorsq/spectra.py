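"""Spectral data model and plain-text readers/writers.

All downstream stages (simulation, scaled subtraction, chemometrics) operate on
:class:`Spectrum` objects that share a single uniform wavenumber grid, bundled
into a :class:`SpectralDataset` of matched traditional/offset acquisition
pairs.  Datasets serialize to a pair of CSV tables:

* spectra table: a ``wavenumber_cm-1`` column plus one intensity column per
  acquisition, named ``<sample_id>__<acquisition>``;
* metadata table: one row per sample with container, origin, and (when known)
  the ground-truth formulation in % v/v.

Floats are serialized with :func:`repr`-style shortest round-trip formatting,
so a write → read → write cycle is byte-identical.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional

import numpy as np

ACQUISITIONS = ("traditional", "offset", "scaled_subtracted")
ORIGINS = ("training", "test_house", "test_commercial")

#: Components a formulation may contain, in canonical column order.
COMPONENTS = ("ethanol", "methanol", "propan2ol", "propan1ol", "glycerin", "h2o2")
#: The four alcohols quantified by the regression models.
ALCOHOLS = ("ethanol", "methanol", "propan2ol", "propan1ol")
#: Alcohols approved as hand-sanitizer active ingredients.
APPROVED = ("ethanol", "propan2ol")
#: Toxic contaminant/adulterant alcohols.
CONTAMINANTS = ("methanol", "propan1ol")

WAVENUMBER_COLUMN = "wavenumber_cm-1"


class DatasetError(ValueError):
    """Raised for malformed spectral datasets or tables."""


@dataclass(frozen=True)
class WavenumberGrid:
    """Uniform Raman-shift grid in cm^-1, strictly increasing.

    The default 200-1800 cm^-1 span matches the spectral range of portable
    spatially offset Raman instruments used for through-container screening.
    """

    start: float = 200.0
    stop: float = 1800.0
    n_points: int = 1601

    def __post_init__(self) -> None:
        if not (np.isfinite(self.start) and np.isfinite(self.stop)):
            raise ValueError("grid endpoints must be finite")
        if self.stop <= self.start:
            raise ValueError("grid must be strictly increasing (stop > start)")
        if self.n_points < 2:
            raise ValueError("grid needs at least 2 points")

    @property
    def values(self) -> np.ndarray:
        return np.linspace(self.start, self.stop, self.n_points)

    @property
    def spacing(self) -> float:
        return (self.stop - self.start) / (self.n_points - 1)

    def __len__(self) -> int:
        return self.n_points

    @classmethod
    def from_spacing(cls, start: float, stop: float, spacing: float) -> "WavenumberGrid":
        n = int(round((stop - start) / spacing)) + 1
        return cls(start=start, stop=stop, n_points=n)

    @classmethod
    def from_values(cls, values: np.ndarray, rtol: float = 1e-6) -> "WavenumberGrid":
        """Build a grid from an array, verifying uniform spacing."""
        values = np.asarray(values, dtype=float)
        if values.ndim != 1 or values.size < 2:
            raise DatasetError("wavenumber axis must be a 1-D array of >= 2 values")
        steps = np.diff(values)
        if np.any(steps <= 0):
            raise DatasetError("wavenumber axis must be strictly increasing")
        mean = steps.mean()
        if np.max(np.abs(steps - mean)) > rtol * abs(mean):
            raise DatasetError(
                "non-uniform wavenumber grid; resample spectra onto a uniform "
                "grid first (see resample_to_grid)"
            )
        return cls(start=float(values[0]), stop=float(values[-1]), n_points=values.size)


@dataclass
class Spectrum:
    """One acquisition: intensities (arbitrary counts) on a shared grid."""

    grid: WavenumberGrid
    intensities: np.ndarray
    acquisition: str = "traditional"
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 1 or self.intensities.size != len(self.grid):
            raise ValueError(
                f"intensities length {self.intensities.size} does not match "
                f"grid length {len(self.grid)}"
            )
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")
        if self.acquisition not in ACQUISITIONS:
            raise ValueError(f"acquisition must be one of {ACQUISITIONS}")

    def with_intensities(self, intensities: np.ndarray, acquisition: Optional[str] = None) -> "Spectrum":
        return Spectrum(
            grid=self.grid,
            intensities=np.asarray(intensities, dtype=float),
            acquisition=acquisition or self.acquisition,
            sample_id=self.sample_id,
        )


@dataclass
class SpectrumPair:
    """Matched zero-offset (traditional) and offset acquisitions of one sample."""

    traditional: Spectrum
    offset: Spectrum

    def __post_init__(self) -> None:
        if self.traditional.grid != self.offset.grid:
            raise ValueError("pair members must share one wavenumber grid")
        if self.traditional.acquisition != "traditional":
            raise ValueError("first member must be a traditional acquisition")
        if self.offset.acquisition != "offset":
            raise ValueError("second member must be an offset acquisition")

    @property
    def sample_id(self) -> str:
        return self.traditional.sample_id

    @property
    def grid(self) -> WavenumberGrid:
        return self.traditional.grid


@dataclass(frozen=True)
class Formulation:
    """Ground-truth composition in % v/v; water is the unstated remainder."""

    fractions: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.fractions) - set(COMPONENTS)
        if unknown:
            raise ValueError(f"unknown components {sorted(unknown)}; known: {COMPONENTS}")
        vals = np.array([float(self.fractions.get(c, 0.0)) for c in COMPONENTS])
        if np.any(vals < 0):
            raise ValueError("fractions must be non-negative")
        if vals.sum() > 100.0 + 1e-9:
            raise ValueError(f"fractions sum to {vals.sum():.3f} > 100% v/v")
        object.__setattr__(self, "fractions", {c: float(self.fractions.get(c, 0.0)) for c in COMPONENTS})

    def __getitem__(self, component: str) -> float:
        return self.fractions[component]

    @property
    def total_alcohol(self) -> float:
        return sum(self.fractions[a] for a in ALCOHOLS)

    @property
    def total_approved(self) -> float:
        return sum(self.fractions[a] for a in APPROVED)

    @property
    def water(self) -> float:
        return 100.0 - sum(self.fractions.values())

    def alcohol_vector(self) -> np.ndarray:
        return np.array([self.fractions[a] for a in ALCOHOLS])

    @classmethod
    def make(cls, **fractions: float) -> "Formulation":
        return cls(fractions=fractions)


#: WHO-style reference bases used throughout: 80% v/v ethanol or 75% v/v
#: 2-propanol with 1.45% v/v glycerin and 0.145% v/v hydrogen peroxide.
GLYCERIN_VV = 1.45
H2O2_VV = 0.145


def who_base(alcohol: str, amount: Optional[float] = None) -> Formulation:
    """Reference formulation: the given alcohol plus glycerin/H2O2 excipients."""
    if amount is None:
        amount = 80.0 if alcohol in ("ethanol", "methanol") else 75.0
    return Formulation.make(**{alcohol: amount, "glycerin": GLYCERIN_VV, "h2o2": H2O2_VV})


@dataclass
class SampleRecord:
    """Metadata for one measured sample."""

    sample_id: str
    formulation: Optional[Formulation]
    container_id: str
    origin: str = "training"
    true_label: Optional[str] = None  # fair | subpotent | contaminated, when known

    def __post_init__(self) -> None:
        if self.origin not in ORIGINS:
            raise ValueError(f"origin must be one of {ORIGINS}")


@dataclass
class SpectralDataset:
    """All spectra of a cohort on one shared grid plus per-sample metadata."""

    grid: WavenumberGrid
    records: List[SampleRecord]
    pairs: Dict[str, SpectrumPair]

    def __post_init__(self) -> None:
        ids = [r.sample_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise DatasetError(f"duplicate sample_ids: {dupes}")
        for r in self.records:
            pair = self.pairs.get(r.sample_id)
            if pair is None:
                raise DatasetError(f"sample {r.sample_id!r} has no spectra")
            if pair.grid != self.grid:
                raise DatasetError(f"sample {r.sample_id!r} is not on the dataset grid")
        extra = set(self.pairs) - set(ids)
        if extra:
            raise DatasetError(f"spectra without metadata: {sorted(extra)}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def sample_ids(self) -> List[str]:
        return [r.sample_id for r in self.records]

    def record(self, sample_id: str) -> SampleRecord:
        for r in self.records:
            if r.sample_id == sample_id:
                return r
        raise KeyError(sample_id)

    def subset(self, sample_ids: Iterable[str]) -> "SpectralDataset":
        keep = list(sample_ids)
        keep_set = set(keep)
        records = [r for r in self.records if r.sample_id in keep_set]
        pairs = {r.sample_id: self.pairs[r.sample_id] for r in records}
        return SpectralDataset(grid=self.grid, records=records, pairs=pairs)


# ---------------------------------------------------------------------------
# resampling


def resample_to_grid(s: Spectrum, g: WavenumberGrid) -> Spectrum:
    """Linear interpolation of a spectrum onto grid ``g``.

    ``g`` must lie inside the support of ``s.grid``; extrapolation is refused.
    """
    lo, hi = s.grid.start, s.grid.stop
    eps = 1e-9 * max(abs(lo), abs(hi), 1.0)
    if g.start < lo - eps or g.stop > hi + eps:
        raise ValueError(
            f"target grid [{g.start}, {g.stop}] extends beyond source support "
            f"[{lo}, {hi}]; extrapolation is not supported"
        )
    if g == s.grid:
        return replace(s)
    new = np.interp(g.values, s.grid.values, s.intensities)
    return Spectrum(grid=g, intensities=new, acquisition=s.acquisition, sample_id=s.sample_id)


# ---------------------------------------------------------------------------
# CSV serialization


def _fmt(x: float) -> str:
    """Shortest decimal string that round-trips to the same float (>= 9 sig digits
    whenever needed)."""
    return repr(float(x))


_UNKNOWN = "unknown"


def write_dataset(ds: SpectralDataset, spectra_path, metadata_path) -> None:
    """Write a dataset as the two CSV tables understood by :func:`read_dataset`."""
    # spectra table
    columns: List[str] = []
    arrays: List[np.ndarray] = []
    for r in ds.records:
        pair = ds.pairs[r.sample_id]
        if "__" in r.sample_id:
            raise DatasetError(f"sample_id {r.sample_id!r} must not contain '__'")
        for spec in (pair.traditional, pair.offset):
            columns.append(f"{r.sample_id}__{spec.acquisition}")
            arrays.append(spec.intensities)
    wn = ds.grid.values
    with open(spectra_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow([WAVENUMBER_COLUMN, *columns])
        for i in range(len(ds.grid)):
            w.writerow([_fmt(wn[i]), *(_fmt(a[i]) for a in arrays)])

    # metadata table
    meta_cols = ["sample_id", "container_id", "origin", *COMPONENTS, "true_label"]
    with open(metadata_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(meta_cols)
        for r in ds.records:
            if r.formulation is None:
                comp = [_UNKNOWN] * len(COMPONENTS)
            else:
                comp = [_fmt(r.formulation[c]) for c in COMPONENTS]
            w.writerow([r.sample_id, r.container_id, r.origin, *comp, r.true_label or ""])


def read_dataset(spectra_path, metadata_path) -> SpectralDataset:
    """Read and validate the CSV pair written by :func:`write_dataset`."""
    with open(spectra_path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        rows = list(reader)
    if not header or header[0] != WAVENUMBER_COLUMN:
        raise DatasetError(f"first spectra column must be {WAVENUMBER_COLUMN!r}")
    data = np.array([[float(x) for x in row] for row in rows], dtype=float) if rows else np.empty((0, len(header)))
    if rows:
        grid = WavenumberGrid.from_values(data[:, 0])
    else:
        grid = WavenumberGrid()

    spectra: Dict[str, Dict[str, Spectrum]] = {}
    for j, col in enumerate(header[1:], start=1):
        if "__" not in col:
            raise DatasetError(f"intensity column {col!r} is not named <sample_id>__<acquisition>")
        sid, acq = col.rsplit("__", 1)
        if acq not in ("traditional", "offset"):
            raise DatasetError(f"column {col!r}: acquisition must be traditional or offset")
        spectra.setdefault(sid, {})[acq] = Spectrum(
            grid=grid, intensities=data[:, j] if rows else np.zeros(len(grid)),
            acquisition=acq, sample_id=sid,
        )

    with open(metadata_path, newline="") as fh:
        mreader = csv.DictReader(fh)
        meta_rows = list(mreader)

    records: List[SampleRecord] = []
    pairs: Dict[str, SpectrumPair] = {}
    for row in meta_rows:
        sid = row["sample_id"]
        acqs = spectra.get(sid, {})
        missing = [a for a in ("traditional", "offset") if a not in acqs]
        if missing:
            raise DatasetError(f"sample {sid!r} is missing {' and '.join(missing)} spectra")
        comp_vals = [row.get(c, "") for c in COMPONENTS]
        if any(v.strip().lower() == _UNKNOWN for v in comp_vals):
            formulation = None
        else:
            formulation = Formulation(fractions={c: float(v) for c, v in zip(COMPONENTS, comp_vals)})
        records.append(SampleRecord(
            sample_id=sid,
            formulation=formulation,
            container_id=row.get("container_id", ""),
            origin=row.get("origin", "training"),
            true_label=(row.get("true_label") or None),
        ))
        pairs[sid] = SpectrumPair(traditional=acqs["traditional"], offset=acqs["offset"])

    unmatched = set(spectra) - {r.sample_id for r in records}
    if unmatched:
        raise DatasetError(f"spectra columns without metadata rows: {sorted(unmatched)}")
    return SpectralDataset(grid=grid, records=records, pairs=pairs)
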