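"""Domain types and delimited-text I/O for worm tracks and plate assays.

Internal units are fixed: millimetres for positions, seconds for time.
Coordinates are plate-centric Cartesian with the origin at the plate
centre and the x-axis along the control/odorant (A-B) axis.  Tracking
gaps are represented in-band as frames with ``valid=False`` rather than
by splitting a track, so per-animal quantities aggregate over one
logical trajectory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict, fields as dc_fields
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, FormatError

logger = logging.getLogger("wormassay")

#: Odorant vocabulary: 2,4,5-trimethylthiazole, 2-butanone, isoamyl
#: alcohol, benzaldehyde, pyrazine, diacetyl, and the ethanol-only
#: (no-odorant) control.
ODORANTS = ("TT", "BT", "IA", "BZ", "PZ", "DC", "ET")

SPECIES_LABELS = ("elegans", "inopinata", "synthetic")
STAGE_LABELS = ("adult", "L3")
CONDITION_LABELS = ("odorant", "control")

_UNIT_TO_MM = {"mm": 1.0, "cm": 10.0, "um": 1e-3, "µm": 1e-3}


@dataclass(frozen=True)
class FrameSample:
    """One time point of one animal.

    ``valid=False`` marks a tracking gap; downstream computations ignore
    the positions of invalid frames entirely.
    """

    time: float
    centroid: tuple[float, float]
    head: tuple[float, float]
    valid: bool = True


@dataclass
class Track:
    """Ordered trajectory of one animal (centroid and head tip).

    Positions are stored as ``(n, 2)`` arrays in millimetres; ``times``
    in seconds, strictly increasing.  ``meta`` may carry generator
    ground truth for synthetic tracks; analysis code never reads it.
    """

    animal_id: str
    times: np.ndarray
    centroid: np.ndarray
    head: np.ndarray
    valid: np.ndarray
    species: str = "synthetic"
    stage: str = "adult"
    condition: str = "control"
    nominal_dt: float = 0.1
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.centroid = np.asarray(self.centroid, dtype=float).reshape(-1, 2)
        self.head = np.asarray(self.head, dtype=float).reshape(-1, 2)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = len(self.times)
        if not (len(self.centroid) == len(self.head) == len(self.valid) == n):
            raise DataError(
                f"track {self.animal_id!r}: field lengths disagree "
                f"(times={n}, centroid={len(self.centroid)}, "
                f"head={len(self.head)}, valid={len(self.valid)})"
            )
        if n >= 2:
            dts = np.diff(self.times)
            bad = np.nonzero(dts <= 0)[0]
            if bad.size:
                raise DataError(
                    f"track {self.animal_id!r}: time not strictly increasing "
                    f"at row {bad[0] + 1} (t={self.times[bad[0] + 1]!r})"
                )
        if not self.nominal_dt > 0:
            raise DataError(f"track {self.animal_id!r}: nominal_dt must be > 0")
        if n >= 2:
            med = float(np.median(np.diff(self.times)))
            if abs(med - self.nominal_dt) > 0.1 * self.nominal_dt:
                raise DataError(
                    f"track {self.animal_id!r}: median inter-frame interval "
                    f"{med:.6g}s deviates >10% from nominal_dt "
                    f"{self.nominal_dt:.6g}s"
                )

    def __len__(self) -> int:
        return len(self.times)

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    @property
    def frames(self) -> list[FrameSample]:
        return [
            FrameSample(
                time=float(t),
                centroid=(float(c[0]), float(c[1])),
                head=(float(h[0]), float(h[1])),
                valid=bool(v),
            )
            for t, c, h, v in zip(self.times, self.centroid, self.head, self.valid)
        ]


@dataclass
class PlateAssay:
    """Endpoint counts of one chemotaxis plate.

    Counts are reported odorant-anchored: ``count_odorant`` is always the
    odorant zone (B) regardless of which physical side held the odorant.
    """

    plate_id: str
    species: str
    stage: str
    odorant: str
    dilution: str
    odorant_side: str
    count_control: int
    count_odorant: int
    count_central: int

    def __post_init__(self) -> None:
        for name in ("count_control", "count_odorant", "count_central"):
            v = getattr(self, name)
            if int(v) != v or int(v) < 0:
                raise DataError(
                    f"plate {self.plate_id!r}: {name}={v!r} must be a "
                    "non-negative integer"
                )
            setattr(self, name, int(v))
        if self.odorant not in ODORANTS:
            raise DataError(
                f"plate {self.plate_id!r}: unknown odorant "
                f"{self.odorant!r}; allowed: {', '.join(ODORANTS)}"
            )
        if self.odorant_side not in ("left", "right"):
            raise DataError(
                f"plate {self.plate_id!r}: odorant_side must be 'left' or "
                f"'right', got {self.odorant_side!r}"
            )

    @property
    def n_scored(self) -> int:
        return self.count_control + self.count_odorant


@dataclass(frozen=True)
class PlateGeometry:
    """Two-point assay plate geometry.

    The plate is split by a midline perpendicular to the A-B axis; a
    central band of half-width ``central_band_halfwidth`` (1-cm total
    width by default) is excluded from scoring.
    """

    diameter: float = 50.0
    central_band_halfwidth: float = 5.0

    def __post_init__(self) -> None:
        if not 2 * self.central_band_halfwidth < self.diameter:
            raise DataError(
                "central band must be narrower than the plate: "
                f"2*{self.central_band_halfwidth} >= {self.diameter}"
            )

    @property
    def radius(self) -> float:
        return self.diameter / 2.0


@dataclass(frozen=True)
class TrackDialect:
    """Column mapping for a tracker export.

    The defaults are the package's reference dialect.  ``time`` names a
    column of seconds; alternatively set ``frame`` (an integer frame
    index) together with ``dt``.  ``unit`` declares the position unit of
    the file (mm, cm or um); positions are converted to millimetres on
    read.
    """

    track_id: str = "track_id"
    time: str | None = "time_s"
    frame: str | None = None
    centroid_x: str = "centroid_x_mm"
    centroid_y: str = "centroid_y_mm"
    head_x: str = "head_x_mm"
    head_y: str = "head_y_mm"
    unit: str = "mm"
    dt: float | None = None
    species: str = "synthetic"
    stage: str = "adult"
    condition: str = "control"

    def position_scale(self) -> float:
        try:
            return _UNIT_TO_MM[self.unit]
        except KeyError:
            raise FormatError(
                f"unknown position unit {self.unit!r}; use mm, cm or um"
            ) from None


#: The WormLab-like reference dialect.
REFERENCE_DIALECT = TrackDialect()


def read_tracks(path: str | Path, dialect: TrackDialect = REFERENCE_DIALECT) -> list[Track]:
    """Read a delimited track table into a list of :class:`Track`.

    CSV/TSV is autodetected.  Rows with any missing coordinate become
    ``valid=False`` frames.  Times must be strictly increasing within a
    track; a violation raises :class:`DataError` citing the row.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    needed = [dialect.track_id, dialect.centroid_x, dialect.centroid_y,
              dialect.head_x, dialect.head_y]
    if dialect.time is not None:
        needed.append(dialect.time)
    elif dialect.frame is not None:
        if dialect.dt is None:
            raise FormatError("dialect uses a frame column but declares no dt")
        needed.append(dialect.frame)
    else:
        raise FormatError("dialect must name either a time or a frame column")
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: missing required column(s) {missing}; found {list(df.columns)}"
        )

    scale = dialect.position_scale()
    tracks: list[Track] = []
    for tid, sub in df.groupby(dialect.track_id, sort=True):
        if dialect.time is not None:
            times = sub[dialect.time].to_numpy(dtype=float)
        else:
            times = sub[dialect.frame].to_numpy(dtype=float) * dialect.dt
        pos = sub[[dialect.centroid_x, dialect.centroid_y,
                   dialect.head_x, dialect.head_y]].to_numpy(dtype=float) * scale
        valid = ~np.isnan(pos).any(axis=1)
        if len(times) >= 2:
            bad = np.nonzero(np.diff(times) <= 0)[0]
            if bad.size:
                row = sub.index[bad[0] + 1]
                raise DataError(
                    f"{path}: track {tid!r} time not strictly increasing at "
                    f"input row {row}"
                )
            nominal_dt = dialect.dt or float(np.median(np.diff(times)))
        else:
            nominal_dt = dialect.dt or 0.1
        tracks.append(Track(
            animal_id=str(tid),
            times=times,
            centroid=pos[:, 0:2],
            head=pos[:, 2:4],
            valid=valid,
            species=dialect.species,
            stage=dialect.stage,
            condition=dialect.condition,
            nominal_dt=nominal_dt,
        ))
    logger.info("read %d track(s) from %s", len(tracks), path)
    return tracks


_PLATE_COLUMNS = ["plate_id", "species", "stage", "odorant", "dilution",
                  "odorant_side", "count_control", "count_odorant",
                  "count_central"]


def read_plate_counts(path: str | Path) -> list[PlateAssay]:
    """Read a plate-count table (one row per plate) into typed records."""
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in _PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    assays = []
    for _, row in df.iterrows():
        assays.append(PlateAssay(
            plate_id=str(row["plate_id"]),
            species=str(row["species"]),
            stage=str(row["stage"]),
            odorant=str(row["odorant"]),
            dilution=str(row["dilution"]),
            odorant_side=str(row["odorant_side"]),
            count_control=row["count_control"],
            count_odorant=row["count_odorant"],
            count_central=row["count_central"],
        ))
    logger.info("read %d plate(s) from %s", len(assays), path)
    return assays


def write_results(records: Sequence, path: str | Path,
                  columns: Iterable[str] | None = None) -> None:
    """Write homogeneous result rows (dataclasses, dicts, or a DataFrame)
    as CSV with a header and 6-significant-digit floats."""
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        rows = []
        for r in records:
            if hasattr(r, "__dataclass_fields__"):
                rows.append(asdict(r))
            else:
                rows.append(dict(r))
        if rows:
            df = pd.DataFrame(rows)
        else:
            df = pd.DataFrame(columns=list(columns) if columns else [])
    df.to_csv(path, index=False, float_format="%.6g")
    logger.info("wrote %d row(s) to %s", len(df), path)


def plate_assays_to_frame(assays: Sequence[PlateAssay]) -> pd.DataFrame:
    """Tabulate plate assays with stable column order."""
    return pd.DataFrame([asdict(a) for a in assays],
                        columns=[f.name for f in dc_fields(PlateAssay)])
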