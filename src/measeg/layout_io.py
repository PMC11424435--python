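"""Data model and I/O for electrode layouts, spike trains and raw recordings.

Layouts are planar: each electrode has an id, a position in micrometres and
an optional compartment label (``C1``..``C4`` for the four sub-populations,
``unassigned`` for electrodes under the separating mask or outside any
compartment).  Only pairwise distances are consumed downstream, so the
coordinate origin is arbitrary.

Spike times are stored in seconds as 64-bit floats; distances are kept in
micrometres here and converted to millimetres only where a formula demands
it (clustering coefficient, propagation-speed filter).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import h5py
import numpy as np
import pandas as pd

logger = logging.getLogger("measeg")

UNASSIGNED = "unassigned"

__all__ = [
    "UNASSIGNED",
    "ElectrodeLayout",
    "SpikeTrains",
    "RawRecording",
    "grid_layout",
    "read_layout",
    "write_layout",
    "read_spike_trains",
    "write_spike_trains",
    "read_raw_recording",
    "write_raw_recording",
]


# ---------------------------------------------------------------------------
# Electrode layout
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ElectrodeLayout:
    """Electrode ids, planar positions (um) and compartment labels.

    Parameters
    ----------
    ids
        Unique electrode identifiers, one per electrode.
    positions_um
        ``(n, 2)`` array of x/y coordinates in micrometres.
    compartments
        One label per electrode; ``"unassigned"`` marks electrodes that do
        not belong to any compartment (e.g. under the mask arms).
    pitch_um
        Informative inter-electrode pitch; not used in computations.
    """

    ids: tuple[str, ...]
    positions_um: np.ndarray
    compartments: tuple[str, ...]
    pitch_um: float | None = None

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions_um, dtype=float)
        object.__setattr__(self, "positions_um", pos)
        if len(self.ids) != len(set(self.ids)):
            raise ValueError("duplicate electrode ids in layout")
        if pos.ndim != 2 or pos.shape != (len(self.ids), 2):
            raise ValueError("positions_um must be (n_electrodes, 2)")
        if not np.all(np.isfinite(pos)):
            raise ValueError("non-finite electrode coordinates")
        if len(self.compartments) != len(self.ids):
            raise ValueError("one compartment label per electrode required")
        d = self.distance_matrix_um()
        n = len(self.ids)
        if n > 1:
            off = d[~np.eye(n, dtype=bool)]
            if np.any(off <= 0):
                raise ValueError("two electrodes share identical coordinates")

    @property
    def n_electrodes(self) -> int:
        return len(self.ids)

    @property
    def compartment_names(self) -> tuple[str, ...]:
        """Sorted distinct compartment labels, excluding unassigned."""
        return tuple(sorted({c for c in self.compartments if c != UNASSIGNED}))

    def electrodes_in(self, compartment: str) -> tuple[str, ...]:
        return tuple(
            e for e, c in zip(self.ids, self.compartments) if c == compartment
        )

    def compartment_of(self, electrode_id: str) -> str:
        try:
            return self.compartments[self.ids.index(electrode_id)]
        except ValueError:
            raise KeyError(f"unknown electrode id {electrode_id!r}") from None

    def distance_matrix_um(self) -> np.ndarray:
        """Symmetric pairwise Euclidean distance matrix in micrometres."""
        diff = self.positions_um[:, None, :] - self.positions_um[None, :, :]
        return np.sqrt((diff ** 2).sum(axis=-1))

    def distance_matrix_mm(self) -> np.ndarray:
        return self.distance_matrix_um() / 1000.0

    def compartment_centroids_um(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for c in self.compartment_names:
            sel = [i for i, lab in enumerate(self.compartments) if lab == c]
            out[c] = self.positions_um[sel].mean(axis=0)
        return out

    def require_compartments(self, n_required: int = 4) -> None:
        """Validate the layout for compartmental (4C) analysis.

        Raises if fewer than ``n_required`` non-empty named compartments
        exist.  Unassigned electrodes are permitted (and logged) — they are
        simply ignored by per-compartment operations.
        """
        names = self.compartment_names
        if len(names) < n_required:
            raise ValueError(
                f"compartmental analysis requires {n_required} non-empty "
                f"compartments, layout has {len(names)}: {names}"
            )
        n_unassigned = sum(1 for c in self.compartments if c == UNASSIGNED)
        if n_unassigned:
            logger.info(
                "layout: %d electrodes unassigned (ignored in per-compartment "
                "analysis)", n_unassigned,
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": list(self.ids),
                "x_um": self.positions_um[:, 0],
                "y_um": self.positions_um[:, 1],
                "compartment": list(self.compartments),
            }
        )


def grid_layout(
    rows: int = 12,
    cols: int = 12,
    pitch_um: float = 200.0,
    n_compartments: int = 4,
) -> ElectrodeLayout:
    """120-electrode planar array with four quadrant compartments.

    Emulates a 12x12-grid MEA with the six electrodes of each corner
    triangle absent (144 - 24 = 120 recording sites) and a cross-shaped
    mask partitioning the culture into four quadrant compartments.  In each
    quadrant the 4x4 electrode block nearest the corner (one cell of which
    falls in the absent corner triangle) is assigned to a compartment,
    giving 15 electrodes per compartment; the 60 electrodes under or near
    the mask arms remain unassigned.

    ``n_compartments`` in {1..4} limits how many quadrants receive labels.
    """
    if n_compartments < 1 or n_compartments > 4:
        raise ValueError("n_compartments must be in 1..4")
    if rows < 10 or cols < 10:
        raise ValueError("grid too small for corner-quadrant compartments")

    def corner_key(r: int, c: int) -> int:
        return min(r, rows - 1 - r) + min(c, cols - 1 - c)

    # Absent corner sites: taxicab distance < 3 from a grid corner.
    absent = {
        (r, c)
        for r in range(rows)
        for c in range(cols)
        if corner_key(r, c) < 3
    }
    # Quadrant blocks: 4x4 anchored one step in from each corner.
    anchors = [
        (1, 1),                    # C1: top-left
        (1, cols - 5),             # C2: top-right
        (rows - 5, 1),             # C3: bottom-left
        (rows - 5, cols - 5),      # C4: bottom-right
    ]
    block_members: dict[tuple[int, int], str] = {}
    for k in range(n_compartments):
        r0, c0 = anchors[k]
        for dr in range(4):
            for dc in range(4):
                cell = (r0 + dr, c0 + dc)
                if cell not in absent:
                    block_members[cell] = f"C{k + 1}"
    ids, xs, ys, comps = [], [], [], []
    for r in range(rows):
        for c in range(cols):
            if (r, c) in absent:
                continue
            ids.append(f"e{r:02d}{c:02d}")
            xs.append(c * pitch_um)
            ys.append(r * pitch_um)
            comps.append(block_members.get((r, c), UNASSIGNED))
    pos = np.column_stack([xs, ys]).astype(float)
    return ElectrodeLayout(tuple(ids), pos, tuple(comps), pitch_um=pitch_um)


def read_layout(path: str | Path, require_n_compartments: int | None = None
                ) -> ElectrodeLayout:
    """Read an electrode layout from JSON or CSV.

    JSON dialect: ``{"pitch_um": 200, "electrodes": [{"id": ..., "x_um":
    ..., "y_um": ..., "compartment": ...}, ...]}``.  CSV dialect: header
    ``id,x_um,y_um,compartment``.  A missing/empty compartment field means
    unassigned.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            doc = json.load(fh)
        elecs = doc["electrodes"]
        ids = tuple(str(e["id"]) for e in elecs)
        pos = np.array([[float(e["x_um"]), float(e["y_um"])] for e in elecs])
        comps = tuple(
            str(e.get("compartment") or UNASSIGNED) for e in elecs
        )
        pitch = doc.get("pitch_um")
    else:
        df = pd.read_csv(path, dtype={"id": str, "compartment": str})
        required = {"id", "x_um", "y_um"}
        if not required.issubset(df.columns):
            raise ValueError(f"layout CSV must have columns {sorted(required)}")
        ids = tuple(df["id"])
        pos = df[["x_um", "y_um"]].to_numpy(dtype=float)
        if "compartment" in df.columns:
            comps = tuple(
                c if isinstance(c, str) and c.strip() else UNASSIGNED
                for c in df["compartment"]
            )
        else:
            comps = tuple([UNASSIGNED] * len(ids))
        pitch = None
    layout = ElectrodeLayout(ids, pos, comps, pitch_um=pitch)
    if require_n_compartments is not None:
        layout.require_compartments(require_n_compartments)
    return layout


def write_layout(layout: ElectrodeLayout, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        doc = {
            "pitch_um": layout.pitch_um,
            "electrodes": [
                {
                    "id": e,
                    "x_um": float(x),
                    "y_um": float(y),
                    "compartment": c,
                }
                for e, (x, y), c in zip(
                    layout.ids, layout.positions_um, layout.compartments
                )
            ],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)
    else:
        layout.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Spike trains
# ---------------------------------------------------------------------------

@dataclass
class SpikeTrains:
    """Per-electrode sorted spike times in seconds.

    The central currency of the pipeline.  ``trains`` maps electrode id to a
    strictly increasing float64 array of spike times in ``[0, duration_s]``.
    """

    trains: dict[str, np.ndarray]
    duration_s: float

    def __post_init__(self) -> None:
        if not self.duration_s > 0:
            raise ValueError("duration_s must be positive")
        clean: dict[str, np.ndarray] = {}
        for eid, t in self.trains.items():
            t = np.asarray(t, dtype=np.float64)
            if t.size and (t.min() < 0 or t.max() > self.duration_s):
                raise ValueError(
                    f"electrode {eid}: spike times outside [0, duration]"
                )
            if t.size > 1 and np.any(np.diff(t) < 0):
                raise ValueError(f"electrode {eid}: spike times not sorted")
            clean[eid] = t
        self.trains = clean

    @property
    def electrode_ids(self) -> tuple[str, ...]:
        return tuple(self.trains.keys())

    def __getitem__(self, eid: str) -> np.ndarray:
        return self.trains[eid]

    def n_spikes(self, eid: str | None = None) -> int:
        if eid is not None:
            return int(self.trains[eid].size)
        return int(sum(t.size for t in self.trains.values()))

    def mean_firing_rates(self) -> dict[str, float]:
        """Spikes per second per electrode over the full duration."""
        return {e: t.size / self.duration_s for e, t in self.trains.items()}

    def active_electrodes(self, mfr_threshold: float = 0.1) -> tuple[str, ...]:
        """Electrodes with MFR strictly above ``mfr_threshold`` spikes/s."""
        mfr = self.mean_firing_rates()
        return tuple(e for e in self.trains if mfr[e] > mfr_threshold)


def read_spike_trains(path: str | Path,
                      duration_s: float | None = None) -> SpikeTrains:
    """Read spike trains from long-format CSV or HDF5.

    CSV columns: ``electrode,time_s``; HDF5: one float64 dataset per
    electrode under the root group, file attribute ``duration_s``.  Times
    are sorted on read; unsorted input triggers a warning, not an error.
    """
    path = Path(path)
    if path.suffix.lower() in {".h5", ".hdf5"}:
        trains: dict[str, np.ndarray] = {}
        with h5py.File(path, "r") as fh:
            dur = float(fh.attrs["duration_s"])
            for eid in fh.keys():
                trains[str(eid)] = np.asarray(fh[eid][()], dtype=np.float64)
    else:
        df = pd.read_csv(path, dtype={"electrode": str},
                         float_precision="round_trip")
        if not {"electrode", "time_s"}.issubset(df.columns):
            raise ValueError("spike CSV must have columns electrode,time_s")
        dur = duration_s if duration_s is not None else float(
            df["time_s"].max() if len(df) else 0.0
        )
        trains = {
            str(eid): grp["time_s"].to_numpy(dtype=np.float64)
            for eid, grp in df.groupby("electrode", sort=True)
        }
    if duration_s is not None:
        dur = duration_s
    for eid, t in trains.items():
        if np.any(t < 0):
            raise ValueError(f"electrode {eid}: negative spike times")
        if t.size and t.max() > dur:
            raise ValueError(
                f"electrode {eid}: spike time exceeds duration {dur}"
            )
        if t.size > 1 and np.any(np.diff(t) < 0):
            warnings.warn(
                f"electrode {eid}: unsorted spike times in {path.name}; "
                "sorting", stacklevel=2,
            )
            trains[eid] = np.sort(t)
    return SpikeTrains(trains, duration_s=dur)


def write_spike_trains(trains: SpikeTrains, path: str | Path) -> None:
    """Write spike trains to CSV or HDF5; round-trips to full precision."""
    path = Path(path)
    if path.suffix.lower() in {".h5", ".hdf5"}:
        with h5py.File(path, "w") as fh:
            fh.attrs["duration_s"] = trains.duration_s
            for eid, t in trains.trains.items():
                fh.create_dataset(eid, data=np.asarray(t, dtype=np.float64))
    else:
        with open(path, "w") as fh:
            fh.write("electrode,time_s\n")
            for eid in trains.electrode_ids:
                for t in trains[eid]:
                    # repr round-trips float64 exactly
                    fh.write(f"{eid},{float(t)!r}\n")


# ---------------------------------------------------------------------------
# Raw recordings
# ---------------------------------------------------------------------------

@dataclass
class RawRecording:
    """Per-electrode sampled voltage traces (uV) at a common sampling rate."""

    traces: dict[str, np.ndarray]
    fs_hz: float

    def __post_init__(self) -> None:
        if not self.fs_hz > 0:
            raise ValueError("sampling rate must be positive")
        lengths = {t.size for t in self.traces.values()}
        if len(lengths) > 1:
            raise ValueError("all channels must have equal length")
        self.traces = {
            e: np.asarray(t, dtype=np.float64) for e, t in self.traces.items()
        }

    @property
    def n_samples(self) -> int:
        return next(iter(self.traces.values())).size if self.traces else 0

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz


def read_raw_recording(path: str | Path) -> RawRecording:
    """Read raw traces from HDF5 (datasets ``traces/<id>``, attr ``fs_hz``)."""
    with h5py.File(path, "r") as fh:
        fs = float(fh.attrs["fs_hz"])
        grp = fh["traces"]
        traces = {str(k): np.asarray(grp[k][()], dtype=np.float64)
                  for k in grp.keys()}
    return RawRecording(traces, fs_hz=fs)


def write_raw_recording(rec: RawRecording, path: str | Path) -> None:
    with h5py.File(path, "w") as fh:
        fh.attrs["fs_hz"] = rec.fs_hz
        grp = fh.create_group("traces")
        for eid, t in rec.traces.items():
            grp.create_dataset(eid, data=t)
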