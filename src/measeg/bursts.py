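"""String-method burst detection and firing/bursting statistics.

A burst is a maximal run of consecutive spikes on one electrode in which
every inter-spike interval is at most ``max_isi`` (default 100 ms) and the
run contains at least ``min_spikes`` spikes (default 5).  The ISI bound is
inclusive: an interval of exactly 100 ms still joins the run.

Per-electrode statistics:

* MFR  — mean firing rate, spikes/s over the recording;
* MBR  — mean bursting rate, bursts/min;
* MFIB — mean frequency intra burst, spikes over burst duration (spikes/s),
  averaged over an electrode's bursts;
* RS   — random spikes, percentage of spikes occurring outside bursts.

An electrode is *active* when its MFR exceeds 0.1 spikes/s.  Compartment
values are unweighted means over that compartment's active electrodes
(configurable; inactive electrodes excluded by default).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .layout_io import UNASSIGNED, ElectrodeLayout, SpikeTrains

logger = logging.getLogger("measeg")

__all__ = [
    "Burst",
    "detect_bursts",
    "detect_bursts_all",
    "firing_stats",
    "FiringStats",
]

MIN_SPIKES_DEFAULT = 5
MAX_ISI_MS_DEFAULT = 100.0
ACTIVE_MFR_THRESHOLD = 0.1  # spikes/s


@dataclass(frozen=True)
class Burst:
    """One single-electrode burst."""

    electrode: str
    start_s: float
    end_s: float
    n_spikes: int

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def detect_bursts(
    train: np.ndarray,
    electrode: str = "",
    min_spikes: int = MIN_SPIKES_DEFAULT,
    max_isi_ms: float = MAX_ISI_MS_DEFAULT,
) -> list[Burst]:
    """String-method bursts of a sorted spike train.

    Splits the train at every ISI larger than ``max_isi_ms`` and keeps the
    maximal runs of at least ``min_spikes`` spikes.  Runs are disjoint and
    each spike belongs to at most one burst.
    """
    t = np.asarray(train, dtype=float)
    if t.size < min_spikes:
        return []
    # inclusive boundary (an ISI of exactly max_isi joins the string); the
    # 1 ns slack absorbs float64 representation error at the boundary
    max_isi_s = max_isi_ms / 1000.0 + 1e-9
    gaps = np.where(np.diff(t) > max_isi_s)[0] + 1
    out: list[Burst] = []
    for seg in np.split(t, gaps):
        if seg.size >= min_spikes:
            out.append(Burst(electrode, float(seg[0]), float(seg[-1]),
                             int(seg.size)))
    return out


def detect_bursts_all(
    trains: SpikeTrains,
    min_spikes: int = MIN_SPIKES_DEFAULT,
    max_isi_ms: float = MAX_ISI_MS_DEFAULT,
) -> dict[str, list[Burst]]:
    return {
        eid: detect_bursts(trains[eid], eid, min_spikes, max_isi_ms)
        for eid in trains.electrode_ids
    }


@dataclass
class FiringStats:
    """Per-electrode and per-compartment firing/bursting statistics."""

    per_electrode: pd.DataFrame   # index: electrode; MFR, MBR, MFIB, RS,
                                  # active, compartment, n_spikes, n_bursts
    per_compartment: pd.DataFrame  # index: compartment; means over active


def _electrode_stats(t: np.ndarray, bursts: list[Burst],
                     duration_s: float) -> dict[str, float]:
    n_spikes = int(t.size)
    mfr = n_spikes / duration_s
    mbr = len(bursts) * 60.0 / duration_s
    burst_spikes = sum(b.n_spikes for b in bursts)
    if bursts:
        mfibs = [b.n_spikes / b.duration_s for b in bursts
                 if b.duration_s > 0]
        mfib = float(np.mean(mfibs)) if mfibs else math.nan
    else:
        mfib = math.nan
    rs = (100.0 * (n_spikes - burst_spikes) / n_spikes
          if n_spikes else math.nan)
    return {
        "n_spikes": n_spikes,
        "n_bursts": len(bursts),
        "MFR": mfr,
        "MBR": mbr,
        "MFIB": mfib,
        "RS": rs,
        "active": mfr > ACTIVE_MFR_THRESHOLD,
    }


def firing_stats(
    trains: SpikeTrains,
    bursts: dict[str, list[Burst]] | None = None,
    layout: ElectrodeLayout | None = None,
    active_mfr_threshold: float = ACTIVE_MFR_THRESHOLD,
    include_inactive_in_means: bool = False,
) -> FiringStats:
    """Firing/bursting statistics per electrode and per compartment.

    ``bursts`` must derive from the same trains (computed here when
    omitted).  Compartment rows average the electrodes of each compartment;
    by default only active ones (MFR > ``active_mfr_threshold``) enter the
    means, and unassigned electrodes never do.  RS and MFIB are missing
    (NaN) for electrodes without spikes or bursts respectively.
    """
    if trains.duration_s <= 0:
        raise ValueError("zero-duration recording")
    if bursts is None:
        bursts = detect_bursts_all(trains)
    rows = {}
    for eid in trains.electrode_ids:
        row = _electrode_stats(trains[eid], bursts.get(eid, []),
                               trains.duration_s)
        row["active"] = row["MFR"] > active_mfr_threshold
        row["compartment"] = (layout.compartment_of(eid)
                              if layout is not None else UNASSIGNED)
        rows[eid] = row
    per_electrode = pd.DataFrame.from_dict(rows, orient="index")
    per_electrode.index.name = "electrode"

    metrics = ["MFR", "MBR", "MFIB", "RS"]
    comp_rows = {}
    if layout is not None:
        for comp in layout.compartment_names:
            sub = per_electrode[per_electrode["compartment"] == comp]
            if not include_inactive_in_means:
                sub = sub[sub["active"]]
            comp_rows[comp] = {
                "n_electrodes": len(sub),
                **{m: float(sub[m].mean()) if len(sub) else math.nan
                   for m in metrics},
            }
    per_compartment = pd.DataFrame.from_dict(comp_rows, orient="index")
    per_compartment.index.name = "compartment"
    return FiringStats(per_electrode=per_electrode,
                       per_compartment=per_compartment)
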