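"""Network-burst detection, compartment involvement and initiation analysis.

Population events are found on a binned product statistic: the recording is
cut into 25 ms bins and, per bin, (number of electrodes firing) x (number
of spikes) is evaluated.  Maximal runs of bins whose product exceeds 5% of
the recording's maximum form candidate network bursts; candidates closer
than 80 ms are merged, and each event window is then refined to the first
and last spike it contains, so durations are not quantized to the bin.

Per event we report the involved electrodes (>= 1 spike inside the window)
with their first-spike times, the involved compartments (>= 3 involved
electrodes, i.e. 20% of a ~15-electrode compartment), the initiating
(leader) electrode and compartment — earliest first spike, ties broken by
electrode id — and each compartment's activation delay (minimum follower
delay relative to the leader's first spike).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .layout_io import UNASSIGNED, ElectrodeLayout, SpikeTrains

logger = logging.getLogger("measeg")

__all__ = [
    "NetworkBurst",
    "network_burst_statistic",
    "detect_network_bursts",
    "involvement_spectrum",
    "leader_hierarchy",
]

BIN_MS_DEFAULT = 25.0
FRAC_DEFAULT = 0.05
MIN_GAP_MS_DEFAULT = 80.0
MIN_ELECTRODES_PER_COMPARTMENT = 3


@dataclass(frozen=True)
class NetworkBurst:
    """One detected network burst."""

    start_s: float
    end_s: float
    first_spike_times: dict[str, float]          # involved electrodes only
    involved_compartments: tuple[str, ...]       # >= 3 involved electrodes
    leader_electrode: str
    leader_compartment: str
    compartment_delays_ms: dict[str, float]      # min delay vs leader spike
    leader_in_involved_compartment: bool = True

    @property
    def duration_s(self) -> float:
        """Network burst duration (NBD)."""
        return self.end_s - self.start_s

    @property
    def n_involved_electrodes(self) -> int:
        return len(self.first_spike_times)


def network_burst_statistic(
    trains: SpikeTrains,
    bin_ms: float = BIN_MS_DEFAULT,
) -> np.ndarray:
    """Per-bin product of active sites and spike count.

    Half-open bins ``[k*bin, (k+1)*bin)``; ``S(k)`` = (#electrodes with at
    least one spike in bin k) x (#spikes in bin k).
    """
    if bin_ms <= 0:
        raise ValueError("bin width must be positive")
    bin_s = bin_ms / 1000.0
    n_bins = int(np.ceil(trains.duration_s / bin_s))
    if n_bins == 0:
        return np.zeros(0, dtype=np.int64)
    spikes = np.zeros(n_bins, dtype=np.int64)
    sites = np.zeros(n_bins, dtype=np.int64)
    for eid in trains.electrode_ids:
        t = trains[eid]
        if not t.size:
            continue
        k = np.minimum((t / bin_s).astype(np.int64), n_bins - 1)
        counts = np.bincount(k, minlength=n_bins)
        spikes += counts
        sites += counts > 0
    return sites * spikes


def _candidate_runs(supra: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs [start_bin, end_bin] (inclusive) of a boolean mask."""
    idx = np.flatnonzero(supra)
    if not idx.size:
        return []
    breaks = np.where(np.diff(idx) > 1)[0]
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    ends = np.concatenate([idx[breaks], [idx[-1]]])
    return list(zip(starts.tolist(), ends.tolist()))


def _merge_runs(runs: list[tuple[int, int]], bin_s: float,
                min_gap_s: float) -> list[tuple[int, int]]:
    """Merge candidate runs whose temporal gap is below ``min_gap_s``."""
    if not runs:
        return []
    merged = [runs[0]]
    for s, e in runs[1:]:
        ps, pe = merged[-1]
        gap = (s - (pe + 1)) * bin_s
        if gap < min_gap_s:
            merged[-1] = (ps, e)
        else:
            merged.append((s, e))
    return merged


def detect_network_bursts(
    trains: SpikeTrains,
    layout: ElectrodeLayout,
    bin_ms: float = BIN_MS_DEFAULT,
    frac: float = FRAC_DEFAULT,
    min_gap_ms: float = MIN_GAP_MS_DEFAULT,
    min_electrodes_per_compartment: int = MIN_ELECTRODES_PER_COMPARTMENT,
    leader_within_involved: bool = True,
) -> list[NetworkBurst]:
    """Detect network bursts on the binned product statistic.

    Bins with statistic strictly above ``frac`` x (recording maximum) seed
    candidate events; events separated by less than ``min_gap_ms`` are
    merged; each event window is refined to [first spike, last spike]
    within its supra-threshold span, and involvement/leader quantities are
    computed on the refined window.

    ``leader_within_involved`` restricts the initiating electrode to
    compartments that satisfy the involvement rule, so an isolated stray
    spike cannot claim initiation for an otherwise silent compartment;
    with ``False`` the leader is the earliest first spike over all
    involved electrodes, whatever its compartment.
    """
    stat = network_burst_statistic(trains, bin_ms)
    if stat.size == 0 or stat.max() == 0:
        warnings.warn("silent recording: no network bursts", stacklevel=2)
        return []
    bin_s = bin_ms / 1000.0
    threshold = frac * float(stat.max())
    runs = _candidate_runs(stat > threshold)
    runs = _merge_runs(runs, bin_s, min_gap_ms / 1000.0)

    out: list[NetworkBurst] = []
    for s_bin, e_bin in runs:
        w_lo, w_hi = s_bin * bin_s, (e_bin + 1) * bin_s
        first: dict[str, float] = {}
        t_first, t_last = np.inf, -np.inf
        for eid in trains.electrode_ids:
            t = trains[eid]
            inside = t[(t >= w_lo) & (t < w_hi)]
            if inside.size:
                first[eid] = float(inside[0])
                t_first = min(t_first, float(inside[0]))
                t_last = max(t_last, float(inside[-1]))
        if not first:
            continue  # supra-threshold span without spikes cannot occur
        # compartment involvement: >= min_electrodes involved electrodes
        involved: list[str] = []
        comp_first: dict[str, float] = {}
        for comp in layout.compartment_names:
            members = [e for e in layout.electrodes_in(comp) if e in first]
            if members:
                comp_first[comp] = min(first[e] for e in members)
            if len(members) >= min_electrodes_per_compartment:
                involved.append(comp)
        # leader: earliest first spike, ties by electrode id order
        comp_of = {e: layout.compartment_of(e) for e in first}
        pool = (
            [e for e in first if comp_of[e] in involved]
            if leader_within_involved and involved else list(first)
        )
        leader = min(pool, key=lambda e: (first[e], e))
        t0 = first[leader]
        leader_comp = comp_of[leader]
        delays = {c: 1000.0 * (tc - t0) for c, tc in comp_first.items()}
        out.append(NetworkBurst(
            start_s=t_first,
            end_s=t_last,
            first_spike_times=first,
            involved_compartments=tuple(involved),
            leader_electrode=leader,
            leader_compartment=leader_comp,
            compartment_delays_ms=delays,
            leader_in_involved_compartment=(leader_comp in involved),
        ))
    return out


def involvement_spectrum(nbs: list[NetworkBurst],
                         n_compartments: int = 4) -> dict[str, float]:
    """Percentage of network bursts involving 1..n compartments.

    Keys ``"1C"``..``"nC"`` give percentages over events involving at least
    one compartment (these sum to 100); ``"0C_count"`` reports separately
    the events in which no compartment reached the involvement rule.
    """
    if not nbs:
        raise ValueError("no network bursts")
    counts = np.zeros(n_compartments + 1, dtype=int)
    for nb in nbs:
        k = min(len(nb.involved_compartments), n_compartments)
        counts[k] += 1
    n_valid = counts[1:].sum()
    out: dict[str, float] = {}
    for k in range(1, n_compartments + 1):
        out[f"{k}C"] = 100.0 * counts[k] / n_valid if n_valid else np.nan
    out["0C_count"] = int(counts[0])
    return out


def leader_hierarchy(nbs: list[NetworkBurst],
                     n_compartments: int = 4) -> pd.DataFrame:
    """Initiation percentages per compartment, ordered hierarchically.

    Counts how often each compartment hosts the initiating electrode,
    converts to percentages, and orders them descending (1st..nth).  Events
    whose leader electrode is unassigned are excluded (an error if that
    leaves nothing).  The uniform null reference is ``100 / n`` percent.
    """
    leaders = [nb.leader_compartment for nb in nbs
               if nb.leader_compartment != UNASSIGNED]
    if not leaders:
        raise ValueError("no network burst has a leader in an assigned "
                         "compartment")
    counts = pd.Series(leaders).value_counts()
    pct = 100.0 * counts / counts.sum()
    pct = pct.sort_values(ascending=False, kind="stable")
    df = pd.DataFrame({
        "rank": [f"{i + 1}" for i in range(len(pct))],
        "compartment": pct.index,
        "percentage": pct.to_numpy(),
    })
    # compartments that never lead appear with 0%
    missing = [c for c in (f"C{i+1}" for i in range(n_compartments))
               if c not in set(df["compartment"])]
    for j, c in enumerate(missing):
        df.loc[len(df)] = [f"{len(df) + 1}", c, 0.0]
    df.attrs["uniform_null_pct"] = 100.0 / n_compartments
    return df
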