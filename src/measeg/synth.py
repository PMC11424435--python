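"""Generative model of compartmentalized MEA cultures with ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, at controllable inter-compartment coupling:

* per-electrode background firing as a homogeneous Poisson process;
* single-electrode bursts (>= 5 spikes, short intra-burst ISIs);
* network-burst events that initiate in a leader compartment and recruit
  each other compartment independently with probability ``p_couple``, with
  inter-compartment onset delays consistent with axonal conduction speeds
  in the 30-300 mm/s band;
* optional lag-coupled electrode pairs (a source electrode whose spikes
  are echoed by a target at a fixed millisecond lag), the planted signal
  for connectivity-recovery experiments;
* optional raw 10 kHz voltage traces (Gaussian noise plus a biphasic spike
  template) to exercise the threshold-based spike detector.

Everything random flows from a single seed, so identical configs reproduce
identical recordings, and the hidden labels (event times, leaders,
recruited compartments, coupled pairs) are returned alongside the spikes
for parameter-recovery tests.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .layout_io import ElectrodeLayout, RawRecording, SpikeTrains, grid_layout

logger = logging.getLogger("measeg")

__all__ = [
    "SynthConfig",
    "NetworkEvent",
    "CoupledPair",
    "SynthGroundTruth",
    "generate_spike_trains",
    "generate_raw_traces",
    "biphasic_template",
]


@dataclass
class SynthConfig:
    """Study conditions for a synthetic compartmentalized recording.

    Defaults model a four-compartment culture on the 120-electrode quadrant
    layout at moderate coupling.  Rates are per electrode; times in seconds
    unless suffixed otherwise.
    """

    n_compartments: int = 4
    electrodes_per_compartment: int = 15
    duration_s: float = 300.0
    background_rate: float = 0.5          # spikes/s per assigned electrode
    masked_background_rate: float = 0.0   # spikes/s under the mask arms
    # single-electrode burst shape
    burst_min_spikes: int = 5
    burst_max_spikes: int = 10
    burst_mean_isi_ms: float = 10.0       # gamma(shape=2) ISIs, mean 10 ms
    # network-burst events
    nb_rate_per_min: float = 10.0
    n_events: int | None = None           # overrides nb_rate when set
    min_event_separation_s: float = 1.5
    leader_weights: tuple[float, ...] | None = None  # uniform when None
    p_couple: float = 0.5
    recruit_fraction: float = 0.8
    jitter_sd_ms: float = 5.0
    # drawn once per recording; the range keeps compartment onset delays
    # (~1.2-1.8 mm centroid distances) both inside the 30-300 mm/s band and
    # well above the onset-jitter scale, so planted leaders are unambiguous
    conduction_speed_range_mm_s: tuple[float, float] = (50.0, 100.0)
    # planted lag-coupled electrode pairs (connectivity ground truth)
    n_coupled_pairs: int = 0
    coupled_lag_ms: float = 5.0
    coupled_jitter_sd_ms: float = 0.5
    coupled_rate: float = 2.0             # extra source spikes/s
    coupled_follow_prob: float = 0.8
    coupled_pairs_in_band: bool = True    # pair distance inside 30-300 mm/s
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_couple <= 1.0:
            raise ValueError("p_couple must be in [0, 1]")
        for name in ("background_rate", "nb_rate_per_min", "coupled_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.burst_min_spikes < 5:
            raise ValueError("bursts must contain at least 5 spikes")
        if self.burst_mean_isi_ms > 100.0:
            raise ValueError("intra-burst mean ISI must be <= 100 ms")
        if self.leader_weights is not None:
            w = np.asarray(self.leader_weights, dtype=float)
            if w.size != self.n_compartments or np.any(w < 0):
                raise ValueError("leader_weights: one non-negative weight "
                                 "per compartment")
            if not np.isclose(w.sum(), 1.0):
                raise ValueError("leader_weights must sum to 1")
        if not 0.0 < self.recruit_fraction <= 1.0:
            raise ValueError("recruit_fraction must be in (0, 1]")


@dataclass(frozen=True)
class NetworkEvent:
    """Ground truth for one planted network-burst event."""

    t_start_s: float
    leader_compartment: str
    recruited_compartments: tuple[str, ...]   # includes the leader
    onset_delays_ms: dict[str, float]         # leader -> 0.0


@dataclass(frozen=True)
class CoupledPair:
    """Ground truth for one planted lag-coupled electrode pair."""

    source: str
    target: str
    lag_ms: float
    distance_um: float


@dataclass
class SynthGroundTruth:
    """Hidden labels emitted alongside the synthetic spike trains."""

    events: list[NetworkEvent]
    coupled_pairs: list[CoupledPair]
    config: SynthConfig

    def __post_init__(self) -> None:
        for ev in self.events:
            if ev.leader_compartment not in ev.recruited_compartments:
                raise ValueError("recruited set must contain the leader")
            if ev.onset_delays_ms[ev.leader_compartment] != 0.0:
                raise ValueError("leader onset delay must be 0")
            if any(d < 0 for d in ev.onset_delays_ms.values()):
                raise ValueError("onset delays must be >= 0")


def _event_times(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """Event start times with a minimum separation, away from the edges."""
    if cfg.n_events is not None:
        n = cfg.n_events
    else:
        n = rng.poisson(cfg.nb_rate_per_min * cfg.duration_s / 60.0)
    if n == 0:
        return np.empty(0)
    margin = 0.5
    lo, hi = margin, cfg.duration_s - margin
    if hi <= lo or (n * cfg.min_event_separation_s) > (hi - lo):
        warnings.warn(
            "infeasible event schedule: too many network events for the "
            "recording duration; thinning", stacklevel=2,
        )
    times: list[float] = []
    # sequential rejection; cap attempts so degenerate configs terminate
    for _ in range(50 * max(n, 1)):
        if len(times) == n:
            break
        t = rng.uniform(lo, hi)
        if all(abs(t - u) >= cfg.min_event_separation_s for u in times):
            times.append(t)
    return np.sort(np.asarray(times))


def _burst_spike_times(cfg: SynthConfig, t0: float,
                       rng: np.random.Generator) -> np.ndarray:
    n = int(rng.integers(cfg.burst_min_spikes, cfg.burst_max_spikes + 1))
    # gamma(shape=2) keeps ISIs away from zero while matching the mean
    isis = rng.gamma(2.0, cfg.burst_mean_isi_ms / 2.0, size=n - 1) / 1000.0
    return t0 + np.concatenate([[0.0], np.cumsum(isis)])


def _select_coupled_pairs(cfg: SynthConfig, layout: ElectrodeLayout,
                          rng: np.random.Generator) -> list[CoupledPair]:
    """Disjoint electrode pairs whose distance/lag sits in (or out of) the
    30-300 mm/s propagation band."""
    if cfg.n_coupled_pairs == 0:
        return []
    lag_s = cfg.coupled_lag_ms / 1000.0
    d_lo, d_hi = 30.0 * lag_s * 1000.0, 300.0 * lag_s * 1000.0  # um
    ids = [e for e, c in zip(layout.ids, layout.compartments)
           if c != "unassigned"]
    idx = {e: layout.ids.index(e) for e in ids}
    dm = layout.distance_matrix_um()
    candidates = []
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            d = dm[idx[a], idx[b]]
            in_band = d_lo <= d <= d_hi
            if in_band == cfg.coupled_pairs_in_band:
                candidates.append((a, b, d))
    if len(candidates) < cfg.n_coupled_pairs:
        raise ValueError("not enough electrode pairs at the requested "
                         "distance band for coupled-pair planting")
    rng.shuffle(candidates)
    pairs: list[CoupledPair] = []
    used: set[str] = set()
    for a, b, d in candidates:
        if a in used or b in used:
            continue
        pairs.append(CoupledPair(a, b, cfg.coupled_lag_ms, float(d)))
        used.update((a, b))
        if len(pairs) == cfg.n_coupled_pairs:
            break
    if len(pairs) < cfg.n_coupled_pairs:
        raise ValueError("could not plant the requested number of disjoint "
                         "coupled pairs")
    return pairs


def generate_spike_trains(
    config: SynthConfig,
    layout: ElectrodeLayout | None = None,
) -> tuple[SpikeTrains, SynthGroundTruth]:
    """Simulate a compartmentalized culture recording.

    Returns the spike trains for every electrode of ``layout`` (default:
    the 120-electrode quadrant layout) together with the ground truth.
    Identical ``config`` (including seed) and layout give identical output.
    """
    cfg = config
    if layout is None:
        layout = grid_layout(n_compartments=cfg.n_compartments)
    comp_names = layout.compartment_names[: cfg.n_compartments]
    if len(comp_names) < cfg.n_compartments:
        raise ValueError("layout provides fewer compartments than requested")
    rng = np.random.default_rng(cfg.seed)

    spikes: dict[str, list[np.ndarray]] = {e: [] for e in layout.ids}

    # --- background Poisson firing -------------------------------------
    # electrodes under the mask (unassigned) see no cells: silent by default
    for eid, comp in zip(layout.ids, layout.compartments):
        rate = (cfg.background_rate if comp != "unassigned"
                else cfg.masked_background_rate)
        n = rng.poisson(rate * cfg.duration_s)
        if n:
            spikes[eid].append(np.sort(rng.uniform(0, cfg.duration_s, n)))

    # --- network-burst events ------------------------------------------
    weights = (np.asarray(cfg.leader_weights, dtype=float)
               if cfg.leader_weights is not None
               else np.full(cfg.n_compartments, 1.0 / cfg.n_compartments))
    centroids = layout.compartment_centroids_um()
    v_lo, v_hi = cfg.conduction_speed_range_mm_s
    speed_mm_s = rng.uniform(v_lo, v_hi)  # one axonal speed per recording
    t_events = _event_times(cfg, rng)
    if cfg.nb_rate_per_min * cfg.duration_s / 60.0 < 1 and cfg.n_events is None:
        warnings.warn("expected number of network events < 1", stacklevel=2)

    events: list[NetworkEvent] = []
    jitter_sd = cfg.jitter_sd_ms / 1000.0
    for t0 in t_events:
        leader = comp_names[rng.choice(cfg.n_compartments, p=weights)]
        recruited = [leader]
        for c in comp_names:
            if c != leader and rng.random() < cfg.p_couple:
                recruited.append(c)
        delays_ms: dict[str, float] = {}
        for c in recruited:
            if c == leader:
                delays_ms[c] = 0.0
            else:
                d_mm = float(
                    np.linalg.norm(centroids[c] - centroids[leader])) / 1000.0
                delays_ms[c] = d_mm / speed_mm_s * 1000.0
        for c in recruited:
            members = layout.electrodes_in(c)
            k = max(1, int(round(cfg.recruit_fraction * len(members))))
            chosen = rng.choice(len(members), size=k, replace=False)
            onset = t0 + delays_ms[c] / 1000.0
            for m in chosen:
                t_burst = onset + rng.normal(0.0, jitter_sd)
                spikes[members[m]].append(_burst_spike_times(cfg, t_burst, rng))
        events.append(NetworkEvent(
            t_start_s=float(t0),
            leader_compartment=leader,
            recruited_compartments=tuple(sorted(recruited)),
            onset_delays_ms=delays_ms,
        ))

    # --- planted lag-coupled pairs --------------------------------------
    pairs = _select_coupled_pairs(cfg, layout, rng)
    for p in pairs:
        n = rng.poisson(cfg.coupled_rate * cfg.duration_s)
        src = np.sort(rng.uniform(0, cfg.duration_s, n))
        follow = rng.random(n) < cfg.coupled_follow_prob
        tgt = (src[follow] + p.lag_ms / 1000.0
               + rng.normal(0.0, cfg.coupled_jitter_sd_ms / 1000.0,
                            follow.sum()))
        spikes[p.source].append(src)
        spikes[p.target].append(tgt)

    trains: dict[str, np.ndarray] = {}
    for eid, chunks in spikes.items():
        if chunks:
            t = np.concatenate(chunks)
            t = np.unique(t[(t >= 0) & (t <= cfg.duration_s)])
        else:
            t = np.empty(0)
        trains[eid] = t
    st = SpikeTrains(trains, duration_s=cfg.duration_s)
    gt = SynthGroundTruth(events=events, coupled_pairs=pairs, config=cfg)
    return st, gt


# ---------------------------------------------------------------------------
# Raw-trace synthesis (fixture for the spike-detection stage)
# ---------------------------------------------------------------------------

def biphasic_template(fs_hz: float, peak_to_peak_uv: float,
                      duration_ms: float = 1.0) -> np.ndarray:
    """Biphasic extracellular spike waveform (negative-leading).

    One period of a Hann-windowed sine: a sharp negative trough followed by
    a positive rebound, scaled to the requested peak-to-peak amplitude.
    """
    n = max(4, int(round(duration_ms / 1000.0 * fs_hz)))
    t = np.arange(n) / n
    w = -np.sin(2 * np.pi * t) * np.hanning(n)
    return w / np.ptp(w) * peak_to_peak_uv


def generate_raw_traces(
    trains: SpikeTrains,
    noise_sd_uv: float,
    spike_template: np.ndarray,
    fs_hz: float = 10_000.0,
    seed: int = 0,
) -> RawRecording:
    """Render spike trains as sampled voltage traces.

    Gaussian noise with the stated SD plus ``spike_template`` added at each
    spike time (template anchored at its extremal sample, so the nominal
    spike time coincides with the waveform trough).
    """
    if fs_hz < 10_000.0:
        warnings.warn("sampling rates below 10 kHz under-resolve the "
                      "2 ms peak lifetime window", stacklevel=2)
    tmpl = np.asarray(spike_template, dtype=float)
    min_isi = min(
        (float(np.diff(t).min()) for t in trains.trains.values()
         if t.size > 1),
        default=np.inf,
    )
    if tmpl.size / fs_hz > min_isi:
        raise ValueError("spike template longer than the minimum ISI; "
                         "events would merge")
    rng = np.random.default_rng(seed)
    n_samples = int(round(trains.duration_s * fs_hz))
    anchor = int(np.argmax(np.abs(tmpl)))
    traces: dict[str, np.ndarray] = {}
    for eid in trains.electrode_ids:
        x = rng.normal(0.0, noise_sd_uv, n_samples)
        for t in trains[eid]:
            i0 = int(round(t * fs_hz)) - anchor
            a = max(i0, 0)
            b = min(i0 + tmpl.size, n_samples)
            if b > a:
                x[a:b] += tmpl[a - i0: b - i0]
        traces[eid] = x
    return RawRecording(traces, fs_hz=fs_hz)
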