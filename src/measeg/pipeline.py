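"""End-to-end orchestration: spikes -> bursts -> network bursts ->
connectivity -> graph metrics, with per-compartment reporting.

``run_pipeline`` takes a :class:`RunConfig` (all stage parameters default
to the analysis' reference values) and returns a result bundle of tidy
tables plus a provenance record, deterministic given inputs and seed.
``summarize_groups`` stacks bundles from several recordings into one
long-format table keyed by group and timepoint labels; inferential group
testing is deliberately left to standard statistics packages.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bursts import detect_bursts_all, firing_stats
from .connectivity import (
    TSPEParams,
    bhattacharyya,
    clustering_coefficient,
    estimate_cm_tspe,
    label_intra_inter,
    length_distributions,
    node_degree,
    speed_filter,
    strong_connections,
    threshold_cm,
)
from .layout_io import ElectrodeLayout, SpikeTrains
from .netbursts import (
    detect_network_bursts,
    involvement_spectrum,
    leader_hierarchy,
)

logger = logging.getLogger("measeg")

__all__ = ["RunConfig", "run_pipeline", "summarize_groups"]


@dataclass
class RunConfig:
    """Stage parameters of a full analysis run (defaults = reference values).

    Spike detection (8x SD, 2 ms, 1 ms) happens upstream when starting from
    raw traces; this config covers the spike-train-level stages.
    """

    # bursts
    burst_min_spikes: int = 5
    burst_max_isi_ms: float = 100.0
    active_mfr_threshold: float = 0.1     # spikes/s
    # network bursts
    nb_bin_ms: float = 25.0
    nb_frac: float = 0.05
    nb_min_gap_ms: float = 80.0
    nb_min_electrodes: int = 3
    # connectivity
    tspe: TSPEParams = field(default_factory=TSPEParams)
    v_min_mm_s: float = 30.0
    v_max_mm_s: float = 300.0
    length_bin_mm: float = 0.1
    # bookkeeping
    recording_id: str = "recording"
    group: str = ""
    timepoint: str = ""
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("burst_max_isi_ms", "nb_bin_ms", "nb_frac",
                     "nb_min_gap_ms", "v_min_mm_s", "v_max_mm_s",
                     "length_bin_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _nb_table(nbs, recording_id: str) -> pd.DataFrame:
    rows = [
        {
            "recording": recording_id,
            "start_s": nb.start_s,
            "end_s": nb.end_s,
            "NBD_s": nb.duration_s,
            "n_involved_electrodes": nb.n_involved_electrodes,
            "n_involved_compartments": len(nb.involved_compartments),
            "involved_compartments": ",".join(nb.involved_compartments),
            "leader_electrode": nb.leader_electrode,
            "leader_compartment": nb.leader_compartment,
        }
        for nb in nbs
    ]
    return pd.DataFrame(rows)


def run_pipeline(
    trains: SpikeTrains,
    layout: ElectrodeLayout,
    config: RunConfig | None = None,
) -> dict[str, object]:
    """Run every spike-train-level analysis stage on one recording.

    Returns a bundle with keys ``firing_stats`` (per electrode/compartment),
    ``bursts``, ``network_bursts`` (table), ``involvement``, ``hierarchy``,
    ``cm``/``cm_speed``/``tcm``/``strong`` (connectivity matrices),
    ``metrics`` (graph summary) and ``provenance``.  Connectivity entries
    are None (with a logged reason) when the recording cannot support the
    estimation (e.g. fewer than two active electrodes).
    """
    cfg = config or RunConfig()
    rid = cfg.recording_id

    bursts = detect_bursts_all(trains, cfg.burst_min_spikes,
                               cfg.burst_max_isi_ms)
    stats = firing_stats(trains, bursts, layout,
                         active_mfr_threshold=cfg.active_mfr_threshold)

    nbs = detect_network_bursts(
        trains, layout, cfg.nb_bin_ms, cfg.nb_frac,
        cfg.nb_min_gap_ms, cfg.nb_min_electrodes,
    ) if trains.n_spikes() else []
    nb_table = _nb_table(nbs, rid)
    n_comp = len(layout.compartment_names)
    involvement = (involvement_spectrum(nbs, n_comp) if nbs else None)
    hierarchy = (leader_hierarchy(nbs, n_comp) if nbs else None)

    cm = cm_speed = tcm = strong = None
    metrics: dict[str, object] = {}
    try:
        cm = estimate_cm_tspe(trains, layout, cfg.tspe,
                              cfg.active_mfr_threshold)
        cm_speed = speed_filter(cm, layout, cfg.v_min_mm_s, cfg.v_max_mm_s)
        tcm, mu, sigma = threshold_cm(cm_speed)
        strong = strong_connections(tcm, mu, sigma)
        labels = label_intra_inter(tcm, layout)
        labels_strong = label_intra_inter(strong, layout)
        degree = node_degree(tcm)
        cc = clustering_coefficient(tcm, layout)
        try:
            A, B, edges = length_distributions(tcm, layout, cfg.length_bin_mm)
            bc = bhattacharyya(A, B)
        except ValueError as err:
            logger.warning("%s: length distributions unavailable (%s)",
                           rid, err)
            A = B = edges = None
            bc = math.nan
        metrics = {
            "mu": mu,
            "sigma": sigma,
            "n_edges": tcm.n_edges(),
            "n_strong_edges": strong.n_edges(),
            "pct_intra": labels["pct_intra"],
            "pct_inter": labels["pct_inter"],
            "intra_inter_ratio": labels["intra_inter_ratio"],
            "pct_intra_strong": labels_strong["pct_intra"],
            "pct_inter_strong": labels_strong["pct_inter"],
            "mean_degree": float(degree.mean()),
            "mean_cc": float(cc.mean()),
            "degree": degree,
            "clustering_coefficient": cc,
            "length_hist_total": A,
            "length_hist_inter": B,
            "length_bin_edges_mm": edges,
            "bhattacharyya": bc,
        }
    except ValueError as err:
        logger.warning("%s: connectivity stage skipped (%s)", rid, err)

    provenance = {
        "recording": rid,
        "group": cfg.group,
        "timepoint": cfg.timepoint,
        "measeg_version": __version__,
        "duration_s": trains.duration_s,
        "n_electrodes": len(layout.ids),
        "config": {
            k: (dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v)
            for k, v in dataclasses.asdict(cfg).items()
        },
    }
    return {
        "recording": rid,
        "firing_stats": stats,
        "bursts": bursts,
        "network_bursts": nbs,
        "nb_table": nb_table,
        "involvement": involvement,
        "hierarchy": hierarchy,
        "cm": cm,
        "cm_speed": cm_speed,
        "tcm": tcm,
        "strong": strong,
        "metrics": metrics,
        "provenance": provenance,
    }


def summarize_groups(
    bundles: list[dict[str, object]],
    group_key: str = "group",
    timepoint_key: str = "timepoint",
) -> pd.DataFrame:
    """Long-format summary of several result bundles.

    One row per (recording, compartment/network, metric); grouping labels
    come from each bundle's provenance.  Raises on an empty bundle list.
    """
    if not bundles:
        raise ValueError("no bundles to summarize")
    rows: list[dict[str, object]] = []
    for b in bundles:
        prov = b["provenance"]
        base = {
            "recording": prov["recording"],
            "group": prov.get(group_key, prov.get("group", "")),
            "timepoint": prov.get(timepoint_key, prov.get("timepoint", "")),
        }
        stats = b["firing_stats"]
        for comp, row in stats.per_compartment.iterrows():
            for m in ("MFR", "MBR", "MFIB", "RS"):
                rows.append({**base, "scope": comp, "metric": m,
                             "value": row[m]})
        nb = b["nb_table"]
        if len(nb):
            rows.append({**base, "scope": "network", "metric": "NBD_s",
                         "value": float(nb["NBD_s"].mean())})
        for m in ("mean_degree", "mean_cc", "pct_intra", "pct_inter",
                  "pct_intra_strong", "pct_inter_strong", "bhattacharyya"):
            if m in b["metrics"]:
                rows.append({**base, "scope": "network", "metric": m,
                             "value": b["metrics"][m]})
    return pd.DataFrame(rows)


def write_bundle(bundle: dict[str, object], out_dir: str | Path) -> None:
    """Write a result bundle's tables and matrices under one directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stats = bundle["firing_stats"]
    stats.per_electrode.to_csv(out / "firing_stats_electrode.csv")
    stats.per_compartment.to_csv(out / "firing_stats_compartment.csv")
    bundle["nb_table"].to_csv(out / "network_bursts.csv", index=False)
    for key in ("cm", "tcm", "strong"):
        mat = bundle.get(key)
        if mat is not None:
            pd.DataFrame(mat.weights, index=list(mat.ids),
                         columns=list(mat.ids)).to_csv(
                out / f"{key}_weights.csv")
            pd.DataFrame(mat.delays_ms, index=list(mat.ids),
                         columns=list(mat.ids)).to_csv(
                out / f"{key}_delays_ms.csv")
    scalars = {
        k: v for k, v in bundle["metrics"].items()
        if isinstance(v, (int, float, str))
    }
    with open(out / "metrics.json", "w") as fh:
        json.dump({"metrics": scalars,
                   "involvement": bundle["involvement"],
                   "provenance": bundle["provenance"]}, fh, indent=1,
                  default=str)
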