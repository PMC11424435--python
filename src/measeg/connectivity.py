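"""Functional connectivity from spike trains and graph-level metrics.

The estimator is a total-spiking-probability-edges (TSPE) style
cross-correlation method: spike trains are binarized at 1 ms, the
normalized cross-correlogram of every ordered electrode pair is computed
over lags up to 25 ms, and a family of running-window contrast (edge)
filters — a central averaging window flanked, beyond a crossover gap, by
negative surround windows — suppresses slow co-modulation and retains sharp
delay structure.  The edge weight ``w_ij`` is the extremal filtered value
(positive: excitatory drive of j by i; negative: inhibitory) and the edge
delay is the lag at that extremum.

Post-processing follows the physiology:

* a spatial *speed filter* keeps only edges whose implied propagation
  speed (electrode distance / delay) lies in the 30-300 mm/s axonal band;
* a hard threshold at mu +/- sigma of the non-zero connectivity values
  (positive weights must exceed mu + sigma, negative fall below
  mu - sigma) yields the thresholded matrix;
* *strong* connections are thresholded edges with |w| > mu + sigma, using
  the same mu and sigma.

Graph metrics: in+out node degree; a distance-weighted clustering
coefficient ``CC_i = (sum_j 1/d_ij^2) / (k_i (k_i - 1) / 2)`` with ``d_ij``
in millimetres, summed over the unique undirected neighbours of node i
(``k_i`` = that neighbour count); intra- vs inter-compartment edge labels
and percentages; connection-length histograms and their Bhattacharyya
distance ``BC = -ln sum_x sqrt(A(x) B(x))``.
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
    "TSPEParams",
    "ConnectivityMatrix",
    "estimate_cm_tspe",
    "speed_filter",
    "threshold_cm",
    "strong_connections",
    "label_intra_inter",
    "node_degree",
    "clustering_coefficient",
    "length_distributions",
    "bhattacharyya",
]

V_MIN_MM_S = 30.0
V_MAX_MM_S = 300.0
ACTIVE_MFR_THRESHOLD = 0.1


@dataclass(frozen=True)
class TSPEParams:
    """Estimator parameters.

    ``a_set`` are central averaging-window lengths (bins), ``b_set``
    crossover gaps; the surround windows have the same length as the centre.
    All filter combinations are averaged.
    """

    cc_bin_ms: float = 1.0
    max_delay_ms: float = 25.0
    a_set: tuple[int, ...] = (3, 4, 5, 6, 7, 8)
    b_set: tuple[int, ...] = (2, 3, 4, 5, 6)

    @property
    def max_delay_bins(self) -> int:
        return int(round(self.max_delay_ms / self.cc_bin_ms))

    @property
    def pad_bins(self) -> int:
        a, b = max(self.a_set), max(self.b_set)
        return a // 2 + b + a


@dataclass
class ConnectivityMatrix:
    """Directed signed weights and delays between electrodes.

    ``weights[i, j]`` is the strength of the functional edge i -> j (zero
    diagonal); ``delays_ms[i, j]`` the estimated conduction delay, defined
    (> 0) wherever the weight is non-zero.
    """

    weights: np.ndarray
    delays_ms: np.ndarray
    ids: tuple[str, ...]

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        d = np.asarray(self.delays_ms, dtype=float)
        n = len(self.ids)
        if w.shape != (n, n) or d.shape != (n, n):
            raise ValueError("weights/delays must be n x n")
        if not np.all(np.isfinite(w)):
            raise ValueError("non-finite connectivity weights")
        if np.any(np.diag(w) != 0):
            raise ValueError("diagonal must be zero")
        self.weights, self.delays_ms = w, d

    @property
    def n(self) -> int:
        return len(self.ids)

    def edge_mask(self) -> np.ndarray:
        return self.weights != 0

    def n_edges(self) -> int:
        return int(self.edge_mask().sum())

    def copy_with(self, weights: np.ndarray,
                  delays_ms: np.ndarray | None = None) -> "ConnectivityMatrix":
        return ConnectivityMatrix(
            weights=weights,
            delays_ms=self.delays_ms if delays_ms is None else delays_ms,
            ids=self.ids,
        )


def _edge_filter_operator(params: TSPEParams) -> tuple[np.ndarray, int]:
    """Linear operator mapping a cross-correlogram to filtered delay values.

    Returns ``(M, offset)`` such that, for a correlogram ``h`` over integer
    lags ``-L..L`` (``L = max_delay_bins + pad_bins``), ``h @ M`` gives the
    filtered value at lags ``1..max_delay_bins``; ``offset`` is the index of
    lag 0 in ``h``.
    """
    L = params.max_delay_bins + params.pad_bins
    n_lags = 2 * L + 1
    offset = L
    D = params.max_delay_bins
    M = np.zeros((n_lags, D))
    combos = [(a, b) for a in params.a_set for b in params.b_set]
    for a, b in combos:
        c = a  # surround length tied to centre length
        lo_c = -((a - 1) // 2)
        hi_c = a // 2
        for d in range(1, D + 1):
            col = d - 1
            # windows clipped to causal lags (>= 1): the anticausal side of
            # the correlogram belongs to the reverse edge and must not leak
            # into this direction's centre or baseline
            centre = np.arange(max(d + lo_c, 1), d + hi_c + 1)
            left = np.arange(max(d + lo_c - b - c, 1), max(d + lo_c - b, 1))
            right = np.arange(d + hi_c + b + 1, d + hi_c + b + c + 1)
            n_flank = left.size + right.size
            M[offset + centre, col] += 1.0 / centre.size
            M[offset + left, col] -= 1.0 / n_flank
            M[offset + right, col] -= 1.0 / n_flank
    M /= len(combos)
    return M, offset


def _lag_histogram(bi: np.ndarray, bj: np.ndarray, L: int) -> np.ndarray:
    """Counts of bin-lag differences ``bj - bi`` over ``-L..L``.

    ``bi``/``bj`` are sorted integer arrays of occupied 1 ms bins.
    """
    lo = np.searchsorted(bj, bi - L)
    hi = np.searchsorted(bj, bi + L + 1)
    m = hi - lo
    total = int(m.sum())
    if total == 0:
        return np.zeros(2 * L + 1, dtype=np.int64)
    # gather all in-window differences
    idx = np.repeat(lo, m) + (np.arange(total) -
                              np.repeat(np.cumsum(m) - m, m))
    diffs = bj[idx] - np.repeat(bi, m)
    return np.bincount(diffs + L, minlength=2 * L + 1)


def estimate_cm_tspe(
    trains: SpikeTrains,
    layout: ElectrodeLayout,
    params: TSPEParams = TSPEParams(),
    active_mfr_threshold: float = ACTIVE_MFR_THRESHOLD,
) -> ConnectivityMatrix:
    """Estimate the directed connectivity matrix of a recording.

    Only active electrodes (MFR above ``active_mfr_threshold``) are
    estimated; silent or near-silent channels get zero rows and columns.
    The matrix is indexed by the layout's electrode order.
    """
    ids = layout.ids
    n = len(ids)
    active = set(trains.active_electrodes(active_mfr_threshold))
    active &= set(trains.electrode_ids)
    if len(active) < 2:
        raise ValueError("need at least 2 active electrodes for "
                         "connectivity estimation")
    bin_s = params.cc_bin_ms / 1000.0
    D = params.max_delay_bins
    L = D + params.pad_bins
    M, offset = _edge_filter_operator(params)

    bins: dict[str, np.ndarray] = {}
    for eid in ids:
        if eid in active:
            b = np.unique((trains[eid] / bin_s).astype(np.int64))
            if b.size < 2:
                logger.warning("electrode %s: degenerate train, zeroed", eid)
                continue
            bins[eid] = b

    weights = np.zeros((n, n))
    delays = np.zeros((n, n))
    index = {e: k for k, e in enumerate(ids)}
    elig = [e for e in ids if e in bins]
    for ii, ei in enumerate(elig):
        bi = bins[ei]
        ni = bi.size
        for ej in elig[ii + 1:]:
            bj = bins[ej]
            h = _lag_histogram(bi, bj, L).astype(float)
            h /= math.sqrt(ni * bj.size)
            # i -> j uses positive lags; j -> i the mirrored correlogram
            for (src, dst, hh) in ((ei, ej, h), (ej, ei, h[::-1])):
                spe = hh @ M
                k = int(np.argmax(np.abs(spe)))
                weights[index[src], index[dst]] = spe[k]
                delays[index[src], index[dst]] = (k + 1) * params.cc_bin_ms
    return ConnectivityMatrix(weights=weights, delays_ms=delays, ids=ids)


def speed_filter(
    cm: ConnectivityMatrix,
    layout: ElectrodeLayout,
    v_min_mm_s: float = V_MIN_MM_S,
    v_max_mm_s: float = V_MAX_MM_S,
) -> ConnectivityMatrix:
    """Keep edges whose implied propagation speed is physiological.

    Speed = electrode distance (mm) / delay (s); edges outside
    ``[v_min, v_max]`` mm/s, and edges with zero delay, are removed.
    """
    if tuple(cm.ids) != tuple(layout.ids):
        raise ValueError("connectivity matrix and layout electrode order "
                         "must match")
    d_mm = layout.distance_matrix_mm()
    tau_s = cm.delays_ms / 1000.0
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.where(tau_s > 0, d_mm / np.where(tau_s > 0, tau_s, 1.0),
                     np.inf)
    keep = (v >= v_min_mm_s) & (v <= v_max_mm_s)
    zero_tau = (tau_s <= 0) & cm.edge_mask()
    if zero_tau.any():
        logger.warning("speed filter: removed %d edges with zero delay",
                       int(zero_tau.sum()))
    w = np.where(keep, cm.weights, 0.0)
    d = np.where(keep, cm.delays_ms, 0.0)
    return cm.copy_with(w, d)


def threshold_cm(cm: ConnectivityMatrix
                 ) -> tuple[ConnectivityMatrix, float, float]:
    """Hard threshold at mu +/- sigma of the non-zero connectivity values.

    ``mu`` and ``sigma`` are the mean and sample standard deviation (n-1
    denominator) of all non-zero entries.  Positive entries are kept when
    strictly above ``mu + sigma``, negative entries when strictly below
    ``mu - sigma``.  Returns the thresholded matrix together with
    ``(mu, sigma)`` for reuse by :func:`strong_connections`.
    """
    nz = cm.weights[cm.edge_mask()]
    if nz.size == 0:
        raise ValueError("all-zero connectivity matrix")
    mu = float(nz.mean())
    sigma = float(nz.std(ddof=1)) if nz.size > 1 else 0.0
    w0 = cm.weights
    keep = ((w0 > 0) & (w0 > mu + sigma)) | ((w0 < 0) & (w0 < mu - sigma))
    w = np.where(keep, cm.weights, 0.0)
    d = np.where(keep, cm.delays_ms, 0.0)
    return cm.copy_with(w, d), mu, sigma


def strong_connections(tcm: ConnectivityMatrix, mu: float, sigma: float
                       ) -> ConnectivityMatrix:
    """Strong edges: thresholded entries with ``|w| > mu + sigma``.

    Reapplies the hard threshold to the thresholded matrix with the same
    ``mu`` and ``sigma``, on the absolute weight.
    """
    keep = np.abs(tcm.weights) > (mu + sigma)
    keep &= tcm.edge_mask()
    w = np.where(keep, tcm.weights, 0.0)
    d = np.where(keep, tcm.delays_ms, 0.0)
    return tcm.copy_with(w, d)


def label_intra_inter(cm: ConnectivityMatrix, layout: ElectrodeLayout
                      ) -> dict[str, object]:
    """Classify edges as intra- or inter-compartment.

    Edges with both endpoints in assigned compartments are classified;
    edges touching unassigned electrodes are counted separately.  Returns
    percentages over classified edges (summing to 100), the intra/inter
    count ratio (inf when no inter edge exists) and a per-edge table.
    """
    if tuple(cm.ids) != tuple(layout.ids):
        raise ValueError("matrix/layout electrode order mismatch")
    comps = layout.compartments
    rows = []
    n_intra = n_inter = n_unclassified = 0
    src_idx, dst_idx = np.nonzero(cm.edge_mask())
    for i, j in zip(src_idx, dst_idx):
        ci, cj = comps[i], comps[j]
        if ci == UNASSIGNED or cj == UNASSIGNED:
            label = "unclassified"
            n_unclassified += 1
        elif ci == cj:
            label = "intra"
            n_intra += 1
        else:
            label = "inter"
            n_inter += 1
        rows.append((cm.ids[i], cm.ids[j], ci, cj, label,
                     cm.weights[i, j], cm.delays_ms[i, j]))
    table = pd.DataFrame(
        rows, columns=["source", "target", "source_compartment",
                       "target_compartment", "label", "weight", "delay_ms"])
    n_classified = n_intra + n_inter
    pct_intra = 100.0 * n_intra / n_classified if n_classified else math.nan
    pct_inter = 100.0 * n_inter / n_classified if n_classified else math.nan
    ratio = (n_intra / n_inter) if n_inter else math.inf
    return {
        "edges": table,
        "n_intra": n_intra,
        "n_inter": n_inter,
        "n_unclassified": n_unclassified,
        "pct_intra": pct_intra,
        "pct_inter": pct_inter,
        "intra_inter_ratio": ratio,
    }


def node_degree(cm: ConnectivityMatrix) -> pd.Series:
    """In + out degree per electrode (non-zero row plus column entries)."""
    mask = cm.edge_mask()
    k = mask.sum(axis=1) + mask.sum(axis=0)
    return pd.Series(k, index=list(cm.ids), name="degree")


def clustering_coefficient(cm: ConnectivityMatrix, layout: ElectrodeLayout
                           ) -> pd.Series:
    """Distance-weighted clustering coefficient per node.

    ``CC_i = (sum over unique undirected neighbours j of 1/d_ij^2)
    / (k_i (k_i - 1) / 2)`` with ``d_ij`` in mm and ``k_i`` the unique
    neighbour count.  Nodes with fewer than two neighbours get 0.  Note
    this differs from the in+out :func:`node_degree` convention, which
    would double-count reciprocal edges.
    """
    if tuple(cm.ids) != tuple(layout.ids):
        raise ValueError("matrix/layout electrode order mismatch")
    mask = cm.edge_mask()
    neigh = mask | mask.T
    np.fill_diagonal(neigh, False)
    d_mm = layout.distance_matrix_mm()
    cc = np.zeros(cm.n)
    for i in range(cm.n):
        js = np.flatnonzero(neigh[i])
        k = js.size
        if k < 2:
            continue
        cc[i] = float(np.sum(1.0 / d_mm[i, js] ** 2)) / (k * (k - 1) / 2.0)
    return pd.Series(cc, index=list(cm.ids), name="clustering_coefficient")


def length_distributions(
    cm: ConnectivityMatrix,
    layout: ElectrodeLayout,
    bin_mm: float = 0.1,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Normalized length histograms of all edges and of inter edges.

    Edge length is the Euclidean distance (mm) between the endpoints of
    each directed edge.  Both histograms share one binning (``bin_mm`` wide
    bins spanning the layout diameter) and each sums to 1.  Returns
    ``(A_total, B_inter, bin_edges_mm)``; raises when the edge set is empty
    or no inter-compartment edge exists.
    """
    if tuple(cm.ids) != tuple(layout.ids):
        raise ValueError("matrix/layout electrode order mismatch")
    d_mm = layout.distance_matrix_mm()
    mask = cm.edge_mask()
    if not mask.any():
        raise ValueError("empty edge set")
    comps = layout.compartments
    src, dst = np.nonzero(mask)
    lengths = d_mm[src, dst]
    inter = np.array([
        comps[i] != comps[j] and UNASSIGNED not in (comps[i], comps[j])
        for i, j in zip(src, dst)
    ])
    diameter = float(d_mm.max())
    n_bins = max(1, int(np.ceil(diameter / bin_mm)))
    edges = np.arange(n_bins + 1) * bin_mm
    a, _ = np.histogram(lengths, bins=edges)
    b, _ = np.histogram(lengths[inter], bins=edges)
    if b.sum() == 0:
        raise ValueError("no inter-compartment edges: inter length "
                         "distribution undefined")
    return a / a.sum(), b / b.sum(), edges


def bhattacharyya(A: np.ndarray, B: np.ndarray) -> float:
    """Bhattacharyya distance between two histograms on identical bins.

    ``BC = -ln sum_x sqrt(A(x) B(x))``; 0 for identical distributions,
    +inf for disjoint supports.  Natural logarithm.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape:
        raise ValueError("histograms must share one binning")
    s = float(np.sum(np.sqrt(A * B)))
    if s <= 0.0:
        return math.inf
    return max(0.0, -math.log(s))
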