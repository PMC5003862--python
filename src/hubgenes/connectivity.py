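"""Wavelet functional connectivity and MST-anchored binary graphs.

Functional connectivity is the Pearson correlation of undecimated
(shift-invariant) discrete wavelet transform coefficients of regional
BOLD time series, pooled over the requested wavelet scales (Daubechies-4
filters, reflection boundary). Binary graphs are built by taking the
minimum spanning tree of the correlation-derived distances — which
guarantees a connected graph at any density — and superimposing the
remaining edges in order of decreasing correlation up to a target
connection density.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pywt
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import cdist

DEFAULT_SCALES = (2, 3)
WAVELET = "db4"


@dataclass
class TimeSeriesSet:
    """Regional time series for a cohort: subjects x regions x timepoints."""

    values: np.ndarray
    tr_seconds: float
    region_ids: list

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        if self.values.ndim == 2:  # single subject convenience
            self.values = self.values[None]
        if self.values.ndim != 3:
            raise ValueError("values must be subjects x regions x timepoints")
        if np.isnan(self.values).any():
            raise ValueError("time series contain missing values")
        if self.values.shape[2] < 32:
            raise ValueError("need at least 32 timepoints")
        if self.values.shape[1] != len(self.region_ids):
            raise ValueError("region_ids length does not match values")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]


@dataclass
class ConnectivityMatrix:
    """Symmetric region x region correlation matrix (unit diagonal)."""

    r: np.ndarray
    region_ids: list
    scales: tuple
    subject_id: str = "group-mean"

    def __post_init__(self):
        self.r = np.asarray(self.r, float)
        n = self.r.shape[0]
        if self.r.shape != (n, n):
            raise ValueError("correlation matrix must be square")
        if n != len(self.region_ids):
            raise ValueError("region_ids length does not match matrix")
        if not np.allclose(self.r, self.r.T, atol=1e-8):
            raise ValueError("correlation matrix must be symmetric")
        if np.nanmax(np.abs(self.r)) > 1 + 1e-8:
            raise ValueError("correlations must lie in [-1, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=self.region_ids, columns=self.region_ids)


@dataclass
class BinaryGraph:
    """Undirected, unweighted, connected graph with per-edge lengths."""

    adjacency: np.ndarray
    region_ids: list
    coords: np.ndarray
    density: float
    edges: pd.DataFrame  # region_i, region_j, r, length_mm
    warnings: list = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum() // 2)

    def to_networkx(self):
        import networkx as nx

        G = nx.from_numpy_array(self.adjacency.astype(int))
        nx.relabel_nodes(G, dict(enumerate(self.region_ids)), copy=False)
        return G

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(int)


def scale_band(tr_seconds: float, scale: int) -> tuple[float, float]:
    """Frequency band (Hz) of a dyadic wavelet scale at sampling interval TR.

    Scale j covers [1 / (2**(j+1) TR), 1 / (2**j TR)]; incrementing the
    scale halves both band edges.
    """
    if tr_seconds <= 0:
        raise ValueError("tr_seconds must be positive")
    if scale < 1:
        raise ValueError("scale must be >= 1")
    return 1.0 / (2 ** (scale + 1) * tr_seconds), 1.0 / (2**scale * tr_seconds)


def _modwt_details(x: np.ndarray, scales: tuple) -> list[np.ndarray]:
    """Per-scale detail coefficients of the undecimated DWT (db4).

    The series is reflection-padded to the dyadic length `swt` requires
    and coefficients are cropped back to the original support.
    """
    max_scale = max(scales)
    n = x.shape[-1]
    block = 2**max_scale
    pad = (-n) % block
    if pad:
        x = np.concatenate([x, x[..., ::-1][..., :pad]], axis=-1)
    coeffs = pywt.swt(x, WAVELET, level=max_scale, axis=-1, trim_approx=True, norm=True)
    # coeffs = [cA_max, cD_max, cD_{max-1}, ..., cD_1]
    return [np.asarray(coeffs[max_scale - s + 1])[..., :n] for s in scales]


def wavelet_correlation(
    ts: TimeSeriesSet,
    scales: tuple = DEFAULT_SCALES,
    pool: bool = True,
) -> list:
    """Per-subject wavelet correlation matrices.

    With ``pool=True`` (default) coefficients of the requested scales are
    concatenated before correlating, yielding one matrix per subject
    spanning the whole band; with ``pool=False`` a dict of per-scale
    matrices is returned per subject.
    """
    if not scales:
        raise ValueError("scales must be nonempty")
    scales = tuple(sorted(int(s) for s in scales))
    need = 2 ** (max(scales) + 2)
    if ts.values.shape[2] < need:
        raise ValueError(f"need >= {need} timepoints for scale {max(scales)}, got {ts.values.shape[2]}")

    sd = ts.values.std(axis=2)
    flat = np.argwhere(sd == 0)
    if flat.size:
        s, r = flat[0]
        raise ValueError(f"constant time series for region {ts.region_ids[r]!r} (subject index {s})")

    out = []
    for s in range(ts.n_subjects):
        details = _modwt_details(ts.values[s], scales)
        if pool:
            pooled = np.concatenate(details, axis=-1)
            out.append(ConnectivityMatrix(_corr(pooled), ts.region_ids, scales, subject_id=f"subject{s:03d}"))
        else:
            out.append(
                {
                    sc: ConnectivityMatrix(_corr(d), ts.region_ids, (sc,), subject_id=f"subject{s:03d}")
                    for sc, d in zip(scales, details)
                }
            )
    return out


def _corr(rows: np.ndarray) -> np.ndarray:
    r = np.corrcoef(rows)
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return (r + r.T) / 2


def group_mean_matrix(mats: list[ConnectivityMatrix]) -> ConnectivityMatrix:
    """Element-wise mean correlation matrix over subjects, tagged group-mean.

    The diagonal is forced back to exactly 1 by convention.
    """
    if not mats:
        raise ValueError("empty matrix list")
    ids, scales = mats[0].region_ids, mats[0].scales
    for m in mats[1:]:
        if m.region_ids != ids:
            raise ValueError("matrices cover different region sets")
        if m.scales != scales:
            raise ValueError("matrices computed at different wavelet scales")
    mean = np.mean([m.r for m in mats], axis=0)
    np.fill_diagonal(mean, 1.0)
    return ConnectivityMatrix(mean, ids, scales, subject_id="group-mean")


def target_edge_count(n: int, density: float) -> int:
    """Edges at a connection density, rounding half away from zero; never
    fewer than the n-1 edges a spanning tree needs."""
    possible = n * (n - 1) // 2
    return max(n - 1, int(np.floor(density * possible + 0.5)))


def build_graph(mat: ConnectivityMatrix, density: float, coords: np.ndarray) -> BinaryGraph:
    """MST-anchored binary graph at a target connection density.

    The minimum spanning tree of (1 - r) edge weights guarantees a
    connected graph; remaining node pairs are then superimposed in order
    of decreasing signed correlation (ties broken lexicographically by
    region index) until the target edge count is reached. Per-edge
    Euclidean lengths come from the region centroids.
    """
    if not (0 <= density <= 1):
        raise ValueError("density must lie in [0, 1]")
    r = mat.r
    n = r.shape[0]
    coords = np.asarray(coords, float)
    if coords.shape != (n, 3):
        raise ValueError("coords must be n_regions x 3")

    target = target_edge_count(n, density)
    warn_records = []
    if density * n * (n - 1) / 2 < n - 1:
        msg = f"density {density} implies fewer than n-1 edges; returning the MST only"
        warn_records.append(msg)
        warnings.warn(msg, stacklevel=2)

    # MST on weights 2 - r: strictly positive (so sparse zeros are safe)
    # and monotone in -r, hence the same tree as 1 - r.
    mst = minimum_spanning_tree(csr_matrix(np.triu(2.0 - r, k=1)))
    adj = np.zeros((n, n), dtype=bool)
    mi, mj = mst.nonzero()
    adj[mi, mj] = adj[mj, mi] = True

    n_mst = len(mi)
    if target > n_mst:
        iu, ju = np.triu_indices(n, k=1)
        free = ~adj[iu, ju]
        iu, ju, rv = iu[free], ju[free], r[iu, ju][free]
        order = np.lexsort((ju, iu, -rv))  # by -r, then (i, j)
        extra = target - n_mst
        sel = order[:extra]
        adj[iu[sel], ju[sel]] = adj[ju[sel], iu[sel]] = True

    ei, ej = np.nonzero(np.triu(adj, k=1))
    lengths = np.linalg.norm(coords[ei] - coords[ej], axis=1)
    edges = pd.DataFrame(
        {
            "region_i": [mat.region_ids[i] for i in ei],
            "region_j": [mat.region_ids[j] for j in ej],
            "r": r[ei, ej],
            "length_mm": lengths,
        }
    )
    return BinaryGraph(
        adjacency=adj,
        region_ids=list(mat.region_ids),
        coords=coords,
        density=density,
        edges=edges,
        warnings=warn_records,
    )


def distance_matrix(coords: np.ndarray) -> np.ndarray:
    return cdist(coords, coords)
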