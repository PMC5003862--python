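"""Synthetic data with planted, recoverable ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes in real resting-state fMRI + microarray data:

* spatially embedded modular connectivity — regions form isotropic
  Gaussian clusters of centroids inside a brain-scale box, and regions
  in the same module share a common signal, so modules are both
  topological and spatial clusters (the distance/modularity confound
  the analysis has to live with);
* designated inter-modular hubs that couple to the factors of several
  modules and therefore acquire high inter-modular degree;
* distance-dependent local coupling, so nearby regions correlate above
  and beyond module membership;
* low-rank gene expression: two planted components whose regional
  patterns are tied to nodal network metrics (component 1 to high
  intra-modular degree and short connection distance, component 2 to
  high inter-modular degree and long connection distance), buried in a
  spatially autocorrelated noise field;
* GMT annotation in which a few terms are enriched for the planted
  signal genes and the rest are uniform background.

Everything is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic study.

    Defaults are the study conditions the package is verified under:
    200 cortical regions in 8 modules observed in 38 subjects, ~10 min
    of BOLD at TR = 2.42 s, 5000 genes with two planted expression
    components of 100 signal genes each at signal-to-noise 2.
    """

    n_regions: int = 200
    n_modules: int = 8
    n_subjects: int = 38
    n_timepoints: int = 256
    tr_seconds: float = 2.42
    p_in: float = 0.8
    p_out: float = 0.1
    n_hubs: int = 16
    distance_decay: float = 20.0  # mm
    n_genes: int = 5000
    n_signal_genes_per_component: int = 100
    effect_size: float = 2.0
    spatial_corr_length: float = 5.0  # mm
    n_terms: int = 40
    term_size: int = 20
    seed: int = 0
    box_size: float = 150.0  # mm, side of the bounding box
    cluster_sd: float = 12.0  # mm, spread of centroids around module centres

    def validate(self) -> None:
        counts = dict(
            n_regions=self.n_regions,
            n_modules=self.n_modules,
            n_subjects=self.n_subjects,
            n_timepoints=self.n_timepoints,
            n_genes=self.n_genes,
            n_signal_genes_per_component=self.n_signal_genes_per_component,
            n_terms=self.n_terms,
            term_size=self.term_size,
        )
        for name, v in counts.items():
            if v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
        if self.n_modules < 1:
            raise ValueError("n_modules must be >= 1")
        if self.n_modules > self.n_regions:
            raise ValueError("n_modules may not exceed n_regions")
        if self.n_hubs >= self.n_regions:
            raise ValueError("n_hubs must be smaller than n_regions")
        if self.n_hubs < 0:
            raise ValueError("n_hubs must be non-negative")
        if not (self.p_in >= self.p_out >= 0):
            raise ValueError("require p_in >= p_out >= 0")
        if self.n_modules >= 2 and self.p_out > 0 and self.p_in <= self.p_out:
            raise ValueError("require p_in > p_out for a modular network")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")


@dataclass
class GroundTruth:
    """What the generator planted, for recovery checks."""

    module_labels: np.ndarray  # per region, 1..M
    hub_region_ids: list
    block_labels: np.ndarray  # spatially contiguous groups (== spatial clusters)
    gene_weights: dict = field(default_factory=dict)  # component -> vector over genes
    planted_term_ids: list = field(default_factory=list)

    def to_json(self) -> dict:
        return {
            "module_labels": self.module_labels.tolist(),
            "hub_region_ids": list(self.hub_region_ids),
            "block_labels": self.block_labels.tolist(),
            "gene_weights": {str(k): v.tolist() for k, v in self.gene_weights.items()},
            "planted_term_ids": list(self.planted_term_ids),
        }


def _module_centres(rng: np.random.Generator, cfg: SyntheticConfig) -> np.ndarray:
    """Rejection-sample well-separated module centres in one hemisphere
    (x > 0 half of the box); each module's second, mirrored cluster sits
    at the x-flipped location."""
    half = cfg.box_size / 2
    min_sep = 3.0 * cfg.cluster_sd
    lo = np.array([0.15 * half, -half, -half])
    hi = np.array([half, half, half])
    centres: list[np.ndarray] = []
    attempts = 0
    while len(centres) < cfg.n_modules:
        c = rng.uniform(lo, hi)
        if all(np.linalg.norm(c - o) >= min_sep for o in centres):
            centres.append(c)
        attempts += 1
        if attempts > 20000:
            # box too crowded for the separation target; relax it
            min_sep *= 0.8
            attempts = 0
    return np.array(centres)


def generate_regions(cfg: SyntheticConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Place region centroids as bilateral pairs of Gaussian clusters.

    Each module owns two mirrored spatial clusters, one per hemisphere
    (sign-flipped x), as cortical systems do; intra-modular edges
    therefore include long inter-hemispheric connections between
    homologous clusters, so connection distance is not a mere proxy for
    inter-modular degree. Returns a region table (region_id, x, y, z,
    class, block, module) and the ground truth. Module sizes are as
    equal as possible; hubs are drawn across modules in round-robin
    order so every module contributes hubs. Block labels are the 2M
    hemisphere clusters — spatially contiguous groups for the block
    permutation test. The synthetic cytoarchitectonic class cycles over
    seven labels with module, mimicking the association between
    histology and module membership seen in cortex.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    centres = _module_centres(rng, cfg)
    module_labels = np.array([(i % cfg.n_modules) + 1 for i in range(cfg.n_regions)])
    module_labels.sort()
    # alternate hemispheres within each module
    hemi = np.empty(cfg.n_regions, dtype=int)
    for m in range(1, cfg.n_modules + 1):
        members = np.flatnonzero(module_labels == m)
        hemi[members] = np.resize([1, -1], len(members))
    base = centres[module_labels - 1] * np.stack([hemi, np.ones_like(hemi), np.ones_like(hemi)], axis=1)
    coords = base + rng.normal(0.0, cfg.cluster_sd, size=(cfg.n_regions, 3))

    region_ids = [f"R{i:04d}" for i in range(cfg.n_regions)]
    classes = [f"class{((m - 1) % 7) + 1}" for m in module_labels]
    block_labels = np.array([f"B{m:02d}{'R' if h > 0 else 'L'}" for m, h in zip(module_labels, hemi)])

    # hubs: round-robin over modules so cross-module couplers are spread out
    hubs: list[int] = []
    by_module = {m: list(np.flatnonzero(module_labels == m)) for m in range(1, cfg.n_modules + 1)}
    for m in by_module:
        rng.shuffle(by_module[m])
    m_cycle = 0
    while len(hubs) < cfg.n_hubs:
        m = (m_cycle % cfg.n_modules) + 1
        if by_module[m]:
            hubs.append(int(by_module[m].pop()))
        m_cycle += 1

    regions = pd.DataFrame(
        {
            "region_id": region_ids,
            "x": coords[:, 0],
            "y": coords[:, 1],
            "z": coords[:, 2],
            "class": classes,
            "block": block_labels,
            "module": module_labels,
        }
    )
    truth = GroundTruth(
        module_labels=module_labels.copy(),
        hub_region_ids=[region_ids[i] for i in sorted(hubs)],
        block_labels=block_labels.copy(),
    )
    return regions, truth


def generate_time_series(regions: pd.DataFrame, truth: GroundTruth, cfg: SyntheticConfig):
    """Simulate BOLD-like regional signals with the planted correlation structure.

    Per subject, each region's signal is a weighted sum of module
    factors (own module weight p_in, other modules p_out; hubs couple
    to foreign modules at (p_in + p_out)/2), plus a distance-decaying
    shared local field, plus unit-variance independent noise. Each
    region's own-module coupling carries a fixed multiplicative gain
    (uniform on [0.5, 1.5]) so intra-modular degree varies within a
    module independently of spatial position, giving the broad degree
    distribution seen in real functional networks.
    """
    from .connectivity import TimeSeriesSet

    cfg.validate()
    if cfg.n_timepoints < 32:
        raise ValueError("n_timepoints must be >= 32 (scale-3 wavelet correlation needs 2**5 samples)")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    n, T, M = cfg.n_regions, cfg.n_timepoints, cfg.n_modules
    coords = regions[["x", "y", "z"]].to_numpy(float)
    labels = truth.module_labels
    hub_idx = regions.index[regions["region_id"].isin(truth.hub_region_ids)].to_numpy()

    # region-by-module coupling weights; a per-region gain scales both
    # intra- and inter-module coupling (hubness is a graded regional
    # property, not a hub-only switch), with designated hubs on top
    gain = rng.uniform(0.5, 1.5, size=n)
    W = np.full((n, M), cfg.p_out) * gain[:, None]
    W[np.arange(n), labels - 1] = cfg.p_in * gain
    hub_w = 0.5 * (cfg.p_in + cfg.p_out)
    for i in hub_idx:
        foreign = np.arange(M) != (labels[i] - 1)
        W[i, foreign] = hub_w * gain[i]

    # distance-decaying mixing kernel for the shared local field
    D = cdist(coords, coords)
    if cfg.distance_decay > 0:
        K = np.exp(-D / cfg.distance_decay)
        K /= np.linalg.norm(K, axis=1, keepdims=True)
    else:
        K = np.eye(n)
    local_amp = 0.3

    values = np.empty((cfg.n_subjects, n, T))
    for s in range(cfg.n_subjects):
        factors = rng.standard_normal((M, T))
        local = K @ rng.standard_normal((n, T))
        noise = rng.standard_normal((n, T))
        values[s] = W @ factors + local_amp * local + noise
    return TimeSeriesSet(values=values, tr_seconds=cfg.tr_seconds, region_ids=list(regions["region_id"]))


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot standardize a constant vector")
    return (v - v.mean()) / sd


def planted_patterns(metrics: pd.DataFrame) -> dict[int, np.ndarray]:
    """Regional patterns the two expression components follow.

    Component 1 tracks intra-modular hubness with short wiring
    (z(k_intra) - z(d)); component 2 tracks inter-modular hubness with
    long wiring (z(k_inter) + z(d)). Each pattern is re-standardized.
    """
    p1 = _standardize(metrics["k_intra"].to_numpy(float)) - _standardize(metrics["d"].to_numpy(float))
    p2 = _standardize(metrics["k_inter"].to_numpy(float)) + _standardize(metrics["d"].to_numpy(float))
    return {1: _standardize(p1), 2: _standardize(p2)}


# Planted weight magnitudes per component. The mild asymmetry fixes the
# component order (strongest covariance first) and breaks the exact
# rotational degeneracy of the cross-covariance SVD that equal planted
# strengths would leave.
_COMPONENT_AMPLITUDE = {1: 1.3, 2: 1.0}


def generate_expression(
    regions: pd.DataFrame,
    metrics: pd.DataFrame,
    cfg: SyntheticConfig,
    truth: GroundTruth | None = None,
) -> tuple[pd.DataFrame, GroundTruth, dict]:
    """Plant two low-rank expression components in spatially smooth noise.

    expression = effect_size * sum_c w_c (x) pattern_c + noise, where the
    noise field is i.i.d. Gaussian mixed through a distance kernel of
    length spatial_corr_length (rows re-normalized, so each gene keeps
    unit noise variance). Also emits a GMT annotation with two planted
    terms per component drawn from that component's signal genes, plus
    uniform background terms, and two 19-gene candidate sets (one drawn
    from component-2 signal genes, mirroring a supragranular-enriched
    set; one uniform control).

    Returns (genes x regions raw expression, updated GroundTruth,
    annotation dict with keys 'annotation' and 'gene_sets').
    """
    cfg.validate()
    n_sig = cfg.n_signal_genes_per_component
    if 2 * n_sig > cfg.n_genes:
        raise ValueError("need n_genes >= 2 * n_signal_genes_per_component")
    if truth is None:
        truth = GroundTruth(
            module_labels=regions["module"].to_numpy(),
            hub_region_ids=[],
            block_labels=regions["module"].to_numpy(),
        )
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    n, g = cfg.n_regions, cfg.n_genes
    genes = [f"G{i:05d}" for i in range(g)]
    patterns = planted_patterns(metrics)

    perm = rng.permutation(g)
    signal_idx = {1: np.sort(perm[:n_sig]), 2: np.sort(perm[n_sig : 2 * n_sig])}
    weights = {}
    for c in (1, 2):
        w = np.zeros(g)
        w[signal_idx[c]] = _COMPONENT_AMPLITUDE[c] * (1.0 + 0.2 * rng.standard_normal(n_sig))
        weights[c] = w

    coords = regions[["x", "y", "z"]].to_numpy(float)
    if cfg.spatial_corr_length > 0:
        D = cdist(coords, coords)
        K = np.exp(-D / cfg.spatial_corr_length)
        K /= np.linalg.norm(K, axis=1, keepdims=True)
        noise = rng.standard_normal((g, n)) @ K.T
    else:
        noise = rng.standard_normal((g, n))

    signal = sum(np.outer(weights[c], patterns[c]) for c in (1, 2))
    expr = cfg.effect_size * signal + noise
    expr_df = pd.DataFrame(expr, index=genes, columns=list(regions["region_id"]))

    annotation, planted_terms = _make_annotation(rng, genes, signal_idx, cfg)
    gene_sets = _make_candidate_sets(rng, genes, signal_idx)

    truth = replace(truth, gene_weights=dict(weights), planted_term_ids=planted_terms)
    return expr_df, truth, {"annotation": annotation, "gene_sets": gene_sets}


def _make_annotation(rng, genes, signal_idx, cfg):
    """Two planted terms per component from its signal genes; the rest uniform."""
    annotation: dict[str, dict] = {}
    planted: list[str] = []
    for c in (1, 2):
        for rep in (1, 2):
            size = min(cfg.term_size, len(signal_idx[c]))
            pick = rng.choice(signal_idx[c], size=size, replace=False)
            term = f"PLANTED_C{c}_{rep}"
            annotation[term] = {
                "description": f"planted term enriched in component-{c} signal genes",
                "genes": [genes[i] for i in np.sort(pick)],
            }
            planted.append(term)
    n_background = max(cfg.n_terms - len(planted), 0)
    for t in range(n_background):
        pick = rng.choice(len(genes), size=cfg.term_size, replace=False)
        annotation[f"BG_{t:03d}"] = {
            "description": "background term, uniform draw",
            "genes": [genes[i] for i in np.sort(pick)],
        }
    return annotation, planted


def _make_candidate_sets(rng, genes, signal_idx, size=19):
    hub_pick = rng.choice(signal_idx[2], size=min(size, len(signal_idx[2])), replace=False)
    ctrl_pick = rng.choice(len(genes), size=size, replace=False)
    return {
        "HUB_SET": {
            "description": "synthetic candidate set drawn from component-2 (inter-modular hub) signal genes",
            "genes": [genes[i] for i in np.sort(hub_pick)],
        },
        "CONTROL_SET": {
            "description": "synthetic control set, uniform draw",
            "genes": [genes[i] for i in np.sort(ctrl_pick)],
        },
    }


def morans_i(values: np.ndarray, coords: np.ndarray) -> float:
    """Moran's I with inverse-distance weights (diagnostic for spatial
    autocorrelation of an expression profile)."""
    n = len(values)
    D = cdist(coords, coords)
    with np.errstate(divide="ignore"):
        W = 1.0 / D
    np.fill_diagonal(W, 0.0)
    z = values - values.mean()
    num = n * float(z @ W @ z)
    den = W.sum() * float(z @ z)
    return num / den
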