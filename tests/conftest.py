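import numpy as np
import pandas as pd
import pytest

import hubgenes as hg


@pytest.fixture(scope="session")
def small_cfg():
    """Small but fully structured synthetic study (fast)."""
    return hg.SyntheticConfig(
        n_regions=60,
        n_modules=4,
        n_subjects=4,
        n_timepoints=64,
        n_genes=300,
        n_signal_genes_per_component=30,
        n_hubs=8,
        n_terms=12,
        term_size=10,
        seed=1,
    )


@pytest.fixture(scope="session")
def small_study(small_cfg):
    """Generated small study up to nodal metrics and expression."""
    regions, truth = hg.generate_regions(small_cfg)
    ts = hg.generate_time_series(regions, truth, small_cfg)
    mats = hg.wavelet_correlation(ts)
    group = hg.group_mean_matrix(mats)
    coords = regions[["x", "y", "z"]].to_numpy(float)
    graph = hg.build_graph(group, 0.10, coords)
    partition = hg.consensus_partition(graph, gamma=1.0, n_runs=20, seed=3)
    metrics = hg.nodal_metrics(graph, partition)
    expr, truth, sets = hg.generate_expression(regions, metrics, small_cfg, truth)
    from hubgenes.transcriptome import zscore

    return {
        "cfg": small_cfg,
        "regions": regions,
        "truth": truth,
        "ts": ts,
        "group": group,
        "coords": coords,
        "graph": graph,
        "partition": partition,
        "metrics": metrics,
        "expression_raw": expr,
        "T": zscore(expr),
        "C": hg.response_matrix(metrics),
        "annotation": sets["annotation"],
        "gene_sets": sets["gene_sets"],
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_binary_graph(rng, n, density=0.2, coords=None):
    """Random connected BinaryGraph via the package's own builder."""
    from hubgenes.connectivity import ConnectivityMatrix, build_graph

    r = rng.uniform(-1, 1, size=(n, n))
    r = (r + r.T) / 2
    np.fill_diagonal(r, 1.0)
    mat = ConnectivityMatrix(r, [f"R{i:03d}" for i in range(n)], scales=(2, 3))
    if coords is None:
        coords = rng.uniform(-50, 50, size=(n, 3))
    return build_graph(mat, density, coords)
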