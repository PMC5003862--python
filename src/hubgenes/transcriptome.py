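"""Assembly of the gene x region expression matrix T.

Mirrors the standard microarray-to-parcellation workflow: average
probes into genes, match each region centroid to the nearest expression
sample (per donor, with hemispheric mirroring), average over donors and
hemispheres, Z-score each gene across regions, and drop regions whose
expression profile is an outlier. The fixed pipeline order is
collapse -> match -> average -> Z-score -> outlier-exclude -> re-Z-score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)


@dataclass
class SampleExpression:
    """Probe-level expression with sample geometry.

    expr: probe x sample (log2 intensity); probe_map: probe -> gene
    symbol (NaN/None = unmapped); samples: table with sample_id, x, y,
    z, donor (coordinates in the same mm space as the region table).
    """

    expr: pd.DataFrame
    probe_map: pd.Series
    samples: pd.DataFrame

    def __post_init__(self):
        if not np.isfinite(self.samples[["x", "y", "z"]].to_numpy(float)).all():
            raise ValueError("sample coordinates must be finite")
        missing = [p for p in self.expr.index if p not in self.probe_map.index]
        if missing:
            raise ValueError(f"probes absent from the probe map: {missing[:5]}...")


def collapse_probes(se: SampleExpression) -> pd.DataFrame:
    """Average probes of the same gene; drop unmapped probes (logged)."""
    gene_of = se.probe_map.reindex(se.expr.index)
    keep = gene_of.notna()
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropping %d probes without a gene symbol", n_dropped)
    if keep.sum() == 0:
        raise ValueError("no probes are mapped to gene symbols")
    return se.expr.loc[keep].groupby(gene_of[keep]).mean()


def match_regions(
    regions: pd.DataFrame,
    gene_by_sample: pd.DataFrame,
    samples: pd.DataFrame,
    max_distance: float | None = None,
    mirror: bool = True,
    radius: float | None = None,
) -> tuple[pd.DataFrame, list]:
    """Assign each region the expression of its nearest sample(s).

    For every region centroid (and, with ``mirror=True``, its
    x-mirrored twin, matching homologous regions in both hemispheres)
    the nearest sample of each donor under Euclidean distance is
    selected — ties broken by lower sample id — and expression is
    averaged over donors and hemispheres. With ``radius`` set, all of a
    donor's samples within that distance are averaged instead of the
    single nearest. Regions farther than ``max_distance`` from every
    sample are flagged unmatched and excluded from the output.

    Returns (gene x region matrix, list of unmatched region ids).
    """
    sample_xyz = samples[["x", "y", "z"]].to_numpy(float)
    sample_ids = list(samples["sample_id"])
    order = np.argsort(sample_ids)  # deterministic tie-break by sample id
    donors = samples["donor"].to_numpy()
    region_xyz = regions[["x", "y", "z"]].to_numpy(float)

    out = {}
    unmatched = []
    for ridx, rid in enumerate(regions["region_id"]):
        targets = [region_xyz[ridx]]
        if mirror:
            targets.append(region_xyz[ridx] * np.array([-1.0, 1.0, 1.0]))
        dists = cdist(np.array(targets), sample_xyz)  # targets x samples
        if max_distance is not None and dists.min() > max_distance:
            unmatched.append(rid)
            logger.warning("region %s unmatched: nearest sample at %.1f mm", rid, dists.min())
            continue
        profiles = []
        for t in range(dists.shape[0]):
            for donor in pd.unique(donors):
                mask = donors == donor
                dd = dists[t][mask]
                ids_d = np.array(sample_ids, dtype=object)[mask]
                if radius is not None:
                    chosen = ids_d[dd <= radius]
                    if len(chosen) == 0:
                        continue
                else:
                    pos = np.flatnonzero(dd == dd.min())
                    chosen = [sorted(ids_d[pos])[0]]
                profiles.append(gene_by_sample.loc[:, list(chosen)].mean(axis=1))
        out[rid] = pd.concat(profiles, axis=1).mean(axis=1)
    if not out:
        raise ValueError("no region could be matched to any sample")
    return pd.DataFrame(out), unmatched


def zscore(T_raw: pd.DataFrame) -> pd.DataFrame:
    """Z-score each gene across regions (sample sd); zero-variance genes
    are dropped with a log entry."""
    if T_raw.shape[1] < 2:
        raise ValueError("Z-scoring needs at least two regions")
    sd = T_raw.std(axis=1, ddof=1)
    flat = sd == 0
    if flat.any():
        logger.info("dropping %d zero-variance genes", int(flat.sum()))
        T_raw = T_raw.loc[~flat]
        sd = sd.loc[~flat]
    return T_raw.sub(T_raw.mean(axis=1), axis=0).div(sd, axis=0)


def exclude_outlier_regions(
    T: pd.DataFrame, threshold: float = 3.0, max_fraction: float = 0.2
) -> tuple[pd.DataFrame, list]:
    """Drop regions whose expression profile is an outlier, then re-Z-score.

    A region is flagged when its mean correlation with all other
    regions' profiles falls below median - threshold * IQR of those mean
    correlations (scale-free and robust). Flagging more than
    ``max_fraction`` of regions raises, since that points to an
    upstream mismatch rather than a few bad regions.
    """
    corr = np.corrcoef(T.to_numpy(float).T)
    n = corr.shape[0]
    mean_r = (corr.sum(axis=1) - 1.0) / (n - 1)
    med = np.median(mean_r)
    q75, q25 = np.percentile(mean_r, [75, 25])
    iqr = q75 - q25
    cut = med - threshold * iqr
    flagged = np.flatnonzero(mean_r < cut)
    excluded = [T.columns[i] for i in flagged]
    if len(excluded) > max_fraction * n:
        raise ValueError(
            f"{len(excluded)} of {n} regions flagged as expression outliers; "
            "check the region/sample matching"
        )
    if not excluded:
        return T.copy(), []
    logger.info("excluding outlier regions: %s", excluded)
    kept = T.drop(columns=excluded)
    return zscore(kept), excluded


def assemble_expression_matrix(
    se: SampleExpression,
    regions: pd.DataFrame,
    max_distance: float | None = None,
    mirror: bool = True,
    outlier_threshold: float = 3.0,
) -> tuple[pd.DataFrame, dict]:
    """Full assembly: collapse -> match -> Z-score -> outlier-exclude.

    Returns the final gene x region matrix T and a report of dropped
    probes/genes/regions with matrix dimensions after each step.
    """
    report: dict = {}
    by_gene = collapse_probes(se)
    report["after_collapse"] = list(by_gene.shape)
    matched, unmatched = match_regions(regions, by_gene, se.samples, max_distance=max_distance, mirror=mirror)
    report["unmatched_regions"] = unmatched
    report["after_match"] = list(matched.shape)
    T = zscore(matched)
    report["after_zscore"] = list(T.shape)
    T, excluded = exclude_outlier_regions(T, threshold=outlier_threshold)
    report["excluded_outlier_regions"] = excluded
    report["final"] = list(T.shape)
    logger.info("expression assembly: %s", report)
    return T, report
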