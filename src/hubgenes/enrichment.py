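"""Ranked-gene-list enrichment and candidate-set permutation tests.

The ranked test is threshold-free: for each annotation term it takes
the minimum hypergeometric tail (mHG) over all cutoffs of the ranking,
then converts that minimum into a term-level p value — exactly, by a
path-counting dynamic programme over the rank/annotation grid, when the
grid is small enough, and by a Bonferroni bound over the candidate
cutoffs otherwise. Both ends of the ranking (most positively and most
negatively weighted genes) are tested, term p values are BH-FDR
corrected within each direction, and terms are flagged (not deleted)
when they are very large or fail the FDR threshold.

The candidate-set test compares the mean bootstrap Z of an a-priori
gene set (e.g. supragranular-enriched genes) with the mean Z of
uniformly drawn same-size sets.
"""

from __future__ import annotations

import logging
import math
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

# exact mHG p when the DP grid N*(K+1) is at most this many cells
EXACT_GRID_LIMIT = 500_000


def _log_hypergeom_pmf_grid(N: int, K: int) -> np.ndarray:
    """log PMF of drawing b successes in the first n ranks, for the full
    grid n = 0..N, b = 0..K (impossible cells are -inf)."""
    n = np.arange(N + 1)[:, None]
    b = np.arange(K + 1)[None, :]
    with np.errstate(invalid="ignore"):
        lp = (
            gammaln(K + 1)
            - gammaln(b + 1)
            - gammaln(K - b + 1)
            + gammaln(N - K + 1)
            - gammaln(n - b + 1)
            - gammaln(N - K - (n - b) + 1)
            + gammaln(n + 1)
            + gammaln(N - n + 1)
            - gammaln(N + 1)
        )
    invalid = (b > n) | ((n - b) > (N - K))
    lp = np.where(invalid, -np.inf, lp)
    return lp


def _log_tail_grid(N: int, K: int) -> np.ndarray:
    """log P(X >= b) for hypergeometric(N, K, n) over the full (n, b) grid."""
    lp = _log_hypergeom_pmf_grid(N, K)
    # reversed cumulative logsumexp along the b axis
    rev = lp[:, ::-1]
    acc = np.logaddexp.accumulate(rev, axis=1)
    return acc[:, ::-1]


def hypergeom_tail(N: int, K: int, n: int, k: int) -> float:
    """Upper tail P(X >= k) of hypergeometric(N, K, n), in log space.

    N genes total, K annotated, n drawn (top of the ranking), k of the
    drawn annotated.
    """
    if not (0 <= k <= min(K, n) and K <= N and n <= N and K >= 0 and n >= 0):
        raise ValueError(f"inconsistent hypergeometric counts N={N}, K={K}, n={n}, k={k}")
    if k == 0:
        return 1.0
    xs = np.arange(k, min(K, n) + 1)
    logs = (
        gammaln(K + 1)
        - gammaln(xs + 1)
        - gammaln(K - xs + 1)
        + gammaln(N - K + 1)
        - gammaln(n - xs + 1)
        - gammaln(N - K - n + xs + 1)
        + gammaln(n + 1)
        + gammaln(N - n + 1)
        - gammaln(N + 1)
    )
    m = logs.max()
    return float(min(1.0, np.exp(m) * np.exp(logs - m).sum()))


def mhg_statistic(membership: np.ndarray) -> tuple[float, int, int]:
    """Minimum hypergeometric tail over all cutoffs of a ranked list.

    ``membership`` is a boolean vector in rank order (True = annotated).
    The minimum over cutoffs n = 1..N-1 is attained at a cutoff ending
    with an annotated gene, so only those are evaluated.
    Returns (s_star, best_cutoff, successes_at_cutoff).
    """
    membership = np.asarray(membership, bool)
    N = len(membership)
    K = int(membership.sum())
    if K == 0:
        return 1.0, 0, 0
    positions = np.flatnonzero(membership)  # 0-based rank of each annotated gene
    best = (1.0, 0, 0)
    for j, pos in enumerate(positions, start=1):
        n = int(pos) + 1
        if n >= N:
            break
        tail = hypergeom_tail(N, K, n, j)
        if tail < best[0]:
            best = (tail, n, j)
    return best


def _mhg_pvalue_exact(N: int, K: int, s_star: float) -> float:
    """Exact P(mHG <= s_star) by big-integer path counting.

    Counts the orderings whose rank/annotation walk never enters a cell
    with hypergeometric tail <= s_star (cutoffs 1..N-1), as a fraction
    of C(N, K).
    """
    log_tail = _log_tail_grid(N, K)
    thresh = math.log(s_star) + 1e-9 if s_star > 0 else -np.inf
    forbidden = log_tail <= thresh
    forbidden[0, :] = False  # n = 0 not a cutoff
    forbidden[N, :] = False  # n = N not a cutoff

    prev = [0] * (K + 1)
    prev[0] = 1
    for n in range(1, N + 1):
        cur = [0] * (K + 1)
        bmax = min(n, K)
        bmin = max(0, n - (N - K))
        for b in range(bmin, bmax + 1):
            if forbidden[n][b]:
                continue
            total = 0
            if b <= min(n - 1, K) and b >= max(0, (n - 1) - (N - K)):
                total += prev[b]
            if b > 0:
                total += prev[b - 1]
            cur[b] = total
        prev = cur
    allowed = prev[K]
    return float(1 - Fraction(allowed, math.comb(N, K)))


def mhg_pvalue(N: int, K: int, s_star: float) -> float:
    """Term-level p for an observed mHG statistic.

    Exact dynamic programme when the N x (K+1) grid is tractable
    (covers whole-matrix runs up to 5000 genes at realistic term
    sizes); otherwise the Bonferroni bound over the K candidate cutoffs
    (those ending at an annotated gene), capped at 1.
    """
    if K == 0 or s_star >= 1.0:
        return 1.0
    if N * (K + 1) <= EXACT_GRID_LIMIT:
        return _mhg_pvalue_exact(N, K, s_star)
    return min(1.0, K * s_star)


def _ranking_genes(ranking) -> list:
    """Accept a bootstrap-ranking DataFrame (gene/z/rank) or a plain
    sequence of genes already in rank order."""
    if isinstance(ranking, pd.DataFrame):
        if "rank" in ranking.columns:
            return list(ranking.sort_values("rank")["gene"])
        return list(ranking["gene"])
    return list(ranking)


def ranked_enrichment(
    ranking,
    annotation: dict[str, dict],
    fdr_threshold: float = 0.001,
    max_term_genes: int = 2500,
) -> pd.DataFrame:
    """mHG enrichment of every annotation term at both ends of a ranking.

    Annotation genes absent from the ranking are dropped (logged). The
    output has one row per term and direction ('pos' = top of the
    ranking, 'neg' = reversed list), with the mHG statistic, exact or
    Bonferroni p, BH-FDR within direction, the optimal rank cutoff, the
    overlapping genes at that cutoff, and two flags: ``large_term``
    (more annotated genes than ``max_term_genes``, a visualization-only
    filter) and ``significant`` (P_FDR below ``fdr_threshold``).
    Flagged terms are retained in the table, never deleted.
    """
    if not annotation:
        raise ValueError("empty annotation")
    genes = _ranking_genes(ranking)
    index = {g: i for i, g in enumerate(genes)}
    N = len(genes)

    rows = []
    for direction in ("pos", "neg"):
        pos_of = index if direction == "pos" else {g: N - 1 - i for g, i in index.items()}
        for term, rec in annotation.items():
            present = [g for g in rec["genes"] if g in index]
            dropped = len(rec["genes"]) - len(present)
            if dropped:
                logger.info("term %s: %d annotated genes absent from ranking", term, dropped)
            if not present:
                continue
            membership = np.zeros(N, dtype=bool)
            membership[[pos_of[g] for g in present]] = True
            s_star, cutoff, k_at = mhg_statistic(membership)
            p = mhg_pvalue(N, int(membership.sum()), s_star)
            # annotated genes among the top `cutoff` ranks of this direction
            overlap = [g for g in present if pos_of[g] < cutoff]
            rows.append(
                {
                    "term": term,
                    "direction": direction,
                    "n_annotated": len(present),
                    "mhg": s_star,
                    "p": p,
                    "cutoff": cutoff,
                    "overlap_genes": ",".join(sorted(overlap)),
                    "large_term": len(rec["genes"]) > max_term_genes,
                }
            )
    table = pd.DataFrame(rows)
    table["p_fdr"] = np.nan
    for direction in ("pos", "neg"):
        mask = table["direction"] == direction
        if mask.any():
            table.loc[mask, "p_fdr"] = multipletests(table.loc[mask, "p"], method="fdr_bh")[1]
    table["significant"] = table["p_fdr"] < fdr_threshold
    return table.sort_values(["direction", "p"]).reset_index(drop=True)


def candidate_set_test(
    ranking: pd.DataFrame,
    gene_set: list | dict,
    n_perm: int = 1000,
    seed: int = 0,
):
    """Permutation test of a candidate gene set's mean bootstrap Z.

    Null sets are drawn uniformly (without replacement) from all ranked
    genes, with exactly the retained set's size; genes of the candidate
    set missing from the ranking are dropped and logged. One-sided
    (enrichment among positively weighted genes), add-one p.
    """
    from .pls import PermutationResult

    if isinstance(gene_set, dict):
        gene_set = gene_set["genes"]
    z = ranking.set_index("gene")["z"]
    retained = [g for g in gene_set if g in z.index]
    dropped = len(gene_set) - len(retained)
    if dropped:
        logger.info("candidate set: %d genes absent from ranking dropped", dropped)
    if not retained:
        raise ValueError("no candidate-set gene is present in the ranking")
    observed = float(z.loc[retained].mean())
    rng = np.random.default_rng(seed)
    values = z.to_numpy()
    m = len(retained)
    null = np.array([values[rng.choice(len(values), size=m, replace=False)].mean() for _ in range(n_perm)])
    p = (1 + int((null >= observed).sum())) / (1 + n_perm)
    return PermutationResult(observed=observed, null=null, p=p, scheme="candidate-set", n_perm=n_perm, seed=seed)
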