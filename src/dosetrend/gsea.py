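"""Gene-set enrichment with a gene-label permutation null.

Given genes ranked by a signed metric (the summed trend composite for the
acute settings; ``sign(t) * -log10(p)`` for the chronic setting), the
running-sum enrichment score for a set walks the ranking from top to
bottom, incrementing by the hit gene's normalized weight ``|metric|**p``
and decrementing by ``1/(N - N_hit)`` for every miss; the enrichment score
(ES) is the signed maximum deviation from zero.  Significance comes from
permuting gene labels (metric values stay put, set membership is
randomized), with the nominal p computed against same-sign null scores and
a normalized-score (NES) ratio estimator for the false discovery rate.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .synthetic import GeneSetCollection

__all__ = ["enrichment_score", "permutation_test", "report_enriched"]


class EnrichmentInputError(ValueError):
    pass


def _sorted_ranking(ranking: pd.Series) -> pd.Series:
    """Descending metric order; ties broken by gene symbol for determinism."""
    df = ranking.rename("metric").rename_axis("gene").reset_index()
    df = df.sort_values(["metric", "gene"], ascending=[False, True])
    return pd.Series(df["metric"].to_numpy(), index=df["gene"].to_numpy())


def _es_batch(positions: np.ndarray, w_rank: np.ndarray, n_genes: int) -> np.ndarray:
    """ES for each row of 0-based, ascending hit positions.

    ``w_rank`` holds the (already exponentiated) weight of every rank
    position.  The extremes of the running sum occur right after a hit
    (candidate maxima) or right before one (candidate minima), so only hit
    positions need inspecting.
    """
    positions = np.atleast_2d(positions)
    k = positions.shape[1]
    if not (0 < k < n_genes):
        raise EnrichmentInputError("set must be a proper non-empty subset of the ranking")
    w = w_rank[positions]
    total_w = w.sum(axis=1, keepdims=True)
    if np.any(total_w == 0):
        raise EnrichmentInputError("all in-set metric weights are zero")
    hitcum = np.cumsum(w, axis=1) / total_w
    j = np.arange(1, k + 1)
    miss = (positions + 1 - j) / (n_genes - k)
    after = hitcum - miss
    before = (hitcum - w / total_w) - miss
    i_max = after.argmax(axis=1)
    i_min = before.argmin(axis=1)
    rows = np.arange(positions.shape[0])
    max_after = after[rows, i_max]
    min_before = before[rows, i_min]
    # signed maximum deviation; magnitude ties (to fp tolerance) resolve to
    # whichever extreme the running sum attains first
    pos_max = positions[rows, i_max]          # profile index of the maximum
    pos_min = positions[rows, i_min] - 1      # just before the minimizing hit
    tol = 1e-9 * np.maximum(1.0, np.abs(max_after))
    tie = np.abs(max_after + min_before) <= tol
    take_max = (max_after > -min_before + tol) | (tie & (pos_max <= pos_min))
    return np.where(take_max, max_after, min_before)


def enrichment_score(ranking: pd.Series, gene_set, weight_p: float = 1.0):
    """Running-sum enrichment score of one gene set.

    Parameters
    ----------
    ranking
        Signed metric indexed by gene symbol (need not be pre-sorted).
    gene_set
        Iterable of member symbols; must intersect the ranking but not
        cover it entirely.
    weight_p
        Exponent on ``|metric|`` for hit increments; ``0`` gives the
        unweighted Kolmogorov-Smirnov-style statistic.

    Returns ``(es, profile)`` where ``profile`` is the full running sum
    over ranking positions.
    """
    srt = _sorted_ranking(ranking)
    members = set(gene_set) & set(srt.index)
    if not members:
        raise EnrichmentInputError("gene set does not intersect the ranking")
    if len(members) == len(srt):
        raise EnrichmentInputError("gene set covers the entire ranking")
    n = len(srt)
    hit = srt.index.isin(members)
    pos = np.flatnonzero(hit)
    w_rank = np.abs(srt.to_numpy()) ** weight_p
    es = float(_es_batch(pos[None, :], w_rank, n)[0])

    w_hit = w_rank[pos]
    steps = np.where(hit, 0.0, -1.0 / (n - len(pos)))
    steps[pos] = w_hit / w_hit.sum() if w_hit.sum() else 0.0
    profile = pd.Series(np.cumsum(steps), index=srt.index, name="running_sum")
    return es, profile


def permutation_test(
    ranking: pd.Series,
    collection: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
    weight_p: float = 1.0,
    min_size: int = 5,
    max_size: int = 500,
) -> pd.DataFrame:
    """Permutation ES test for every set in the collection.

    One gene-label permutation per round is shared by all sets (metric
    values keep their rank positions; the assignment of genes to positions
    is shuffled), which is the gene-based null.  Per set: nominal p is the
    add-one-smoothed fraction of same-sign null scores at least as extreme
    as the observed ES; NES divides ES by the mean magnitude of same-sign
    null scores; the FDR q compares the null and observed NES tail
    fractions, clipped to [0, 1].
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    srt = _sorted_ranking(ranking)
    metric = srt.to_numpy()
    if np.unique(metric).size == 1:
        raise EnrichmentInputError("degenerate metric: all values equal")
    n = len(srt)
    w_rank = np.abs(metric) ** weight_p
    gene_pos = {g: i for i, g in enumerate(srt.index)}

    usable = collection.filtered(min_size=min_size, max_size=max_size, universe=srt.index)
    if not len(usable):
        raise EnrichmentInputError("no gene set within the size filter intersects the ranking")

    rng = np.random.default_rng(seed)
    order = np.argsort(rng.random((n_perm, n)), axis=1)
    pos_of_gene = np.argsort(order, axis=1)  # inverse permutation

    rows = []
    null_nes_all = []
    for name, members in usable.sets.items():
        idx = np.fromiter((gene_pos[g] for g in members), dtype=np.intp)
        es = float(_es_batch(np.sort(idx)[None, :], w_rank, n)[0])
        null_pos = np.sort(pos_of_gene[:, idx], axis=1)
        null_es = _es_batch(null_pos, w_rank, n)

        pos_null = null_es[null_es > 0]
        neg_null = null_es[null_es < 0]
        same = pos_null if es >= 0 else neg_null
        b = int(np.sum(np.abs(same) >= abs(es)))
        p_nominal = (1 + b) / (1 + same.size)
        mean_same = np.abs(same).mean() if same.size else np.nan
        nes = es / mean_same if mean_same else np.nan

        null_nes = np.empty_like(null_es)
        null_nes[:] = np.nan
        if pos_null.size:
            null_nes[null_es > 0] = pos_null / np.abs(pos_null).mean()
        if neg_null.size:
            null_nes[null_es < 0] = neg_null / np.abs(neg_null).mean()
        null_nes[null_es == 0] = 0.0
        null_nes_all.append(null_nes)

        rows.append(
            {"set": name, "es": es, "nes": nes, "p_nominal": p_nominal,
             "direction": "up" if es >= 0 else "down", "size": len(members)}
        )

    results = pd.DataFrame(rows)
    null_nes_flat = np.concatenate(null_nes_all)
    null_nes_flat = null_nes_flat[np.isfinite(null_nes_flat)]
    obs_nes = results["nes"].to_numpy()

    qs = np.ones(len(results))
    for i, nes in enumerate(obs_nes):
        if not np.isfinite(nes):
            continue
        if nes >= 0:
            null_tail = np.mean(null_nes_flat[null_nes_flat >= 0] >= nes) if (null_nes_flat >= 0).any() else 0.0
            obs_tail = np.mean(obs_nes[obs_nes >= 0] >= nes)
        else:
            null_tail = np.mean(null_nes_flat[null_nes_flat <= 0] <= nes) if (null_nes_flat <= 0).any() else 0.0
            obs_tail = np.mean(obs_nes[obs_nes <= 0] <= nes)
        qs[i] = min(1.0, null_tail / obs_tail) if obs_tail > 0 else 1.0
    results["fdr_q"] = qs
    return results.sort_values(["fdr_q", "p_nominal", "set"]).reset_index(drop=True)


def report_enriched(
    results: pd.DataFrame, fdr_max: float = 0.10, p_max: float = 0.025
) -> pd.DataFrame:
    """Rows meeting both reporting thresholds (FDR and nominal p), by FDR.

    Accepts any table with ``fdr_q`` and ``p_nominal`` columns — either
    :func:`permutation_test` output or a parsed published enrichment table.
    """
    if results.empty:
        return results.copy()
    keep = (results["fdr_q"] <= fdr_max) & (results["p_nominal"] <= p_max)
    return results.loc[keep].sort_values(["fdr_q", "p_nominal"]).reset_index(drop=True)
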