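"""Ranked-list word-enrichment landscapes (hypergeometric, gene-level presence).

Genes are ranked from most downregulated to most upregulated; for each
leading bin of the ranking a hypergeometric tail probability tests whether
genes whose 3' UTR contains a seed site are over-represented in the bin.
The statistic is gene-level presence (a simplification of occurrence-count
word enrichment with composition correction); p values are computed exactly
in log space.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from circscreen.annotation_io import revcomp
from circscreen.offtarget_scan import count_overlapping

_LN10 = np.log(10.0)


# ---------------------------------------------------------------------------
# Hypergeometric tails
# ---------------------------------------------------------------------------


def _check_args(N: int, K: int, n: int, k: int) -> None:
    if not (0 <= K <= N):
        raise ValueError(f"need 0 <= K <= N, got K={K}, N={N}")
    if not (0 <= n <= N):
        raise ValueError(f"need 0 <= n <= N, got n={n}, N={N}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"need 0 <= k <= min(K, n), got k={k}, K={K}, n={n}")


@lru_cache(maxsize=200_000)
def _log_pmf_range(N: int, K: int, n: int, lo: int, hi: int) -> float:
    """ln P[lo <= X <= hi] for X ~ Hypergeometric(N, K, n), exact in log space."""
    js = np.arange(lo, hi + 1, dtype=np.float64)
    logp = (
        gammaln(K + 1)
        - gammaln(js + 1)
        - gammaln(K - js + 1)
        + gammaln(N - K + 1)
        - gammaln(n - js + 1)
        - gammaln(N - K - n + js + 1)
        - (gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1))
    )
    return float(logsumexp(logp))


def log_hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """ln P[X >= k] for X ~ Hypergeometric(N, K, n)."""
    _check_args(N, K, n, k)
    support_lo = max(0, n + K - N)
    if k <= support_lo:
        return 0.0
    return min(0.0, _log_pmf_range(N, K, n, k, min(K, n)))


def log_hypergeom_lower_tail(N: int, K: int, n: int, k: int) -> float:
    """ln P[X <= k] for X ~ Hypergeometric(N, K, n)."""
    _check_args(N, K, n, k)
    if k >= min(K, n):
        return 0.0
    return min(0.0, _log_pmf_range(N, K, n, max(0, n + K - N), k))


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P[X >= k] for X ~ Hypergeometric(N, K, n): k successes in n draws
    without replacement from N items of which K are successes."""
    return float(np.exp(log_hypergeom_upper_tail(N, K, n, k)))


# ---------------------------------------------------------------------------
# Ranking and presence
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RankedGeneList:
    """Genes ordered most-downregulated first.

    Sort key: log2fc ascending, ties broken by p value ascending then
    gene_id.  ``n_down`` counts genes with log2fc < 0; ``n_dropped`` counts
    genes removed for lacking a UTR entry.
    """

    genes: Tuple[str, ...]
    n_down: int
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene_ids in ranked list")

    def __len__(self) -> int:
        return len(self.genes)


def rank_genes(
    table: pd.DataFrame, utrs: Optional[Mapping[str, str]] = None
) -> RankedGeneList:
    """Rank a DE table from downregulated to upregulated.

    Genes without a UTR entry (when ``utrs`` is given) are dropped; the
    dropped count is recorded on the returned list.
    """
    df = table.copy()
    n_dropped = 0
    if utrs is not None:
        keep = df["gene_id"].isin(utrs)
        n_dropped = int((~keep).sum())
        df = df.loc[keep]
    if df.empty:
        raise ValueError("ranked gene list is empty")
    df = df.sort_values(
        ["log2fc", "pvalue", "gene_id"], ascending=True, na_position="last"
    )
    return RankedGeneList(
        genes=tuple(df["gene_id"]),
        n_down=int((df["log2fc"] < 0).sum()),
        n_dropped=n_dropped,
    )


def build_presence_table(
    words: Sequence[str], utrs: Mapping[str, str]
) -> pd.DataFrame:
    """Gene x word boolean table: does the word's site (revcomp) occur in the UTR?"""
    if not words:
        raise ValueError("words must be non-empty")
    data = {
        word: [count_overlapping(utr, revcomp(word)) > 0 for utr in utrs.values()]
        for word in words
    }
    return pd.DataFrame(data, index=list(utrs.keys()), dtype=bool)


# ---------------------------------------------------------------------------
# Landscapes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EnrichmentLandscape:
    """Signed hypergeometric landscape for one word over leading bins.

    ``signed_logp[i]`` is ``-log10 p_upper`` when the word is enriched in the
    leading bin ``bin_edges[i]`` (positive values) and ``+log10 p_lower``
    when depleted (negative values).  At the full-universe bin the value is 0
    by construction.
    """

    word: str
    bin_edges: Tuple[int, ...]
    signed_logp: Tuple[float, ...]
    k_in_bin: Tuple[int, ...]
    log_p_upper: Tuple[float, ...]  # natural log
    K: int
    N: int


def bin_edges_for(n_genes: int, bin_step: int) -> List[int]:
    edges = list(range(bin_step, n_genes + 1, bin_step))
    if not edges or edges[-1] != n_genes:
        edges.append(n_genes)
    return edges


def enrichment_landscape(
    ranked: RankedGeneList,
    presence: pd.DataFrame,
    word: str,
    bin_step: int = 50,
) -> EnrichmentLandscape:
    """Hypergeometric landscape of one word across leading bins of the ranking."""
    if len(ranked) == 0:
        raise ValueError("empty ranked gene list")
    missing = [g for g in ranked.genes if g not in presence.index]
    if missing:
        raise ValueError(
            f"{len(missing)} ranked genes absent from presence table "
            f"(first: {missing[0]!r})"
        )
    if word not in presence.columns:
        raise ValueError(f"word {word!r} absent from presence table")
    pres = presence.loc[list(ranked.genes), word].to_numpy(dtype=bool)
    N = len(pres)
    K = int(pres.sum())
    cum = np.cumsum(pres)
    edges = bin_edges_for(N, bin_step)
    signed, ks, log_uppers = [], [], []
    for n in edges:
        k = int(cum[n - 1])
        log_up = log_hypergeom_upper_tail(N, K, n, k)
        log_low = log_hypergeom_lower_tail(N, K, n, k)
        if log_up <= log_low:
            signed.append(-log_up / _LN10)  # enrichment: positive
        else:
            signed.append(log_low / _LN10)  # depletion: negative
        ks.append(k)
        log_uppers.append(log_up)
    return EnrichmentLandscape(
        word=word,
        bin_edges=tuple(edges),
        signed_logp=tuple(signed),
        k_in_bin=tuple(ks),
        log_p_upper=tuple(log_uppers),
        K=K,
        N=N,
    )


@dataclass(frozen=True)
class SeedVerdict:
    """Bonferroni-corrected enrichment call for one seed word."""

    word: str
    enriched: bool
    min_p_upper: float
    corrected_min_p: float
    best_bin: Optional[int]


def landscape_verdict(
    landscapes: Mapping[str, EnrichmentLandscape],
    n_downregulated: int,
    alpha: float = 0.05,
) -> Dict[str, SeedVerdict]:
    """Per-seed enrichment verdicts over the downregulated part of the ranking.

    A seed is called enriched iff its minimum upper-tail p over bins lying
    within the downregulated prefix, Bonferroni-corrected by (number of bins
    x number of seeds), is below ``alpha``.
    """
    if not landscapes:
        return {}
    edge_sets = {ls.bin_edges for ls in landscapes.values()}
    if len(edge_sets) != 1:
        raise ValueError("landscapes must share bin_edges")
    edges = next(iter(edge_sets))
    n_tests = len(edges) * len(landscapes)
    verdicts = {}
    for word, ls in landscapes.items():
        best_p, best_bin = 1.0, None
        for edge, log_up in zip(ls.bin_edges, ls.log_p_upper):
            if edge > n_downregulated:
                continue
            p = float(np.exp(log_up))
            if p < best_p:
                best_p, best_bin = p, edge
        corrected = min(1.0, best_p * n_tests)
        verdicts[word] = SeedVerdict(
            word=word,
            enriched=corrected < alpha,
            min_p_upper=best_p,
            corrected_min_p=corrected,
            best_bin=best_bin,
        )
    return verdicts
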