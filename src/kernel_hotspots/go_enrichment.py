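"""GO term over-representation: one-sided hypergeometric test with BH FDR.

For a study set of n genes drawn from a background of N, a term annotating K
background genes and k study genes is scored by the upper-tail probability
P(X >= k) for X ~ Hypergeometric(N, K, n). P-values over all tested terms
(those with k >= 1) are adjusted by Benjamini-Hochberg.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class EnrichmentRow:
    term_id: str
    term_name: str
    k: int           # study genes with the term
    n: int           # study size
    K: int           # background genes with the term
    N: int           # background size
    p_value: float
    fdr: float
    significant: bool


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), computed stably.

    Parameters follow the enrichment convention: N background genes of which
    K carry the term; n genes drawn (the study set); k of them carry it.
    """
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(n, K)):
        raise ValueError(
            f"invalid hypergeometric parameters k={k}, K={K}, n={n}, N={N}"
        )
    if k == 0:
        return 1.0
    # sf(k-1) = P(X >= k); scipy's signature is (M=N, n=K, N=n)
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich(
    study: Iterable[str],
    background: Iterable[str],
    term_to_genes: Mapping[str, Iterable[str]],
    fdr_threshold: float = 0.05,
    term_names: Mapping[str, str] | None = None,
) -> list[EnrichmentRow]:
    """Test every term with >= 1 study hit; BH-adjust across tested terms.

    Annotations are restricted to background genes. Rows are ordered by
    (p-value, term_id) so the output is deterministic under permutation of
    the inputs.
    """
    study_set = set(study)
    bg = set(background)
    stray = sorted(study_set - bg)
    if stray:
        raise ValueError(f"study gene(s) absent from background: {stray}")
    n, N = len(study_set), len(bg)
    term_names = term_names or {}

    tested = []
    for term_id in sorted(term_to_genes):
        genes = set(term_to_genes[term_id]) & bg
        k = len(genes & study_set)
        if k >= 1:
            K = len(genes)
            tested.append((term_id, k, K, hypergeom_upper_tail(k, K, n, N)))
    if not tested:
        return []

    pvals = [t[3] for t in tested]
    reject, fdrs, _, _ = multipletests(pvals, alpha=fdr_threshold, method="fdr_bh")
    rows = [
        EnrichmentRow(
            term_id=term_id,
            term_name=term_names.get(term_id, ""),
            k=k, n=n, K=K, N=N,
            p_value=p,
            fdr=float(fdr),
            significant=float(fdr) <= fdr_threshold,
        )
        for (term_id, k, K, p), fdr, rej in zip(tested, fdrs, reject)
    ]
    rows.sort(key=lambda r: (r.p_value, r.term_id))
    return rows


def enrichment_table(rows: Iterable[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term_id": r.term_id,
                "term_name": r.term_name,
                "k": r.k, "n": r.n, "K": r.K, "N": r.N,
                "p_value": r.p_value,
                "fdr": r.fdr,
                "significant": r.significant,
            }
            for r in rows
        ],
        columns=("term_id", "term_name", "k", "n", "K", "N", "p_value", "fdr", "significant"),
    )
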