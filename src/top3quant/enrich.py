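"""Over-representation analysis against local GMT gene sets.

A one-sided hypergeometric test (equivalently a one-tailed Fisher exact
test) scores each set for enrichment of a query list within a universe,
with Benjamini-Hochberg FDR control across sets; sets at FDR <= 0.05 are
flagged retained and -log10(FDR) is exported for bar plots. The test and
FDR procedure are standard ORA surrogates for a pathway-database lookup and
are named in the output metadata. The recommended universe is the list of
quantified proteins, not a whole annotation, to avoid anticonservative
enrichment on biased (e.g. membrane-enriched) inputs. Identifier matching
is exact-string and case-sensitive.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .qio import GeneSetCollection

TEST_NAME = "one-sided hypergeometric (Fisher exact, upper tail)"
FDR_NAME = "Benjamini-Hochberg step-up"


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), computed stably.

    ``k`` hits in the query, ``K`` set members in the universe, ``n`` query
    size, ``N`` universe size.
    """
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"need 0 <= k <= min(K, n); got k={k}, K={K}, n={n}")
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"need K, n <= N; got K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_fdr(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order.

    q(i) = min over j >= i of p(j) * m / j along the sorted p-values,
    clipped to 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_ora(
    query_ids: Iterable[str],
    gene_sets: GeneSetCollection,
    universe_ids: Iterable[str],
    fdr_cutoff: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric ORA of ``query_ids`` against every gene set.

    The query is restricted to the universe; sets with no universe member
    are omitted. Output columns: set_id, description, k (hits), K (set size
    in universe), n (query size), N (universe size), p_value, fdr,
    neg_log10_fdr, retained (fdr <= cutoff); sorted by fdr then set_id.
    """
    universe = list(dict.fromkeys(str(u) for u in universe_ids))
    uni = set(universe)
    query = [q for q in dict.fromkeys(str(q) for q in query_ids) if q in uni]
    if not query:
        raise ValueError("query and universe share no identifiers")
    qset = set(query)
    N, n = len(universe), len(query)

    rows = []
    for set_id, members in gene_sets.sets.items():
        in_uni = [m for m in members if m in uni]
        K = len(in_uni)
        if K == 0:
            continue
        k = sum(1 for m in in_uni if m in qset)
        rows.append({
            "set_id": set_id,
            "description": gene_sets.descriptions.get(set_id, ""),
            "k": k, "K": K, "n": n, "N": N,
            "p_value": hypergeom_upper_tail(k, K, n, N),
        })
    if not rows:
        return pd.DataFrame(columns=["set_id", "description", "k", "K", "n", "N",
                                     "p_value", "fdr", "neg_log10_fdr", "retained"])
    out = pd.DataFrame(rows)
    out["fdr"] = bh_fdr(out["p_value"].to_numpy())
    with np.errstate(divide="ignore"):
        out["neg_log10_fdr"] = -np.log10(out["fdr"])
    out["retained"] = out["fdr"] <= fdr_cutoff
    out = out.sort_values(["fdr", "set_id"], ignore_index=True)
    out.attrs["test"] = TEST_NAME
    out.attrs["fdr_procedure"] = FDR_NAME
    return out
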