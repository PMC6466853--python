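"""Gene-set category enrichment by Fisher's exact test with Bonferroni correction.

For a query set of size n drawn from a universe of size N, a category with
K members in the universe and k in the query gives the 2x2 table
``[[k, n-k], [K-k, N-K-n+k]]``; the one-sided p-value is the upper
hypergeometric tail P(X >= k). Bonferroni multiplies by the number of
testable categories (K >= 1 after intersecting with the universe), capped
at 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats as sps

__all__ = [
    "CategoryEnrichmentResult",
    "hypergeom_pvalue",
    "fisher_enrichment",
    "read_categories_tsv",
    "read_gmt",
    "enrichment_results_to_frame",
    "write_enrichment_results_tsv",
]


@dataclass(frozen=True)
class CategoryEnrichmentResult:
    category: str
    k: int  # query ∩ category
    K: int  # category size in the universe
    n: int  # query size
    N: int  # universe size
    p_raw: float
    p_adj: float


def hypergeom_pvalue(k: int, K: int, n: int, N: int, alternative: str = "greater") -> float:
    """Fisher's exact p-value for the 2x2 table defined by (k, K, n, N).

    'greater' is the upper hypergeometric tail P(X >= k); 'two_sided' sums
    the probabilities of all tables at most as probable as the observed one.
    """
    if not (0 <= k <= min(K, n) and K <= N and n <= N and k >= max(0, K + n - N)):
        raise ValueError(f"inconsistent table k={k}, K={K}, n={n}, N={N}")
    if alternative == "greater":
        return float(sps.hypergeom.sf(k - 1, N, K, n))
    if alternative == "two_sided":
        table = [[k, n - k], [K - k, N - K - n + k]]
        return float(sps.fisher_exact(table, alternative="two-sided")[1])
    raise ValueError(f"unknown alternative {alternative!r}")


def fisher_enrichment(
    gene_set: Iterable[str],
    universe: Iterable[str],
    categories: Mapping[str, Iterable[str]],
    alternative: str = "greater",
) -> list[CategoryEnrichmentResult]:
    """Test each category for over-representation in ``gene_set``.

    Category memberships are intersected with the universe first; categories
    left empty are dropped before the Bonferroni factor m is counted, so
    untestable hypotheses do not inflate the correction. Results are sorted
    by adjusted then raw p-value.
    """
    query = set(gene_set)
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    stray = query - uni
    if stray:
        raise ValueError(
            f"gene_set not contained in universe, e.g. {sorted(stray)[:10]}"
        )
    N, n = len(uni), len(query)
    trimmed = {
        name: set(members) & uni for name, members in categories.items()
    }
    trimmed = {name: members for name, members in trimmed.items() if members}
    m = len(trimmed)
    results = []
    for name, members in trimmed.items():
        K = len(members)
        k = len(members & query)
        p = hypergeom_pvalue(k, K, n, N, alternative=alternative)
        results.append(
            CategoryEnrichmentResult(
                category=name, k=k, K=K, n=n, N=N,
                p_raw=p, p_adj=min(1.0, p * m),
            )
        )
    results.sort(key=lambda r: (r.p_adj, r.p_raw, r.category))
    return results


def read_categories_tsv(path: str | Path) -> dict[str, set[str]]:
    """Two-column TSV (category, gene_id) -> category membership sets."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.rstrip("\n")
            if not s.strip() or s.startswith("#"):
                continue
            fields = s.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated fields")
            out.setdefault(fields[0], set()).add(fields[1])
    return out


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT format: name <tab> description <tab> gene1 <tab> gene2 ..."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.rstrip("\n")
            if not s.strip() or s.startswith("#"):
                continue
            fields = s.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 tab-separated fields")
            out[fields[0]] = {g for g in fields[2:] if g}
    return out


def enrichment_results_to_frame(
    results: Iterable[CategoryEnrichmentResult],
) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.category, r.k, r.K, r.n, r.N, r.p_raw, r.p_adj) for r in results],
        columns=["category", "k", "K", "n", "N", "p_raw", "p_adj"],
    )


def write_enrichment_results_tsv(
    results: Iterable[CategoryEnrichmentResult], path: str | Path
) -> None:
    enrichment_results_to_frame(results).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )
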