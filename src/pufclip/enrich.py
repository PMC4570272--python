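"""Length-stratified functional-term enrichment.

For each binding-element length class, targets are tested for
over-representation of functional terms with a hypergeometric upper-tail
test against the whole genome (every gene in the feature table) as
background, and corrected for multiple testing with the Holm-Bonferroni
step-down procedure. The correction family is per length class by default
(each class's term tests form one family); a global family over all
(class, term) pairs is available.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    N genes in the background, K of them in the term, n targets drawn;
    k targets observed in the term.
    """
    for name, v in (("k", k), ("K", K), ("n", n), ("N", N)):
        if not isinstance(v, (int, np.integer)) or v < 0:
            raise ValueError(f"{name} must be a non-negative integer")
    if k > n or K > N or k > K or n > N:
        raise ValueError(f"inconsistent counts k={k} K={K} n={n} N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def holm_bonferroni(
    p_values: list[float] | np.ndarray, alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Step-down Holm-Bonferroni adjustment.

    Sort ascending; adjusted p_(i) = max_{j<=i} min(1, (m-j)*p_(j)) with
    0-based j; rejections are step-down at ``alpha``. Returns
    (adjusted p, reject) in the original order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = np.minimum(1.0, (m - np.arange(m)) * p[order])
    adj_sorted = np.maximum.accumulate(adj_sorted)
    adjusted = np.empty(m)
    adjusted[order] = adj_sorted
    reject = adjusted < alpha
    return adjusted, reject


def read_term_map(path: str | Path) -> dict[str, set[str]]:
    """2-column TSV (gene_id, term_id) -> gene -> set of terms."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        first = fh.readline()
        if first and not first.lower().startswith("gene_id"):
            fh.seek(0)
        for line in fh:
            if not line.strip():
                continue
            gene, term = line.rstrip("\n").split("\t")[:2]
            out.setdefault(gene, set()).add(term)
    return out


def stratified_enrichment(
    targets_by_class: dict[int, set[str]],
    term_map: dict[str, set[str]],
    background: set[str],
    alpha: float = 0.05,
    family: str = "per-class",
) -> pd.DataFrame:
    """Hypergeometric term enrichment per element length class.

    ``targets_by_class`` maps each length class to its target gene set
    (a gene with several peaks counts once per class). Terms absent from
    the background are dropped. Returns a table sorted by adjusted p.
    """
    if family not in ("per-class", "global"):
        raise ValueError("family must be 'per-class' or 'global'")
    if not background:
        raise ValueError("background gene set is empty")

    genes_per_term: dict[str, set[str]] = {}
    for gene in background:
        for term in term_map.get(gene, ()):
            genes_per_term.setdefault(term, set()).add(gene)

    N = len(background)
    rows: list[dict] = []
    for cls in sorted(targets_by_class):
        targets = targets_by_class[cls] & background
        n = len(targets)
        if n == 0:
            continue
        terms = sorted({t for g in targets for t in term_map.get(g, ())})
        for term in terms:
            K = len(genes_per_term.get(term, ()))
            if K == 0:
                continue
            k = len(targets & genes_per_term[term])
            if k == 0:
                continue
            rows.append(
                {
                    "length_class": cls,
                    "term": term,
                    "k": k,
                    "K": K,
                    "n": n,
                    "N": N,
                    "p_raw": hypergeom_upper_tail(k, K, n, N),
                }
            )
    df = pd.DataFrame(
        rows, columns=["length_class", "term", "k", "K", "n", "N", "p_raw"]
    )
    if df.empty:
        df["p_adj"] = pd.Series(dtype=float)
        df["significant"] = pd.Series(dtype=bool)
        return df
    if family == "global":
        adj, rej = holm_bonferroni(df["p_raw"].to_numpy(), alpha)
        df["p_adj"], df["significant"] = adj, rej
    else:
        df["p_adj"] = np.nan
        df["significant"] = False
        for cls, idx in df.groupby("length_class").groups.items():
            adj, rej = holm_bonferroni(df.loc[idx, "p_raw"].to_numpy(), alpha)
            df.loc[idx, "p_adj"] = adj
            df.loc[idx, "significant"] = rej
    return df.sort_values(["p_adj", "p_raw"]).reset_index(drop=True)
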