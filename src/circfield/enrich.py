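"""Gene-set over-representation analysis for circRNA-derived genes.

A plain upper-tail hypergeometric test per pathway term with Bonferroni
correction over the tested terms. This is a native stand-in for web-based
enrichment services; it does not replicate their modified (EASE) scoring.
"""
from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd
from scipy import stats


def read_gmt(path: str) -> dict[str, tuple[str, set[str]]]:
    """GMT rows: term_id <tab> description <tab> gene1 <tab> gene2 ..."""
    table: dict[str, tuple[str, set[str]]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: GMT line {ln} has fewer than 3 fields")
            table[fields[0]] = (fields[1], set(fields[2:]))
    return table


def write_gmt(table: Mapping[str, tuple[str, set[str]]], path: str) -> None:
    with open(path, "w") as fh:
        for term_id, (name, genes) in table.items():
            fh.write("\t".join([term_id, name, *sorted(genes)]) + "\n")


def enrich(
    query_genes: Iterable[str],
    pathway_table: Mapping[str, tuple[str, set[str]]] | Mapping[str, set[str]],
    background_genes: Iterable[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of query genes in each term.

    p = P(X >= k) drawing n query genes from a background of N containing
    K term genes; Bonferroni multiplies by the number of tested terms
    (terms with no background overlap are skipped). Results are sorted by
    ascending p-value.
    """
    query = set(query_genes)
    background = set(background_genes)
    offenders = query - background
    if offenders:
        raise ValueError(
            f"query genes absent from background: {sorted(offenders)[:10]}"
        )
    N, n = len(background), len(query)
    rows = []
    for term_id, value in pathway_table.items():
        name, genes = value if isinstance(value, tuple) else (term_id, value)
        term_genes = set(genes) & background
        K = len(term_genes)
        if K == 0:
            continue
        k = len(term_genes & query)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "term_id": term_id,
                "term_name": name,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p_value": min(1.0, p),
            }
        )
    result = pd.DataFrame(
        rows, columns=["term_id", "term_name", "k", "K", "n", "N", "p_value"]
    )
    m = len(result)
    result["p_bonferroni"] = (result["p_value"] * m).clip(upper=1.0)
    return result.sort_values("p_value", kind="mergesort").reset_index(drop=True)


def plot_enrichment(results_by_group: Mapping[str, pd.DataFrame], path: str, top: int = 10) -> None:
    """Bar plot of -log10 p per term for each group (axis labelled as such)."""
    import math

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    groups = list(results_by_group)
    fig, axes = plt.subplots(1, max(len(groups), 1), figsize=(5 * max(len(groups), 1), 4))
    if len(groups) <= 1:
        axes = [axes]
    for ax, g in zip(axes, groups):
        df = results_by_group[g].head(top)
        ax.barh(
            df["term_name"][::-1],
            [-math.log10(max(p, 1e-300)) for p in df["p_value"][::-1]],
        )
        ax.set_xlabel("-log10 p")
        ax.set_title(g)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
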