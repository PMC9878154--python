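"""Hypergeometric over-representation test over a user-supplied term map.

Stands in for GO/KEGG enrichment without shipping any ontology: the caller
provides a term -> gene mapping (2-column TSV) and a gene population, and
each term is scored with the upper hypergeometric tail, BH-adjusted.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from scipy import stats

from .errors import ValidationError
from .methylation import adjust_fdr


def read_term_map(path: str | Path) -> dict[str, set[str]]:
    """Read a 2-column TSV (term, gene) into a term -> gene-set mapping."""
    terms: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            term, gene = line.split("\t")[:2]
            terms.setdefault(term, set()).add(gene)
    return terms


def hypergeom_enrich(
    study: set[str],
    population: set[str],
    term_map: dict[str, set[str]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-term over-representation of the study set within the population.

    For a term hitting K of N population genes and k of the n study genes,
    p = P(X >= k) under Hypergeometric(N, K, n).  Terms are intersected with
    the population first; results are BH-adjusted and sorted by p.
    """
    offenders = study - population
    if offenders:
        raise ValidationError(
            f"study genes absent from population: {sorted(offenders)[:10]}"
        )
    N = len(population)
    n = len(study)
    rows = []
    for term, genes in term_map.items():
        members = genes & population
        if not members:
            continue
        K = len(members)
        k = len(members & study)
        # upper tail P(X >= k)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"term": term, "k": k, "K": K, "n": n, "N": N, "p": p})
    df = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "p"])
    if len(df):
        df["q"] = adjust_fdr(df["p"].to_numpy())
        df["significant"] = df["q"] < alpha
        df = df.sort_values("p", kind="stable").reset_index(drop=True)
    else:
        df["q"] = []
        df["significant"] = []
    return df
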