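"""Binomial-tail enrichment of top differentially expressed genes in modules.

If resistance-related genes were unrelated to the co-expression structure,
the top-fraction DE genes would fall uniformly across modules, each hitting
a module at the background rate q (the top fraction itself).  A module
enriched beyond that rate — exact upper-tail binomial probability
P(X >= k), X ~ Binomial(n, q) — is scored by -ln(p) as its likelihood of
association with the resistance phenotype, with the module's tumor
correlation reported as a companion coordinate.  Candidate genes are the
top-DE genes inside enriched modules, ordered by module score and fold
change.
"""

from __future__ import annotations

import logging
from collections.abc import Collection

import numpy as np
import pandas as pd
from scipy import stats

from .coexpression import ModulePartition

logger = logging.getLogger(__name__)


def intersect_gene_universe(
    de_genes: Collection[str], cohort_genes: Collection[str]
) -> list[str]:
    """Sorted intersection of the DE-profile and cohort gene sets.

    Every downstream count (module size n, hit count k, the top fraction)
    is taken on this common universe only.
    """
    de_set, cohort_set = set(de_genes), set(cohort_genes)
    if not de_set or not cohort_set:
        raise ValueError("gene sets must be nonempty")
    common = sorted(de_set & cohort_set)
    if not common:
        raise ValueError("gene universes do not intersect")
    return common


def binomial_tail(n: int, k: int, q: float) -> float:
    """Exact upper tail P(X >= k) for X ~ Binomial(n, q)."""
    if not (0 <= k <= n):
        raise ValueError("need 0 <= k <= n")
    if not (0.0 < q < 1.0):
        raise ValueError("q must be in (0, 1)")
    if k == 0:
        return 1.0
    return float(stats.binom.sf(k - 1, n, q))


def _log_binomial_tail(n: int, k: int, q: float) -> float:
    if k == 0:
        return 0.0
    return float(stats.binom.logsf(k - 1, n, q))


def score_modules(
    partition: ModulePartition,
    top_genes: Collection[str],
    trait_corr: pd.DataFrame | None = None,
    q: float = 0.1,
    alpha: float = 0.05,
    test: str = "binomial",
) -> pd.DataFrame:
    """Per-module enrichment of the top-DE gene set.

    ``q`` must be the same fraction used to flag the top genes.  A module is
    ``enriched`` when p < alpha and its observed top-gene fraction k/n
    exceeds q; module 0 (unassigned genes) is reported but never enriched.
    ``test="hypergeometric"`` swaps the binomial tail for the finite-universe
    hypergeometric tail.  Output is sorted by score descending.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    if test not in ("binomial", "hypergeometric"):
        raise ValueError("test must be 'binomial' or 'hypergeometric'")
    universe = set(partition.labels.index)
    top = set(top_genes)
    if not top <= universe:
        raise ValueError("top genes are not a subset of the partition's gene universe")
    tumor_r: dict = {}
    if trait_corr is not None:
        sub = trait_corr[trait_corr["trait"] == "tumor"]
        tumor_r = dict(zip(sub["module"], sub["r"]))
    records = []
    for m in sorted(partition.labels.unique()):
        members = set(partition.members(m))
        n, k = len(members), len(members & top)
        if test == "hypergeometric":
            p = float(stats.hypergeom.sf(k - 1, len(universe), len(top), n)) if k else 1.0
            log_p = np.log(max(p, np.finfo(float).tiny))
        else:
            p = binomial_tail(n, k, q)
            log_p = _log_binomial_tail(n, k, q)
        records.append(
            {
                "module": m,
                "n": n,
                "k": k,
                "q": q,
                "p_binom": p,
                "score": -log_p,
                "tumor_r": tumor_r.get(f"ME{m}", np.nan),
                "enriched": bool(m != 0 and p < alpha and k / n > q),
            }
        )
    out = pd.DataFrame(records).sort_values(
        ["score", "module"], ascending=[False, True], kind="mergesort"
    )
    return out.reset_index(drop=True)


def prioritize_genes(
    enrichment: pd.DataFrame,
    partition: ModulePartition,
    de_table: pd.DataFrame,
    top_genes: Collection[str] | None = None,
) -> pd.DataFrame:
    """Ranked candidate list: top-DE genes inside enriched modules.

    Ordered by (module score desc, |log2fc| desc, gene_id asc); returns an
    empty table (with a logged notice) when no module is enriched.
    """
    if top_genes is None:
        top_genes = set(de_table.loc[de_table["top_flag"], "gene_id"])
    top = set(top_genes)
    enriched = enrichment[enrichment["enriched"]]
    columns = ["gene_id", "module", "module_score", "abs_log2fc", "log2fc", "rank"]
    if enriched.empty:
        logger.warning("no enriched modules: no candidates to rank")
        return pd.DataFrame(columns=columns)
    score_by_module = dict(zip(enriched["module"], enriched["score"]))
    lfc = de_table.set_index("gene_id")["log2fc"]
    rows = []
    for gene in sorted(top):
        m = int(partition.labels.get(gene, 0))
        if m in score_by_module:
            rows.append(
                {"gene_id": gene, "module": m, "module_score": float(score_by_module[m]),
                 "log2fc": float(lfc[gene]), "abs_log2fc": abs(float(lfc[gene]))}
            )
    if not rows:
        logger.warning("enriched modules contain no top-DE genes")
        return pd.DataFrame(columns=columns)
    out = pd.DataFrame(rows).sort_values(
        ["module_score", "abs_log2fc", "gene_id"], ascending=[False, False, True],
        kind="mergesort",
    )
    out["rank"] = np.arange(1, len(out) + 1)
    return out.reset_index(drop=True)[columns]
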