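"""miRNA target-set over-representation in pathway gene sets.

Each candidate miRNA's target list is tested against every pathway set
with the one-sided hypergeometric (Fisher) over-representation test, BH
adjusted within each miRNA across its tested sets.  A miRNA survives the
pathway filter when at least one whitelisted cancer-related pathway is
enriched at the FDR threshold.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats

from .diffexp import benjamini_hochberg
from .io import GeneSetCollection

logger = logging.getLogger(__name__)

#: cancer-related pathway names retained by default
DEFAULT_WHITELIST = frozenset(
    {
        "Hedgehog signaling",
        "NF-kB signaling",
        "TGF-beta signaling",
        "angiogenesis",
        "cell cycle",
        "DNA damage response",
        "pathways in cancer",
    }
)


def hypergeometric_ora(
    targets: Iterable[str], pathway: Iterable[str], universe: Iterable[str]
) -> tuple[int, float]:
    """Upper-tail hypergeometric over-representation probability.

    With N = |universe|, K = |pathway|, n = |targets| and
    k = |targets ∩ pathway|, returns (k, P(X >= k)).
    """
    universe = frozenset(universe)
    if not universe:
        raise ValueError("empty universe")
    targets = frozenset(targets) & universe
    pathway = frozenset(pathway) & universe
    k = len(targets & pathway)
    N, K, n = len(universe), len(pathway), len(targets)
    if k == 0:
        return 0, 1.0
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return k, min(p, 1.0)


def enrich_mirnas(
    target_map: Mapping[str, frozenset[str]],
    sets: GeneSetCollection,
    universe: frozenset[str] | None = None,
) -> pd.DataFrame:
    """All pairwise (miRNA, pathway) over-representation tests.

    The universe defaults to the union of all pathway members and all
    mapped targets.  FDR is BH within each miRNA across its tested sets.
    Returns a DataFrame with columns mirna_id, set_name, k, n, K, N,
    p_hyper, fdr.
    """
    if not target_map or not sets.sets:
        raise ValueError("need a non-empty target map and gene-set collection")
    if universe is None:
        universe = frozenset().union(sets.universe, *target_map.values())
    rows = []
    for mirna_id in sorted(target_map):
        targets = frozenset(target_map[mirna_id]) & universe
        if not targets:
            logger.warning("miRNA %s has no targets in the universe; skipped", mirna_id)
            continue
        block = []
        for set_name in sorted(sets.sets):
            members = sets.sets[set_name] & universe
            k, p = hypergeometric_ora(targets, members, universe)
            block.append(
                dict(mirna_id=mirna_id, set_name=set_name, k=k, n=len(targets),
                     K=len(members), N=len(universe), p_hyper=p)
            )
        fdr = benjamini_hochberg([b["p_hyper"] for b in block])
        for b, q in zip(block, fdr):
            b["fdr"] = float(q)
        rows.extend(block)
    return pd.DataFrame.from_records(
        rows, columns=["mirna_id", "set_name", "k", "n", "K", "N", "p_hyper", "fdr"]
    )


def cancer_pathway_filter(
    results: pd.DataFrame,
    whitelist: Iterable[str] = DEFAULT_WHITELIST,
    alpha_enrich: float = 0.05,
) -> set[str]:
    """miRNAs with at least one whitelisted pathway enriched at the FDR cut."""
    whitelist = set(whitelist)
    if not whitelist:
        raise ValueError("whitelist must be non-empty")
    if results.empty:
        return set()
    hits = results[
        results["set_name"].isin(whitelist) & (results["fdr"] <= alpha_enrich)
    ]
    return set(hits["mirna_id"])
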