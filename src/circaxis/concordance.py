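"""Parent-gene concordance against an independent reference cohort.

A circRNA arises from a parent gene by back splicing, so — under the
working hypothesis that circRNA abundance tracks its parent's transcription
— a candidate circRNA's tumor-vs-normal direction should be mirrored by its
parent gene in a large independent reference cohort (emulating a
TCGA-style tumor/normal comparison).  The check is encoded as a hard
filter by default; ``require=False`` softens it to an annotation-only flag.
"""

from __future__ import annotations

import logging
from typing import Mapping

import pandas as pd

from .diffexp import DIRECTION_NS
from .io import CircAnnotation

logger = logging.getLogger(__name__)


def parent_gene_concordance(
    circ_de: pd.DataFrame,
    annotations: Mapping[str, CircAnnotation],
    gene_de: pd.DataFrame,
    alpha_ref: float = 0.05,
) -> pd.DataFrame:
    """One concordance record per candidate circRNA.

    A circRNA is concordant when its direction equals its parent gene's
    direction of change in the reference cohort, both are not ``ns``, and
    the reference raw p value is <= ``alpha_ref``.  Candidates without an
    annotation or whose parent is absent from the reference results are
    marked non-concordant and logged, never dropped.
    """
    records = []
    for circ_id, row in circ_de.iterrows():
        ann = annotations.get(circ_id)
        if ann is None:
            logger.warning("no annotation for %s; marked non-concordant", circ_id)
            records.append(
                dict(circ_id=circ_id, parent_gene_id="", circ_direction=row["direction"],
                     gene_direction=DIRECTION_NS, gene_p=float("nan"), concordant=False)
            )
            continue
        gene = ann.parent_gene_id
        if gene not in gene_de.index:
            logger.warning(
                "parent gene %s of %s absent from reference results", gene, circ_id
            )
            records.append(
                dict(circ_id=circ_id, parent_gene_id=gene, circ_direction=row["direction"],
                     gene_direction=DIRECTION_NS, gene_p=float("nan"), concordant=False)
            )
            continue
        gene_row = gene_de.loc[gene]
        # raw sign of the reference-cohort change; significance is gated
        # separately on the reference raw p (per-gene p values, not FDR)
        if gene_row["log2fc"] > 0:
            gene_dir = "up"
        elif gene_row["log2fc"] < 0:
            gene_dir = "down"
        else:
            gene_dir = DIRECTION_NS
        concordant = (
            row["direction"] != DIRECTION_NS
            and gene_dir == row["direction"]
            and gene_row["p"] <= alpha_ref
        )
        records.append(
            dict(circ_id=circ_id, parent_gene_id=gene, circ_direction=row["direction"],
                 gene_direction=gene_dir, gene_p=float(gene_row["p"]),
                 concordant=bool(concordant))
        )
    return pd.DataFrame.from_records(
        records,
        columns=["circ_id", "parent_gene_id", "circ_direction", "gene_direction",
                 "gene_p", "concordant"],
    ).set_index("circ_id")
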