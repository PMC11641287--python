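"""Assembly and classification of mRNA/circRNA/miRNA regulatory axes.

An axis is a (parent gene, circRNA, miRNA) triple supported by six
evidence layers applied as hard gates in the strict mode:

1. the circRNA is significantly differentially expressed (``circ_de``),
2. its parent gene changes in the same direction in an independent
   reference cohort (``parent_concordant``),
3. the pair has a high-confidence predicted sponge site (``binding_high``),
4. the miRNA is significantly DE with direction opposite the circRNA
   (``mirna_reciprocal``),
5. the miRNA's expression stratum with worse survival matches its
   direction (``survival_concordant``),
6. the miRNA's targets are enriched in a cancer-related pathway
   (``pathway_enriched``).

Classification follows the sponge logic: a downregulated circRNA frees a
rising oncomiR (tumor-suppressor axis), an upregulated circRNA sequesters
a falling tumor-suppressive miRNA (onco-axis).  Vertical confidence counts
the evidence layers an axis satisfies; horizontal confidence counts the
validated axes in the panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .survival import ConcordanceCall

TUMOR_SUPPRESSOR_AXIS = "TumorSuppressorAxis"
ONCO_AXIS = "OncoAxis"

EVIDENCE_FLAGS = (
    "circ_de",
    "parent_concordant",
    "binding_high",
    "mirna_reciprocal",
    "survival_concordant",
    "pathway_enriched",
)


@dataclass
class AxisRecord:
    parent_gene_id: str
    circ_id: str
    mirna_id: str
    axis_class: str | None
    evidence: dict[str, bool]
    vertical_confidence: int


@dataclass
class AxisPanel:
    records: list[AxisRecord] = field(default_factory=list)

    @property
    def horizontal_confidence(self) -> int:
        return len(self.records)

    @property
    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for rec in self.records:
            key = rec.axis_class or "unclassified"
            counts[key] = counts.get(key, 0) + 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rec in self.records:
            row = {
                "parent_gene_id": rec.parent_gene_id,
                "circ_id": rec.circ_id,
                "mirna_id": rec.mirna_id,
                "axis_class": rec.axis_class or "unclassified",
            }
            row.update({f: rec.evidence[f] for f in EVIDENCE_FLAGS})
            row["vertical_confidence"] = rec.vertical_confidence
            rows.append(row)
        return pd.DataFrame(
            rows,
            columns=["parent_gene_id", "circ_id", "mirna_id", "axis_class",
                     *EVIDENCE_FLAGS, "vertical_confidence"],
        )


def reciprocal_match(circ_direction: str, mirna_direction: str) -> bool:
    """True iff the circRNA and miRNA move in opposite (non-ns) directions."""
    if circ_direction == "ns" or mirna_direction == "ns":
        return False
    return {circ_direction, mirna_direction} == {"up", "down"}


def classify_axis(circ_direction: str, mirna_direction: str) -> str:
    """Map opposite non-ns directions to the axis class.

    circRNA down with miRNA up: loss of a tumor-suppressive sponge frees an
    oncomiR (TumorSuppressorAxis).  circRNA up with miRNA down: an
    oncogenic sponge depletes a tumor-suppressive miRNA (OncoAxis).
    """
    if not reciprocal_match(circ_direction, mirna_direction):
        raise ValueError(
            f"cannot classify non-reciprocal directions "
            f"({circ_direction!r}, {mirna_direction!r})"
        )
    return TUMOR_SUPPRESSOR_AXIS if circ_direction == "down" else ONCO_AXIS


def assemble_axes(
    circ_de: pd.DataFrame,
    concordance: pd.DataFrame,
    candidate_pairs: pd.DataFrame,
    mirna_de: pd.DataFrame,
    survival_calls: Mapping[str, ConcordanceCall],
    enriched_mirnas: set[str],
    min_percentile: float = 72.0,
    mode: str = "strict",
    required_flags: tuple[str, ...] = EVIDENCE_FLAGS,
) -> AxisPanel:
    """Combine the evidence layers into a classified axis panel.

    ``candidate_pairs`` carries one row per (circ_id, mirna_id) pair with
    its best ``context_percentile``; ``concordance`` is indexed by circ_id
    and supplies the parent gene; ``survival_calls`` maps mirna_id to its
    survival-direction call.  In strict mode only triples with all six
    evidence flags are returned; exploratory mode returns every pair whose
    circRNA is significantly DE, with partial evidence visible.
    """
    if mode not in ("strict", "exploratory"):
        raise ValueError(f"unknown mode {mode!r}")
    records: list[AxisRecord] = []
    for row in candidate_pairs.itertuples():
        circ_id = row.circ_id
        mirna_id = row.mirna_id
        circ_dir = (
            str(circ_de.loc[circ_id, "direction"]) if circ_id in circ_de.index else "ns"
        )
        mirna_dir = (
            str(mirna_de.loc[mirna_id, "direction"])
            if mirna_id in mirna_de.index
            else "ns"
        )
        evidence = {
            "circ_de": circ_dir != "ns",
            "parent_concordant": bool(
                circ_id in concordance.index and concordance.loc[circ_id, "concordant"]
            ),
            "binding_high": bool(row.context_percentile >= min_percentile),
            "mirna_reciprocal": reciprocal_match(circ_dir, mirna_dir),
            "survival_concordant": bool(
                mirna_id in survival_calls and survival_calls[mirna_id].survival_pass
            ),
            "pathway_enriched": mirna_id in enriched_mirnas,
        }
        if mode == "strict" and not all(evidence[f] for f in required_flags):
            continue
        if mode == "exploratory" and not evidence["circ_de"]:
            continue
        axis_class = (
            classify_axis(circ_dir, mirna_dir)
            if evidence["mirna_reciprocal"]
            else None
        )
        parent = (
            str(concordance.loc[circ_id, "parent_gene_id"])
            if circ_id in concordance.index
            else ""
        )
        records.append(
            AxisRecord(
                parent_gene_id=parent,
                circ_id=circ_id,
                mirna_id=mirna_id,
                axis_class=axis_class,
                evidence=evidence,
                vertical_confidence=sum(evidence.values()),
            )
        )
    # deterministic ordering: class, then circ id, then miRNA id
    records.sort(key=lambda r: (r.axis_class or "zz", r.circ_id, r.mirna_id))
    return AxisPanel(records=records)


def confidence_report(panel: AxisPanel) -> dict:
    """Panel-level summary: vertical/horizontal confidence, class counts,
    and miRNAs shared across more than one axis."""
    shared: dict[str, int] = {}
    for rec in panel.records:
        shared[rec.mirna_id] = shared.get(rec.mirna_id, 0) + 1
    return {
        "horizontal_confidence": panel.horizontal_confidence,
        "class_counts": panel.class_counts,
        "axes": [
            {
                "parent_gene_id": r.parent_gene_id,
                "circ_id": r.circ_id,
                "mirna_id": r.mirna_id,
                "axis_class": r.axis_class or "unclassified",
                "vertical_confidence": r.vertical_confidence,
            }
            for r in panel.records
        ],
        "shared_mirnas": {m: c for m, c in sorted(shared.items()) if c > 1},
    }
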