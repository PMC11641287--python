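"""Bundled worked example: a published five-axis breast-cancer evidence panel.

The package ships, as plain data, the per-layer evidence for five candidate
mRNA/circRNA/miRNA axes reported in breast cancer: circRNA fold changes and
p values from a 5-tumor/5-normal array cohort, parent-gene p values from a
large reference tumor/normal comparison, context percentiles of the
predicted sponge interactions, miRNA fold changes and p values from a
10-pair cohort, and the log-rank p values of median-split survival curves.
These numbers were produced upstream with external services and
unpublished settings, so they are *inputs* here — loaded verbatim, never
recomputed.  What the package does recompute is everything downstream of
them: concordance, reciprocity, the survival-direction rule, pathway
over-representation (on bundled synthetic stand-in target/pathway tables
built around the miRNAs' reported target genes), and the axis assembly.

Expected outcome with default thresholds: exactly five axes — two
tumor-suppressor axes (down circRNA, up miRNA) and three onco-axes (up
circRNA, down miRNA), with hsa-miR-326-3p shared by two axes.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from . import io as cio
from .axes import AxisPanel, assemble_axes, confidence_report
from .concordance import parent_gene_concordance
from .enrichment import cancer_pathway_filter, enrich_mirnas
from .pipeline import PipelineConfig
from .survival import ConcordanceCall, LogRankResult

_DATA = resources.files("circaxis") / "data"


def _data_path(name: str):
    return _DATA / name


def load_example_evidence() -> pd.DataFrame:
    """The shipped per-axis evidence table, exactly as bundled."""
    with resources.as_file(_data_path("example_evidence.tsv")) as path:
        return pd.read_csv(path, sep="\t")


def load_example_design() -> cio.SampleDesign:
    """The 5-tumor/5-normal paired design of the circRNA cohort."""
    with resources.as_file(_data_path("example_circ_design.tsv")) as path:
        return cio.read_design_tsv(path)


def load_example_targets() -> dict[str, frozenset[str]]:
    with resources.as_file(_data_path("example_targets.tsv")) as path:
        return cio.read_target_map(path)


def load_example_pathways() -> cio.GeneSetCollection:
    with resources.as_file(_data_path("example_pathways.gmt")) as path:
        return cio.read_gmt(path)


def _de_frame(ids, log2fc, p, direction) -> pd.DataFrame:
    """DE-results frame from shipped summary statistics (fdr = shipped p)."""
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "t": log2fc,  # placeholder with the correct sign; not used downstream
            "p": p,
            "fdr": p,
            "direction": direction,
            "flagged": False,
        },
        index=pd.Index(ids, name="feature_id"),
    )


def load_example_inputs(config: PipelineConfig | None = None) -> dict:
    """Build every assembly input from the shipped evidence."""
    cfg = config or PipelineConfig()
    ev = load_example_evidence()

    circ = ev.drop_duplicates("circ_id")
    circ_de = _de_frame(circ["circ_id"], circ["circ_log2fc"].to_numpy(),
                        circ["circ_p"].to_numpy(), circ["circ_direction"].to_numpy())
    gene = ev.drop_duplicates("parent_gene_id")
    gene_sign = gene["gene_direction"].map({"up": 1.0, "down": -1.0}).to_numpy()
    gene_de = _de_frame(gene["parent_gene_id"], gene_sign,
                        gene["gene_p"].to_numpy(), gene["gene_direction"].to_numpy())
    mir = ev.drop_duplicates("mirna_id")
    mirna_de = _de_frame(mir["mirna_id"], mir["mirna_log2fc"].to_numpy(),
                         mir["mirna_p"].to_numpy(), mir["mirna_direction"].to_numpy())

    annotations = {
        row.circ_id: cio.CircAnnotation(row.circ_id, row.parent_gene_id)
        for row in ev.itertuples()
    }
    concordance = parent_gene_concordance(circ_de, annotations, gene_de,
                                          alpha_ref=cfg.alpha_ref)

    pairs = ev[["circ_id", "mirna_id", "context_percentile"]].copy()
    pairs.insert(2, "site_type", "")

    survival_calls: dict[str, ConcordanceCall] = {}
    for row in mir.itertuples():
        result = LogRankResult(
            mirna_id=row.mirna_id, chi2=float("nan"), p_value=float(row.km_p),
            worse_group=row.km_worse_group, n_high=0, n_low=0,
            median_cut=float("nan"))
        ok = result.p_value <= cfg.alpha_surv and (
            (row.mirna_direction == "up" and result.worse_group == "high")
            or (row.mirna_direction == "down" and result.worse_group == "low")
        )
        survival_calls[row.mirna_id] = ConcordanceCall(
            row.mirna_id, row.mirna_direction, bool(ok),
            "shipped survival evidence", result)

    enrichment = enrich_mirnas(load_example_targets(), load_example_pathways())
    enriched = cancer_pathway_filter(enrichment, cfg.whitelist, cfg.alpha_enrich)

    return dict(
        circ_de=circ_de, gene_de=gene_de, mirna_de=mirna_de,
        concordance=concordance, pairs=pairs, survival_calls=survival_calls,
        enrichment=enrichment, enriched_mirnas=enriched,
    )


def run_worked_example(config: PipelineConfig | None = None) -> tuple[AxisPanel, dict]:
    """Assemble the bundled evidence into the axis panel; returns (panel, report)."""
    cfg = config or PipelineConfig()
    inputs = load_example_inputs(cfg)
    panel = assemble_axes(
        inputs["circ_de"], inputs["concordance"], inputs["pairs"],
        inputs["mirna_de"], inputs["survival_calls"], inputs["enriched_mirnas"],
        min_percentile=cfg.min_percentile, mode=cfg.mode,
        required_flags=cfg.required_flags)
    return panel, confidence_report(panel)
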