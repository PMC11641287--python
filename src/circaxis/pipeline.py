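"""Stage orchestration: thresholds, manifests, and file-based stage runners.

The pipeline can run fully in memory on a :class:`~circaxis.simulate.Bundle`
(:func:`run_bundle`) or stage-by-stage over files in a bundle directory
(:func:`run_stage`, :func:`run_all`), which is what the CLI drives.  Every
file-based run appends to a JSON manifest in the output directory: resolved
configuration, per-stage input/output checksums, and surviving-candidate
counts.  All randomness lives in the synthetic generator; given fixed
inputs and configuration every stage is deterministic.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as cio
from .axes import EVIDENCE_FLAGS, AxisPanel, assemble_axes, confidence_report
from .concordance import parent_gene_concordance
from .diffexp import differential_expression, write_de_tsv, read_de_tsv
from .enrichment import DEFAULT_WHITELIST, cancer_pathway_filter, enrich_mirnas
from .simulate import BUNDLE_FILES, Bundle
from .sponge import filter_high_confidence, scan_pairs
from .survival import ConcordanceCall, survival_concordance

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


@dataclass
class PipelineConfig:
    """Thresholds and switches for one pipeline run."""

    alpha_de: float = 0.05        # FDR cut for circRNA/miRNA differential expression
    lfc_min: float = 0.0          # minimum |log2 fold change| for an up/down call
    alpha_ref: float = 0.05       # raw-p cut in the reference (parent-gene) cohort
    min_percentile: float = 72.0  # context-percentile cut for sponge sites
    alpha_surv: float = 0.06      # log-rank p cut (0.06 admits borderline 0.051 calls)
    alpha_enrich: float = 0.05    # FDR cut for pathway over-representation
    whitelist: tuple[str, ...] = tuple(sorted(DEFAULT_WHITELIST))
    mode: str = "strict"          # strict: all six evidence gates; exploratory: partial
    moderated: bool = True        # empirical-Bayes variance moderation in DE
    circular: bool = True         # scan circRNA sequences as rings
    parent_filter: bool = True    # require parent-gene concordance as a hard gate

    def __post_init__(self) -> None:
        for name in ("alpha_de", "alpha_ref", "alpha_surv", "alpha_enrich"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")
        if not 0 <= self.min_percentile <= 100:
            raise ValueError("min_percentile must lie in [0, 100]")
        if self.lfc_min < 0:
            raise ValueError("lfc_min must be >= 0")
        if self.mode not in ("strict", "exploratory"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def required_flags(self) -> tuple[str, ...]:
        if self.parent_filter:
            return EVIDENCE_FLAGS
        return tuple(f for f in EVIDENCE_FLAGS if f != "parent_concordant")


@dataclass
class RunResult:
    """Outputs of an in-memory end-to-end run."""

    circ_de: pd.DataFrame
    mirna_de: pd.DataFrame
    gene_de: pd.DataFrame
    concordance: pd.DataFrame
    sites: pd.DataFrame
    pairs: pd.DataFrame
    survival_calls: dict[str, ConcordanceCall]
    enrichment: pd.DataFrame
    enriched_mirnas: set[str]
    panel: AxisPanel
    report: dict
    filter_chain: dict[str, int] = field(default_factory=dict)


def run_bundle(bundle: Bundle, config: PipelineConfig | None = None) -> RunResult:
    """Run every stage on an in-memory bundle and assemble the axis panel."""
    cfg = config or PipelineConfig()
    circ_de = differential_expression(
        bundle.circ_matrix, bundle.circ_design,
        alpha=cfg.alpha_de, lfc_min=cfg.lfc_min, moderated=cfg.moderated)
    mirna_de = differential_expression(
        bundle.mirna_matrix, bundle.mirna_design,
        alpha=cfg.alpha_de, lfc_min=cfg.lfc_min, moderated=cfg.moderated)
    gene_de = differential_expression(
        bundle.gene_matrix, bundle.gene_design,
        alpha=cfg.alpha_de, lfc_min=cfg.lfc_min, moderated=cfg.moderated)
    concordance = parent_gene_concordance(
        circ_de, bundle.annotations, gene_de, alpha_ref=cfg.alpha_ref)

    sig_circ = [c for c in circ_de.index[circ_de["direction"] != "ns"]
                if c in bundle.circ_seqs]
    sites = scan_pairs({c: bundle.circ_seqs[c] for c in sig_circ},
                       bundle.mirna_seqs, circular=cfg.circular)
    # keep every pair of a significant circRNA; the percentile gate is
    # applied as an evidence flag during assembly
    pairs = filter_high_confidence(sites, circ_de, min_percentile=0.0)

    candidate_mirnas = sorted(set(pairs["mirna_id"])) if not pairs.empty else []
    survival_calls = {
        m: survival_concordance(m, mirna_de, bundle.survival, alpha_surv=cfg.alpha_surv)
        for m in candidate_mirnas
    }
    sub_map = {m: bundle.target_map[m] for m in candidate_mirnas
               if m in bundle.target_map and bundle.target_map[m]}
    if sub_map:
        enrichment = enrich_mirnas(sub_map, bundle.gene_sets)
        enriched = cancer_pathway_filter(enrichment, cfg.whitelist, cfg.alpha_enrich)
    else:
        enrichment = pd.DataFrame(
            columns=["mirna_id", "set_name", "k", "n", "K", "N", "p_hyper", "fdr"])
        enriched = set()

    panel = assemble_axes(
        circ_de, concordance, pairs, mirna_de, survival_calls, enriched,
        min_percentile=cfg.min_percentile, mode=cfg.mode,
        required_flags=cfg.required_flags)
    exploratory = assemble_axes(
        circ_de, concordance, pairs, mirna_de, survival_calls, enriched,
        min_percentile=cfg.min_percentile, mode="exploratory")
    chain = _filter_chain(exploratory)
    report = confidence_report(panel)
    report["filter_chain"] = chain
    return RunResult(
        circ_de=circ_de, mirna_de=mirna_de, gene_de=gene_de,
        concordance=concordance, sites=sites, pairs=pairs,
        survival_calls=survival_calls, enrichment=enrichment,
        enriched_mirnas=enriched, panel=panel, report=report,
        filter_chain=chain)


def _filter_chain(exploratory: AxisPanel) -> dict[str, int]:
    """Candidates surviving each cumulative gate, in pipeline order."""
    order = ["circ_de", "parent_concordant", "binding_high",
             "mirna_reciprocal", "survival_concordant", "pathway_enriched"]
    chain: dict[str, int] = {}
    for i, gate in enumerate(order):
        upto = order[: i + 1]
        chain[gate] = sum(
            1 for r in exploratory.records if all(r.evidence[g] for g in upto)
        )
    return chain


# ---------------------------------------------------------------------------
# file-based stages (the CLI layer)
# ---------------------------------------------------------------------------

STAGE_ORDER = ("diffexp", "concordance", "sites", "survival", "enrich", "axes")

#: per-stage (input files, producing stage or None for bundle inputs)
_STAGE_INPUTS = {
    "diffexp": {
        "circ_expression.tsv": None, "circ_design.tsv": None,
        "mirna_expression.tsv": None, "mirna_design.tsv": None,
        "gene_expression.tsv": None, "gene_design.tsv": None,
    },
    "concordance": {
        "circ_de.tsv": "diffexp", "gene_de.tsv": "diffexp",
        "annotations.tsv": None,
    },
    "sites": {
        "circ_de.tsv": "diffexp", "circ_sequences.fasta": None,
        "mirna_sequences.fasta": None,
    },
    "survival": {
        "mirna_de.tsv": "diffexp", "pairs.tsv": "sites", "survival.tsv": None,
    },
    "enrich": {
        "pairs.tsv": "sites", "targets.tsv": None, "pathways.gmt": None,
    },
    "axes": {
        "circ_de.tsv": "diffexp", "mirna_de.tsv": "diffexp",
        "concordance.tsv": "concordance", "pairs.tsv": "sites",
        "survival_calls.tsv": "survival", "retained_mirnas.tsv": "enrich",
    },
}


class StageError(RuntimeError):
    pass


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _locate(name: str, bundle_dir: Path, outdir: Path, producer: str | None) -> Path:
    where = outdir if producer else bundle_dir
    path = where / name
    if not path.exists():
        if producer:
            raise StageError(
                f"missing input {path}: run the '{producer}' stage first")
        raise StageError(f"missing bundle input {path}")
    return path


def run_stage(
    name: str, bundle_dir: str | Path, outdir: str | Path,
    config: PipelineConfig | None = None,
) -> dict:
    """Run one named stage over files; returns its manifest entry."""
    cfg = config or PipelineConfig()
    bundle_dir, outdir = Path(bundle_dir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if name not in _STAGE_INPUTS:
        raise StageError(f"unknown stage {name!r}; choose from {STAGE_ORDER}")
    input_spec = _STAGE_INPUTS[name]
    if name == "sites" and (bundle_dir / "interactions.tsv").exists():
        # precomputed interaction table: bypass sequence scanning entirely
        input_spec = {"circ_de.tsv": "diffexp", "interactions.tsv": None}
    inputs = {
        fname: _locate(fname, bundle_dir, outdir, producer)
        for fname, producer in input_spec.items()
    }
    counts = _STAGE_IMPL[name](inputs, outdir, cfg)
    entry = {
        "stage": name,
        "inputs": {str(p): _sha256(p) for p in inputs.values()},
        "outputs": {str(outdir / f): _sha256(outdir / f)
                    for f in _STAGE_OUTPUTS[name]},
        "counts": counts,
    }
    _append_manifest(outdir, cfg, entry)
    logger.info("stage %s: %s", name, counts)
    return entry


def _append_manifest(outdir: Path, cfg: PipelineConfig, entry: dict) -> None:
    path = outdir / "run_manifest.json"
    manifest = (
        json.loads(path.read_text(encoding="utf-8")) if path.exists()
        else {"version": __version__, "config": dataclasses.asdict(cfg),
              "stages": {}}
    )
    manifest["config"] = dataclasses.asdict(cfg)
    manifest["timestamp"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest["stages"][entry["stage"]] = entry
    path.write_text(json.dumps(manifest, indent=2, default=list) + "\n",
                    encoding="utf-8")


def _stage_diffexp(inputs, outdir: Path, cfg: PipelineConfig) -> dict:
    counts = {}
    for pool in ("circ", "mirna", "gene"):
        matrix, design = cio.read_expression_tsv(
            inputs[f"{pool}_expression.tsv"], inputs[f"{pool}_design.tsv"])
        de = differential_expression(
            matrix, design, alpha=cfg.alpha_de, lfc_min=cfg.lfc_min,
            moderated=cfg.moderated)
        write_de_tsv(de, outdir / f"{pool}_de.tsv")
        counts[f"{pool}_tested"] = int(len(de))
        counts[f"{pool}_significant"] = int((de["direction"] != "ns").sum())
    return counts


def _stage_concordance(inputs, outdir: Path, cfg: PipelineConfig) -> dict:
    circ_de = read_de_tsv(inputs["circ_de.tsv"])
    gene_de = read_de_tsv(inputs["gene_de.tsv"])
    annotations = cio.read_annotations(inputs["annotations.tsv"])
    conc = parent_gene_concordance(circ_de, annotations, gene_de,
                                   alpha_ref=cfg.alpha_ref)
    conc.to_csv(outdir / "concordance.tsv", sep="\t")
    return {"candidates": int(len(conc)),
            "concordant": int(conc["concordant"].sum())}


def _stage_sites(inputs, outdir: Path, cfg: PipelineConfig) -> dict:
    circ_de = read_de_tsv(inputs["circ_de.tsv"])
    if "interactions.tsv" in inputs:
        sites = cio.read_interaction_table(inputs["interactions.tsv"])
        if "site_type" not in sites.columns:
            sites["site_type"] = ""
    else:
        circ_seqs = cio.read_fasta(inputs["circ_sequences.fasta"])
        mirna_seqs = cio.read_fasta(inputs["mirna_sequences.fasta"])
        sig = [c for c in circ_de.index[circ_de["direction"] != "ns"]
               if c in circ_seqs]
        sites = scan_pairs({c: circ_seqs[c] for c in sig}, mirna_seqs,
                           circular=cfg.circular)
    cio.write_interaction_table(sites, outdir / "sites.tsv")
    pairs = filter_high_confidence(sites, circ_de, min_percentile=0.0)
    pairs.to_csv(outdir / "pairs.tsv", sep="\t", index=False)
    return {"sites": int(len(sites)), "pairs": int(len(pairs)),
            "pairs_high_confidence":
                int((pairs["context_percentile"] >= cfg.min_percentile).sum())
                if not pairs.empty else 0}


def _stage_survival(inputs, outdir: Path, cfg: PipelineConfig) -> dict:
    mirna_de = read_de_tsv(inputs["mirna_de.tsv"])
    pairs = pd.read_csv(inputs["pairs.tsv"], sep="\t", dtype={"mirna_id": str})
    table = cio.read_survival_tsv(inputs["survival.tsv"])
    calls = []
    for m in sorted(set(pairs["mirna_id"])) if not pairs.empty else []:
        call = survival_concordance(m, mirna_de, table, alpha_surv=cfg.alpha_surv)
        lr = call.logrank
        calls.append(
            dict(mirna_id=m, direction=call.mirna_direction,
                 chi2=lr.chi2 if lr else float("nan"),
                 p=lr.p_value if lr else float("nan"),
                 worse_group=lr.worse_group if lr else "",
                 survival_pass=call.survival_pass, reason=call.reason))
    df = pd.DataFrame(calls, columns=["mirna_id", "direction", "chi2", "p",
                                      "worse_group", "survival_pass", "reason"])
    df.to_csv(outdir / "survival_calls.tsv", sep="\t", index=False)
    return {"tested": int(len(df)),
            "passing": int(df["survival_pass"].sum()) if not df.empty else 0}


def _stage_enrich(inputs, outdir: Path, cfg: PipelineConfig) -> dict:
    pairs = pd.read_csv(inputs["pairs.tsv"], sep="\t", dtype={"mirna_id": str})
    target_map = cio.read_target_map(inputs["targets.tsv"])
    sets = cio.read_gmt(inputs["pathways.gmt"])
    candidates = sorted(set(pairs["mirna_id"])) if not pairs.empty else []
    sub = {m: target_map[m] for m in candidates if m in target_map}
    if sub:
        enr = enrich_mirnas(sub, sets)
        retained = cancer_pathway_filter(enr, cfg.whitelist, cfg.alpha_enrich)
    else:
        enr = pd.DataFrame(columns=["mirna_id", "set_name", "k", "n", "K", "N",
                                    "p_hyper", "fdr"])
        retained = set()
    enr.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
    pd.DataFrame({"mirna_id": sorted(retained)}).to_csv(
        outdir / "retained_mirnas.tsv", sep="\t", index=False)
    return {"mirnas_tested": int(len(sub)), "mirnas_retained": int(len(retained))}


def _stage_axes(inputs, outdir: Path, cfg: PipelineConfig) -> dict:
    circ_de = read_de_tsv(inputs["circ_de.tsv"])
    mirna_de = read_de_tsv(inputs["mirna_de.tsv"])
    conc = pd.read_csv(inputs["concordance.tsv"], sep="\t", index_col="circ_id")
    pairs = pd.read_csv(inputs["pairs.tsv"], sep="\t",
                        dtype={"circ_id": str, "mirna_id": str})
    surv = pd.read_csv(inputs["survival_calls.tsv"], sep="\t",
                       dtype={"mirna_id": str})
    retained = pd.read_csv(inputs["retained_mirnas.tsv"], sep="\t", dtype=str)
    calls = {
        r.mirna_id: ConcordanceCall(r.mirna_id, r.direction,
                                    bool(r.survival_pass), str(r.reason))
        for r in surv.itertuples()
    }
    enriched = set(retained["mirna_id"]) if not retained.empty else set()
    panel = assemble_axes(circ_de, conc, pairs, mirna_de, calls, enriched,
                          min_percentile=cfg.min_percentile, mode=cfg.mode,
                          required_flags=cfg.required_flags)
    panel.to_frame().to_csv(outdir / "panel.tsv", sep="\t", index=False)
    exploratory = assemble_axes(circ_de, conc, pairs, mirna_de, calls, enriched,
                                min_percentile=cfg.min_percentile,
                                mode="exploratory")
    report = confidence_report(panel)
    report["filter_chain"] = _filter_chain(exploratory)
    (outdir / "report.json").write_text(
        json.dumps(report, indent=2, default=list) + "\n", encoding="utf-8")
    counts = {"axes": panel.horizontal_confidence}
    counts.update({f"class_{k}": v for k, v in panel.class_counts.items()})
    return counts


_STAGE_IMPL = {
    "diffexp": _stage_diffexp,
    "concordance": _stage_concordance,
    "sites": _stage_sites,
    "survival": _stage_survival,
    "enrich": _stage_enrich,
    "axes": _stage_axes,
}

_STAGE_OUTPUTS = {
    "diffexp": ["circ_de.tsv", "mirna_de.tsv", "gene_de.tsv"],
    "concordance": ["concordance.tsv"],
    "sites": ["sites.tsv", "pairs.tsv"],
    "survival": ["survival_calls.tsv"],
    "enrich": ["enrichment.tsv", "retained_mirnas.tsv"],
    "axes": ["panel.tsv", "report.json"],
}


def run_all(bundle_dir: str | Path, outdir: str | Path,
            config: PipelineConfig | None = None) -> list[dict]:
    """Run every stage in order; returns the manifest entries."""
    return [run_stage(name, bundle_dir, outdir, config) for name in STAGE_ORDER]
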