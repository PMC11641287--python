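"""Synthetic cohort bundles with planted regulatory axes.

The generator emulates every input the axis-discovery pipeline consumes:
a small paired circRNA microarray cohort (default 5 tumor / 5 normal), a
paired miRNA cohort (default 10/10), a large unpaired reference
gene-expression cohort (default 114 normal / 1097 tumor), circRNA
sequences with planted seed sites, a miRNA->target map, pathway gene sets,
and an independent survival cohort whose hazard is linked to planted miRNA
expression.

Expression for feature f in sample s is
``baseline_f + group_shift + pair_effect + Normal(0, sigma^2)`` on the
log2 scale.  A planted tumor-suppressor axis shifts its gene by -delta,
its circRNA by -rho*delta and its miRNA by +gamma*delta in tumors; an
onco-axis is the mirror image.  Unplanted features have zero shift.

CircRNA backgrounds are rejection-sampled so that no circRNA carries a
chance seed match to any planted miRNA: the only (circRNA, planted-miRNA)
sites in the bundle are the deliberately planted ones.

Survival times are Weibull (exponential by default) with rate
``baseline_hazard * exp(sum of signed beta * z)`` over the planted
miRNAs' standardized expression (positive sign for upregulated miRNAs,
negative for downregulated ones); a fixed fraction of subjects is censored
uniformly on (0, t).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .axes import AxisPanel, ONCO_AXIS, TUMOR_SUPPRESSOR_AXIS
from .enrichment import DEFAULT_WHITELIST

_DECOY_SETS = (
    "olfactory transduction",
    "cardiac muscle contraction",
    "taste transduction",
    "circadian entrainment",
    "ribosome biogenesis",
)

_NT = np.array(list("AUCG"))
_COMPLEMENT = str.maketrans("AUCG", "UAGC")


@dataclass
class SyntheticConfig:
    """Cohort shapes, planted effects and noise for one synthetic bundle."""

    n_genes: int = 300
    n_circ: int = 200
    n_mirna: int = 150
    circ_tumor: int = 5
    circ_normal: int = 5
    circ_paired: bool = True
    mirna_tumor: int = 10
    mirna_normal: int = 10
    mirna_paired: bool = True
    ref_normal: int = 114
    ref_tumor: int = 1097
    #: (axis_class, effect size delta in log2 units) per planted axis
    planted_axes: tuple[tuple[str, float], ...] = (
        (TUMOR_SUPPRESSOR_AXIS, 1.5),
        (TUMOR_SUPPRESSOR_AXIS, 1.5),
        (ONCO_AXIS, 1.5),
        (ONCO_AXIS, 1.5),
        (ONCO_AXIS, 1.5),
    )
    baseline_range: tuple[float, float] = (6.0, 12.0)
    noise_sd: float = 0.4
    pair_sd: float = 0.2
    rho: float = 1.0    # circRNA/parent-gene coupling
    gamma: float = 1.0  # miRNA reciprocity
    surv_n: int = 200
    baseline_hazard: float = 0.1
    beta: float = 1.0
    censor_frac: float = 0.3
    weibull_shape: float = 1.0
    sites_per_pair: int = 2
    circ_length: int = 500
    mirna_length: int = 22
    seed: int = 0

    def __post_init__(self) -> None:
        counts = [self.n_genes, self.n_circ, self.n_mirna, self.circ_tumor,
                  self.circ_normal, self.mirna_tumor, self.mirna_normal,
                  self.ref_normal, self.ref_tumor, self.surv_n,
                  self.sites_per_pair, self.circ_length]
        if any(c <= 0 for c in counts):
            raise ValueError("all counts must be positive")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if not 0 <= self.censor_frac < 1:
            raise ValueError("censor_frac must lie in [0, 1)")
        if len(self.planted_axes) > min(self.n_genes, self.n_circ, self.n_mirna):
            raise ValueError("more planted axes than available features")
        for cls, delta in self.planted_axes:
            if cls not in (TUMOR_SUPPRESSOR_AXIS, ONCO_AXIS):
                raise ValueError(f"unknown axis class {cls!r}")
            if delta <= 0:
                raise ValueError("planted effect sizes must be positive")


@dataclass
class PlantedAxis:
    gene_id: str
    circ_id: str
    mirna_id: str
    axis_class: str
    delta: float


@dataclass
class Bundle:
    """In-memory synthetic bundle (one object per generated cohort set)."""

    config: SyntheticConfig
    circ_matrix: cio.ExpressionMatrix
    circ_design: cio.SampleDesign
    mirna_matrix: cio.ExpressionMatrix
    mirna_design: cio.SampleDesign
    gene_matrix: cio.ExpressionMatrix
    gene_design: cio.SampleDesign
    annotations: dict[str, cio.CircAnnotation]
    circ_seqs: dict[str, str]
    mirna_seqs: dict[str, str]
    target_map: dict[str, frozenset[str]]
    gene_sets: cio.GeneSetCollection
    survival: cio.SurvivalTable
    truth: list[PlantedAxis] = field(default_factory=list)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_NT, size=length))


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _make_matrix(rng, feature_ids, shifts, n_tumor, n_normal, paired, cfg, prefix):
    lo, hi = cfg.baseline_range
    baselines = rng.uniform(lo, hi, size=len(feature_ids))
    tumor_ids = [f"{prefix}_T{i + 1:04d}" for i in range(n_tumor)]
    normal_ids = [f"{prefix}_N{i + 1:04d}" for i in range(n_normal)]
    values = np.empty((len(feature_ids), n_tumor + n_normal))
    if paired:
        if n_tumor != n_normal:
            raise ValueError("paired cohorts need equal group sizes")
        pair_fx = rng.normal(0.0, cfg.pair_sd, size=(len(feature_ids), n_tumor))
    noise = rng.normal(0.0, cfg.noise_sd, size=values.shape)
    for j in range(n_tumor):
        values[:, j] = baselines + shifts + noise[:, j]
        if paired:
            values[:, j] += pair_fx[:, j]
    for j in range(n_normal):
        col = n_tumor + j
        values[:, col] = baselines + noise[:, col]
        if paired:
            values[:, col] += pair_fx[:, j]
    df = pd.DataFrame(values, index=feature_ids, columns=tumor_ids + normal_ids)
    groups = pd.Series(
        [cio.GROUP_TUMOR] * n_tumor + [cio.GROUP_NORMAL] * n_normal,
        index=pd.Index(tumor_ids + normal_ids, name="sample_id"),
    )
    pairs = None
    if paired:
        pairs = pd.Series(
            [f"{prefix}_P{i + 1:04d}" for i in range(n_tumor)] * 2,
            index=pd.Index(tumor_ids + normal_ids),
        )
    return cio.ExpressionMatrix(df), cio.SampleDesign(groups=groups, pairs=pairs)


def _core(mirna_seq: str) -> str:
    return _revcomp(mirna_seq[1:7])


def _site8(mirna_seq: str) -> str:
    # 8mer target site read 5'->3': complement of positions 2-8, then the A1 anchor
    return _revcomp(mirna_seq[1:8]) + "A"


def _count_core(seq: str, core: str) -> int:
    doubled = seq + seq[:5]
    return sum(1 for i in range(len(seq)) if doubled[i : i + 6] == core)


def _make_mirna_seqs(rng, mirna_ids, planted_ids, length):
    """Random miRNA sequences; planted miRNAs get mutually distinct seeds."""
    seqs: dict[str, str] = {}
    planted_cores: set[str] = set()
    for mid in mirna_ids:
        for _ in range(1000):
            seq = _random_seq(rng, length)
            if mid in planted_ids:
                core = _core(seq)
                if core in planted_cores:
                    continue
                planted_cores.add(core)
            seqs[mid] = seq
            break
        else:  # pragma: no cover - astronomically unlikely
            raise RuntimeError("could not draw a distinct miRNA seed")
    return seqs


def _make_circ_seqs(rng, circ_ids, planted_pairs, mirna_seqs, planted_mirnas, cfg):
    """Backgrounds free of chance seed matches to any planted miRNA.

    ``planted_pairs`` maps circ_id -> mirna_id for the true sponge pairs;
    those circRNAs carry ``sites_per_pair`` planted 8mer sites, everything
    else carries none.
    """
    cores = {m: _core(mirna_seqs[m]) for m in planted_mirnas}
    seqs: dict[str, str] = {}
    for circ_id in circ_ids:
        own = planted_pairs.get(circ_id)
        for _ in range(2000):
            seq = _random_seq(rng, cfg.circ_length)
            if own is not None:
                site = _site8(mirna_seqs[own])
                step = cfg.circ_length // cfg.sites_per_pair
                offsets = [
                    (i * step + int(rng.integers(0, max(1, step - len(site)))))
                    % cfg.circ_length
                    for i in range(cfg.sites_per_pair)
                ]
                chars = list(seq)
                for off in offsets:
                    for j, ch in enumerate(site):
                        chars[(off + j) % cfg.circ_length] = ch
                seq = "".join(chars)
            counts = {m: _count_core(seq, cores[m]) for m in planted_mirnas}
            expected = {m: 0 for m in planted_mirnas}
            if own is not None:
                expected[own] = cfg.sites_per_pair
            if counts == expected:
                seqs[circ_id] = seq
                break
        else:
            raise RuntimeError(f"rejection sampling failed for {circ_id}")
    return seqs


def generate(config: SyntheticConfig) -> Bundle:
    """Generate one fully in-memory bundle; deterministic for a fixed seed."""
    rng = np.random.default_rng(config.seed)
    gene_ids = [f"GENE{i + 1:04d}" for i in range(config.n_genes)]
    circ_ids = [f"circ_{i + 1:04d}" for i in range(config.n_circ)]
    mirna_ids = [f"miR-{i + 1:04d}" for i in range(config.n_mirna)]

    k = len(config.planted_axes)
    g_idx = rng.choice(config.n_genes, size=k, replace=False)
    c_idx = rng.choice(config.n_circ, size=k, replace=False)
    m_idx = rng.choice(config.n_mirna, size=k, replace=False)
    truth = [
        PlantedAxis(gene_ids[g], circ_ids[c], mirna_ids[m], cls, delta)
        for (cls, delta), g, c, m in zip(config.planted_axes, g_idx, c_idx, m_idx)
    ]

    # signed shifts per feature pool (tumor minus normal, log2 units)
    gene_shift = np.zeros(config.n_genes)
    circ_shift = np.zeros(config.n_circ)
    mirna_shift = np.zeros(config.n_mirna)
    for ax, g, c, m in zip(truth, g_idx, c_idx, m_idx):
        sign = -1.0 if ax.axis_class == TUMOR_SUPPRESSOR_AXIS else 1.0
        gene_shift[g] = sign * ax.delta
        circ_shift[c] = sign * config.rho * ax.delta
        mirna_shift[m] = -sign * config.gamma * ax.delta

    circ_matrix, circ_design = _make_matrix(
        rng, circ_ids, circ_shift, config.circ_tumor, config.circ_normal,
        config.circ_paired, config, "CIRC")
    mirna_matrix, mirna_design = _make_matrix(
        rng, mirna_ids, mirna_shift, config.mirna_tumor, config.mirna_normal,
        config.mirna_paired, config, "MIR")
    gene_matrix, gene_design = _make_matrix(
        rng, gene_ids, gene_shift, config.ref_tumor, config.ref_normal,
        False, config, "REF")

    # annotations: planted circRNAs point at their planted parent; the rest
    # draw a parent uniformly from the unplanted genes
    planted_gene_of = {ax.circ_id: ax.gene_id for ax in truth}
    unplanted_genes = [g for i, g in enumerate(gene_ids) if i not in set(g_idx)]
    annotations = {}
    for circ_id in circ_ids:
        parent = planted_gene_of.get(circ_id)
        if parent is None:
            parent = unplanted_genes[int(rng.integers(0, len(unplanted_genes)))]
        annotations[circ_id] = cio.CircAnnotation(circ_id, parent)

    planted_mirnas = sorted({ax.mirna_id for ax in truth})
    mirna_seqs = _make_mirna_seqs(rng, mirna_ids, set(planted_mirnas),
                                  config.mirna_length)
    planted_pairs = {ax.circ_id: ax.mirna_id for ax in truth}
    circ_seqs = _make_circ_seqs(rng, circ_ids, planted_pairs, mirna_seqs,
                                planted_mirnas, config)

    # pathway sets over a dedicated pathway-gene pool, plus decoys
    pool = [f"PATH{i + 1:04d}" for i in range(400)]
    set_names = sorted(DEFAULT_WHITELIST) + list(_DECOY_SETS)
    sets = {}
    for name in set_names:
        members = rng.choice(len(pool), size=25, replace=False)
        sets[name] = frozenset(pool[i] for i in members)
    gene_sets = cio.GeneSetCollection(sets=sets, universe=frozenset(pool))

    whitelist_cycle = sorted(DEFAULT_WHITELIST)
    target_map: dict[str, frozenset[str]] = {}
    planted_set_of = {
        m: whitelist_cycle[i % len(whitelist_cycle)]
        for i, m in enumerate(planted_mirnas)
    }
    for mid in mirna_ids:
        if mid in planted_set_of:
            members = sorted(sets[planted_set_of[mid]])
            in_set = rng.choice(len(members), size=8, replace=False)
            background = rng.choice(len(pool), size=7, replace=False)
            targets = {members[i] for i in in_set} | {pool[i] for i in background}
        else:
            background = rng.choice(len(pool), size=15, replace=False)
            targets = {pool[i] for i in background}
        target_map[mid] = frozenset(targets)

    # survival cohort: standardized expression per miRNA; hazard tied to the
    # planted miRNAs only (positive beta for up-miRNAs, negative for down)
    z = rng.standard_normal((config.surv_n, config.n_mirna))
    expr = pd.DataFrame(
        z, index=[f"SURV{i + 1:04d}" for i in range(config.surv_n)],
        columns=mirna_ids,
    )
    log_rel_hazard = np.zeros(config.surv_n)
    for ax in truth:
        j = mirna_ids.index(ax.mirna_id)
        sign = 1.0 if ax.axis_class == TUMOR_SUPPRESSOR_AXIS else -1.0
        # TS axis -> miRNA up in tumors -> high expression worse (beta > 0)
        log_rel_hazard += sign * config.beta * z[:, j]
    rate = config.baseline_hazard * np.exp(log_rel_hazard)
    base = rng.exponential(1.0, size=config.surv_n)
    times = (base / rate) ** (1.0 / config.weibull_shape)
    events = np.ones(config.surv_n, dtype=int)
    n_censor = int(np.floor(config.censor_frac * config.surv_n))
    if n_censor:
        censored = rng.choice(config.surv_n, size=n_censor, replace=False)
        times[censored] *= rng.uniform(0.0, 1.0, size=n_censor)
        events[censored] = 0
    times = np.maximum(times, 1e-9)
    survival = cio.SurvivalTable(
        time=pd.Series(times, index=expr.index),
        event=pd.Series(events, index=expr.index),
        expression=expr,
    )

    return Bundle(
        config=config,
        circ_matrix=circ_matrix, circ_design=circ_design,
        mirna_matrix=mirna_matrix, mirna_design=mirna_design,
        gene_matrix=gene_matrix, gene_design=gene_design,
        annotations=annotations, circ_seqs=circ_seqs, mirna_seqs=mirna_seqs,
        target_map=target_map, gene_sets=gene_sets, survival=survival,
        truth=truth,
    )


BUNDLE_FILES = {
    "circ_expression": "circ_expression.tsv",
    "circ_design": "circ_design.tsv",
    "mirna_expression": "mirna_expression.tsv",
    "mirna_design": "mirna_design.tsv",
    "gene_expression": "gene_expression.tsv",
    "gene_design": "gene_design.tsv",
    "annotations": "annotations.tsv",
    "circ_fasta": "circ_sequences.fasta",
    "mirna_fasta": "mirna_sequences.fasta",
    "targets": "targets.tsv",
    "gmt": "pathways.gmt",
    "survival": "survival.tsv",
    "truth": "truth.tsv",
    "manifest": "manifest.json",
}


def generate_bundle(config: SyntheticConfig, outdir: str | Path) -> Bundle:
    """Generate a bundle and write it to ``outdir`` in the pipeline's formats."""
    bundle = generate(config)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    f = {k: out / v for k, v in BUNDLE_FILES.items()}
    cio.write_expression_tsv(bundle.circ_matrix, f["circ_expression"])
    cio.write_design_tsv(bundle.circ_design, f["circ_design"])
    cio.write_expression_tsv(bundle.mirna_matrix, f["mirna_expression"])
    cio.write_design_tsv(bundle.mirna_design, f["mirna_design"])
    cio.write_expression_tsv(bundle.gene_matrix, f["gene_expression"])
    cio.write_design_tsv(bundle.gene_design, f["gene_design"])
    cio.write_annotations(bundle.annotations, f["annotations"])
    cio.write_fasta(bundle.circ_seqs, f["circ_fasta"])
    cio.write_fasta(bundle.mirna_seqs, f["mirna_fasta"])
    cio.write_target_map(bundle.target_map, f["targets"])
    cio.write_gmt(bundle.gene_sets, f["gmt"])
    cio.write_survival_tsv(bundle.survival, f["survival"])
    pd.DataFrame(
        [dataclasses.asdict(ax) for ax in bundle.truth],
        columns=["gene_id", "circ_id", "mirna_id", "axis_class", "delta"],
    ).to_csv(f["truth"], sep="\t", index=False)
    manifest = {
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "rng": "numpy default_rng (PCG64), single stream, fixed draw order",
        "files": {k: v for k, v in BUNDLE_FILES.items() if k != "manifest"},
    }
    f["manifest"].write_text(json.dumps(manifest, indent=2, default=list) + "\n",
                             encoding="utf-8")
    return bundle


def read_truth(path: str | Path) -> list[PlantedAxis]:
    df = pd.read_csv(path, sep="\t", dtype={"delta": float})
    return [
        PlantedAxis(r.gene_id, r.circ_id, r.mirna_id, r.axis_class, float(r.delta))
        for r in df.itertuples()
    ]


def recovery_metrics(panel: AxisPanel, truth: list[PlantedAxis]) -> tuple[float, float]:
    """(sensitivity, false-discovery proportion) of a panel vs the planted truth.

    Sensitivity = recovered planted triples / planted; FDP = non-planted
    recovered / recovered, defined as 0 for an empty panel.
    """
    truth_triples = {(ax.gene_id, ax.circ_id, ax.mirna_id) for ax in truth}
    found = {(r.parent_gene_id, r.circ_id, r.mirna_id) for r in panel.records}
    if truth_triples:
        sensitivity = len(found & truth_triples) / len(truth_triples)
    else:
        sensitivity = float("nan")
    fdp = len(found - truth_triples) / len(found) if found else 0.0
    return sensitivity, fdp
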