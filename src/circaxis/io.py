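"""Domain containers and plain-text readers/writers.

Every external format the pipeline touches is tab-separated UTF-8 text
(expression matrices, sample designs, circRNA annotations, interaction
tables, miRNA target maps, survival tables), GMT for gene sets, or FASTA
for sequences.  All expression values are assumed already log2-transformed
and normalized; normalization is a precondition, not a pipeline stage.

Identifiers are opaque, case-sensitive strings.  Readers validate
invariants eagerly and report the offending location; they never silently
drop rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

RNA_ALPHABET = frozenset("AUCG")

GROUP_TUMOR = "tumor"
GROUP_NORMAL = "normal"


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class ExpressionMatrix:
    """Features x samples grid of log2 intensities.

    ``values`` is a pandas DataFrame indexed by feature id with sample ids
    as columns.  Entries must be finite or NaN; NaN marks a missing
    measurement (such features are dropped, never imputed, in any contrast
    that touches them).
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.duplicated().any():
            dup = idx[idx.duplicated()][0]
            raise FormatError(f"duplicate feature id: {dup!r}")
        if cols.duplicated().any():
            dup = cols[cols.duplicated()][0]
            raise FormatError(f"duplicate sample id: {dup!r}")
        arr = self.values.to_numpy().astype(float, copy=False)
        if arr.size and np.isinf(arr).any():
            bad = np.argwhere(np.isinf(arr))[0]
            raise FormatError(
                f"non-finite value at feature {idx[bad[0]]!r}, sample {cols[bad[1]]!r}"
            )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class SampleDesign:
    """Tumor/normal group assignment with optional tumor-normal pairing."""

    groups: pd.Series  # sample_id -> {tumor, normal}
    pairs: pd.Series | None = None  # sample_id -> pair_id

    def __post_init__(self) -> None:
        bad = set(self.groups.unique()) - {GROUP_TUMOR, GROUP_NORMAL}
        if bad:
            raise FormatError(f"unknown group label(s): {sorted(bad)}")
        if self.groups.index.duplicated().any():
            dup = self.groups.index[self.groups.index.duplicated()][0]
            raise FormatError(f"sample {dup!r} assigned more than once")
        if self.pairs is not None:
            for pair_id, members in self.pairs.groupby(self.pairs).groups.items():
                labels = sorted(self.groups.loc[list(members)])
                if labels != [GROUP_NORMAL, GROUP_TUMOR]:
                    raise FormatError(
                        f"pair {pair_id!r} must contain exactly one tumor and one "
                        f"normal sample, got {labels}"
                    )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.groups.index)

    def samples_in(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])

    @property
    def is_paired(self) -> bool:
        return self.pairs is not None and len(self.pairs) > 0


@dataclass
class CircAnnotation:
    """circRNA to parent gene mapping, optionally with the circular sequence."""

    circ_id: str
    parent_gene_id: str
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.sequence is not None:
            if not self.sequence:
                raise FormatError(f"{self.circ_id}: empty sequence")
            extra = set(self.sequence) - RNA_ALPHABET
            if extra:
                raise FormatError(
                    f"{self.circ_id}: invalid RNA characters {sorted(extra)}"
                )


@dataclass
class GeneSetCollection:
    """Named gene sets over a common universe."""

    sets: dict[str, frozenset[str]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise FormatError(f"gene set {name!r} is empty")
            stray = members - self.universe
            if stray:
                raise FormatError(
                    f"gene set {name!r} has members outside the universe: "
                    f"{sorted(stray)[:5]}"
                )


@dataclass
class SurvivalTable:
    """Per-sample follow-up time, event flag and expression per miRNA."""

    time: pd.Series
    event: pd.Series
    expression: pd.DataFrame  # samples x miRNAs

    def __post_init__(self) -> None:
        if (self.time <= 0).any():
            bad = self.time.index[self.time <= 0][0]
            raise FormatError(f"non-positive survival time for sample {bad!r}")
        if not self.event.isin([0, 1]).all():
            bad = self.event.index[~self.event.isin([0, 1])][0]
            raise FormatError(f"event flag not in {{0,1}} for sample {bad!r}")

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.expression.columns)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_expression_tsv(
    path: str | Path, design_path: str | Path
) -> tuple[ExpressionMatrix, SampleDesign]:
    """Read an expression matrix plus its sample design.

    The matrix TSV has a header row of sample ids and feature ids in the
    first column; the design TSV has columns ``sample_id``, ``group`` and
    optionally ``pair_id``.  Every matrix sample must appear in the design.
    Row and column order are preserved.
    """
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    seen: set[str] = set()
    for sample in header:
        if sample in seen:
            raise FormatError(f"{path}: duplicate sample id: {sample!r}")
        seen.add(sample)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            raise FormatError(
                f"{path}: non-numeric value at feature {df.index[bad.argmax()]!r}, "
                f"sample {col!r}"
            )
        df[col] = coerced
    matrix = ExpressionMatrix(df.astype(float))
    design = read_design_tsv(design_path)
    missing = set(matrix.sample_ids) - set(design.sample_ids)
    if missing:
        raise FormatError(
            f"{path}: sample(s) missing from design: {sorted(missing)}"
        )
    return matrix, design


def read_design_tsv(path: str | Path) -> SampleDesign:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "group"}
    if not required <= set(df.columns):
        raise FormatError(f"{path}: design needs columns {sorted(required)}")
    groups = pd.Series(
        df["group"].to_numpy(), index=pd.Index(df["sample_id"], name="sample_id")
    )
    pairs = None
    if "pair_id" in df.columns and df["pair_id"].notna().any():
        sub = df[df["pair_id"].notna()]
        pairs = pd.Series(
            sub["pair_id"].to_numpy(), index=pd.Index(sub["sample_id"])
        )
    return SampleDesign(groups=groups, pairs=pairs)


def write_expression_tsv(
    matrix: ExpressionMatrix, path: str | Path, design: SampleDesign | None = None,
    design_path: str | Path | None = None,
) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="feature_id")
    if design is not None and design_path is not None:
        write_design_tsv(design, design_path)


def write_design_tsv(design: SampleDesign, path: str | Path) -> None:
    df = pd.DataFrame({"sample_id": design.sample_ids,
                       "group": design.groups.to_numpy()})
    if design.pairs is not None:
        df["pair_id"] = [design.pairs.get(s, "") for s in design.sample_ids]
    df.to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path, universe: set[str] | None = None) -> GeneSetCollection:
    """Read a GMT file: one set per line — name, description, members.

    The universe defaults to the union of all members unless supplied.
    """
    sets: dict[str, frozenset[str]] = {}
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not any(line.strip() for line in lines):
        raise FormatError(f"{path}: empty GMT file")
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(
                f"{path}:{lineno}: GMT line needs >=3 tab-separated fields"
            )
        name = fields[0]
        members = frozenset(m for m in fields[2:] if m)
        if name in sets:
            raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
        sets[name] = members
    full = frozenset().union(*sets.values())
    uni = frozenset(universe) if universe is not None else full
    return GeneSetCollection(sets=sets, universe=uni | full)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in collection.sets.items():
            fh.write("\t".join([name, "na", *sorted(members)]) + "\n")


def read_interaction_table(path: str | Path) -> pd.DataFrame:
    """Read a precomputed circRNA-miRNA interaction table.

    Columns: circ_id, mirna_id, context_percentile (0-100), optional
    site_type and position.  Returns one row per predicted site.
    """
    df = pd.read_csv(path, sep="\t", dtype={"circ_id": str, "mirna_id": str})
    required = {"circ_id", "mirna_id", "context_percentile"}
    if not required <= set(df.columns):
        raise FormatError(f"{path}: interaction table needs columns {sorted(required)}")
    pct = pd.to_numeric(df["context_percentile"], errors="coerce")
    if pct.isna().any():
        raise FormatError(f"{path}: non-numeric context percentile")
    if ((pct < 0) | (pct > 100)).any():
        row = int(((pct < 0) | (pct > 100)).argmax())
        raise FormatError(
            f"{path}: context percentile outside [0,100] at data row {row + 1} "
            f"({pct.iloc[row]})"
        )
    df["context_percentile"] = pct.astype(float)
    return df


def write_interaction_table(sites: pd.DataFrame, path: str | Path) -> None:
    sites.to_csv(path, sep="\t", index=False)


def read_annotations(path: str | Path) -> dict[str, CircAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"circ_id", "parent_gene_id"} <= set(df.columns):
        raise FormatError(f"{path}: annotation needs circ_id and parent_gene_id")
    if df["circ_id"].duplicated().any():
        dup = df["circ_id"][df["circ_id"].duplicated()].iloc[0]
        raise FormatError(f"{path}: duplicate circ_id {dup!r}")
    return {
        row.circ_id: CircAnnotation(row.circ_id, row.parent_gene_id)
        for row in df.itertuples()
    }


def write_annotations(annotations: Mapping[str, CircAnnotation], path: str | Path) -> None:
    pd.DataFrame(
        {"circ_id": [a.circ_id for a in annotations.values()],
         "parent_gene_id": [a.parent_gene_id for a in annotations.values()]}
    ).to_csv(path, sep="\t", index=False)


def read_target_map(path: str | Path) -> dict[str, frozenset[str]]:
    """Read a miRNA -> target-gene table (one mirna_id, gene_id pair per line)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"mirna_id", "gene_id"} <= set(df.columns):
        raise FormatError(f"{path}: target map needs mirna_id and gene_id columns")
    return {
        mirna: frozenset(sub["gene_id"])
        for mirna, sub in df.groupby("mirna_id", sort=True)
    }


def write_target_map(target_map: Mapping[str, frozenset[str]], path: str | Path) -> None:
    rows = [
        {"mirna_id": m, "gene_id": g}
        for m in sorted(target_map)
        for g in sorted(target_map[m])
    ]
    pd.DataFrame(rows, columns=["mirna_id", "gene_id"]).to_csv(path, sep="\t", index=False)


def read_survival_tsv(path: str | Path) -> SurvivalTable:
    """Read a survival table: sample_id, time, event, one column per miRNA."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if not {"sample_id", "time", "event"} <= set(df.columns):
        raise FormatError(f"{path}: survival table needs sample_id, time, event")
    df = df.set_index("sample_id")
    expr_cols = [c for c in df.columns if c not in ("time", "event")]
    return SurvivalTable(
        time=df["time"].astype(float),
        event=df["event"].astype(int),
        expression=df[expr_cols].astype(float),
    )


def write_survival_tsv(table: SurvivalTable, path: str | Path) -> None:
    out = pd.DataFrame({"time": table.time, "event": table.event})
    out = pd.concat([out, table.expression], axis=1)
    out.to_csv(path, sep="\t", index_label="sample_id")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read RNA sequences from FASTA; validates the AUCG alphabet."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        extra = set(seq) - RNA_ALPHABET
        if extra:
            raise FormatError(f"{path}: {rec.id}: invalid characters {sorted(extra)}")
        if rec.id in seqs:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        seqs[rec.id] = seq
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")
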