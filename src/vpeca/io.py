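"""Data model and tabular/interval readers and writers.

All genomic intervals are 0-based half-open ``[start, end)`` (BED
convention); a TSS is a single 0-based position.  Matrices are pandas
DataFrames whose columns are sample ids tied to a :class:`SampleDesign`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TIME_LEVELS = ("0h", "6h", "1d", "3d", "5d")
POPULATIONS = ("adaptive", "wildtype")


class AlignmentError(ValueError):
    """Sample sets of a matrix and the design do not match."""


class DesignError(ValueError):
    """The sample design violates an invariant."""


@dataclass
class SampleDesign:
    """Sample sheet: one row per sample (individual x time point).

    The population label is binary, ``adaptive`` vs ``wildtype``; the
    indicator ``delta`` is 1 for adaptive samples.  Each individual keeps
    one population label across all its time points and each
    (individual, time) pair occurs once.
    """

    table: pd.DataFrame  # columns: sample_id, individual, time, population

    def __post_init__(self) -> None:
        required = {"sample_id", "individual", "time", "population"}
        missing = required - set(self.table.columns)
        if missing:
            raise DesignError(f"design is missing columns: {sorted(missing)}")
        t = self.table
        bad_time = set(t["time"]) - set(TIME_LEVELS)
        if bad_time:
            raise DesignError(f"unknown time levels {sorted(bad_time)}; expected {TIME_LEVELS}")
        bad_pop = set(t["population"]) - set(POPULATIONS)
        if bad_pop:
            raise DesignError(f"unknown population labels {sorted(bad_pop)}")
        if t["sample_id"].duplicated().any():
            raise DesignError("duplicated sample_id in design")
        dup = t.duplicated(subset=["individual", "time"])
        if dup.any():
            pair = t.loc[dup, ["individual", "time"]].iloc[0]
            raise DesignError(f"duplicated (individual, time) pair: {tuple(pair)}")
        npop = t.groupby("individual")["population"].nunique()
        if (npop > 1).any():
            raise DesignError(f"individual with >1 population label: {npop[npop > 1].index.tolist()}")
        self.table = t.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    @property
    def delta(self) -> np.ndarray:
        """Per-sample population indicator (1 = adaptive)."""
        return (self.table["population"].to_numpy() == "adaptive").astype(float)

    def groups(self) -> pd.core.groupby.DataFrameGroupBy:
        """Replicate groups, one per (population, time) condition."""
        return self.table.groupby(["population", "time"], sort=False)

    def samples_at(self, time: str) -> pd.DataFrame:
        return self.table[self.table["time"] == time]


def _check_alignment(values: pd.DataFrame, design: SampleDesign, what: str) -> pd.DataFrame:
    missing = set(design.sample_ids) - set(values.columns)
    if missing:
        raise AlignmentError(f"{what} is missing design sample(s): {sorted(missing)}")
    extra = set(values.columns) - set(design.sample_ids)
    if extra:
        raise AlignmentError(f"{what} has sample(s) absent from design: {sorted(extra)}")
    values = values[design.sample_ids]
    if not np.isfinite(values.to_numpy(dtype=float)).all():
        raise ValueError(f"{what} contains non-finite values")
    return values


@dataclass
class ExpressionMatrix:
    """FPKM-like expression, genes x samples, aligned to a design."""

    values: pd.DataFrame
    design: SampleDesign
    gene_roles: pd.Series | None = None  # per-gene flag: TF | TG | both

    def __post_init__(self) -> None:
        self.values = _check_alignment(self.values, self.design, "expression matrix")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")
        if self.values.isna().all(axis=1).any():
            raise ValueError("expression matrix has an all-missing gene row")

    @property
    def genes(self) -> list[str]:
        return self.values.index.tolist()


@dataclass
class OpennessMatrix:
    """Openness scores, REs x samples, aligned to a design."""

    values: pd.DataFrame
    design: SampleDesign

    def __post_init__(self) -> None:
        self.values = _check_alignment(self.values, self.design, "openness matrix")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("openness values must be non-negative")

    @property
    def res(self) -> list[str]:
        return self.values.index.tolist()


@dataclass(frozen=True)
class GeneAnnotation:
    gene_id: str
    chrom: str
    tss: int
    strand: str

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValueError(f"{self.gene_id}: TSS must be >= 0")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be + or -")


@dataclass(frozen=True)
class RegulatoryElement:
    re_id: str
    chrom: str
    start: int
    end: int
    re_class: str = "distal"  # promoter | distal

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.re_id}: empty/inverted interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class LoopRecord:
    """A chromatin loop; the span covers both anchors."""

    chrom: str
    anchor1: tuple[int, int]
    anchor2: tuple[int, int]

    @property
    def span(self) -> tuple[int, int]:
        return (min(self.anchor1[0], self.anchor2[0]), max(self.anchor1[1], self.anchor2[1]))

    def contains(self, pos: int) -> bool:
        s, e = self.span
        return s <= pos < e


@dataclass
class MotifHitMatrix:
    """Summed motif match strengths, REs x TFs.

    ``B.loc[k, m]`` is the sum of the match strengths of every motif
    assigned to TF ``m`` on RE ``k`` (reference-genome scan, shared by all
    individuals).  ``mb(k)`` is the TF set with any hit on RE ``k``.
    """

    B: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.B.to_numpy() < 0).any():
            raise ValueError("motif match strengths must be non-negative")

    @property
    def tfs(self) -> list[str]:
        return self.B.columns.tolist()

    def mb(self, re_id: str) -> list[str]:
        row = self.B.loc[re_id]
        return row.index[row > 0].tolist()


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_design(path) -> SampleDesign:
    return SampleDesign(pd.read_csv(path, sep="\t", dtype=str))


def _read_matrix(path, what: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.to_numpy().nonzero()[0][0]]
            raise ValueError(f"{what}: non-numeric cell at row {row!r}, column {col!r}")
    return df.astype(float)


def read_design_and_matrices(expression_path, openness_path, design_path):
    """Read the three core TSVs and column-align the matrices to the design."""
    design = read_design(design_path)
    expr = ExpressionMatrix(_read_matrix(expression_path, "expression matrix"), design)
    openness = OpennessMatrix(_read_matrix(openness_path, "openness matrix"), design)
    return expr, openness, design


def read_intervals(path, kind: str = "bed"):
    """Parse a BED3+ file into REs, or a BEDPE file into loops.

    BEDPE records whose anchors sit on different chromosomes are skipped
    with a warning (trans contacts carry no regulatory boundary here).
    """
    if kind not in ("bed", "bedpe"):
        raise ValueError(f"kind must be 'bed' or 'bedpe', got {kind!r}")
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            try:
                if kind == "bed":
                    chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                    name = fields[3] if len(fields) > 3 else f"{chrom}_{start}_{end}"
                    out.append(RegulatoryElement(name, chrom, start, end))
                else:
                    c1, s1, e1 = fields[0], int(fields[1]), int(fields[2])
                    c2, s2, e2 = fields[3], int(fields[4]), int(fields[5])
                    if c1 != c2:
                        warnings.warn(f"{path}:{lineno}: trans BEDPE record skipped")
                        continue
                    out.append(LoopRecord(c1, (s1, e1), (s2, e2)))
            except (IndexError, ValueError) as exc:
                if isinstance(exc, ValueError) and "interval" in str(exc):
                    raise ValueError(f"{path}:{lineno}: {exc}") from None
                raise ValueError(f"{path}:{lineno}: malformed {kind.upper()} line") from None
    return out


def read_motif_hits(path, res: list[str] | None = None, tfs: list[str] | None = None) -> MotifHitMatrix:
    """Read a motif-hit TSV (motif_id, tf, re_id, strength) into a summed RE x TF matrix.

    Several motifs may map to one TF; strengths are summed per (RE, TF).
    """
    df = pd.read_csv(path, sep="\t", dtype={"motif_id": str, "tf": str, "re_id": str})
    pivot = df.pivot_table(index="re_id", columns="tf", values="strength", aggfunc="sum", fill_value=0.0)
    if res is not None:
        pivot = pivot.reindex(res, fill_value=0.0)
    if tfs is not None:
        pivot = pivot.reindex(columns=tfs, fill_value=0.0)
    return MotifHitMatrix(pivot)


NETWORK_COLUMNS = ["TF", "RE_id", "TG", "beta", "gamma", "alpha", "P_selected", "class", "omega_flag"]


def write_network(triplets: pd.DataFrame, path) -> None:
    """Write a triplet table (one row per TF-RE-TG) to TSV."""
    df = triplets.reindex(columns=NETWORK_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_network(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"TF": str, "RE_id": str, "TG": str, "class": str})
    if df.empty:
        return df.reindex(columns=NETWORK_COLUMNS)
    df["omega_flag"] = df["omega_flag"].astype(bool)
    return df


def write_matrix(values: pd.DataFrame, path, index_label: str) -> None:
    values.to_csv(path, sep="\t", index_label=index_label)


def write_design(design: SampleDesign, path) -> None:
    design.table.to_csv(path, sep="\t", index=False)


def write_res_bed(res: list[RegulatoryElement], path) -> None:
    with open(path, "w") as fh:
        for r in res:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.re_id}\t{r.re_class}\n")


def write_loops_bedpe(loops: list[LoopRecord], path) -> None:
    with open(path, "w") as fh:
        for lp in loops:
            a1, a2 = lp.anchor1, lp.anchor2
            fh.write(f"{lp.chrom}\t{a1[0]}\t{a1[1]}\t{lp.chrom}\t{a2[0]}\t{a2[1]}\n")
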