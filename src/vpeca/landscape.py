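"""RE catalog, per-gene regulatory boundaries and candidate RE->gene map.

A gene's regulatory boundary is the +/-1 Mb window around its TSS,
intersected with the smallest chromatin loop whose span contains the TSS
(no containing loop: the bare window).  Candidate distal REs are the
intersection of the H3K27ac and H3K4me1 mark sets; every gene also gets a
2 kb strand-aware promoter.  Openness is quantified as the fold change of
reads per base pair over the genome-wide average, so uniform coverage
scores 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GeneAnnotation, RegulatoryElement, SampleDesign


def regulatory_boundary(gene: GeneAnnotation, loops, flank: int = 1_000_000) -> tuple[int, int]:
    """The TSS window clipped at 0, intersected with the tightest containing loop.

    Among loops whose span contains the TSS, the smallest span wins (ties:
    leftmost start).  A containing loop wider than the window leaves the
    window unchanged.
    """
    w = (max(0, gene.tss - flank), gene.tss + flank)
    containing = [lp for lp in loops if lp.chrom == gene.chrom and lp.contains(gene.tss)]
    if not containing:
        return w
    best = min(containing, key=lambda lp: (lp.span[1] - lp.span[0], lp.span[0]))
    s, e = best.span
    return (max(w[0], s), min(w[1], e))


def _merge(intervals) -> list[tuple[int, int]]:
    """Merge a list of (start, end), joining touching intervals."""
    out: list[list[int]] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def _intersect(a, b) -> list[tuple[int, int]]:
    out = []
    i = j = 0
    a, b = _merge(a), _merge(b)
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def promoter_interval(gene: GeneAnnotation, promoter_len: int = 2000) -> tuple[int, int]:
    """Strand-aware promoter window upstream of the TSS."""
    if gene.strand == "+":
        return (max(0, gene.tss - promoter_len), gene.tss)
    return (gene.tss, gene.tss + promoter_len)


def promoter_id(gene_id: str) -> str:
    return f"P_{gene_id}"


def build_candidate_res(
    h3k27ac,
    h3k4me1,
    genes,
    promoter_len: int = 2000,
) -> list[RegulatoryElement]:
    """Distal REs = H3K27ac n H3K4me1 intersection; plus one promoter per gene.

    Mark inputs are lists of :class:`RegulatoryElement` (or anything with
    chrom/start/end).  Promoters stay distinct from overlapping distal REs,
    flagged by class.
    """
    by_chrom: dict[str, tuple[list, list]] = {}
    for rec in h3k27ac:
        by_chrom.setdefault(rec.chrom, ([], []))[0].append((rec.start, rec.end))
    for rec in h3k4me1:
        by_chrom.setdefault(rec.chrom, ([], []))[1].append((rec.start, rec.end))
    out: list[RegulatoryElement] = []
    for chrom in sorted(by_chrom):
        a, b = by_chrom[chrom]
        for s, e in _intersect(a, b):
            out.append(RegulatoryElement(f"{chrom}_{s}_{e}", chrom, s, e, "distal"))
    for g in genes:
        s, e = promoter_interval(g, promoter_len)
        if s < e:
            out.append(RegulatoryElement(promoter_id(g.gene_id), g.chrom, s, e, "promoter"))
    return out


@dataclass
class CandidateMap:
    """Per-gene regulatory boundary and ordered candidate RE set I_l."""

    boundaries: dict[str, tuple[int, int]]
    candidates: dict[str, list[str]]  # gene -> RE ids inside boundary
    promoters: dict[str, str]  # gene -> promoter RE id

    def genes(self) -> list[str]:
        return list(self.candidates)


def candidate_map(
    res,
    genes,
    boundaries: dict[str, tuple[int, int]],
    prior_beta0: pd.DataFrame | None = None,
    min_abs_prior: float = 0.0,
) -> CandidateMap:
    """Candidate REs per gene: interval overlap with the gene's boundary.

    With ``min_abs_prior`` > 0 the positional candidates are additionally
    filtered by |cross-context RE-gene correlation| >= the threshold
    (the promoter is always retained).  Genes whose promoter RE is missing
    from the catalog are skipped with a warning.
    """
    by_chrom: dict[str, list[RegulatoryElement]] = {}
    for re in res:
        by_chrom.setdefault(re.chrom, []).append(re)
    for lst in by_chrom.values():
        lst.sort(key=lambda r: (r.start, r.end))

    cands: dict[str, list[str]] = {}
    proms: dict[str, str] = {}
    kept_bounds: dict[str, tuple[int, int]] = {}
    for g in genes:
        b = boundaries[g.gene_id]
        hits = [
            re.re_id
            for re in by_chrom.get(g.chrom, [])
            if re.start < b[1] and re.end > b[0]
        ]
        pid = promoter_id(g.gene_id)
        if pid not in hits:
            warnings.warn(f"gene {g.gene_id}: promoter RE not in catalog/boundary; gene skipped")
            continue
        if prior_beta0 is not None and min_abs_prior > 0:
            hits = [
                k
                for k in hits
                if k == pid
                or (
                    k in prior_beta0.index
                    and g.gene_id in prior_beta0.columns
                    and abs(prior_beta0.loc[k, g.gene_id]) >= min_abs_prior
                )
            ]
        cands[g.gene_id] = hits
        proms[g.gene_id] = pid
        kept_bounds[g.gene_id] = b
    return CandidateMap(kept_bounds, cands, proms)


def openness_scores(
    read_counts: pd.DataFrame,
    re_lengths: pd.Series,
    library_sizes: pd.Series,
    genome_len: int,
) -> pd.DataFrame:
    """Openness = (reads per bp in the RE) / (library reads per genome bp)."""
    lengths = re_lengths.reindex(read_counts.index)
    if (lengths <= 0).any():
        raise ValueError("RE lengths must be positive")
    libs = library_sizes.reindex(read_counts.columns)
    if (libs <= 0).any():
        raise ValueError("library sizes must be positive")
    per_bp = read_counts.div(lengths, axis=0)
    background = libs / genome_len
    return per_bp.div(background, axis=1)


@dataclass
class FilterReport:
    kept: list[str]
    dropped: dict[str, str] = field(default_factory=dict)  # id -> reason

    def apply(self, values: pd.DataFrame) -> pd.DataFrame:
        return values.loc[self.kept]


def filter_rows(
    values: pd.DataFrame,
    design: SampleDesign,
    max_min_ratio: float = 500.0,
) -> FilterReport:
    """Drop all-zero rows and rows inconsistent within any replicate group.

    Replicate groups are the (population, time) conditions.  A group with
    max/min > ``max_min_ratio`` is inconsistent; min = 0 with max > 0
    counts as an infinite ratio.
    """
    values = values[design.sample_ids]
    group_cols = [grp["sample_id"].tolist() for _, grp in design.groups()]
    kept: list[str] = []
    dropped: dict[str, str] = {}
    arr = values.to_numpy(dtype=float)
    for i, row_id in enumerate(values.index):
        row = arr[i]
        if (row == 0).all():
            dropped[row_id] = "all_zero"
            continue
        bad = False
        for cols in group_cols:
            sub = values.loc[row_id, cols].to_numpy(dtype=float)
            lo, hi = sub.min(), sub.max()
            if hi > 0 and (lo == 0 or hi / lo > max_min_ratio):
                bad = True
                break
        if bad:
            dropped[row_id] = "replicate_inconsistent"
        else:
            kept.append(row_id)
    return FilterReport(kept, dropped)
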