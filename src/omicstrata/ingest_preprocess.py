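"""Readers for the tab-delimited input formats and the preprocessing rules.

Coordinates in all input files are 1-based inclusive (SEG/MAF convention);
interval arithmetic internally uses 0-based half-open coordinates.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import EmptyResultError, InvalidInputError, MalformedRecordError
from .matrix import OmicsMatrix

SILENT_CLASSIFICATIONS = frozenset({"intron", "silent"})


@dataclass(frozen=True)
class Segment:
    """One copy-number segment; start/end are 1-based inclusive."""

    sample: str
    chrom: str
    start: int
    end: int
    num_probes: int
    value: float

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise MalformedRecordError(
                f"segment start > end ({self.sample} {self.chrom}:{self.start}-{self.end})"
            )
        if self.num_probes < 0:
            raise MalformedRecordError("num_probes must be >= 0")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class ProbeRecord:
    probe_id: str
    chrom: str
    position: int
    gene: str | None
    region_class: str


@dataclass(frozen=True)
class GeneAnnotation:
    gene: str
    chrom: str
    strand: str
    tss: int
    gene_start: int
    gene_end: int

    def __post_init__(self) -> None:
        if self.gene_start > self.gene_end:
            raise MalformedRecordError(f"gene {self.gene}: gene_start > gene_end")
        if self.strand not in ("+", "-"):
            raise MalformedRecordError(f"gene {self.gene}: strand must be + or -")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InvalidInputError(f"{path}: missing required columns {missing} (line 1)")


def read_seg(path) -> list[Segment]:
    df = pd.read_csv(path, sep="\t", dtype={"Chromosome": str})
    _require_columns(df, ["Sample", "Chromosome", "Start", "End", "Num_Probes", "Segment_Mean"], path)
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            out.append(Segment(str(row.Sample), str(row.Chromosome), int(row.Start),
                               int(row.End), int(row.Num_Probes), float(row.Segment_Mean)))
        except (ValueError, MalformedRecordError) as exc:
            raise MalformedRecordError(f"{path}: line {i}: {exc}") from exc
    return out


def read_matrix(path, kind: str) -> OmicsMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise InvalidInputError(f"{path}: duplicate feature ids")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return OmicsMatrix(kind, df.astype(float))


def read_probe_annotation(path) -> list[ProbeRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    _require_columns(df, ["probe", "chrom", "position", "gene", "region_class"], path)
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        gene = None if pd.isna(row.gene) else str(row.gene)
        out.append(ProbeRecord(str(row.probe), str(row.chrom), int(row.position), gene,
                               str(row.region_class)))
        if out[-1].position < 1:
            raise MalformedRecordError(f"{path}: line {i}: position must be >= 1")
    return out


def read_gene_annotation(path) -> list[GeneAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    _require_columns(df, ["gene", "chrom", "strand", "tss", "gene_start", "gene_end"], path)
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            out.append(GeneAnnotation(str(row.gene), str(row.chrom), str(row.strand),
                                      int(row.tss), int(row.gene_start), int(row.gene_end)))
        except MalformedRecordError as exc:
            raise MalformedRecordError(f"{path}: line {i}: {exc}") from exc
    return out


def read_maf(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification"], path)
    return df


def read_clinical(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["sample", "OS_time", "OS_event"], path)
    df = df.set_index("sample")
    df.index = df.index.astype(str)
    if (df["OS_time"] <= 0).any():
        raise InvalidInputError(f"{path}: OS_time must be > 0")
    if not df["OS_event"].isin([0, 1]).all():
        raise InvalidInputError(f"{path}: OS_event must be 0 or 1")
    return df


def read_gmt(path) -> dict[str, set[str]]:
    collections: dict[str, set[str]] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise MalformedRecordError(f"{path}: line {i}: GMT rows need name, desc, >=1 gene")
            collections[parts[0]] = set(g for g in parts[2:] if g)
    return collections


def read_gene_set(path) -> set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def merge_cnv_segments(
    segments: list[Segment],
    reciprocal_overlap: float = 0.5,
    min_probes: int = 5,
) -> list[Segment]:
    """Drop thin segments and merge reciprocally overlapping ones.

    Segments with fewer than ``min_probes`` probes are removed. Within each
    (sample, chromosome) group, segments whose overlap covers at least
    ``reciprocal_overlap`` of *both* intervals are connected; connected
    components are merged into their union interval with a
    probe-count-weighted mean value.
    """
    kept = [s for s in segments if s.num_probes >= min_probes]
    out: list[Segment] = []
    groups: dict[tuple[str, str], list[Segment]] = {}
    for s in kept:
        groups.setdefault((s.sample, s.chrom), []).append(s)

    for (sample, chrom), segs in sorted(groups.items()):
        segs = sorted(segs, key=lambda s: (s.start, s.end, s.num_probes, s.value))
        parent = list(range(len(segs)))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        def union(i: int, j: int) -> None:
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[rj] = ri

        # sweep: only intervals that intersect can satisfy the reciprocal rule
        active: list[int] = []
        for i, s in enumerate(segs):
            active = [j for j in active if segs[j].end >= s.start]
            for j in active:
                o = segs[j]
                ov = min(o.end, s.end) - max(o.start, s.start) + 1
                if ov / o.length >= reciprocal_overlap and ov / s.length >= reciprocal_overlap:
                    union(i, j)
            active.append(i)

        comps: dict[int, list[Segment]] = {}
        for i, s in enumerate(segs):
            comps.setdefault(find(i), []).append(s)
        for members in comps.values():
            if len(members) == 1:
                out.append(members[0])
                continue
            start = min(m.start for m in members)
            end = max(m.end for m in members)
            probes = sum(m.num_probes for m in members)
            value = sum(m.value * m.num_probes for m in members) / probes
            out.append(Segment(sample, chrom, start, end, probes, value))
    out.sort(key=lambda s: (s.sample, s.chrom, s.start, s.end))
    return out


def map_cnv_to_genes(segments: list[Segment], annotation: list[GeneAnnotation]) -> OmicsMatrix:
    """Gene-level CNV: unweighted mean of all merged segments overlapping each gene body."""
    if not annotation:
        raise InvalidInputError("empty gene annotation")
    genes = [a.gene for a in annotation]
    gene_idx = {g: i for i, g in enumerate(genes)}
    samples = sorted({s.sample for s in segments})
    sample_idx = {s: i for i, s in enumerate(samples)}

    sums = np.zeros((len(genes), len(samples)))
    counts = np.zeros((len(genes), len(samples)))

    by_chrom: dict[str, list[GeneAnnotation]] = {}
    for a in annotation:
        by_chrom.setdefault(a.chrom, []).append(a)
    chrom_arrays = {}
    for chrom, annos in by_chrom.items():
        annos = sorted(annos, key=lambda a: a.gene_start)
        starts = np.array([a.gene_start for a in annos])
        ends = np.array([a.gene_end for a in annos])
        cummax_end = np.maximum.accumulate(ends)
        chrom_arrays[chrom] = (annos, starts, ends, cummax_end)

    for seg in segments:
        arr = chrom_arrays.get(seg.chrom)
        if arr is None:
            continue
        annos, starts, ends, cummax_end = arr
        hi = int(np.searchsorted(starts, seg.end, side="right"))
        lo = int(np.searchsorted(cummax_end, seg.start, side="left"))
        si = sample_idx[seg.sample]
        for a in annos[lo:hi]:
            if a.gene_end >= seg.start and a.gene_start <= seg.end:
                gi = gene_idx[a.gene]
                sums[gi, si] += seg.value
                counts[gi, si] += 1

    with np.errstate(invalid="ignore"):
        values = np.where(counts > 0, sums / np.where(counts > 0, counts, 1), np.nan)
    return OmicsMatrix("cnv_logratio", pd.DataFrame(values, index=genes, columns=samples))


def filter_impute_methylation(
    matrix: OmicsMatrix,
    max_missing_fraction: float = 0.7,
    k_neighbors: int = 10,
) -> OmicsMatrix:
    """Drop mostly-missing probes, then impute the rest by probe-row KNN.

    A probe is dropped when missing in strictly more than ``max_missing_fraction``
    of samples. Remaining gaps are filled from the ``k_neighbors`` nearest probe
    rows (Euclidean distance averaged over shared observed samples; equidistant
    neighbors are ordered by probe id). If the nearest neighbor sits at distance
    zero (a duplicate row) the imputed value is the mean over the zero-distance
    neighbors only, so exact duplicates are reproduced exactly.
    """
    if matrix.kind != "beta":
        raise InvalidInputError("expected a beta matrix")
    df = matrix.values
    x = df.to_numpy(dtype=float)
    n = x.shape[1]
    missing_frac = np.isnan(x).sum(axis=1) / n
    keep = missing_frac <= max_missing_fraction
    if not keep.any():
        raise EmptyResultError(
            f"all {x.shape[0]} probes missing in > {max_missing_fraction:.0%} of samples"
        )
    df = df.loc[keep]
    x = x[keep]
    nan_rows = np.nonzero(np.isnan(x).any(axis=1))[0]
    if nan_rows.size == 0:
        return OmicsMatrix("beta", df)

    out = x.copy()
    probe_order = np.argsort(df.index.to_numpy())  # tie-break: lowest probe id
    rank = np.empty(len(df), dtype=int)
    rank[probe_order] = np.arange(len(df))
    for i in nan_rows:
        diff = x - x[i]
        sq = diff * diff
        shared = ~np.isnan(sq)
        n_shared = shared.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.sqrt(np.nansum(sq, axis=1) / np.where(n_shared > 0, n_shared, 1))
        d[n_shared == 0] = np.inf
        d[i] = np.inf
        cols = np.nonzero(np.isnan(x[i]))[0]
        for c in cols:
            cand = np.isfinite(x[:, c]) & np.isfinite(d)
            cand[i] = False
            idx = np.nonzero(cand)[0]
            if idx.size == 0:
                continue
            order = idx[np.lexsort((rank[idx], d[idx]))]
            nearest = order[: k_neighbors]
            if d[nearest[0]] == 0.0:
                zero = order[d[order] == 0.0]
                out[i, c] = float(np.mean(x[zero, c]))
            else:
                out[i, c] = float(np.mean(x[nearest, c]))
    out = np.clip(out, 0.0, 1.0)
    return OmicsMatrix("beta", pd.DataFrame(out, index=df.index, columns=df.columns))


def map_probes_to_promoters(
    probes: list[ProbeRecord],
    matrix: OmicsMatrix,
    annotation: list[GeneAnnotation],
    upstream: int = 2000,
    downstream: int = 200,
) -> OmicsMatrix:
    """Average promoter-window probes per gene.

    The window is strand-aware: [tss - upstream, tss + downstream] on '+',
    [tss - downstream, tss + upstream] on '-'. Probes on chromosomes absent from
    the annotation are skipped with a warning.
    """
    if not annotation:
        raise InvalidInputError("empty gene annotation")
    known_chroms = {a.chrom for a in annotation}
    by_chrom: dict[str, list[GeneAnnotation]] = {}
    for a in annotation:
        by_chrom.setdefault(a.chrom, []).append(a)
    windows = {}
    for chrom, annos in by_chrom.items():
        recs = []
        for a in annos:
            if a.strand == "+":
                recs.append((a.tss - upstream, a.tss + downstream, a.gene))
            else:
                recs.append((a.tss - downstream, a.tss + upstream, a.gene))
        recs.sort()
        los = np.array([r[0] for r in recs])
        his = np.array([r[1] for r in recs])
        windows[chrom] = (los, np.maximum.accumulate(his), his, [r[2] for r in recs])

    df = matrix.values
    probe_rows = {p: i for i, p in enumerate(df.index)}
    gene_probes: dict[str, list[int]] = {}
    skipped = 0
    for pr in probes:
        if pr.probe_id not in probe_rows:
            continue
        if pr.chrom not in known_chroms:
            skipped += 1
            continue
        los, cummax_his, his, names = windows[pr.chrom]
        hi_idx = int(np.searchsorted(los, pr.position, side="right"))
        lo_idx = int(np.searchsorted(cummax_his, pr.position, side="left"))
        for j in range(lo_idx, hi_idx):
            if his[j] >= pr.position:
                gene_probes.setdefault(names[j], []).append(probe_rows[pr.probe_id])
    if skipped:
        warnings.warn(f"skipped {skipped} probes on chromosomes absent from the annotation")

    x = df.to_numpy(dtype=float)
    genes = [a.gene for a in annotation if a.gene in gene_probes]
    values = np.vstack([np.nanmean(x[gene_probes[g]], axis=0) for g in genes]) if genes else \
        np.empty((0, x.shape[1]))
    return OmicsMatrix("beta", pd.DataFrame(values, index=genes, columns=df.columns))


def filter_expression(matrix: OmicsMatrix, max_zero_fraction: float = 0.5) -> OmicsMatrix:
    """Keep genes whose zero fraction is strictly below ``max_zero_fraction``."""
    if matrix.kind not in ("fpkm", "counts"):
        raise InvalidInputError("expected an expression matrix")
    x = matrix.to_numpy()
    zero_frac = (x == 0).sum(axis=1) / x.shape[1]
    keep = zero_frac < max_zero_fraction
    if not keep.any():
        warnings.warn("expression filter removed every gene")
    return OmicsMatrix(matrix.kind, matrix.values.loc[keep])


def filter_mutations(records: pd.DataFrame, removed_classes=SILENT_CLASSIFICATIONS) -> pd.DataFrame:
    """Drop intronic and silent mutation calls (case-insensitive class match)."""
    if len(records) == 0:
        return records.copy()
    if "Variant_Classification" not in records.columns:
        raise MalformedRecordError("mutation records lack Variant_Classification")
    cls = records["Variant_Classification"]
    if cls.isna().any():
        raise MalformedRecordError("mutation record with missing Variant_Classification")
    lowered = {c.lower() for c in removed_classes}
    keep = ~cls.str.lower().isin(lowered)
    return records.loc[keep].reset_index(drop=True)
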