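"""Interval algebra and the three-condition direct-target funnel.

The funnel nominates genes as direct targets of a histone methyltransferase
by requiring, jointly: (1) a significantly reduced histone-methylation peak
annotated to the gene, (2) a transcription-factor binding site falling inside
tissue-specific open chromatin annotated to the gene, and (3) reduced mRNA in
the knockdown.  All coordinates are 0-based half-open; intervals touching
only at a shared endpoint do not overlap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import GeneTable, IntervalSet


@dataclass(frozen=True)
class PeakFilterParams:
    """Differential-peak significance thresholds.

    ``fdr_max`` defaults to 0.05; a stricter 0.01 is equally supported (both
    conventions appear in published differential-peak work).  ``fc_min`` is a
    linear ratio; direction (reduced/increased) is tested separately so the
    fold threshold applies symmetrically.
    """

    fdr_max: float = 0.05
    fc_min: float = 1.25
    direction: str = "reduced"  # reduced | increased | any

    def __post_init__(self) -> None:
        if not (0 < self.fdr_max <= 1):
            raise ValueError("fdr_max must be in (0, 1]")
        if self.fc_min <= 1:
            raise ValueError("fc_min must exceed 1")
        if self.direction not in ("reduced", "increased", "any"):
            raise ValueError("direction must be reduced, increased or any")


@dataclass(frozen=True)
class AnnotationParams:
    """Peak-to-gene assignment: nearest TSS (midpoint distance, ties kept) or
    overlap with the window [TSS - upstream_window, gene end)."""

    upstream_window: int = 2_000
    mode: str = "nearest_tss"

    def __post_init__(self) -> None:
        if self.upstream_window < 0:
            raise ValueError("upstream_window must be >= 0")
        if self.mode not in ("nearest_tss", "window_overlap"):
            raise ValueError("mode must be nearest_tss or window_overlap")


@dataclass(frozen=True)
class EnrichmentCallParams:
    """Tissue-enrichment call: fold threshold on mean_a/mean_b plus adjusted p."""

    min_fold: float = 2.0
    padj_max: float = 0.05

    def __post_init__(self) -> None:
        if self.min_fold < 1:
            raise ValueError("min_fold must be >= 1")


# ---------------------------------------------------------------------------
# Interval algebra
# ---------------------------------------------------------------------------

def _overlap_any(a: IntervalSet, b: IntervalSet) -> np.ndarray:
    """Boolean mask over a's records: overlaps >= 1 bp with some record of b."""
    mask = np.zeros(len(a), dtype=bool)
    if not len(a) or not len(b):
        return mask
    bdf = b.df
    for chrom, sub_b in bdf.groupby("chrom", sort=False):
        sel = a.df["chrom"] == chrom
        if not sel.any():
            continue
        starts_a = a.df.loc[sel, "start"].to_numpy()
        ends_a = a.df.loc[sel, "end"].to_numpy()
        # merge b intervals on this chromosome, then test a against the merged set
        order = np.argsort(sub_b["start"].to_numpy(), kind="mergesort")
        bs = sub_b["start"].to_numpy()[order]
        be = sub_b["end"].to_numpy()[order]
        merged_s, merged_e = [], []
        for s, e in zip(bs, be):
            if merged_e and s < merged_e[-1]:
                merged_e[-1] = max(merged_e[-1], e)
            else:
                merged_s.append(s)
                merged_e.append(e)
        ms = np.asarray(merged_s)
        me = np.asarray(merged_e)
        # half-open overlap: exists j with start_a < me[j] and end_a > ms[j]
        idx = np.searchsorted(ms, ends_a, side="left") - 1
        hit = (idx >= 0) & (starts_a < me[np.clip(idx, 0, len(me) - 1)])
        # also catch the case where an earlier merged interval extends past start_a
        # (cannot happen after merging: merged intervals are disjoint and sorted)
        mask[np.nonzero(sel.to_numpy())[0]] = hit
    return mask


def intersect_intervals(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Records of ``a`` that overlap (>= 1 bp, half-open) any record of ``b``."""
    return IntervalSet(a.df[_overlap_any(a, b)].reset_index(drop=True))


def overlap_regions(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """The overlapping sub-intervals themselves (one record per overlapping pair)."""
    rows = []
    adf, bdf = a.df, b.df
    for chrom in sorted(set(adf["chrom"]) & set(bdf["chrom"])):
        sub_a = adf[adf["chrom"] == chrom]
        sub_b = bdf[bdf["chrom"] == chrom]
        for sa, ea, name_a in zip(sub_a["start"], sub_a["end"], sub_a["name"]):
            sel = (sub_b["start"] < ea) & (sub_b["end"] > sa)
            for sb, eb in zip(sub_b.loc[sel, "start"], sub_b.loc[sel, "end"]):
                rows.append((chrom, max(sa, sb), min(ea, eb), name_a))
    if not rows:
        return IntervalSet.empty()
    return IntervalSet.from_records(rows).sort()


def merge_intervals(x: IntervalSet) -> IntervalSet:
    """Union of overlapping intervals (transitive chains merged), per chromosome."""
    rows = []
    for chrom, sub in x.df.groupby("chrom", sort=True):
        order = np.argsort(sub["start"].to_numpy(), kind="mergesort")
        starts = sub["start"].to_numpy()[order]
        ends = sub["end"].to_numpy()[order]
        cur_s, cur_e = None, None
        for s, e in zip(starts, ends):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s < cur_e:  # half-open: touching intervals stay separate
                cur_e = max(cur_e, e)
            else:
                rows.append((chrom, cur_s, cur_e, ""))
                cur_s, cur_e = s, e
        if cur_s is not None:
            rows.append((chrom, cur_s, cur_e, ""))
    if not rows:
        return IntervalSet.empty()
    return IntervalSet.from_records(rows)


def consensus_peaks(rep1: IntervalSet, rep2: IntervalSet) -> IntervalSet:
    """Consensus set of two replicate peak sets.

    A consensus peak is the merged union of peaks that overlap (>= 1 bp)
    between the replicates; chained overlaps merge transitively.  Peaks seen
    in only one replicate are dropped.  Symmetric and idempotent against
    re-consensus with either replicate.
    """
    keep1 = rep1.df[_overlap_any(rep1, rep2)]
    keep2 = rep2.df[_overlap_any(rep2, rep1)]
    both = IntervalSet(pd.concat([keep1, keep2], ignore_index=True))
    return merge_intervals(both).sort()


def subtract_blacklist(peaks: IntervalSet, blacklist: IntervalSet) -> IntervalSet:
    """Drop every peak overlapping an artifact-prone (blacklisted) region.

    Whole peaks are removed, not trimmed: a peak touching an artifact region
    is unreliable in its entirety.
    """
    return IntervalSet(peaks.df[~_overlap_any(peaks, blacklist)].reset_index(drop=True))


def filter_differential_peaks(peaks: IntervalSet,
                              params: PeakFilterParams | None = None) -> IntervalSet:
    """Keep peaks with fdr < fdr_max, fold_change > fc_min and matching direction."""
    params = params or PeakFilterParams()
    df = peaks.df
    if not len(df):
        return IntervalSet.empty()
    missing = df.index[df["fdr"].isna() | df["fold_change"].isna()].tolist()
    if missing:
        raise ValueError(f"peaks missing fdr/fold_change at index {missing}")
    keep = (df["fdr"] < params.fdr_max) & (df["fold_change"] > params.fc_min)
    if params.direction == "reduced":
        keep &= df["direction"] == "down"
    elif params.direction == "increased":
        keep &= df["direction"] == "up"
    return IntervalSet(df[keep].reset_index(drop=True))


def annotate_peaks_to_genes(peaks: IntervalSet, genes: IntervalSet,
                            params: AnnotationParams | None = None) -> dict[str, list[str]]:
    """Assign each peak to gene(s): peak name -> list of gene names.

    Gene records use their start coordinate as the TSS (gene models here are
    strandless intervals whose start is the transcription start site).  In
    ``nearest_tss`` mode the peak midpoint is matched to the closest TSS on
    the same chromosome, all exactly tied genes reported; ``window_overlap``
    reports every gene whose [TSS - upstream_window, gene end) overlaps the
    peak.
    """
    params = params or AnnotationParams()
    if not len(genes):
        raise ValueError("empty gene set")
    out: dict[str, list[str]] = {}
    gdf = genes.df
    for chrom, sub_p in peaks.df.groupby("chrom", sort=False):
        sub_g = gdf[gdf["chrom"] == chrom]
        for start, end, pname in zip(sub_p["start"], sub_p["end"], sub_p["name"]):
            if not len(sub_g):
                out[pname] = []
                continue
            if params.mode == "nearest_tss":
                mid = (start + end) / 2.0
                dist = np.abs(sub_g["start"].to_numpy() - mid)
                best = dist.min()
                out[pname] = sub_g["name"].to_numpy()[dist == best].tolist()
            else:
                ws = np.maximum(sub_g["start"].to_numpy() - params.upstream_window, 0)
                we = sub_g["end"].to_numpy()
                hit = (ws < end) & (we > start)
                out[pname] = sub_g["name"].to_numpy()[hit].tolist()
    for pname in peaks.df["name"]:
        out.setdefault(pname, [])
    return out


# ---------------------------------------------------------------------------
# The target funnel
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FunnelResult:
    targets: tuple[str, ...]
    n_reduced_peak_genes: int
    n_with_binding: int
    n_with_reduced_mrna: int


def identify_trx_targets(reduced_peaks: IntervalSet, tf_sites: IntervalSet,
                         open_chromatin: IntervalSet, de_table: GeneTable,
                         genes: IntervalSet,
                         ann: AnnotationParams | None = None,
                         de_padj_max: float = 0.05,
                         peak_filter: PeakFilterParams | None = None) -> FunnelResult:
    """Three-condition direct-target funnel.

    Stage 1: genes annotated to a significantly reduced peak — when the peak
    records carry fdr/fold_change they are filtered with ``peak_filter``
    (default thresholds, direction reduced) first; peaks without statistics
    are taken as already significant.  Stage 2: of those, genes annotated to
    a TF binding site that falls inside open chromatin.  Stage 3: of those,
    genes with reduced mRNA (log2fc < 0, padj < de_padj_max).  Stages are
    nested, so the reported counts are monotone non-increasing.  Returns the
    ordered target list plus the per-stage counts.
    """
    ann = ann or AnnotationParams()
    if len(reduced_peaks) and not reduced_peaks.df["fdr"].isna().all():
        reduced_peaks = filter_differential_peaks(
            reduced_peaks, peak_filter or PeakFilterParams(direction="reduced"))
    if not len(reduced_peaks):
        return FunnelResult(targets=(), n_reduced_peak_genes=0,
                            n_with_binding=0, n_with_reduced_mrna=0)
    peak_genes: set[str] = set()
    for gene_list in annotate_peaks_to_genes(reduced_peaks, genes, ann).values():
        peak_genes.update(gene_list)

    bound_open = overlap_regions(tf_sites, open_chromatin)
    binding_genes: set[str] = set()
    if len(bound_open):
        for gene_list in annotate_peaks_to_genes(bound_open, genes, ann).values():
            binding_genes.update(gene_list)
    stage2 = peak_genes & binding_genes

    de = de_table.df
    down = set(de.loc[(de["log2fc"] < 0) & (de["padj"] < de_padj_max), "gene_id"])
    stage3 = stage2 & down
    return FunnelResult(targets=tuple(sorted(stage3)),
                        n_reduced_peak_genes=len(peak_genes),
                        n_with_binding=len(stage2),
                        n_with_reduced_mrna=len(stage3))


# ---------------------------------------------------------------------------
# Count normalization and tissue-enrichment calls
# ---------------------------------------------------------------------------

def median_of_ratios_normalize(counts) -> tuple[np.ndarray, np.ndarray]:
    """DESeq2-style median-of-ratios size factors and normalized counts.

    The reference per gene is the geometric mean of its counts across
    samples, computed over genes with nonzero counts in every sample; each
    sample's size factor is the median of count/reference over those genes;
    normalized counts divide each sample by its size factor.  Per-sample
    rescalings of the counts are absorbed into the size factors up to one
    global constant, the geometric mean of the scalings — only relative
    library depth is identifiable.
    """
    c = np.asarray(counts, dtype=float)
    if c.ndim != 2 or c.shape[1] < 2:
        raise ValueError("counts must be genes x samples with >= 2 samples")
    if (c < 0).any():
        raise ValueError("negative counts")
    all_nonzero = (c > 0).all(axis=1)
    if not all_nonzero.any():
        raise ValueError("no gene has nonzero counts in all samples")
    logc = np.log(c[all_nonzero])
    log_ref = logc.mean(axis=1, keepdims=True)
    size_factors = np.exp(np.median(logc - log_ref, axis=0))
    return size_factors, c / size_factors


def mb_enrichment_call(table: GeneTable,
                       params: EnrichmentCallParams | None = None) -> pd.DataFrame:
    """Flag genes enriched in tissue A over tissue B.

    Enriched iff mean_a/mean_b > min_fold and padj < padj_max.  A zero
    mean_b gives infinite fold, so the call reduces to the padj condition.
    """
    params = params or EnrichmentCallParams()
    df = table.df.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = df["mean_a"].to_numpy(float) / df["mean_b"].to_numpy(float)
    df["fold"] = fold
    df["enriched"] = (fold > params.min_fold) & (df["padj"] < params.padj_max)
    return df
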