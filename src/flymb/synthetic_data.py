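"""Seeded generators emulating the statistical structure of each assay.

Every generator is a pure function of its parameters and seed, and its output
validates against the package's own readers.  The generators encode the study
conditions each analysis assumes: beta-distributed courtship indices with a
multiplicative training effect, per-minute 0/1 activity with a sinusoidal
circadian propensity, three-channel sensor stacks built by inverting the
unmixing equations so planted ROI ratios are an exact noiseless fixed point,
and toy genomes in which a planted gene set jointly satisfies the target
funnel's three conditions while decoy classes each violate at least one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .courtship_memory import CourtshipGroup
from .fret_imaging import FretStack
from .io_formats import ActivityMatrix, GeneTable, IntervalSet


# ---------------------------------------------------------------------------
# Courtship indices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CourtshipSimParams:
    """Beta-distributed CIs with a fractional training effect.

    ``training_effect`` is the true memory index: the trained mean CI is
    ``ci_naive_mean * (1 - training_effect)``.  ``dispersion`` is the beta
    concentration (a + b); larger is tighter around the mean.
    """

    n_per_group: int = 20
    ci_naive_mean: float = 0.6
    training_effect: float = 0.0
    dispersion: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be positive")
        if not (0 < self.ci_naive_mean < 1):
            raise ValueError("ci_naive_mean must lie in (0, 1)")
        if not (0 <= self.training_effect <= 1):
            raise ValueError("training_effect must lie in [0, 1]")
        trained = self.ci_naive_mean * (1 - self.training_effect)
        if not (0 <= trained < 1):
            raise ValueError("implied trained mean outside [0, 1)")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")


def _beta_sample(rng: np.random.Generator, mean: float, concentration: float,
                 n: int) -> np.ndarray:
    if mean == 0:
        return np.zeros(n)
    a = mean * concentration
    b = (1 - mean) * concentration
    return rng.beta(a, b, size=n)


def gen_courtship_cis(params: CourtshipSimParams, genotype: str = "sim") -> CourtshipGroup:
    """Draw naive and trained CI samples for one genotype."""
    rng = np.random.default_rng(params.seed)
    naive = _beta_sample(rng, params.ci_naive_mean, params.dispersion, params.n_per_group)
    trained_mean = params.ci_naive_mean * (1 - params.training_effect)
    trained = _beta_sample(rng, trained_mean, params.dispersion, params.n_per_group)
    return CourtshipGroup(genotype=genotype, ci_naive=naive, ci_trained=trained)


def write_ci_table(groups: dict[str, CourtshipGroup], path) -> None:
    """Write groups as the (fly_id, genotype, condition, ci) TSV the CLI consumes."""
    rows = []
    for name, g in groups.items():
        for i, ci in enumerate(g.ci_naive):
            rows.append({"fly_id": f"{name}_n{i}", "genotype": name,
                         "condition": "naive", "ci": ci})
        for i, ci in enumerate(g.ci_trained):
            rows.append({"fly_id": f"{name}_t{i}", "genotype": name,
                         "condition": "trained", "ci": ci})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Activity monitor
# ---------------------------------------------------------------------------

def gen_activity_monitor(n_flies: int = 8, n_days: int = 2,
                         sleep_fraction_day: float = 0.2,
                         sleep_fraction_night: float = 0.6,
                         period_hours: float = 24.0,
                         seed: int = 0,
                         regime: str = "LD",
                         lights_on: float = 8.0,
                         lights_off: float = 20.0,
                         start: str = "2024-01-01 08:00:00") -> ActivityMatrix:
    """Per-minute 0/1 activity with circadian structure.

    Time is tiled into 10-minute blocks; each block is entirely asleep with a
    probability that tracks the stated day/night sleep fractions (in LD) or
    their mean (in DD), modulated sinusoidally at ``period_hours``, so the
    expected per-fly asleep fraction equals the stated fractions and every
    asleep block is a clean >= 5-minute inactive run.  Awake minutes carry
    one beam crossing, asleep minutes none.  A sleep fraction of 0 yields
    continuous activity.
    """
    if not (0 <= sleep_fraction_day <= 1 and 0 <= sleep_fraction_night <= 1):
        raise ValueError("sleep fractions must lie in [0, 1]")
    if period_hours <= 0:
        raise ValueError("period_hours must be positive")
    n_minutes = int(round(n_days * 24 * 60))
    rng = np.random.default_rng(seed)
    timestamps = pd.date_range(start, periods=n_minutes, freq="min")
    hours = timestamps.hour + timestamps.minute / 60.0
    is_day = (hours >= lights_on) & (hours < lights_off)

    # circadian modulation of sleep propensity: peak in the subjective night
    minutes = np.arange(n_minutes)
    phase = 2 * np.pi * (minutes / 60.0 - (lights_off - lights_on)) / period_hours
    modulation = np.sin(phase)

    if regime == "DD":
        # free-running: no light-driven square wave, only the circadian modulation
        base = np.full(n_minutes, (sleep_fraction_day + sleep_fraction_night) / 2.0)
        p_sleep = np.clip(base * (1 + 0.9 * modulation), 0.0, 0.95)
    else:
        # light-driven: the 12h:12h square wave carries the rhythm, so the
        # expected asleep fraction matches the stated fractions exactly
        base = np.where(is_day, sleep_fraction_day, sleep_fraction_night)
        p_sleep = np.clip(base, 0.0, 0.95)

    block = 10  # minutes; each asleep block is a clean sleep bout
    counts = np.ones((n_minutes, n_flies), dtype=np.int64)
    for j in range(n_flies):
        for b0 in range(0, n_minutes, block):
            b1 = min(b0 + block, n_minutes)
            if rng.random() < p_sleep[b0:b1].mean():
                counts[b0:b1, j] = 0
    reg = np.full(n_minutes, regime, dtype=object)
    return ActivityMatrix(counts, timestamps, lights_on, lights_off, reg)


# ---------------------------------------------------------------------------
# FRET stacks
# ---------------------------------------------------------------------------

def gen_fret_stack(shape: tuple[int, int] = (64, 64),
                   roi_specs: list[tuple[np.ndarray, float]] | None = None,
                   af_level: float = 4.0,
                   noise_sd: float = 0.0,
                   seed: int = 0,
                   base_yfp: float = 50.0,
                   orientation: str = "cfp_over_yfp") -> tuple[FretStack, dict[str, float]]:
    """Three-channel stack built by inverting the unmixing equations.

    For each ROI with planted ratio r the corrected channels are chosen as
    (corr_cfp, corr_yfp) = (r * base, base) (reciprocal assignment for the
    other orientation) and the raw channels back-computed via
    ``raw = corr / (1 - 1/af)``, so the noiseless pipeline recovers r
    exactly.  Gaussian noise of ``noise_sd`` is added to the raw channels.
    Returns ``(stack, truth)`` with truth mapping ROI names to planted ratios.
    """
    if af_level <= 1:
        raise ValueError("af_level must exceed 1 (the correction is degenerate at 1)")
    if roi_specs is None:
        mask = np.zeros(shape, dtype=bool)
        mask[8:24, 8:24] = True
        roi_specs = [(mask, 0.5)]
    occupancy = np.zeros(shape, dtype=int)
    for mask, ratio in roi_specs:
        if ratio <= 0:
            raise ValueError("true_ratio must be positive")
        occupancy += np.asarray(mask, dtype=bool).astype(int)
    if (occupancy > 1).any():
        raise ValueError("ROIs overlap")

    rng = np.random.default_rng(seed)
    gain = 1.0 - 1.0 / af_level  # corr = raw * gain
    corr_cfp = np.full(shape, 0.5 * base_yfp)
    corr_yfp = np.full(shape, base_yfp)
    roi_masks: dict[str, np.ndarray] = {}
    truth: dict[str, float] = {}
    for i, (mask, ratio) in enumerate(roi_specs):
        mask = np.asarray(mask, dtype=bool)
        name = f"roi{i}"
        roi_masks[name] = mask
        truth[name] = float(ratio)
        if orientation == "cfp_over_yfp":
            corr_cfp[mask] = ratio * base_yfp
            corr_yfp[mask] = base_yfp
        else:
            corr_yfp[mask] = ratio * base_yfp
            corr_cfp[mask] = base_yfp
    cfp = corr_cfp / gain
    yfp = corr_yfp / gain
    af = np.full(shape, float(af_level))
    if noise_sd > 0:
        cfp = cfp + rng.normal(0, noise_sd, shape)
        yfp = yfp + rng.normal(0, noise_sd, shape)
        af = af + rng.normal(0, noise_sd, shape)
    stack = FretStack(cfp=cfp, yfp=yfp, af=af, roi_masks=roi_masks, slice_index=0)
    return stack, truth


# ---------------------------------------------------------------------------
# Planted-target toy genome
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TargetGenomeParams:
    """Toy genome with a planted set of genes satisfying the funnel jointly.

    Genes are laid out on one chromosome at ``gene_spacing`` intervals (TSS =
    gene start), far enough apart that nearest-TSS annotation is unambiguous.
    ``decoy_partial_fraction`` of non-target genes satisfy exactly one or two
    of the three conditions; the rest satisfy none.
    """

    n_genes: int = 50
    n_planted_targets: int = 5
    gene_length: int = 2_000
    gene_spacing: int = 10_000
    peak_width: int = 400
    decoy_partial_fraction: float = 0.5
    de_padj_max: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_planted_targets > self.n_genes:
            raise ValueError("n_planted_targets exceeds n_genes")
        if self.gene_length + 2 * self.peak_width >= self.gene_spacing:
            raise ValueError("gene spacing too small for requested peak geometry")


def gen_target_genome(params: TargetGenomeParams
                      ) -> tuple[IntervalSet, IntervalSet, IntervalSet,
                                 IntervalSet, GeneTable, set[str]]:
    """Generate (genes, reduced_peaks, tf_sites, open_chromatin, de_table, truth).

    Planted targets get: a significant reduced peak at their TSS, a TF site
    inside an open-chromatin window at their TSS, and a significantly
    down-regulated DE row.  Each partial decoy gets a random strict subset of
    those conditions (possibly via a non-significant peak or padj failure);
    full decoys get none.  The truth set is returned for assertions.
    """
    rng = np.random.default_rng(params.seed)
    chrom = "chr2L"
    w = params.peak_width

    gene_rows, peak_rows, tf_rows, oc_rows, de_rows = [], [], [], [], []
    ids = [f"g{i:03d}" for i in range(params.n_genes)]
    order = rng.permutation(params.n_genes)
    target_idx = set(order[: params.n_planted_targets].tolist())
    remaining = order[params.n_planted_targets:]
    n_partial = int(round(len(remaining) * params.decoy_partial_fraction))
    partial_idx = set(remaining[:n_partial].tolist())

    truth: set[str] = set()
    for i, gid in enumerate(ids):
        tss = 5_000 + i * params.gene_spacing
        gene_rows.append((chrom, tss, tss + params.gene_length, gid))
        is_target = i in target_idx
        if is_target:
            conditions = {"peak", "binding", "mrna"}
            truth.add(gid)
        elif i in partial_idx:
            k = int(rng.integers(1, 3))  # satisfy exactly 1 or 2 conditions
            conditions = set(rng.choice(["peak", "binding", "mrna"], size=k, replace=False))
        else:
            conditions = set()

        jitter = int(rng.integers(-w // 4, w // 4 + 1))
        if "peak" in conditions:
            peak_rows.append((chrom, tss - w // 2 + jitter, tss + w // 2 + jitter,
                              f"pk_{gid}", np.nan, 1e-4, 2.0, "down"))
        elif rng.random() < 0.3:
            # non-significant or wrong-direction peak: must not survive filtering
            peak_rows.append((chrom, tss - w // 2 + jitter, tss + w // 2 + jitter,
                              f"pk_{gid}", np.nan, 0.5, 1.1, "down"))
        if "binding" in conditions:
            tf_rows.append((chrom, tss - w // 4, tss + w // 4, f"tf_{gid}"))
            oc_rows.append((chrom, tss - w // 2, tss + w // 2, f"oc_{gid}"))
        elif rng.random() < 0.3:
            # binding site without open chromatin: fails the joint condition
            tf_rows.append((chrom, tss - w // 4, tss + w // 4, f"tf_{gid}"))
        if "mrna" in conditions:
            de_rows.append({"gene_id": gid, "mean_a": 100.0, "mean_b": 100.0,
                            "log2fc": float(-rng.uniform(0.5, 2.0)),
                            "padj": float(rng.uniform(0, params.de_padj_max * 0.9))})
        else:
            de_rows.append({"gene_id": gid, "mean_a": 100.0, "mean_b": 100.0,
                            "log2fc": float(rng.normal(0, 0.2)),
                            "padj": float(rng.uniform(0.5, 1.0))})

    genes = IntervalSet.from_records(gene_rows)
    reduced_peaks = (IntervalSet.from_records(peak_rows)
                     if peak_rows else IntervalSet.empty())
    tf_sites = IntervalSet.from_records(tf_rows) if tf_rows else IntervalSet.empty()
    open_chromatin = IntervalSet.from_records(oc_rows) if oc_rows else IntervalSet.empty()
    de_table = GeneTable(pd.DataFrame(de_rows))
    return genes, reduced_peaks, tf_sites, open_chromatin, de_table, truth


def gen_interval_set(n: int, seed: int = 0, chroms: tuple[str, ...] = ("chr2L", "chr3R"),
                     max_pos: int = 100_000, max_len: int = 500,
                     with_stats: bool = False) -> IntervalSet:
    """Random interval set for property tests (half-open, positive length)."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, max_pos))
        length = int(rng.integers(1, max_len + 1))
        if with_stats:
            rows.append((chrom, start, start + length, f"iv{i}",
                         float(rng.random()), float(rng.random()),
                         float(1 + rng.random() * 3),
                         ["up", "down", "none"][int(rng.integers(3))]))
        else:
            rows.append((chrom, start, start + length, f"iv{i}"))
    if not rows:
        return IntervalSet.empty()
    return IntervalSet.from_records(rows)
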