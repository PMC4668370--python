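"""Synthetic data generation for every input the pipeline consumes.

Emulates the statistical structure the analysis assumes: a small multi-
chromosome genome with non-overlapping gene bodies and CpG islands; MACS-
style peaks with negative-binomial tag counts and a configurable fraction of
tag mass planted inside a target annotation; a monotone 5-hmC-density ->
expression link with a configurable induction link; planted gain/loss gene
sets for the tumor/normal comparison; and binomially sampled TAB-seq clone
counts.  Everything is deterministic under the configured seed and is
written in the same plain-text formats the pipeline's readers consume.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .annotations import AnnotationSet, GeneModel
from .enrichment import observed_tags
from .gene_quant import TagAlignment
from .intervals import ChromSizes, GenomicInterval, Peak, merge, subtract
from .io import write_bed, write_chrom_sizes, write_peaks
from .overlap import ConsensusPeakSet

__all__ = [
    "SimulationConfig",
    "SyntheticGenome",
    "CancerCohort",
    "make_genome",
    "make_peaks_and_tags",
    "make_expression",
    "make_cancer_cohort",
    "make_tabseq",
    "make_overlap_pair",
    "write_genome",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic study.

    Length distributions are log-normal and parameterized by the median and
    the log-scale sigma; tag counts are negative binomial (mean/dispersion).
    ``annotation_enrichment`` is the target fraction q of tag mass planted
    inside the designated annotation (None = uniform placement).
    """

    seed: int = 0
    chrom_lengths: Tuple[int, ...] = (3_000_000, 2_000_000)
    n_genes: int = 300
    gene_length_median: float = 6_000.0
    gene_length_sigma: float = 0.6
    n_islands: int = 100
    island_width_median: float = 1_000.0
    island_width_sigma: float = 0.3
    n_peaks: int = 200
    peak_length_median: float = 500.0
    peak_length_sigma: float = 0.4
    tag_mean: float = 50.0
    tag_dispersion: float = 10.0
    tag_length: int = 50
    annotation_enrichment: float | None = None
    # density -> expression link: log FPKM = link_slope * z(density) + noise
    link_slope: float = 1.0
    link_noise_sd: float = 0.5
    # probability a gene is induced follows a logistic link in z(density)
    frac_up: float = 0.15
    frac_down: float = 0.15
    induction_slope: float = 1.0
    planted_up_genes: Tuple[str, ...] = ()
    planted_down_genes: Tuple[str, ...] = ()
    # tumor/normal cohort
    planted_gain_genes: Tuple[str, ...] = ()
    planted_loss_genes: Tuple[str, ...] = ()
    n_gain_shifted: int = 0
    n_loss_shifted: int = 0
    n_tumor_samples: int = 25
    n_normal_samples: int = 25
    expression_shift_fold: float = 4.0
    expression_noise_sd: float = 0.0
    background_hmc_fraction: float = 0.3
    # TAB-seq truth: condition -> (pct_C, pct_5mC, pct_5hmC)
    tabseq_truth: Mapping[str, Tuple[float, float, float]] = field(
        default_factory=lambda: {
            "proliferating": (80.0, 15.0, 5.0),
            "differentiated": (15.0, 60.0, 25.0),
        }
    )
    n_cpg_sites: int = 10
    clones_per_site: int = 20
    # consensus overlap scenario: fraction of set a's bases covered by set b
    overlap_fraction: float = 0.65

    def __post_init__(self) -> None:
        if self.annotation_enrichment is not None and not (
            0.0 <= self.annotation_enrichment <= 1.0
        ):
            raise ValueError("annotation_enrichment must be in [0,1]")
        for cond, truth in self.tabseq_truth.items():
            if abs(sum(truth) - 100.0) > 1e-6:
                raise ValueError(f"tabseq truth for {cond!r} must sum to 100")
        if set(self.planted_gain_genes) & set(self.planted_loss_genes):
            raise ValueError("gain and loss gene lists overlap")
        if not (0.0 <= self.overlap_fraction <= 1.0):
            raise ValueError("overlap_fraction must be in [0,1]")

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence((self.seed, salt)))


@dataclass(frozen=True)
class SyntheticGenome:
    sizes: ChromSizes
    genes: Tuple[GeneModel, ...]
    islands: AnnotationSet


def _lognormal_lengths(
    rng: np.random.Generator, n: int, median: float, sigma: float, minimum: int = 50
) -> np.ndarray:
    lens = rng.lognormal(mean=math.log(median), sigma=sigma, size=n)
    return np.maximum(np.round(lens).astype(np.int64), minimum)


def _pack_chromosome(
    rng: np.random.Generator, chrom_len: int, lengths: Sequence[int]
) -> List[int]:
    """Non-overlapping start positions for features of given lengths, with
    the free space split into random gaps."""
    total = int(sum(lengths))
    slack = chrom_len - total
    if slack < 0:
        raise ValueError(
            f"requested feature mass {total} exceeds chromosome length {chrom_len}"
        )
    n = len(lengths)
    gaps = rng.dirichlet(np.ones(n + 1)) * slack
    gaps = np.floor(gaps).astype(np.int64)
    starts = []
    pos = 0
    for i, length in enumerate(lengths):
        pos += int(gaps[i])
        starts.append(pos)
        pos += int(length)
    return starts


def make_genome(config: SimulationConfig) -> SyntheticGenome:
    """Chromosome sizes, gene models, and CpG islands, packed without overlap."""
    rng = config.rng(salt=1)
    sizes = ChromSizes(
        {f"chr{i + 1}": int(l) for i, l in enumerate(config.chrom_lengths)}
    )
    gene_lens = _lognormal_lengths(
        rng, config.n_genes, config.gene_length_median, config.gene_length_sigma, 200
    )
    island_lens = _lognormal_lengths(
        rng, config.n_islands, config.island_width_median, config.island_width_sigma, 100
    )
    kinds = ["gene"] * config.n_genes + ["island"] * config.n_islands
    lens = np.concatenate([gene_lens, island_lens])
    order = rng.permutation(len(lens))
    chrom_names = list(sizes)
    probs = np.array([sizes[c] for c in chrom_names], dtype=float)
    probs /= probs.sum()
    assignment = rng.choice(len(chrom_names), size=len(lens), p=probs)
    genes: List[GeneModel] = []
    islands: List[GenomicInterval] = []
    gene_counter = 0
    island_counter = 0
    for ci, chrom in enumerate(chrom_names):
        idx = [k for k in order if assignment[k] == ci]
        chrom_lens = [int(lens[k]) for k in idx]
        starts = _pack_chromosome(rng, sizes[chrom], chrom_lens)
        for k, start in zip(idx, starts):
            iv_len = int(lens[k])
            if kinds[k] == "gene":
                gene_counter += 1
                strand = "+" if rng.random() < 0.5 else "-"
                body = GenomicInterval(chrom, start, start + iv_len, strand)
                genes.append(GeneModel(f"g{gene_counter:05d}", body))
            else:
                island_counter += 1
                islands.append(GenomicInterval(chrom, start, start + iv_len))
    genes.sort(key=lambda g: (g.body.chrom, g.body.start))
    return SyntheticGenome(sizes, tuple(genes), AnnotationSet.build("CpG islands", islands))


def write_genome(genome: SyntheticGenome, out_dir: str | os.PathLike) -> Dict[str, str]:
    """Write chrom.sizes, a gene GTF, and the island BED; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sizes_path = out / "genome.chrom.sizes"
    gtf_path = out / "genes.gtf"
    bed_path = out / "islands.bed"
    write_chrom_sizes(genome.sizes, sizes_path)
    with open(gtf_path, "w") as fh:
        for g in genome.genes:
            b = g.body
            attrs = f'gene_id "{g.gene_id}"; gene_name "{g.gene_id}";'
            fh.write(
                f"{b.chrom}\thmcdiff_sim\tgene\t{b.start + 1}\t{b.end}\t.\t{b.strand}\t.\t{attrs}\n"
            )
            fh.write(
                f"{b.chrom}\thmcdiff_sim\ttranscript\t{b.start + 1}\t{b.end}\t.\t{b.strand}\t.\t"
                f'{attrs} transcript_id "{g.gene_id}.t1";\n'
            )
    write_bed(genome.islands.intervals, bed_path)
    return {"sizes": str(sizes_path), "gtf": str(gtf_path), "islands": str(bed_path)}


def _place_in_regions(
    rng: np.random.Generator, regions: Sequence[GenomicInterval], length: int
) -> GenomicInterval:
    """Uniform placement of an interval of ``length`` fully inside one of the
    regions, chosen with probability proportional to usable space."""
    usable = np.array([len(r) - length + 1 for r in regions], dtype=float)
    usable[usable < 1] = 0.0
    if usable.sum() == 0:
        raise ValueError(f"no region can contain an interval of length {length}")
    probs = usable / usable.sum()
    ri = int(rng.choice(len(regions), p=probs))
    r = regions[ri]
    start = int(rng.integers(r.start, r.end - length + 1))
    return GenomicInterval(r.chrom, start, start + length)


def _nb_counts(rng: np.random.Generator, n: int, mean: float, dispersion: float) -> np.ndarray:
    """Negative-binomial counts with the given mean and dispersion (size)."""
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=n)


def make_peaks_and_tags(
    config: SimulationConfig,
    sizes: ChromSizes,
    annotation: AnnotationSet | None = None,
) -> Tuple[List[Peak], List[TagAlignment], float]:
    """Peaks with tag counts, the tag alignments inside them, and the realized
    fraction of tag mass inside the annotation.

    With ``annotation_enrichment`` q set, each peak lands fully inside the
    annotation with probability q and fully in its complement otherwise, so
    the planted tag-mass fraction is q in expectation.
    """
    rng = config.rng(salt=2)
    q = config.annotation_enrichment
    genome_regions = [GenomicInterval(c, 0, sizes[c]) for c in sizes]
    if q is not None:
        if annotation is None:
            raise ValueError("annotation_enrichment set but no annotation given")
        inside = list(annotation.intervals)
        outside = subtract(genome_regions, inside)
    peak_lens = _lognormal_lengths(
        rng, config.n_peaks, config.peak_length_median, config.peak_length_sigma, 100
    )
    tag_counts = np.maximum(
        _nb_counts(rng, config.n_peaks, config.tag_mean, config.tag_dispersion), 1
    )
    peaks: List[Peak] = []
    tags: List[TagAlignment] = []
    for i in range(config.n_peaks):
        length = int(peak_lens[i])
        if q is None:
            regions = genome_regions
        elif rng.random() < q:
            regions = inside
        else:
            regions = outside
        # a sampled length no region can hold is truncated to the largest fit
        length = min(length, max(len(r) for r in regions))
        iv = _place_in_regions(rng, regions, length)
        peaks.append(Peak(iv, int(tag_counts[i])))
        tag_len = min(config.tag_length, length)
        starts = rng.integers(iv.start, iv.end - tag_len + 1, size=int(tag_counts[i]))
        for s in starts:
            tags.append(TagAlignment(GenomicInterval(iv.chrom, int(s), int(s) + tag_len)))
    total = float(sum(p.tags for p in peaks))
    realized = observed_tags(peaks, annotation) / total if annotation is not None else float("nan")
    return peaks, tags, realized


def make_expression(
    config: SimulationConfig, gene_densities: Mapping[str, float]
) -> pd.DataFrame:
    """Differential-expression table with a monotone density -> FPKM link.

    log FPKM at the later time point = link_slope * z(density) + noise; the
    probability a gene is induced follows a logistic link in z(density) with
    slope ``induction_slope``.  Planted up/down genes are assigned fold
    changes and q-values that the default classification thresholds call.
    """
    rng = config.rng(salt=3)
    genes = sorted(gene_densities)
    dens = np.array([gene_densities[g] for g in genes], dtype=float)
    sd = dens.std()
    z = (dens - dens.mean()) / sd if sd > 0 else np.zeros_like(dens)
    fpkm = 10.0 * np.exp(
        config.link_slope * z + rng.normal(0.0, config.link_noise_sd, len(genes))
    )
    base = np.log(max(config.frac_up, 1e-9) / (1 - min(config.frac_up, 1 - 1e-9)))
    p_up = 1.0 / (1.0 + np.exp(-(base + config.induction_slope * z)))
    u = rng.random(len(genes))
    is_up = u < p_up
    is_down = (~is_up) & (rng.random(len(genes)) < config.frac_down / max(1e-9, 1 - config.frac_up))
    planted_up = set(config.planted_up_genes)
    planted_down = set(config.planted_down_genes)
    log2fc = rng.normal(0.0, 0.3, len(genes))
    q = rng.uniform(0.05, 1.0, len(genes))
    for i, g in enumerate(genes):
        up = g in planted_up or (is_up[i] and g not in planted_down)
        down = g in planted_down or (is_down[i] and not up and g not in planted_up)
        if up:
            log2fc[i] = rng.normal(2.0, 0.3)
            if log2fc[i] < 1.0:
                log2fc[i] = 1.0 + rng.random()
            q[i] = rng.uniform(1e-6, 0.01)
        elif down:
            log2fc[i] = rng.normal(-2.0, 0.3)
            if log2fc[i] > -1.0:
                log2fc[i] = -1.0 - rng.random()
            q[i] = rng.uniform(1e-6, 0.01)
    return pd.DataFrame(
        {
            "gene_id": genes,
            "fpkm": fpkm,
            "log2fc": log2fc,
            "q_value": q,
        }
    )


@dataclass(frozen=True)
class CancerCohort:
    """Per-sample peak sets (two normals, two tumors) plus expression cohorts."""

    normal_peaks: Tuple[Tuple[Peak, ...], ...]
    tumor_peaks: Tuple[Tuple[Peak, ...], ...]
    tumor_expr: Dict[str, np.ndarray]
    normal_expr: Dict[str, np.ndarray]


def make_cancer_cohort(
    config: SimulationConfig, genome: SyntheticGenome
) -> CancerCohort:
    """Matched tumor/normal cohort with planted 5-hmC gain/loss gene sets.

    Loss genes receive a gene-body peak in both normal samples only, gain
    genes in both tumors only, and a background fraction of the remaining
    genes in all four samples.  The first ``n_loss_shifted`` loss genes (and
    ``n_gain_shifted`` gain genes, in sorted order) also receive a true
    expression shift of ``expression_shift_fold``; unshifted genes get the
    identical expression values in both cohorts (plus optional noise), so at
    zero noise only the planted shifts are statistically detectable.
    """
    rng = config.rng(salt=4)
    gain = sorted(config.planted_gain_genes)
    loss = sorted(config.planted_loss_genes)
    by_id = {g.gene_id: g for g in genome.genes}
    for gid in gain + loss:
        if gid not in by_id:
            raise ValueError(f"planted gene {gid!r} not in genome")
    background = [
        g.gene_id
        for g in genome.genes
        if g.gene_id not in set(gain) | set(loss)
        and rng.random() < config.background_hmc_fraction
    ]

    def body_peak(gid: str) -> Peak:
        body = by_id[gid].body
        width = min(len(body), 1000)
        mid = (body.start + body.end) // 2
        start = max(body.start, mid - width // 2)
        return Peak(
            GenomicInterval(body.chrom, start, min(body.end, start + width)),
            int(max(1, _nb_counts(rng, 1, config.tag_mean, config.tag_dispersion)[0])),
        )

    normal_sets, tumor_sets = [], []
    for _ in range(2):
        normal_sets.append(tuple(body_peak(g) for g in loss + background))
    for _ in range(2):
        tumor_sets.append(tuple(body_peak(g) for g in gain + background))

    n_t, n_n = config.n_tumor_samples, config.n_normal_samples
    tumor_expr: Dict[str, np.ndarray] = {}
    normal_expr: Dict[str, np.ndarray] = {}
    shifted_loss = set(loss[: config.n_loss_shifted])
    shifted_gain = set(gain[: config.n_gain_shifted])
    for g in genome.genes:
        gid = g.gene_id
        base = rng.lognormal(mean=math.log(100.0), sigma=0.5, size=max(n_t, n_n))
        normal = base[:n_n].copy()
        tumor = base[:n_t].copy()
        if gid in shifted_loss:
            tumor = tumor / config.expression_shift_fold
        elif gid in shifted_gain:
            tumor = tumor * config.expression_shift_fold
        if config.expression_noise_sd > 0:
            normal = normal * np.exp(rng.normal(0, config.expression_noise_sd, n_n))
            tumor = tumor * np.exp(rng.normal(0, config.expression_noise_sd, n_t))
        normal_expr[gid] = normal
        tumor_expr[gid] = tumor
    return CancerCohort(
        tuple(normal_sets), tuple(tumor_sets), tumor_expr, normal_expr
    )


def make_tabseq(config: SimulationConfig) -> pd.DataFrame:
    """Clone-count table: per condition and CpG, binomially sampled C/T calls.

    Bisulfite C clones ~ Binomial(clones, (pct_5mC + pct_5hmC)/100); TAB C
    clones ~ Binomial(clones, pct_5hmC/100), independently per site.
    """
    rng = config.rng(salt=5)
    rows = []
    for cond in sorted(config.tabseq_truth):
        pct_c, pct_5mc, pct_5hmc = config.tabseq_truth[cond]
        for i in range(config.n_cpg_sites):
            pos = 1000 + 37 * i
            n = config.clones_per_site
            bs_c = int(rng.binomial(n, (pct_5mc + pct_5hmc) / 100.0))
            tab_c = int(rng.binomial(n, pct_5hmc / 100.0))
            rows.append(("chr1", pos, cond, "bs", bs_c, n - bs_c))
            rows.append(("chr1", pos, cond, "tab", tab_c, n - tab_c))
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "condition", "treatment", "n_C", "n_T"]
    )


def make_overlap_pair(
    config: SimulationConfig,
    n_intervals: int = 50,
    interval_length: int = 2000,
) -> Tuple[ConsensusPeakSet, ConsensusPeakSet]:
    """Two consensus sets where set b covers exactly ``overlap_fraction`` of
    set a's bases (the planted in vitro / in vivo containment scenario), and
    b additionally covers the same amount of extra sequence elsewhere."""
    covered = int(round(interval_length * config.overlap_fraction))
    a_ivs, b_ivs = [], []
    gap = interval_length  # spacing between planted intervals
    pos = 1000
    for _ in range(n_intervals):
        a_ivs.append(GenomicInterval("chr1", pos, pos + interval_length))
        if covered > 0:
            b_ivs.append(GenomicInterval("chr1", pos, pos + covered))
        # extra b-only coverage in the gap after the a interval
        b_ivs.append(
            GenomicInterval("chr1", pos + interval_length + 100,
                            pos + interval_length + 100 + covered)
        ) if covered > 0 else None
        pos += interval_length + 2 * gap
    return (
        ConsensusPeakSet("in_vitro", tuple(merge(a_ivs))),
        ConsensusPeakSet("in_vivo", tuple(merge(b_ivs))),
    )
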