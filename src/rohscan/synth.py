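"""Synthetic SNP-array populations with known ROH truth.

The generator emulates a medium-density genotyping array — roughly one
SNP per 50 kb, the density at which ROH parameter choices matter most —
and plants homozygous segments of known position and length so that
detection can be scored against an exact truth.

Outside planted segments, genotypes are drawn independently per SNP
from Hardy–Weinberg proportions at the SNP's allele frequency; there
is no background LD unless :func:`ld_block_map` is used, which keeps
each test's assumptions isolated.  Inside a planted segment one allele
is drawn per SNP and doubled, so the segment is fully homozygous
(before the independent missing-call mask is applied).

Allele frequencies come either from a uniform MAF distribution
(``maf_range``) or, when none is given, from the single frequency whose
Hardy–Weinberg heterozygosity equals ``background_het`` — so the
requested background heterozygosity is hit exactly in expectation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .genio import HET, HOM_A, HOM_B, MISSING, GenotypeDataset, SnpMap

__all__ = [
    "SynthSpec",
    "SynthTruth",
    "TruthSegment",
    "homozygous_individual",
    "generate",
    "ld_block_map",
    "write_truth_table",
]


@dataclass(frozen=True)
class TruthSegment:
    individual_id: str
    chromosome: str
    start_bp: int
    end_bp: int
    n_snp: int

    @property
    def length_kb(self) -> float:
        return (self.end_bp - self.start_bp + 1) / 1000.0


@dataclass(frozen=True)
class SynthTruth:
    """Planted-segment truth: spans, total ROH kb and true F_ROH per individual."""

    segments: tuple
    l_aut_kb: float

    def total_kb(self, individual_id: str) -> float:
        return sum(
            s.length_kb for s in self.segments if s.individual_id == individual_id
        )

    def f_roh_aut(self, individual_id: str) -> float:
        return self.total_kb(individual_id) / self.l_aut_kb if self.l_aut_kb else 0.0


@dataclass(frozen=True)
class SynthSpec:
    """Recipe for a synthetic population.

    Parameters
    ----------
    n_chromosomes, snps_per_chromosome : int
        Map geometry; chromosomes are labelled "1", "2", ...
    n_individuals : int
        Population size.
    spacing_kb : float
        Mean inter-SNP spacing; 50 kb/SNP emulates a ~50K array on a
        mammalian genome.
    spacing_model : {"uniform", "gamma"}
        "uniform" places SNPs on an exact grid; "gamma" draws spacings
        from a Gamma distribution (shape ``gamma_shape``) with the same
        mean, giving realistic density fluctuation and occasional gaps.
    planted_segments : mapping individual index -> ((chrom_idx, start_snp, n_snp), ...)
        Homozygous segments to plant, in SNP indices (0-based within
        chromosome), converted to bp via the realized map so truth is
        exact under any spacing model.
    background_het : float
        Expected heterozygosity per SNP outside planted segments.
    missing_rate : float
        Independent missing-call probability, applied everywhere.
    maf_range : (low, high) or None
        Per-SNP MAF ~ Uniform[low, high]; when None a single allele
        frequency reproducing ``background_het`` is used for all SNPs.
    """

    n_chromosomes: int = 3
    snps_per_chromosome: int = 1000
    n_individuals: int = 20
    spacing_kb: float = 50.0
    spacing_model: str = "uniform"
    gamma_shape: float = 4.0
    planted_segments: dict = field(default_factory=dict)
    background_het: float = 0.35
    missing_rate: float = 0.01
    maf_range: tuple | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_chromosomes < 1 or self.snps_per_chromosome < 1:
            raise ValueError("need at least one chromosome and one SNP")
        if self.n_individuals < 1:
            raise ValueError("need at least one individual")
        if self.spacing_model not in ("uniform", "gamma"):
            raise ValueError("spacing_model must be 'uniform' or 'gamma'")
        if not 0 <= self.background_het <= 0.5:
            raise ValueError("background_het must be in [0, 0.5]")
        if not 0 <= self.missing_rate <= 1:
            raise ValueError("missing_rate must be in [0, 1]")
        if self.maf_range is not None:
            lo, hi = self.maf_range
            if not 0 <= lo <= hi <= 0.5:
                raise ValueError("maf_range must satisfy 0 <= low <= high <= 0.5")
        for ind, segs in self.planted_segments.items():
            spans: dict = {}
            for chrom_idx, start, n_snp in segs:
                if not 0 <= chrom_idx < self.n_chromosomes:
                    raise ValueError(f"segment chromosome {chrom_idx} out of range")
                if n_snp < 1 or start < 0 or start + n_snp > self.snps_per_chromosome:
                    raise ValueError(
                        f"segment ({chrom_idx}, {start}, {n_snp}) exceeds "
                        "chromosome bounds"
                    )
                for s0, n0 in spans.get(chrom_idx, []):
                    if start < s0 + n0 and s0 < start + n_snp:
                        raise ValueError(
                            f"overlapping planted segments for individual {ind}"
                        )
                spans.setdefault(chrom_idx, []).append((start, n_snp))


def _build_map(spec: SynthSpec, rng: np.random.Generator) -> SnpMap:
    chroms, ids, bps = [], [], []
    spacing_bp = spec.spacing_kb * 1000.0
    for c in range(spec.n_chromosomes):
        label = str(c + 1)
        if spec.spacing_model == "uniform":
            gaps = np.full(spec.snps_per_chromosome - 1, spacing_bp)
        else:
            gaps = rng.gamma(
                spec.gamma_shape,
                spacing_bp / spec.gamma_shape,
                size=spec.snps_per_chromosome - 1,
            )
        pos = 1 + np.concatenate([[0.0], np.cumsum(np.maximum(1, np.round(gaps)))])
        for j, p in enumerate(pos.astype(np.int64)):
            chroms.append(label)
            ids.append(f"snp{c + 1}_{j + 1}")
            bps.append(int(p))
    return SnpMap(
        np.array(chroms, dtype=object),
        np.array(ids, dtype=object),
        np.array(bps, dtype=np.int64),
    )


def _freq_for_het(het: float) -> float:
    """Minor allele frequency whose HW heterozygosity is ``het``."""
    return 0.5 * (1.0 - math.sqrt(max(0.0, 1.0 - 2.0 * het)))


def homozygous_individual(snp_map: SnpMap) -> GenotypeDataset:
    """A single completely homozygous individual on the given map.

    This is the probe used to measure the maximal detectable ROH length
    of a parameter set.
    """
    calls = np.full((1, snp_map.n_snp), HOM_A, dtype=np.int8)
    return GenotypeDataset(snp_map, ("HOM_PROBE",), calls)


def generate(spec: SynthSpec) -> tuple[GenotypeDataset, SynthTruth]:
    """Draw a synthetic population; deterministic for a given seed."""
    rng = np.random.default_rng(spec.seed)
    snp_map = _build_map(spec, rng)
    n_snp = snp_map.n_snp
    n_ind = spec.n_individuals
    per_chrom = spec.snps_per_chromosome

    if spec.maf_range is not None:
        maf = rng.uniform(spec.maf_range[0], spec.maf_range[1], size=n_snp)
    else:
        maf = np.full(n_snp, _freq_for_het(spec.background_het))
    f_b = maf  # B is the minor allele; A-allele frequency is 1 - maf
    p_hom_a = (1.0 - f_b) ** 2
    p_het = 2.0 * f_b * (1.0 - f_b)

    u = rng.random((n_ind, n_snp))
    calls = np.full((n_ind, n_snp), HOM_B, dtype=np.int8)
    calls[u < p_hom_a + p_het] = HET
    calls[u < p_hom_a] = HOM_A

    truth_segments = []
    ids = tuple(f"ind{i + 1}" for i in range(n_ind))
    for ind_idx, segs in spec.planted_segments.items():
        for chrom_idx, start, n in segs:
            g0 = chrom_idx * per_chrom + start
            # one allele drawn per SNP, doubled -> fully homozygous
            hom = np.where(
                rng.random(n) < f_b[g0 : g0 + n], HOM_B, HOM_A
            ).astype(np.int8)
            calls[ind_idx, g0 : g0 + n] = hom
            truth_segments.append(
                TruthSegment(
                    individual_id=ids[ind_idx],
                    chromosome=str(chrom_idx + 1),
                    start_bp=int(snp_map.bp[g0]),
                    end_bp=int(snp_map.bp[g0 + n - 1]),
                    n_snp=n,
                )
            )

    if spec.missing_rate > 0:
        miss = rng.random((n_ind, n_snp)) < spec.missing_rate
        calls[miss] = MISSING

    l_aut = sum(
        (int(snp_map.bp[snp_map.chrom == c][-1]) - int(snp_map.bp[snp_map.chrom == c][0]))
        / 1000.0
        for c in snp_map.chromosomes()
    )
    truth = SynthTruth(tuple(truth_segments), l_aut)
    return GenotypeDataset(snp_map, ids, calls), truth


def ld_block_map(
    spec: SynthSpec, block_size: int, within_block_r2: float
) -> GenotypeDataset:
    """Population with block-structured LD for pruning experiments.

    SNPs within a block are noisy copies of a shared latent template
    genotype: each individual's call copies the template with
    probability ``p`` and is otherwise redrawn from Hardy–Weinberg.
    Two block members then correlate with r² = p⁴, so ``p`` is set to
    ``within_block_r2 ** 0.25``.  Blocks are mutually independent.
    """
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    if not 0 < within_block_r2 <= 1:
        raise ValueError(
            "within_block_r2 must be in (0, 1]; other targets are "
            "unattainable under the copy-noise model"
        )
    rng = np.random.default_rng(spec.seed)
    snp_map = _build_map(spec, rng)
    n_snp = snp_map.n_snp
    n_ind = spec.n_individuals
    p_copy = within_block_r2**0.25

    if spec.maf_range is not None:
        lo, hi = spec.maf_range
    else:
        m = _freq_for_het(spec.background_het)
        lo = hi = m

    calls = np.empty((n_ind, n_snp), dtype=np.int8)
    start = 0
    while start < n_snp:
        # blocks never span chromosomes
        chrom = snp_map.chrom[start]
        chrom_end = start
        while chrom_end < n_snp and snp_map.chrom[chrom_end] == chrom:
            chrom_end += 1
        b = start
        while b < chrom_end:
            width = min(block_size, chrom_end - b)
            f_b = rng.uniform(lo, hi)
            template = _hw_draw(rng, f_b, n_ind)
            for j in range(b, b + width):
                fresh = _hw_draw(rng, f_b, n_ind)
                copy = rng.random(n_ind) < p_copy
                calls[:, j] = np.where(copy, template, fresh)
            b += width
        start = chrom_end

    if spec.missing_rate > 0:
        miss = rng.random((n_ind, n_snp)) < spec.missing_rate
        calls[miss] = MISSING
    ids = tuple(f"ind{i + 1}" for i in range(n_ind))
    return GenotypeDataset(snp_map, ids, calls)


def _hw_draw(rng: np.random.Generator, f_b: float, n: int) -> np.ndarray:
    u = rng.random(n)
    p_hom_a = (1.0 - f_b) ** 2
    p_het = 2.0 * f_b * (1.0 - f_b)
    out = np.full(n, HOM_B, dtype=np.int8)
    out[u < p_hom_a + p_het] = HET
    out[u < p_hom_a] = HOM_A
    return out


def write_truth_table(truth: SynthTruth, path) -> None:
    with open(path, "w") as fh:
        fh.write("IID\tCHR\tPOS1\tPOS2\tNSNP\tKB\n")
        for s in truth.segments:
            fh.write(
                f"{s.individual_id}\t{s.chromosome}\t{s.start_bp}\t"
                f"{s.end_bp}\t{s.n_snp}\t{s.length_kb:.3f}\n"
            )
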