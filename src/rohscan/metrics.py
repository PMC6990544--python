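"""Validation statistics for a ROH parameterization.

Two quantities anchor everything here:

* ``L_aut`` — the autosomal genome length accessible to the array,
  summed over chromosomes as last-SNP minus first-SNP position.

* the **covered length** — the maximal total ROH length any individual
  could exhibit under a given parameter set.  It is measured
  empirically: simulate an individual that is homozygous at every
  marker of the map, run the detector on it with exactly the
  parameters under evaluation, and sum the segment lengths.  Genome
  coverage is then ``100 * covered / L_aut`` and flags parameter sets
  (too-strict density or gap settings, typically) under which parts of
  the genome simply cannot be called as ROH.

The genomic inbreeding coefficient is ``F_ROH = L_ROH / L_aut``, with
``L_ROH`` an individual's total ROH length.  ``f_roh_aut`` normalizes
by the full autosomal length; ``f_roh_cov`` normalizes by the covered
length, and therefore estimates inbreeding over the part of the genome
where detection is actually possible.  Since the covered length never
exceeds ``L_aut``, ``f_roh_cov >= f_roh_aut`` always holds.

Two closed-form helpers round out the module: the Lencz/Purfield
minimum-SNP rule, which sizes ``min_snp`` so that the expected number
of chance ROH across the dataset stays below a false-positive budget
``alpha``, and the scanning-window threshold rule
``t = floor((N_out + 1) / L, 3)`` which converts the number of
unreliable outer SNPs one is willing to discard into a hit-rate
threshold.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .genio import HET, MISSING, GenotypeDataset, SnpMap
from .rohdetect import RohParams, RohSegment, detect_roh

__all__ = [
    "CoverageReport",
    "InbreedingEstimate",
    "LenczInputs",
    "ThresholdSpec",
    "autosome_length",
    "covered_length",
    "f_roh",
    "snp_incidence",
    "lencz_min_snp",
    "window_threshold",
    "mean_heterozygosity",
    "write_coverage_report",
    "write_inbreeding_table",
    "write_incidence_bed",
]


@dataclass(frozen=True)
class CoverageReport:
    """Autosome length, maximal detectable ROH length and coverage %."""

    l_aut_kb: float
    covered_kb: float
    coverage_pct: float
    per_chromosome: tuple  # (chromosome, l_kb, covered_kb) triples

    def __post_init__(self):
        if not 0 <= self.covered_kb <= self.l_aut_kb + 1e-9:
            raise ValueError("covered_kb must lie in [0, l_aut_kb]")


@dataclass(frozen=True)
class InbreedingEstimate:
    individual_id: str
    l_roh_kb: float
    f_roh_aut: float
    f_roh_cov: float  # NaN when covered_kb is 0


@dataclass(frozen=True)
class LenczInputs:
    """Inputs of the minimum-SNP rule.

    n_s: genotyped SNPs per individual; n_i: genotyped individuals;
    alpha: tolerated expected number of false-positive ROH (0.05 by
    convention); het: mean heterozygosity across SNPs.
    """

    n_s: int
    n_i: int
    alpha: float = 0.05
    het: float = 0.3

    def __post_init__(self):
        if self.n_s < 1 or self.n_i < 1:
            raise ValueError("n_s and n_i must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.het < 1:
            raise ValueError("het must be in (0, 1)")


@dataclass(frozen=True)
class ThresholdSpec:
    """Window size L and the number of outer SNPs per side to exclude."""

    window_size: int
    n_out: int = 0

    def __post_init__(self):
        if self.window_size < 1:
            raise ValueError("window_size must be >= 1")
        if not 0 <= self.n_out < self.window_size:
            raise ValueError("n_out must satisfy 0 <= n_out < window_size")


def autosome_length(snp_map: SnpMap) -> tuple[float, list]:
    """L_aut in kb: per chromosome, last-SNP bp minus first-SNP bp.

    Returns (total_kb, [(chromosome, length_kb), ...]).  A single-SNP
    chromosome spans 0 kb and triggers a warning — it can never host a
    detectable ROH.
    """
    per_chrom = []
    total = 0.0
    for c in snp_map.chromosomes():
        pos = snp_map.bp[snp_map.chrom == c]
        l_kb = (int(pos[-1]) - int(pos[0])) / 1000.0
        if len(pos) == 1:
            warnings.warn(
                f"chromosome {c!r} has a single SNP; it contributes 0 kb",
                stacklevel=2,
            )
        per_chrom.append((c, l_kb))
        total += l_kb
    return total, per_chrom


def covered_length(snp_map: SnpMap, p: RohParams) -> CoverageReport:
    """Coverage of a ROH parameterization on a given map.

    Runs the full detector on a simulated completely homozygous
    individual with exactly the parameters under evaluation; the total
    ROH length found is the maximal detectable ROH length.
    """
    from .synth import homozygous_individual

    ds = homozygous_individual(snp_map)
    segments = detect_roh(ds, p)
    l_aut, per_chrom_l = autosome_length(snp_map)
    cov_by_chrom: dict = {c: 0.0 for c, _ in per_chrom_l}
    for seg in segments:
        cov_by_chrom[seg.chromosome] += seg.length_kb
    covered = sum(cov_by_chrom.values())
    # the inclusive +1 bp of each segment can nudge covered a hair past
    # the first-to-last span; clamp so coverage tops out at 100%
    covered = min(covered, l_aut)
    pct = 100.0 * covered / l_aut if l_aut > 0 else 0.0
    per = tuple(
        (c, l_kb, min(cov_by_chrom[c], l_kb)) for c, l_kb in per_chrom_l
    )
    return CoverageReport(l_aut, covered, pct, per)


def f_roh(
    segments: list[RohSegment],
    individual_id: str,
    l_aut_kb: float,
    covered_kb: float,
) -> InbreedingEstimate:
    """F_ROH = L_ROH / L_aut for one individual, on both denominators."""
    l_roh = sum(s.length_kb for s in segments if s.individual_id == individual_id)
    aut = l_roh / l_aut_kb if l_aut_kb > 0 else 0.0
    cov = l_roh / covered_kb if covered_kb > 0 else float("nan")
    return InbreedingEstimate(individual_id, l_roh, aut, cov)


def snp_incidence(
    segments: list[RohSegment], snp_map: SnpMap, n_individuals: int
) -> np.ndarray:
    """Per-SNP ROH incidence as a percentage of the population.

    A SNP counts for an individual when some segment of that individual
    spans the SNP's position on the SNP's chromosome.
    """
    counts = np.zeros(snp_map.n_snp, dtype=np.int64)
    by_ind: dict = {}
    for seg in segments:
        by_ind.setdefault(seg.individual_id, []).append(seg)
    chrom_cache = {c: snp_map.chrom_indices(c) for c in snp_map.chromosomes()}
    for segs in by_ind.values():
        hit = np.zeros(snp_map.n_snp, dtype=bool)
        for seg in segs:
            idx = chrom_cache.get(seg.chromosome)
            if idx is None:
                continue
            pos = snp_map.bp[idx]
            lo = np.searchsorted(pos, seg.start_bp, side="left")
            hi = np.searchsorted(pos, seg.end_bp, side="right")
            hit[idx[lo:hi]] = True
        counts += hit
    return 100.0 * counts / n_individuals


def lencz_min_snp(inp: LenczInputs) -> int:
    """Minimal number of SNPs constituting a ROH.

    L = ln(alpha / (n_s * n_i)) / ln(1 - het), rounded up to the next
    integer (the formula bounds the expected number of chance runs of
    homozygous calls; the ceiling is the conservative closure), with a
    floor of 1.
    """
    value = math.log(inp.alpha / (inp.n_s * inp.n_i)) / math.log(1.0 - inp.het)
    return max(1, math.ceil(value - 1e-12))


def window_threshold(spec: ThresholdSpec) -> float:
    """Scanning-window threshold t = floor((N_out + 1) / L, 3).

    N_out is the number of outer SNPs per side of a homozygous segment
    that should be excluded from the final ROH (outer SNPs may be
    homozygous by chance rather than by descent); flooring is to three
    decimal places.  For a window of 100 SNPs and N_out = 4 the
    threshold is 0.05.
    """
    t = Fraction(spec.n_out + 1, spec.window_size)
    floored = math.floor(t * 1000)
    if floored == 0:
        raise ValueError(
            "threshold floors to 0 at three decimals; increase n_out or "
            "decrease the window size"
        )
    return floored / 1000.0


def mean_heterozygosity(ds: GenotypeDataset) -> float:
    """Mean observed heterozygosity across SNPs (het calls / non-missing)."""
    het = (ds.calls == HET).sum(axis=0)
    called = (ds.calls != MISSING).sum(axis=0)
    with np.errstate(invalid="ignore"):
        per_snp = np.where(called > 0, het / np.maximum(called, 1), np.nan)
    return float(np.nanmean(per_snp))


def write_coverage_report(report: CoverageReport, path) -> None:
    with open(path, "w") as fh:
        fh.write("CHR\tL_KB\tCOVERED_KB\n")
        for c, l_kb, cov_kb in report.per_chromosome:
            fh.write(f"{c}\t{l_kb:.3f}\t{cov_kb:.3f}\n")
        fh.write(f"TOTAL\t{report.l_aut_kb:.3f}\t{report.covered_kb:.3f}\n")
        fh.write(f"#coverage_pct\t{report.coverage_pct:.4f}\n")


def write_inbreeding_table(estimates: list[InbreedingEstimate], path) -> None:
    with open(path, "w") as fh:
        fh.write("IID\tL_ROH_KB\tF_ROH_AUT\tF_ROH_COV\n")
        for e in estimates:
            fh.write(
                f"{e.individual_id}\t{e.l_roh_kb:.3f}\t"
                f"{e.f_roh_aut:.6f}\t{e.f_roh_cov:.6f}\n"
            )


def write_incidence_bed(incidence: np.ndarray, snp_map: SnpMap, path) -> None:
    """BED-like (chrom, pos-1, pos, percent) table for plotting."""
    with open(path, "w") as fh:
        for c, bp, pct in zip(snp_map.chrom, snp_map.bp, incidence):
            fh.write(f"{c}\t{bp - 1}\t{bp}\t{pct:.4f}\n")
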