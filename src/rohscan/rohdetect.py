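"""Scanning-window detection of runs of homozygosity (ROH).

The detector mirrors the three-step procedure behind PLINK's
``--homozyg`` family of options:

1. **Window scan.**  A window of ``window_snp`` consecutive markers
   slides one SNP at a time along each chromosome of one individual.  A
   window is *homozygous* iff it contains at most ``window_het``
   heterozygous and at most ``window_missing`` missing calls.  Each SNP
   is scored with its *hit rate*: the proportion of windows containing
   it that are homozygous.  Near chromosome ends a SNP is contained in
   fewer than ``window_snp`` windows; the denominator is the number of
   windows that actually contain it.

2. **Segment calling.**  Maximal runs of consecutive SNPs whose hit
   rate reaches ``window_threshold`` become candidate segments.  With a
   window of 100 SNPs and a threshold of 0.05 an interior SNP must
   appear in at least five homozygous windows to qualify.  Candidate
   ends are trimmed inward to the outermost homozygous non-missing
   call: a run bounded by a heterozygous or missing genotype is not a
   defensible ROH boundary.

3. **Final constraints.**  Each candidate is split at inter-SNP gaps
   larger than ``max_gap_kb``; pieces with more than ``max_het``
   heterozygous calls are split further at heterozygous SNPs (the
   offending call is excised, it belongs to neither flank); piece ends
   are re-trimmed; and pieces failing the density
   (kb-per-SNP ≤ ``max_density``), minimal length (``min_kb``) or
   minimal SNP count (``min_snp``) requirements are discarded.  Because
   splitting may shorten segments, reported ROH can be smaller than the
   scanning window itself.

Hit-rate comparisons use ``>=`` with a 1e-9 absolute tolerance so that
a rate of exactly k/n windows meets a threshold printed with the same
value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genio import HET, HOM_A, HOM_B, MISSING, GenotypeDataset, SnpMap

__all__ = [
    "RohParams",
    "RohSegment",
    "window_hit_rates",
    "candidate_segments",
    "finalize_segments",
    "detect_roh",
    "write_hom_table",
]

#: tolerance for the hit-rate >= threshold comparison (rates are exact
#: rationals k/n; distinct values differ by far more than this)
HIT_RATE_TOL = 1e-9


@dataclass(frozen=True)
class RohParams:
    """The nine detection settings, mirroring PLINK's --homozyg flags.

    Parameters
    ----------
    window_snp : int
        Scanning window size in SNPs (--homozyg-window-snp).
    window_het : int
        Max heterozygous calls tolerated per window (--homozyg-window-het).
    window_missing : int
        Max missing calls tolerated per window (--homozyg-window-missing).
    window_threshold : float
        Minimal scanning-window hit rate per SNP (--homozyg-window-threshold).
    min_snp : int
        Minimal number of SNPs in a final ROH (--homozyg-snp).
    min_kb : float
        Minimal ROH length in kb (--homozyg-kb).
    max_density : float
        Maximal average marker spacing of a ROH in kb/SNP (--homozyg-density).
    max_gap_kb : float
        Maximal interval between two consecutive SNPs in a ROH, in kb
        (--homozyg-gap).
    max_het : int
        Max heterozygous calls in a final ROH (--homozyg-het).
    """

    window_snp: int = 50
    window_het: int = 1
    window_missing: int = 5
    window_threshold: float = 0.05
    min_snp: int = 100
    min_kb: float = 1000.0
    max_density: float = 50.0
    max_gap_kb: float = 1000.0
    max_het: int = 0

    def __post_init__(self):
        if self.window_snp < 1:
            raise ValueError("window_snp must be >= 1")
        if self.window_het < 0 or self.window_missing < 0 or self.max_het < 0:
            raise ValueError("het/missing tolerances must be >= 0")
        if not 0 < self.window_threshold <= 1:
            raise ValueError("window_threshold must be in (0, 1]")
        if self.min_snp < 0:
            raise ValueError("min_snp must be >= 0")
        if self.min_kb <= 0 or self.max_density <= 0 or self.max_gap_kb <= 0:
            raise ValueError("min_kb, max_density and max_gap_kb must be > 0")


@dataclass(frozen=True)
class RohSegment:
    """One detected run of homozygosity."""

    individual_id: str
    chromosome: object
    start_bp: int
    end_bp: int
    n_snp: int
    length_kb: float
    n_het: int = 0
    n_missing: int = 0

    def __post_init__(self):
        if self.start_bp > self.end_bp:
            raise ValueError("start_bp must be <= end_bp")
        if self.n_snp < 1:
            raise ValueError("a segment contains at least one SNP")


def segment_length_kb(start_bp: int, end_bp: int) -> float:
    """Inclusive bp span in kb: (end - start + 1) / 1000."""
    return (end_bp - start_bp + 1) / 1000.0


def window_hit_rates(calls: np.ndarray, p: RohParams) -> np.ndarray:
    """Per-SNP scanning-window hit rates for one individual-chromosome.

    Returns an array aligned with ``calls``.  A chromosome shorter than
    the window yields zero windows, hence all-zero hit rates.
    """
    calls = np.asarray(calls)
    n = len(calls)
    w = p.window_snp
    if n == 0:
        return np.zeros(0)
    if n < w:
        return np.zeros(n)
    het = (calls == HET).astype(np.int64)
    mis = (calls == MISSING).astype(np.int64)
    # window sums via cumulative sums; window s covers SNPs [s, s+w)
    cs_het = np.concatenate([[0], np.cumsum(het)])
    cs_mis = np.concatenate([[0], np.cumsum(mis)])
    n_win = n - w + 1
    starts = np.arange(n_win)
    hom_win = (
        (cs_het[starts + w] - cs_het[starts] <= p.window_het)
        & (cs_mis[starts + w] - cs_mis[starts] <= p.window_missing)
    ).astype(np.int64)
    cs_hom = np.concatenate([[0], np.cumsum(hom_win)])
    idx = np.arange(n)
    lo = np.maximum(0, idx - w + 1)
    hi = np.minimum(idx, n_win - 1)
    total = hi - lo + 1
    hom_count = cs_hom[hi + 1] - cs_hom[lo]
    return hom_count / total


def _trim_to_homozygous(calls: np.ndarray, start: int, end: int):
    """Shrink [start, end] (inclusive) so both ends are HOM calls.

    Returns None when no homozygous call remains.
    """
    while start <= end and calls[start] not in (HOM_A, HOM_B):
        start += 1
    while end >= start and calls[end] not in (HOM_A, HOM_B):
        end -= 1
    if start > end:
        return None
    return start, end


def candidate_segments(
    hit_rates: np.ndarray, calls: np.ndarray, p: RohParams
) -> list[tuple[int, int]]:
    """Maximal runs of SNPs passing the hit-rate threshold.

    Runs are trimmed so their first and last SNPs are homozygous
    non-missing calls; runs emptied by trimming are dropped.  Index
    ranges are inclusive.
    """
    passing = np.asarray(hit_rates) >= p.window_threshold - HIT_RATE_TOL
    out: list[tuple[int, int]] = []
    n = len(passing)
    i = 0
    while i < n:
        if not passing[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and passing[j + 1]:
            j += 1
        trimmed = _trim_to_homozygous(calls, i, j)
        if trimmed is not None:
            out.append(trimmed)
        i = j + 1
    return out


def _split_at_gaps(bp: np.ndarray, start: int, end: int, max_gap_kb: float):
    """Split inclusive [start, end] at adjacent intervals > max_gap_kb."""
    pieces = []
    s = start
    for k in range(start, end):
        if (bp[k + 1] - bp[k]) / 1000.0 > max_gap_kb:
            pieces.append((s, k))
            s = k + 1
    pieces.append((s, end))
    return pieces


def _split_at_het(calls: np.ndarray, start: int, end: int, max_het: int):
    """Excise leftmost heterozygous calls until every piece obeys max_het.

    While a piece carries more heterozygous calls than allowed, it is
    split at its leftmost het SNP; the het call itself belongs to
    neither flank.  The left flank then holds no het call and is final;
    splitting continues on the right flank.
    """
    pieces = []
    s, e = start, end
    while True:
        het_idx = [k for k in range(s, e + 1) if calls[k] == HET]
        if len(het_idx) <= max_het:
            pieces.append((s, e))
            return pieces
        cut = het_idx[0]
        if cut > s:
            pieces.append((s, cut - 1))
        s = cut + 1
        if s > e:
            return pieces


def finalize_segments(
    ranges: list[tuple[int, int]],
    calls: np.ndarray,
    snp_map_slice: SnpMap,
    p: RohParams,
    individual_id: str = "",
    chromosome=None,
) -> list[RohSegment]:
    """Apply gap, heterozygosity, density, length and SNP-count rules.

    Split order is gap first, then heterozygosity, matching the order
    in which the constraints are stated for the scanning algorithm; the
    order is observable only in rare composite cases and is fixed here.
    """
    bp = snp_map_slice.bp
    segments: list[RohSegment] = []
    for start, end in ranges:
        for gs, ge in _split_at_gaps(bp, start, end, p.max_gap_kb):
            for hs, he in _split_at_het(calls, gs, ge, p.max_het):
                trimmed = _trim_to_homozygous(calls, hs, he)
                if trimmed is None:
                    continue
                ts, te = trimmed
                n_snp = te - ts + 1
                length = segment_length_kb(int(bp[ts]), int(bp[te]))
                if length / n_snp > p.max_density:
                    continue
                if length < p.min_kb or n_snp < p.min_snp:
                    continue
                piece = calls[ts : te + 1]
                segments.append(
                    RohSegment(
                        individual_id=individual_id,
                        chromosome=chromosome,
                        start_bp=int(bp[ts]),
                        end_bp=int(bp[te]),
                        n_snp=n_snp,
                        length_kb=length,
                        n_het=int(np.count_nonzero(piece == HET)),
                        n_missing=int(np.count_nonzero(piece == MISSING)),
                    )
                )
    return segments


def detect_roh(ds: GenotypeDataset, p: RohParams) -> list[RohSegment]:
    """Detect ROH for every individual on every chromosome.

    Output is ordered by (individual, chromosome appearance order,
    start position) and is deterministic.
    """
    segments: list[RohSegment] = []
    chrom_idx = [(c, ds.snp_map.chrom_indices(c)) for c in ds.snp_map.chromosomes()]
    for i, ind in enumerate(ds.individual_ids):
        for c, idx in chrom_idx:
            calls = ds.calls[i, idx]
            sub_map = ds.snp_map.subset(idx)
            rates = window_hit_rates(calls, p)
            ranges = candidate_segments(rates, calls, p)
            segments.extend(
                finalize_segments(ranges, calls, sub_map, p, str(ind), c)
            )
    return segments


def write_hom_table(segments: list[RohSegment], snp_map: SnpMap, path) -> None:
    """Write a PLINK .hom-style tab-delimited segment table."""
    id_by_pos = {}
    for c, s, b in zip(snp_map.chrom, snp_map.snp_id, snp_map.bp):
        id_by_pos[(c, int(b))] = s
    with open(path, "w") as fh:
        fh.write("IID\tCHR\tSNP1\tSNP2\tPOS1\tPOS2\tKB\tNSNP\tNHET\tNMIS\n")
        for seg in segments:
            snp1 = id_by_pos.get((seg.chromosome, seg.start_bp), ".")
            snp2 = id_by_pos.get((seg.chromosome, seg.end_bp), ".")
            fh.write(
                f"{seg.individual_id}\t{seg.chromosome}\t{snp1}\t{snp2}\t"
                f"{seg.start_bp}\t{seg.end_bp}\t{seg.length_kb:.3f}\t"
                f"{seg.n_snp}\t{seg.n_het}\t{seg.n_missing}\n"
            )
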