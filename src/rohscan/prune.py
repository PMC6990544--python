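"""Minor-allele-frequency filtering and windowed LD pruning.

Both filters mirror their PLINK counterparts (``--maf`` and
``--indep-pairwise``).  LD is measured as the squared Pearson
correlation of genotype dosages (0/1/2 copies of the B allele) over
individuals non-missing at both markers — composite LD, the natural
statistic for unphased array data.

``indep_pairwise`` prunes greedily per chromosome: a window of
``ld_window_snps`` consecutive *kept* SNPs is examined, every pair with
r² above the threshold loses one member, the window advances by
``ld_step_snps``, and passes repeat until no window contains a
violating pair.  When a pair must lose a member, the SNP with the
smaller minor allele frequency is removed (approximating PLINK 1.9's
preference for keeping the more informative marker); ties remove the
later SNP in map order.  The procedure is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genio import HET, HOM_A, HOM_B, MISSING, GenotypeDataset

__all__ = [
    "PruneParams",
    "allele_frequencies",
    "maf_filter",
    "r_squared",
    "dosages",
    "indep_pairwise",
]


@dataclass(frozen=True)
class PruneParams:
    """MAF threshold plus the --indep-pairwise window geometry."""

    maf_min: float = 0.0
    ld_window_snps: int = 50
    ld_step_snps: int = 5
    r2_max: float = 1.0

    def __post_init__(self):
        if not 0 <= self.maf_min <= 0.5:
            raise ValueError("maf_min must be in [0, 0.5]")
        if not self.ld_window_snps > self.ld_step_snps > 0:
            raise ValueError("require ld_window_snps > ld_step_snps > 0")
        if not 0 < self.r2_max <= 1:
            raise ValueError("r2_max must be in (0, 1]")


def dosages(calls: np.ndarray) -> np.ndarray:
    """Map calls to B-allele dosage 0/1/2 (float, NaN for missing)."""
    calls = np.asarray(calls)
    out = np.full(calls.shape, np.nan)
    out[calls == HOM_A] = 0.0
    out[calls == HET] = 1.0
    out[calls == HOM_B] = 2.0
    return out


def allele_frequencies(ds: GenotypeDataset) -> np.ndarray:
    """Per-SNP minor allele frequency; NaN where every call is missing."""
    n_a = 2 * (ds.calls == HOM_A).sum(axis=0) + (ds.calls == HET).sum(axis=0)
    called = (ds.calls != MISSING).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        f_a = np.where(called > 0, n_a / (2.0 * np.maximum(called, 1)), np.nan)
    return np.minimum(f_a, 1.0 - f_a)


def maf_filter(ds: GenotypeDataset, maf_min: float) -> GenotypeDataset:
    """Remove SNPs with MAF strictly below ``maf_min``.

    A SNP exactly at the threshold is retained, matching --maf.  SNPs
    with every call missing (undefined MAF) are removed whenever
    maf_min > 0; at maf_min = 0 nothing is removed.
    """
    if not 0 <= maf_min <= 0.5:
        raise ValueError("maf_min must be in [0, 0.5]")
    if maf_min == 0:
        return ds
    maf = allele_frequencies(ds)
    with np.errstate(invalid="ignore"):
        mask = maf >= maf_min
    mask &= ~np.isnan(maf)
    if not mask.any():
        raise ValueError("MAF filter removed every SNP")
    if mask.all():
        return ds
    return ds.subset_snps(mask)


def r_squared(g1: np.ndarray, g2: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Computed over pairwise-complete observations; returns NaN when
    fewer than 2 complete pairs remain or either vector is constant on
    the complete subset.
    """
    d1, d2 = np.asarray(g1, dtype=float), np.asarray(g2, dtype=float)
    ok = ~np.isnan(d1) & ~np.isnan(d2)
    if ok.sum() < 2:
        return float("nan")
    x, y = d1[ok], d2[ok]
    vx = x.var()
    vy = y.var()
    if vx == 0 or vy == 0:
        return float("nan")
    cov = ((x - x.mean()) * (y - y.mean())).mean()
    return float(cov * cov / (vx * vy))


def indep_pairwise(ds: GenotypeDataset, p: PruneParams) -> GenotypeDataset:
    """Greedy windowed LD pruning; returns the dataset on kept SNPs."""
    dose = dosages(ds.calls)
    maf = allele_frequencies(ds)
    kept = np.ones(ds.n_snp, dtype=bool)
    chrom_idx = [ds.snp_map.chrom_indices(c) for c in ds.snp_map.chromosomes()]

    # straightforward nested-loop pruning; datasets are medium density,
    # windows are small, so an O(window^2) pass is fine
    changed = True
    while changed:
        changed = False
        for idx in chrom_idx:
            live = idx[kept[idx]]
            if len(live) < 2:
                continue
            start = 0
            while start < len(live):
                window = live[start : start + p.ld_window_snps]
                for a in range(len(window)):
                    ja = window[a]
                    if not kept[ja]:
                        continue
                    for b in range(a + 1, len(window)):
                        jb = window[b]
                        if not kept[ja]:
                            break
                        if not kept[jb]:
                            continue
                        r2 = r_squared(dose[:, ja], dose[:, jb])
                        if np.isnan(r2) or r2 <= p.r2_max:
                            continue
                        # victim rule: smaller MAF loses; tie -> later SNP
                        ma, mb = maf[ja], maf[jb]
                        if np.isnan(mb) or (not np.isnan(ma) and ma > mb):
                            victim = jb
                        elif np.isnan(ma) or mb > ma:
                            victim = ja
                        else:
                            victim = max(ja, jb)
                        kept[victim] = False
                        changed = True
                start += p.ld_step_snps
    if not kept.any():
        raise ValueError("LD pruning removed every SNP")
    if kept.all():
        return ds
    return ds.subset_snps(kept)
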