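"""PLINK text-format I/O and marker-level quality control.

Genotype calls are stored as a compact ``int8`` matrix (individuals x SNPs)
using the codes :data:`HOM_A`, :data:`HET`, :data:`HOM_B` and
:data:`MISSING`.  The A/B labelling of each SNP is assigned by first
observation while reading a ``.ped`` file; it is an arbitrary but
deterministic bookkeeping choice — allele frequencies and everything
downstream are computed from the call counts, so the labelling cannot
affect any result.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "HOM_A",
    "HET",
    "HOM_B",
    "MISSING",
    "SnpMap",
    "GenotypeDataset",
    "read_map",
    "write_map",
    "read_ped",
    "write_ped",
    "drop_unassigned",
    "call_rate_filter",
]

HOM_A: int = 0
HET: int = 1
HOM_B: int = 2
MISSING: int = -1


class MapParseError(ValueError):
    """Raised when a .map or .ped file cannot be parsed."""


@dataclass(frozen=True)
class SnpMap:
    """Ordered SNP positions, one row per marker.

    Attributes
    ----------
    chrom : np.ndarray of str
        Chromosome label per SNP (kept as strings; "0" is PLINK's
        unassigned code).
    snp_id : np.ndarray of str
        Unique marker identifiers.
    bp : np.ndarray of int
        1-based physical positions, strictly increasing within each
        chromosome in file order.
    cm : np.ndarray of float
        Genetic-map positions; parsed but unused downstream.
    """

    chrom: np.ndarray
    snp_id: np.ndarray
    bp: np.ndarray
    cm: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        chrom = np.asarray(self.chrom, dtype=object)
        snp_id = np.asarray(self.snp_id, dtype=object)
        bp = np.asarray(self.bp, dtype=np.int64)
        cm = (
            np.zeros(len(bp), dtype=float)
            if self.cm is None
            else np.asarray(self.cm, dtype=float)
        )
        if not (len(chrom) == len(snp_id) == len(bp) == len(cm)):
            raise ValueError("SnpMap columns must have equal length")
        if len(np.unique(snp_id)) != len(snp_id):
            raise MapParseError("duplicate snp_id values in map")
        for label in dict.fromkeys(chrom):
            pos = bp[chrom == label]
            if np.any(np.diff(pos) <= 0):
                raise MapParseError(
                    f"bp positions not strictly increasing on chromosome {label!r}"
                )
        object.__setattr__(self, "chrom", chrom)
        object.__setattr__(self, "snp_id", snp_id)
        object.__setattr__(self, "bp", bp)
        object.__setattr__(self, "cm", cm)

    @property
    def n_snp(self) -> int:
        return len(self.bp)

    def chromosomes(self) -> list:
        """Chromosome labels in order of first appearance."""
        return list(dict.fromkeys(self.chrom))

    def chrom_indices(self, label) -> np.ndarray:
        return np.flatnonzero(self.chrom == label)

    def subset(self, mask: np.ndarray) -> "SnpMap":
        mask = np.asarray(mask)
        return SnpMap(self.chrom[mask], self.snp_id[mask], self.bp[mask], self.cm[mask])


@dataclass(frozen=True)
class GenotypeDataset:
    """A SNP map plus individuals plus their genotype calls.

    ``calls`` is an (n_individuals x n_snp) int8 matrix with values in
    {HOM_A, HET, HOM_B, MISSING}.  ``allele_a``/``allele_b`` record the
    allele letters behind the A/B coding so a dataset read from .ped can
    be written back verbatim; synthetic datasets default to "A"/"B".
    """

    snp_map: SnpMap
    individual_ids: tuple
    calls: np.ndarray
    allele_a: np.ndarray = field(default=None)  # type: ignore[assignment]
    allele_b: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        calls = np.asarray(self.calls, dtype=np.int8)
        ids = tuple(self.individual_ids)
        if calls.ndim != 2 or calls.shape[1] != self.snp_map.n_snp:
            raise ValueError(
                f"calls shape {calls.shape} does not match map of "
                f"{self.snp_map.n_snp} SNPs"
            )
        if calls.shape[0] != len(ids):
            raise ValueError("calls row count does not match individual_ids")
        if len(set(ids)) != len(ids):
            raise ValueError("individual_ids must be unique")
        a = (
            np.full(calls.shape[1], "A", dtype=object)
            if self.allele_a is None
            else np.asarray(self.allele_a, dtype=object)
        )
        b = (
            np.full(calls.shape[1], "B", dtype=object)
            if self.allele_b is None
            else np.asarray(self.allele_b, dtype=object)
        )
        object.__setattr__(self, "calls", calls)
        object.__setattr__(self, "individual_ids", ids)
        object.__setattr__(self, "allele_a", a)
        object.__setattr__(self, "allele_b", b)

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_snp(self) -> int:
        return self.snp_map.n_snp

    def subset_snps(self, mask: np.ndarray) -> "GenotypeDataset":
        mask = np.asarray(mask)
        return replace(
            self,
            snp_map=self.snp_map.subset(mask),
            calls=self.calls[:, mask],
            allele_a=self.allele_a[mask],
            allele_b=self.allele_b[mask],
        )


def read_map(path) -> SnpMap:
    """Read a 4-column PLINK ``.map`` file (chrom, id, cM, bp)."""
    chroms, ids, cms, bps = [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 4:
                raise MapParseError(
                    f"{path}:{lineno}: expected 4 columns, got {len(parts)}"
                )
            try:
                cm = float(parts[2])
                bp = int(parts[3])
            except ValueError as exc:
                raise MapParseError(f"{path}:{lineno}: {exc}") from exc
            chroms.append(parts[0])
            ids.append(parts[1])
            cms.append(cm)
            bps.append(bp)
    if not bps:
        raise MapParseError(f"{path}: empty map file")
    return SnpMap(np.array(chroms, dtype=object), np.array(ids, dtype=object),
                  np.array(bps, dtype=np.int64), np.array(cms))


def write_map(snp_map: SnpMap, path) -> None:
    with open(path, "w") as fh:
        for c, s, cm, bp in zip(snp_map.chrom, snp_map.snp_id, snp_map.cm, snp_map.bp):
            fh.write(f"{c}\t{s}\t{cm:g}\t{bp}\n")


def read_ped(path, snp_map: SnpMap) -> GenotypeDataset:
    """Read a PLINK ``.ped`` file against an already-read map.

    Each SNP contributes one allele pair; ``0 0`` is missing.  The first
    non-missing allele observed at a SNP becomes allele A, the second
    distinct one allele B.  More than two distinct alleles at a SNP is an
    error.
    """
    n = snp_map.n_snp
    ids: list[str] = []
    rows: list[np.ndarray] = []
    allele_a = np.full(n, None, dtype=object)
    allele_b = np.full(n, None, dtype=object)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6 + 2 * n:
                raise MapParseError(
                    f"{path}:{lineno}: expected {6 + 2 * n} columns "
                    f"(6 IDs + 2 alleles x {n} SNPs), got {len(parts)}"
                )
            ids.append(parts[1])
            row = np.empty(n, dtype=np.int8)
            alleles = parts[6:]
            for j in range(n):
                a1, a2 = alleles[2 * j], alleles[2 * j + 1]
                if a1 == "0" or a2 == "0":
                    row[j] = MISSING
                    continue
                code = 0
                for al in (a1, a2):
                    if allele_a[j] is None:
                        allele_a[j] = al
                    elif al != allele_a[j] and allele_b[j] is None:
                        allele_b[j] = al
                    if al == allele_a[j]:
                        pass
                    elif al == allele_b[j]:
                        code += 1
                    else:
                        raise MapParseError(
                            f"{path}:{lineno}: more than 2 alleles at SNP "
                            f"{snp_map.snp_id[j]!r}"
                        )
                row[j] = (HOM_A, HET, HOM_B)[code]
            rows.append(row)
    if not rows:
        raise MapParseError(f"{path}: empty ped file")
    allele_a[allele_a == None] = "A"  # noqa: E711 - object-array sentinel
    allele_b[allele_b == None] = "B"  # noqa: E711
    return GenotypeDataset(snp_map, tuple(ids), np.vstack(rows), allele_a, allele_b)


def write_ped(ds: GenotypeDataset, path) -> None:
    """Write a minimal .ped (family = individual id, other ID fields 0)."""
    pair = {HOM_A: ("{a}", "{a}"), HET: ("{a}", "{b}"),
            HOM_B: ("{b}", "{b}"), MISSING: ("0", "0")}
    with open(path, "w") as fh:
        for i, ind in enumerate(ds.individual_ids):
            fields = [str(ind), str(ind), "0", "0", "0", "-9"]
            row = ds.calls[i]
            for j in range(ds.n_snp):
                t1, t2 = pair[int(row[j])]
                a, b = ds.allele_a[j], ds.allele_b[j]
                fields.append(t1.format(a=a, b=b))
                fields.append(t2.format(a=a, b=b))
            fh.write(" ".join(fields) + "\n")


def _nonempty(ds: GenotypeDataset, what: str) -> GenotypeDataset:
    if ds.n_snp == 0:
        raise ValueError(f"{what} removed every SNP")
    return ds


def drop_unassigned(ds: GenotypeDataset, autosome_labels) -> GenotypeDataset:
    """Keep only SNPs whose chromosome is in ``autosome_labels``.

    Mirrors the standard QC step of discarding markers with unassigned
    chromosomal information (PLINK chromosome code "0") and any
    non-autosomal contigs.
    """
    labels = {str(x) for x in autosome_labels}
    if not labels:
        raise ValueError("autosome_labels must be non-empty")
    mask = np.array([str(c) in labels for c in ds.snp_map.chrom])
    if mask.all():
        return ds
    return _nonempty(ds.subset_snps(mask), "autosome filter")


def call_rate_filter(ds: GenotypeDataset, min_rate: float) -> GenotypeDataset:
    """Remove SNPs whose call rate is strictly below ``min_rate``.

    Call rate is the fraction of non-missing calls over individuals; the
    conventional QC threshold is 0.95 (markers called in < 95% of
    individuals are dropped).
    """
    if not 0 <= min_rate <= 1:
        raise ValueError("min_rate must be in (0, 1]")
    rate = (ds.calls != MISSING).mean(axis=0)
    mask = rate >= min_rate
    if mask.all():
        return ds
    return _nonempty(ds.subset_snps(mask), "call-rate filter")
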