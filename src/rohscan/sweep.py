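"""One-parameter sensitivity sweeps over ROH detection settings.

Each sweep varies a single setting while holding the rest at a
baseline, and tabulates genome coverage, mean F_ROH on both
denominators and the number of detected segments per value.  The
baseline follows a conservative medium-density protocol: a small
scanning window (20 SNPs), a large gap (2 Mb), a high density
allowance (200 kb/SNP), a window threshold of 0.05, a minimal ROH
length of 1 Mb, at most one missing call and no heterozygous call per
window, and ``min_snp`` sized by the Lencz/Purfield false-positive
rule for the dataset at hand.

Coverage is recomputed for every swept value, so F_ROH,cov always uses
the covered length matching the exact parameters of that run.  For the
pruning arms (``maf``, ``ld_r2``) pruning is applied to a fresh copy
of the input per value and ``min_snp`` is recomputed on the pruned
dataset (the SNP count entering the Lencz formula changes); the other
arms run on the unpruned genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .genio import GenotypeDataset
from .metrics import LenczInputs, covered_length, f_roh, lencz_min_snp, mean_heterozygosity
from .prune import PruneParams, indep_pairwise, maf_filter
from .rohdetect import RohParams, detect_roh

__all__ = ["SweepResult", "baseline_params", "lencz_for_dataset", "sweep", "SWEEPABLE"]

SWEEPABLE = ("maf", "ld_r2", "max_density", "max_gap_kb", "window_snp", "window_threshold")


@dataclass(frozen=True)
class SweepResult:
    parameter_name: str
    values: tuple
    coverage_pct: tuple
    mean_f_roh_aut: tuple
    mean_f_roh_cov: tuple
    n_segments: tuple

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                self.parameter_name: self.values,
                "coverage_pct": self.coverage_pct,
                "mean_f_roh_aut": self.mean_f_roh_aut,
                "mean_f_roh_cov": self.mean_f_roh_cov,
                "n_segments": self.n_segments,
            }
        )


def lencz_for_dataset(ds: GenotypeDataset, alpha: float = 0.05) -> int:
    """min_snp from the Lencz/Purfield rule, using the dataset's own
    SNP count, sample size and mean observed heterozygosity."""
    het = mean_heterozygosity(ds)
    if not het > 0:
        # no heterozygous calls at all: chance runs of homozygous calls
        # cannot arise, so no SNP-count floor is needed
        return 1
    het = min(het, 1 - 1e-9)
    return lencz_min_snp(LenczInputs(n_s=ds.n_snp, n_i=ds.n_individuals, alpha=alpha, het=het))


def baseline_params(ds: GenotypeDataset | None = None, *, min_snp: int | None = None,
                    alpha: float = 0.05) -> RohParams:
    """The unvaried baseline settings (see module docstring).

    ``min_snp`` is filled from the Lencz rule when a dataset is given;
    pass it explicitly otherwise (default 1, i.e. no SNP-count floor).
    """
    if min_snp is None:
        min_snp = lencz_for_dataset(ds, alpha) if ds is not None else 1
    return RohParams(
        window_snp=20,
        window_het=0,
        window_missing=1,
        window_threshold=0.05,
        min_snp=min_snp,
        min_kb=1000.0,
        max_density=200.0,
        max_gap_kb=2000.0,
        max_het=0,
    )


def _run_once(ds: GenotypeDataset, params: RohParams):
    report = covered_length(ds.snp_map, params)
    segments = detect_roh(ds, params)
    estimates = [
        f_roh(segments, ind, report.l_aut_kb, report.covered_kb)
        for ind in ds.individual_ids
    ]
    auts = [e.f_roh_aut for e in estimates]
    covs = [e.f_roh_cov for e in estimates]
    return (
        report.coverage_pct,
        float(np.mean(auts)),
        float(np.nanmean(covs)) if report.covered_kb > 0 else float("nan"),
        len(segments),
    )


def sweep(
    ds: GenotypeDataset,
    base: RohParams,
    parameter_name: str,
    values,
    *,
    ld_window_snps: int = 50,
    ld_step_snps: int = 5,
    recompute_min_snp: bool = True,
) -> SweepResult:
    """Vary one setting, tabulating coverage and mean F_ROH per value.

    ``parameter_name`` is one of ``maf``, ``ld_r2`` (pruning arms,
    applied to a fresh copy per value) or ``max_density``,
    ``max_gap_kb``, ``window_snp``, ``window_threshold`` (detection
    arms, substituted into ``base``).  An ``ld_r2`` value of 1 means no
    pruning.
    """
    values = list(values)
    if not values:
        raise ValueError("values must be non-empty")
    if parameter_name not in SWEEPABLE:
        raise ValueError(
            f"unknown parameter {parameter_name!r}; choose from {SWEEPABLE}"
        )
    cov, aut, covf, nseg = [], [], [], []
    for v in values:
        if parameter_name == "maf":
            run_ds = maf_filter(ds, v)
            params = base
        elif parameter_name == "ld_r2":
            if v == 1:
                run_ds = ds
            else:
                pp = PruneParams(
                    ld_window_snps=ld_window_snps, ld_step_snps=ld_step_snps, r2_max=v
                )
                run_ds = indep_pairwise(ds, pp)
            params = base
        else:
            run_ds = ds
            try:
                params = replace(base, **{parameter_name: v})
            except ValueError as exc:
                raise ValueError(f"invalid value {v!r} for {parameter_name}: {exc}") from exc
        if parameter_name in ("maf", "ld_r2") and recompute_min_snp:
            params = replace(params, min_snp=lencz_for_dataset(run_ds))
        c, a, f, n = _run_once(run_ds, params)
        cov.append(c)
        aut.append(a)
        covf.append(f)
        nseg.append(n)
    return SweepResult(
        parameter_name, tuple(values), tuple(cov), tuple(aut), tuple(covf), tuple(nseg)
    )
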