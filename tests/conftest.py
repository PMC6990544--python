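import numpy as np
import pytest

from rohscan import GenotypeDataset, RohParams, SnpMap


def make_map(positions_by_chrom):
    """Build a SnpMap from {chrom_label: [bp, ...]}."""
    chroms, ids, bps = [], [], []
    for c, positions in positions_by_chrom.items():
        for k, bp in enumerate(positions):
            chroms.append(str(c))
            ids.append(f"snp{c}_{k}")
            bps.append(int(bp))
    return SnpMap(
        np.array(chroms, dtype=object),
        np.array(ids, dtype=object),
        np.array(bps, dtype=np.int64),
    )


def uniform_map(n_chrom=1, n_snp=100, spacing_kb=50.0, start_bp=1):
    spacing = int(spacing_kb * 1000)
    return make_map(
        {
            c + 1: [start_bp + k * spacing for k in range(n_snp)]
            for c in range(n_chrom)
        }
    )


def dataset_from_calls(snp_map, calls, ids=None):
    calls = np.asarray(calls, dtype=np.int8)
    if calls.ndim == 1:
        calls = calls[None, :]
    if ids is None:
        ids = tuple(f"ind{i + 1}" for i in range(calls.shape[0]))
    return GenotypeDataset(snp_map, tuple(ids), calls)


def random_instance(rng, max_chrom=3, max_snp=200, n_individuals=1):
    """A random small dataset plus random detection parameters, used for
    equivalence checks against the brute-force oracle."""
    n_chrom = int(rng.integers(1, max_chrom + 1))
    positions = {}
    for c in range(n_chrom):
        n = int(rng.integers(5, max_snp + 1))
        gaps = rng.integers(1_000, 400_000, size=n - 1)
        pos = 1 + np.concatenate([[0], np.cumsum(gaps)])
        positions[c + 1] = pos.tolist()
    snp_map = make_map(positions)
    p_het = rng.uniform(0.0, 0.5)
    p_mis = rng.uniform(0.0, 0.1)
    u = rng.random((n_individuals, snp_map.n_snp))
    calls = np.full((n_individuals, snp_map.n_snp), 0, dtype=np.int8)
    calls[u < 0.5] = 2
    v = rng.random((n_individuals, snp_map.n_snp))
    calls[v < p_het + p_mis] = 1
    calls[v < p_mis] = -1
    ds = dataset_from_calls(snp_map, calls)
    params = RohParams(
        window_snp=int(rng.integers(2, 31)),
        window_het=int(rng.integers(0, 3)),
        window_missing=int(rng.integers(0, 3)),
        window_threshold=float(rng.choice([0.01, 0.05, 0.2, 0.5, 1.0])),
        min_snp=int(rng.integers(1, 26)),
        min_kb=float(rng.uniform(10, 1500)),
        max_density=float(rng.uniform(20, 500)),
        max_gap_kb=float(rng.uniform(50, 2000)),
        max_het=int(rng.integers(0, 3)),
    )
    return ds, params


def segments_as_tuples(segments):
    return [
        (s.individual_id, s.chromosome, s.start_bp, s.end_bp, s.n_snp,
         round(s.length_kb, 9), s.n_het, s.n_missing)
        for s in segments
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
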