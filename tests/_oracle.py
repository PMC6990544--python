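"""Independent brute-force reference implementations.

Everything here is written with plain Python loops, deliberately
sharing no code with the package's vectorized implementations, so that
agreement between the two is a meaningful check.  The semantics
implemented are the documented ones: window homozygosity tolerances,
hit rate with edge-aware denominator, >= threshold comparison with the
same 1e-9 tolerance, trim-to-homozygous ends, gap-first then
leftmost-het splitting, excised het calls, then density / length /
SNP-count filters.
"""

HOM = (0, 2)  # HOM_A, HOM_B call codes
HET = 1
MISSING = -1
TOL = 1e-9


def brute_chromosome_segments(calls, bps, p):
    """All final ROH index ranges for one individual-chromosome.

    ``calls`` is a list of call codes, ``bps`` the matching positions,
    ``p`` a RohParams-like object.  Returns a list of dicts.
    """
    n = len(calls)
    w = p.window_snp

    hom_windows = []
    for s in range(0, n - w + 1):
        het = 0
        mis = 0
        for k in range(s, s + w):
            if calls[k] == HET:
                het += 1
            elif calls[k] == MISSING:
                mis += 1
        hom_windows.append(het <= p.window_het and mis <= p.window_missing)

    hit = []
    for i in range(n):
        total = 0
        hom = 0
        for s in range(len(hom_windows)):
            if s <= i <= s + w - 1:
                total += 1
                if hom_windows[s]:
                    hom += 1
        hit.append(hom / total if total else 0.0)

    # maximal passing runs, trimmed to homozygous ends
    runs = []
    i = 0
    while i < n:
        if hit[i] >= p.window_threshold - TOL:
            j = i
            while j + 1 < n and hit[j + 1] >= p.window_threshold - TOL:
                j += 1
            r = _trim(calls, i, j)
            if r is not None:
                runs.append(r)
            i = j + 1
        else:
            i += 1

    final = []
    for a, b in runs:
        for ga, gb in _gap_split(bps, a, b, p.max_gap_kb):
            for ha, hb in _het_split(calls, ga, gb, p.max_het):
                r = _trim(calls, ha, hb)
                if r is None:
                    continue
                ta, tb = r
                nsnp = tb - ta + 1
                length_kb = (bps[tb] - bps[ta] + 1) / 1000.0
                if length_kb / nsnp > p.max_density:
                    continue
                if length_kb < p.min_kb:
                    continue
                if nsnp < p.min_snp:
                    continue
                final.append(
                    {
                        "start_bp": bps[ta],
                        "end_bp": bps[tb],
                        "n_snp": nsnp,
                        "length_kb": length_kb,
                        "n_het": sum(1 for k in range(ta, tb + 1) if calls[k] == HET),
                        "n_missing": sum(
                            1 for k in range(ta, tb + 1) if calls[k] == MISSING
                        ),
                    }
                )
    return final


def _trim(calls, a, b):
    while a <= b and calls[a] not in HOM:
        a += 1
    while b >= a and calls[b] not in HOM:
        b -= 1
    return (a, b) if a <= b else None


def _gap_split(bps, a, b, max_gap_kb):
    pieces = []
    s = a
    for k in range(a, b):
        if (bps[k + 1] - bps[k]) / 1000.0 > max_gap_kb:
            pieces.append((s, k))
            s = k + 1
    pieces.append((s, b))
    return pieces


def _het_split(calls, a, b, max_het):
    pieces = []
    while True:
        hets = [k for k in range(a, b + 1) if calls[k] == HET]
        if len(hets) <= max_het:
            pieces.append((a, b))
            return pieces
        cut = hets[0]
        if cut > a:
            pieces.append((a, cut - 1))
        a = cut + 1
        if a > b:
            return pieces


def brute_detect(ds, p):
    """Brute-force detect_roh over a GenotypeDataset; returns a list of
    (individual_id, chromosome, start_bp, end_bp, n_snp) tuples in the
    same deterministic order as the package implementation."""
    out = []
    chroms = []
    seen = set()
    for c in ds.snp_map.chrom:
        if c not in seen:
            seen.add(c)
            chroms.append(c)
    for i, ind in enumerate(ds.individual_ids):
        for c in chroms:
            idx = [k for k in range(ds.snp_map.n_snp) if ds.snp_map.chrom[k] == c]
            calls = [int(ds.calls[i, k]) for k in idx]
            bps = [int(ds.snp_map.bp[k]) for k in idx]
            for seg in brute_chromosome_segments(calls, bps, p):
                out.append(
                    (str(ind), c, seg["start_bp"], seg["end_bp"], seg["n_snp"],
                     round(seg["length_kb"], 9), seg["n_het"], seg["n_missing"])
                )
    return out


def brute_prune_all_pairs(dose_columns, mafs, r2_max):
    """Greedy all-pairs LD pruning of one chromosome, repeated to a
    fixpoint, with the smaller-MAF-loses / later-SNP-tie victim rule.

    ``dose_columns`` is a list of per-SNP dosage lists (None for
    missing).  Returns the sorted list of kept SNP indices.
    """
    import math

    kept = set(range(len(dose_columns)))
    changed = True
    while changed:
        changed = False
        order = sorted(kept)
        for ai in range(len(order)):
            a = order[ai]
            if a not in kept:
                continue
            for bi in range(ai + 1, len(order)):
                b = order[bi]
                if a not in kept:
                    break
                if b not in kept:
                    continue
                r2 = _pearson_r2(dose_columns[a], dose_columns[b])
                if r2 is None or r2 <= r2_max:
                    continue
                ma, mb = mafs[a], mafs[b]
                if mb is None or math.isnan(mb) or (mb is not None and ma is not None and not math.isnan(ma) and ma > mb):
                    victim = b
                elif ma is None or math.isnan(ma) or mb > ma:
                    victim = a
                else:
                    victim = max(a, b)
                kept.discard(victim)
                changed = True
    return sorted(kept)


def _pearson_r2(xs, ys):
    pairs = [(x, y) for x, y in zip(xs, ys) if x is not None and y is not None]
    if len(pairs) < 2:
        return None
    n = len(pairs)
    mx = sum(x for x, _ in pairs) / n
    my = sum(y for _, y in pairs) / n
    vx = sum((x - mx) ** 2 for x, _ in pairs) / n
    vy = sum((y - my) ** 2 for _, y in pairs) / n
    if vx == 0 or vy == 0:
        return None
    cov = sum((x - mx) * (y - my) for x, y in pairs) / n
    return cov * cov / (vx * vy)
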