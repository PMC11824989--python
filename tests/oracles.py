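"""Independent brute-force recomputations used as test oracles.

Everything here is written by explicit counting with plain Python loops,
deliberately sharing no code with the package implementation.
"""

from __future__ import annotations

import math


def o_freqs(alleles, missing_code):
    """Per-locus allele-code -> frequency dicts plus copy counts."""
    n, L, _ = alleles.shape
    freqs, counts = [], []
    for l in range(L):
        tally = {}
        total = 0
        for i in range(n):
            for c in range(2):
                a = int(alleles[i, l, c])
                if a != missing_code:
                    tally[a] = tally.get(a, 0) + 1
                    total += 1
        counts.append(total)
        freqs.append({a: k / total for a, k in tally.items()} if total else {})
    return freqs, counts


def o_ho(alleles, missing_code):
    """Per-locus observed heterozygosity over fully scored individuals."""
    n, L, _ = alleles.shape
    out = []
    for l in range(L):
        het = tot = 0
        for i in range(n):
            a, b = int(alleles[i, l, 0]), int(alleles[i, l, 1])
            if a != missing_code and b != missing_code:
                tot += 1
                if a != b:
                    het += 1
        out.append(het / tot if tot else float("nan"))
    return out


def o_he(freqs):
    """Per-locus gene diversity 1 - sum p^2."""
    return [1.0 - sum(p * p for p in f.values()) if f else float("nan") for f in freqs]


def o_fst(freqs_sub, freqs_full):
    ratios = []
    for fs, ff in zip(freqs_sub, freqs_full):
        if not fs or not ff:
            continue
        codes = sorted(set(fs) | set(ff))
        ht = 1.0 - sum(((fs.get(a, 0.0) + ff.get(a, 0.0)) / 2.0) ** 2 for a in codes)
        if ht <= 0.0:
            continue
        hs = 0.5 * (
            (1.0 - sum(p * p for p in fs.values()))
            + (1.0 - sum(p * p for p in ff.values()))
        )
        ratios.append((ht - hs) / ht)
    return sum(ratios) / len(ratios) if ratios else 0.0


def o_nei(freqs_a, freqs_b):
    jx = jy = jxy = 0.0
    n = 0
    for fa, fb in zip(freqs_a, freqs_b):
        if not fa or not fb:
            continue
        n += 1
        jx += sum(p * p for p in fa.values())
        jy += sum(q * q for q in fb.values())
        jxy += sum(p * fb.get(a, 0.0) for a, p in fa.items())
    jx, jy, jxy = jx / n, jy / n, jxy / n
    if jxy == 0.0:
        return float("inf")
    return -math.log(jxy / math.sqrt(jx * jy))


def o_rogers(freqs_a, freqs_b):
    vals = []
    for fa, fb in zip(freqs_a, freqs_b):
        if not fa and not fb:
            continue
        codes = sorted(set(fa) | set(fb))
        ss = sum((fa.get(a, 0.0) - fb.get(a, 0.0)) ** 2 for a in codes)
        vals.append(math.sqrt(0.5 * ss))
    return sum(vals) / len(vals) if vals else 0.0


def o_detected(allele_set, freqs_sub):
    hit = sum(1 for (l, a) in allele_set if freqs_sub[l].get(a, 0.0) > 0.0)
    return hit / len(allele_set)


def o_mean_freq_diff(freqs_sub, freqs_full):
    diffs = []
    for fs, ff in zip(freqs_sub, freqs_full):
        for a, p in ff.items():
            diffs.append(abs(fs.get(a, 0.0) - p))
    return sum(diffs) / len(diffs) if diffs else 0.0
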