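"""Independent brute-force LD oracle: explicit counting loops and the
literal textbook formulas, kept deliberately separate from the package's
vectorized count-based implementation."""

import math


def brute_force_ld(alleles, i, j):
    """(D, |D'|, r2, defined) for markers i, j of a 0/1/-1 allele matrix."""
    n = a = b = c = d = 0
    for row in alleles:
        x, y = int(row[i]), int(row[j])
        if x < 0 or y < 0:
            continue
        n += 1
        if x == 1 and y == 1:
            a += 1
        elif x == 1 and y == 0:
            b += 1
        elif x == 0 and y == 1:
            c += 1
        else:
            d += 1
    if n < 2:
        return None, None, None, False
    pAB, pAb, paB, pab = a / n, b / n, c / n, d / n
    pA, pB = pAB + pAb, pAB + paB
    pa, pb = 1 - pA, 1 - pB
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        return None, None, None, False
    D = pAB - pA * pB
    r2 = D * D / (pA * pa * pB * pb)
    if D > 0:
        dmax = min(pA * pb, pa * pB)
    elif D < 0:
        dmax = min(pA * pB, pa * pb)
    else:
        return 0.0, 0.0, 0.0, True
    return D, abs(D) / dmax, r2, True


def enumerate_count_vectors(max_total):
    """All (a, b, c, d) haplotype-class counts with 2 <= a+b+c+d <= max_total."""
    for a in range(max_total + 1):
        for b in range(max_total + 1 - a):
            for c in range(max_total + 1 - a - b):
                for d in range(max_total + 1 - a - b - c):
                    if a + b + c + d >= 2:
                        yield a, b, c, d


def chi2_sf_df3(x):
    """Closed-form chi-square survival function for 3 degrees of freedom:
    sf(x) = erfc(sqrt(x/2)) + sqrt(2x/pi) * exp(-x/2)."""
    return math.erfc(math.sqrt(x / 2)) + math.sqrt(2 * x / math.pi) * math.exp(-x / 2)
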