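"""Independent naive oracles used by the test suite.

These deliberately avoid the package's vectorized/engine code paths: the
IBD oracle is a per-SNP python loop over the moment equations, and the
translation oracle is the hand-written codon table from the generators.
"""

from __future__ import annotations

import numpy as np


def naive_ibd(g_a, g_b, freqs):
    """Per-SNP loop method-of-moments IBD: returns (z0, z1, z2, pi_hat)."""
    N0 = N1 = N2 = 0.0
    S00 = S10 = S20 = S11 = S21 = 0.0
    for a, b, p in zip(g_a, g_b, freqs):
        if a < 0 or b < 0 or not (0.0 < p < 1.0) or not np.isfinite(p):
            continue
        ibs = 2 - abs(int(a) - int(b))
        if ibs == 0:
            N0 += 1
        elif ibs == 1:
            N1 += 1
        else:
            N2 += 1
        q = 1.0 - p
        S00 += 2 * p * p * q * q
        S10 += 4 * p * q * (p * p + q * q)
        S20 += p ** 4 + q ** 4 + 4 * p * p * q * q
        S11 += 2 * p * q
        S21 += 1 - 2 * p * q
    N = N0 + N1 + N2
    if N == 0:
        return (float("nan"),) * 4
    z0 = N0 / S00
    z1 = (N1 - z0 * S10) / S11
    z2 = (N2 - z0 * S20 - z1 * S21) / N
    zs = [max(z, 0.0) for z in (z0, z1, z2)]
    total = sum(zs)
    zs = [z / total for z in zs] if total > 0 else [float("nan")] * 3
    return zs[0], zs[1], zs[2], zs[2] + zs[1] / 2


def hw_pair(rng, freqs):
    """Two unrelated Hardy–Weinberg genotype vectors for the given frequencies."""
    n = len(freqs)
    draw = lambda: ((rng.random(n) < freqs).astype(np.int8)
                    + (rng.random(n) < freqs).astype(np.int8))
    return draw(), draw()


def parent_offspring_pair(rng, freqs):
    """Parent and child genotypes: one allele transmitted per SNP."""
    n = len(freqs)
    h = lambda: (rng.random(n) < freqs).astype(np.int8)
    p1, p2 = h(), h()
    pick = rng.random(n) < 0.5
    child = np.where(pick, p1, p2).astype(np.int8) + h()
    return (p1 + p2).astype(np.int8), child
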