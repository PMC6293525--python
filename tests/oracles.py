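"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own recursions: the HMM oracle
enumerates every founder path with dense transition matrices, the scan
oracle refits each interval with statsmodels WLS, the support-interval
oracle enumerates every contiguous run, and the breeding oracle re-simulates
the funnel + sib-mating pedigree tracking founder identity at exactly two
linked loci.
"""

import itertools

import numpy as np
import statsmodels.api as sm
from scipy import stats


def enumerate_posteriors(emissions: np.ndarray, r: np.ndarray, init: np.ndarray):
    """Exact posteriors by summing over all 8^M founder paths."""
    m, k = emissions.shape
    trans = [
        (1 - rt) * np.eye(k) + (rt / 7.0) * (np.ones((k, k)) - np.eye(k))
        for rt in r
    ]
    paths = np.array(list(itertools.product(range(k), repeat=m)), dtype=np.int8)
    logp = np.log(init[paths[:, 0]]) + np.log(emissions[0, paths[:, 0]])
    for t in range(1, m):
        logp += np.log(trans[t - 1][paths[:, t - 1], paths[:, t]])
        logp += np.log(emissions[t, paths[:, t]])
    w = np.exp(logp - logp.max())
    w /= w.sum()
    post = np.zeros((m, k))
    for t in range(m):
        np.add.at(post[t], paths[:, t], w)
    best = paths[int(np.argmax(logp))]
    return post, best


def wls_interval_logp(y, w, probs_interval):
    """F-test LogP of one interval via statsmodels WLS (all 8 columns,
    one dropped as reference)."""
    X = sm.add_constant(probs_interval[:, :-1])
    full = sm.WLS(y, X, weights=w).fit()
    null = sm.WLS(y, np.ones_like(y), weights=w).fit()
    q = X.shape[1] - 1
    df_den = len(y) - X.shape[1]
    F = ((null.ssr - full.ssr) / q) / (full.ssr / df_den)
    return -np.log10(stats.f.sf(F, q, df_den))


def exhaustive_support(logp, peak, drop=1.0):
    """Largest contiguous index run containing the peak with every member
    >= peak - drop, by checking all O(n^2) runs."""
    n = len(logp)
    cutoff = logp[peak] - drop
    best = (peak, peak)
    for a in range(n):
        for b in range(a, n):
            if a <= peak <= b and all(logp[i] >= cutoff for i in range(a, b + 1)):
                if b - a > best[1] - best[0]:
                    best = (a, b)
    return best


def two_locus_pedigree_prob_diff(d_cm, n_gens, n_rep, rng):
    """P(final haplotype carries different founders at two loci d cM
    apart) from an explicit meiosis-by-meiosis pedigree simulation."""
    r = (1 - np.exp(-d_cm / 50.0)) / 2.0

    def gamete(par):
        pick = rng.integers(2)
        a = par[pick]
        b = par[pick] if rng.random() >= r else par[1 - pick]
        return np.array([a[0], b[1]])

    diff = 0
    for _ in range(n_rep):
        fun = rng.permutation(8)
        g1 = [
            (np.full(2, fun[2 * i]), np.full(2, fun[2 * i + 1]))
            for i in range(4)
        ]
        g2a = (gamete(g1[0]), gamete(g1[1]))
        g2b = (gamete(g1[2]), gamete(g1[3]))
        s1 = (gamete(g2a), gamete(g2b))
        s2 = (gamete(g2a), gamete(g2b))
        for _ in range(n_gens):
            c1 = (gamete(s1), gamete(s2))
            c2 = (gamete(s1), gamete(s2))
            s1, s2 = c1, c2
        diff += s1[0][0] != s1[0][1]
    return diff / n_rep


def regular_founders(n_per_chrom, chr_lengths, seed=0):
    """Founders on a regular midpoint-rule marker grid, so that the
    unweighted marker average equals the cM-uniform integral up to
    discretization error."""
    import pandas as pd

    import ccqg
    from ccqg.genmap import GeneticMap

    rng = np.random.default_rng(seed)
    frames = []
    k = 0
    for ci, (n, L) in enumerate(zip(n_per_chrom, chr_lengths)):
        cm = (np.arange(n) + 0.5) * (L / n)
        frames.append(
            pd.DataFrame(
                {
                    "marker": [f"m{k + i}" for i in range(n)],
                    "chrom": str(ci + 1),
                    "bp": (cm * 2e6).astype(np.int64) + 1,
                    "cM": cm,
                }
            )
        )
        k += n
    gmap = GeneticMap(
        pd.concat(frames, ignore_index=True),
        {str(i + 1): float(L) for i, L in enumerate(chr_lengths)},
    )
    alleles = (rng.random((8, gmap.n_markers)) < 0.5).astype(np.uint8)
    return ccqg.FounderHaplotypes(gmap, alleles)


def true_sharing_fraction(mos_a, mos_b, step_cm=0.5):
    """Expected founder sharing of two mosaics on a dense cM grid:
    average over the four haplotype pairings."""
    num = 0.0
    den = 0.0
    for chrom, L in mos_a.chrom_lengths.items():
        for pos in np.arange(step_cm / 2, L, step_cm):
            a1, a2 = mos_a.founder_at(chrom, pos)
            b1, b2 = mos_b.founder_at(chrom, pos)
            num += sum(x == y for x in (a1, a2) for y in (b1, b2)) / 4.0
            den += 1
    return num / den
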