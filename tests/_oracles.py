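"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they are used to check: the HWE
oracle enumerates the conditional distribution directly from log-factorial
probabilities, the GRM oracle is a double loop, and the LD oracle computes
all pairwise correlations naively.
"""

import numpy as np
from scipy.special import gammaln


def hwe_enumeration(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact HWE p-value by full enumeration over heterozygote counts.

    P(h | n, n_rare) = C(n; r_hom, h, c_hom) * 2^h / C(2n; n_rare) with
    r_hom = (n_rare - h)/2; p-value sums probabilities <= observed.
    """
    n = n_AA + n_Aa + n_aa
    n_rare = 2 * min(n_AA, n_aa) + n_Aa
    hets = np.arange(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2)
    rare_hom = (n_rare - hets) // 2
    common_hom = n - rare_hom - hets
    logp = (
        gammaln(n + 1)
        - gammaln(rare_hom + 1)
        - gammaln(hets + 1)
        - gammaln(common_hom + 1)
        + hets * np.log(2.0)
        + gammaln(n_rare + 1)
        + gammaln(2 * n - n_rare + 1)
        - gammaln(2 * n + 1)
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    p_obs = probs[hets == n_Aa][0]
    return float(min(probs[probs <= p_obs * (1 + 1e-12)].sum(), 1.0))


def grm_double_loop(dosages: np.ndarray) -> np.ndarray:
    """VanRaden GRM computed entry-by-entry."""
    d = np.asarray(dosages, dtype=float)
    n, m = d.shape
    p = d.mean(axis=0) / 2.0
    keep = (p > 0) & (p < 1)
    d, p = d[:, keep], p[keep]
    c = 2.0 * np.sum(p * (1 - p))
    g = np.zeros((n, n))
    for i in range(n):
        for k in range(n):
            acc = 0.0
            for j in range(d.shape[1]):
                acc += (d[i, j] - 2 * p[j]) * (d[k, j] - 2 * p[j])
            g[i, k] = acc / c
    return g


def ld_all_pairs(dosages: np.ndarray) -> dict[tuple[int, int], float]:
    """r2 for every pair of columns, via np.corrcoef per pair."""
    d = np.asarray(dosages, dtype=float)
    m = d.shape[1]
    out = {}
    for a in range(m):
        for b in range(a + 1, m):
            if d[:, a].std() == 0 or d[:, b].std() == 0:
                continue
            r = np.corrcoef(d[:, a], d[:, b])[0, 1]
            out[(a, b)] = r * r
    return out


def adjacent_r2(dosages: np.ndarray) -> float:
    """Mean r2 between adjacent polymorphic columns."""
    d = np.asarray(dosages, dtype=float)
    vals = []
    for j in range(d.shape[1] - 1):
        if d[:, j].std() == 0 or d[:, j + 1].std() == 0:
            continue
        r = np.corrcoef(d[:, j], d[:, j + 1])[0, 1]
        vals.append(r * r)
    return float(np.mean(vals))
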