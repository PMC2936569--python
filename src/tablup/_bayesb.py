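"""Numba kernel for the BayesB Gibbs / Metropolis-Hastings chain.

Kept separate so the public module stays importable-fast; compilation
happens on first use. The chain is single-threaded and seeded through
numba's internal legacy RNG, so runs are bit-reproducible.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def _log_marginal(r, a, s2, se2):
    # log-likelihood of the record vector corrected for all other
    # effects, with this marker's effect integrated out, dropping terms
    # that do not depend on s2:  y* ~ N(0, z z' s2 + I se2)
    v = se2 + a * s2
    return -0.5 * (np.log(v) - r * r * s2 / (v * se2))


@njit(cache=True)
def bayesb_chain(
    Zt,  # (N, n) float64, marker-major genotype rows
    y,  # (n,) float64
    sigma_e2,
    pi_zero,  # prior probability a marker variance is exactly 0
    df,
    scale,
    n_cycles,
    burn_in,
    n_mh,
    fixed_variance,  # > 0 fixes every marker variance (degenerate mode)
    seed,
):
    np.random.seed(seed)
    N, n = Zt.shape
    a = np.empty(N)
    for k in range(N):
        a[k] = np.dot(Zt[k], Zt[k])

    g = np.zeros(N)
    s2 = np.zeros(N)
    mu = np.mean(y)
    ycorr = y - mu

    g_sum = np.zeros(N)
    s2_sum = np.zeros(N)
    mu_sum = 0.0
    kept = 0

    for cycle in range(n_cycles):
        # overall mean, full conditional N(mu + mean(ycorr), se2/n)
        delta = np.sum(ycorr) / n + np.random.normal() * np.sqrt(sigma_e2 / n)
        mu += delta
        ycorr -= delta

        for k in range(N):
            if a[k] == 0.0:  # monomorphic marker: nothing to estimate
                continue
            r = np.dot(Zt[k], ycorr) + a[k] * g[k]
            if fixed_variance > 0.0:
                s2k = fixed_variance
            else:
                s2k = s2[k]
                llc = _log_marginal(r, a[k], s2k, sigma_e2)
                for _ in range(n_mh):
                    if np.random.random() < pi_zero:
                        prop = 0.0
                        if s2k == 0.0:
                            continue
                    else:
                        prop = df * scale / np.random.chisquare(df)
                    llp = _log_marginal(r, a[k], prop, sigma_e2)
                    diff = llp - llc
                    if diff >= 0.0 or np.random.random() < np.exp(diff):
                        s2k = prop
                        llc = llp
                s2[k] = s2k
            if s2k > 0.0:
                denom = a[k] + sigma_e2 / s2k
                gnew = r / denom + np.random.normal() * np.sqrt(sigma_e2 / denom)
            else:
                gnew = 0.0
            if gnew != g[k]:
                ycorr += Zt[k] * (g[k] - gnew)
                g[k] = gnew

        if cycle >= burn_in:
            g_sum += g
            s2_sum += s2
            mu_sum += mu
            kept += 1

    return g_sum / kept, s2_sum / kept, mu_sum / kept
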