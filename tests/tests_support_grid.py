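"""Shared independent oracle: dense-grid posterior for a 2-source,
single-isotope mixing problem (uniform simplex prior, half-normal residual
SD prior), binned for total-variation comparison with MCMC draws."""

import numpy as np


def grid_marginal(obs, mu, sig_scale, alpha=1.0, bins=40, n_p=400, n_sig=300):
    pg = np.linspace(1e-4, 1 - 1e-4, n_p)
    sg = np.linspace(0.02, 8 * sig_scale, n_sig)
    P, S = np.meshgrid(pg, sg, indexing="ij")
    m = P * mu[0] + (1 - P) * mu[1]
    loglik = sum(-0.5 * ((o - m) / S) ** 2 - np.log(S) for o in obs)
    logprior = (alpha - 1) * (np.log(P) + np.log(1 - P)) - 0.5 * (S / sig_scale) ** 2
    w = np.exp(loglik + logprior - (loglik + logprior).max())
    marg = w.sum(axis=1)
    marg = marg / marg.sum()
    return marg.reshape(bins, -1).sum(axis=1)
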