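"""Independent reference reweighting solver used as a test oracle.

Instead of the package's fixed-point iteration, this maximises the WHAM
log-likelihood over the window free-energy shifts with scipy's BFGS (the
multistate-reweighting estimating equations in their variational form).
Only numpy/scipy are used; nothing is shared with acidassoc.wham beyond the
histogram inputs, so agreement is a genuine dual-route check.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

R_KJ = 8.314e-3


def ml_wham_profile(dataset, bin_width: float, zero_start: float = 10.0):
    """Maximum-likelihood PMF for an acidassoc UmbrellaDataset.

    Returns (bin_centers, W) with W zero-referenced over
    [zero_start, max bin]; unsampled bins carry +inf.
    """
    kt = R_KJ * dataset.temperature
    lo = min(w.samples.min() for w in dataset.windows)
    hi = max(w.samples.max() for w in dataset.windows)
    lo = np.floor(lo / bin_width) * bin_width
    n_bins = int(np.ceil((hi - lo) / bin_width)) + 1
    edges = lo + bin_width * np.arange(n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])

    counts = np.stack([np.histogram(w.samples, bins=edges)[0] for w in dataset.windows])
    u_kt = np.stack(
        [0.5 * w.spring_constant * 4.184 * (centers - w.center) ** 2 / kt
         for w in dataset.windows]
    )
    n_i = counts.sum(axis=1).astype(float)
    m_b = counts.sum(axis=0).astype(float)
    occupied = m_b > 0

    def split(g):
        return np.concatenate([[0.0], g])

    def neg_loglik(g):
        f = split(g)
        lse = logsumexp(f[:, None] - u_kt, b=n_i[:, None], axis=0)
        return -(n_i * f).sum() + (m_b[occupied] * lse[occupied]).sum()

    def grad(g):
        f = split(g)
        log_w = f[:, None] - u_kt
        lse = logsumexp(log_w, b=n_i[:, None], axis=0)
        resp = n_i[:, None] * np.exp(log_w - lse)  # window responsibility per bin
        d = -n_i + (resp[:, occupied] * m_b[occupied]).sum(axis=1)
        return d[1:]

    res = minimize(neg_loglik, np.zeros(len(n_i) - 1), jac=grad,
                   method="BFGS", options={"gtol": 1e-10, "maxiter": 5000})
    f = split(res.x)
    lse = logsumexp(f[:, None] - u_kt, b=n_i[:, None], axis=0)
    with np.errstate(divide="ignore"):
        log_p = np.where(occupied, np.log(m_b, where=occupied) - lse, -np.inf)
    W = -kt * log_p
    zmask = (centers >= zero_start) & np.isfinite(W)
    W = W - W[zmask].mean()
    return centers, W
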