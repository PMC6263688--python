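"""Independent brute-force oracles used by unit and acceptance tests.

These are deliberately slow, transparent implementations that never share
code with the package under test.
"""

from __future__ import annotations

import numpy as np


def otsu_histogram(frame: np.ndarray, nbins: int = 256):
    """Probability histogram and bin centers over the frame's min-max range."""
    frame = np.asarray(frame, dtype=float)
    hist, edges = np.histogram(frame, bins=nbins, range=(frame.min(), frame.max()))
    centers = (edges[:-1] + edges[1:]) / 2.0
    return hist / hist.sum(), centers


def between_class_variance(p: np.ndarray, mu: np.ndarray, cuts) -> float:
    """sum_k w_k m_k^2 over the classes induced by the cut indices."""
    v = 0.0
    for idx in np.split(np.arange(p.size), list(cuts)):
        w = p[idx].sum()
        if w > 0:
            m = (p[idx] * mu[idx]).sum() / w
            v += w * m * m
    return v


def otsu_exhaustive(frame: np.ndarray, n_classes: int, nbins: int = 256):
    """Exhaustive search over all histogram cut tuples.

    Returns (best_cut_indices, best_variance). Only n_classes in {2, 3}.
    """
    p, mu = otsu_histogram(frame, nbins)
    nb = p.size
    best, best_cuts = -1.0, None
    if n_classes == 2:
        combos = ((i,) for i in range(1, nb))
    elif n_classes == 3:
        combos = ((i, j) for i in range(1, nb - 1) for j in range(i + 1, nb))
    else:
        raise ValueError("oracle supports 2 or 3 classes")
    for cuts in combos:
        v = between_class_variance(p, mu, cuts)
        if v > best:
            best, best_cuts = v, cuts
    return best_cuts, best


def dft_argmax(x: np.ndarray, fs: float, f_lo: float, f_hi: float, df: float = 0.005):
    """Brute-force windowed DFT power argmax on a fine frequency grid."""
    x = np.asarray(x, dtype=float)
    x = (x - x.mean()) * np.hamming(x.size)
    t = np.arange(x.size) / fs
    freqs = np.arange(f_lo, f_hi + df / 2, df)
    power = np.empty(freqs.size)
    for i, f in enumerate(freqs):
        c = np.exp(-2j * np.pi * f * t)
        power[i] = np.abs(np.dot(c, x)) ** 2
    return freqs[np.argmax(power)]


def l1_objective_oracle(y, templates, lam):
    """Bound-constrained solve of the full [T, I, -I] l1 problem via L-BFGS-B."""
    from scipy.optimize import minimize

    y = np.asarray(y, dtype=float)
    t = np.asarray(templates, dtype=float)
    m, d = t.shape
    a = np.vstack([t, np.eye(d), -np.eye(d)])  # (m + 2d, d)
    n = a.shape[0]

    def fun(c):
        r = y - c @ a
        return float(r @ r + lam * c.sum()), (-2.0 * (a @ r) + lam)

    res = minimize(
        fun,
        np.zeros(n),
        jac=True,
        method="L-BFGS-B",
        bounds=[(0.0, None)] * n,
        options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-10},
    )
    return float(res.fun)


def agreement_oracle(est, ref):
    """Formula-by-formula recomputation of agreement statistics."""
    est = np.asarray(est, dtype=float)
    ref = np.asarray(ref, dtype=float)
    diff = est - ref
    rel = 100.0 * np.abs(diff) / ref
    bias = diff.mean()
    sd = diff.std(ddof=1)
    num = ((est - est.mean()) * (ref - ref.mean())).sum()
    den = np.sqrt(((est - est.mean()) ** 2).sum() * ((ref - ref.mean()) ** 2).sum())
    return {
        "rmse": np.sqrt((diff**2).mean()),
        "mean_rel": rel.mean(),
        "p90_rel": np.percentile(rel, 90),
        "r": num / den if den > 0 else np.nan,
        "bias": bias,
        "loa_low": bias - 1.96 * sd,
        "loa_high": bias + 1.96 * sd,
    }
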