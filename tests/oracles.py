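"""Independent test oracles, kept free of the package's solver code paths."""

import numpy as np


def brute_force_unmix(i_meas, k_matrix, c_max, n_steps=2001):
    """Exhaustive grid search minimizing the squared intensity residual.

    Two-stage: a full grid of ``n_steps`` per axis over [0, C0], then an
    equally dense refinement within +/- one coarse step of the coarse
    minimizer (pure enumeration both times).  Returns the refined minimizer.
    """
    i_meas = np.asarray(i_meas, dtype=float)
    k = np.asarray(k_matrix, dtype=float)

    def search(lo, hi):
        grids = [np.linspace(lo[d], hi[d], n_steps) for d in range(2)]
        # separable factors: I_w(c1, c2) = 10^(-K[w,0]c1) * 10^(-K[w,1]c2)
        resid = sum(
            (
                np.outer(
                    np.power(10.0, -k[w, 0] * grids[0]),
                    np.power(10.0, -k[w, 1] * grids[1]),
                )
                - i_meas[w]
            )
            ** 2
            for w in range(2)
        )
        i1, i2 = np.unravel_index(np.argmin(resid), resid.shape)
        return np.array([grids[0][i1], grids[1][i2]])

    c_max = np.asarray(c_max, dtype=float)
    step = c_max / (n_steps - 1)
    coarse = search(np.zeros(2), c_max)
    lo = np.clip(coarse - step, 0.0, c_max)
    hi = np.clip(coarse + step, 0.0, c_max)
    return search(lo, hi)
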