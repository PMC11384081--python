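"""Central finite-difference derivatives for standard errors."""

from __future__ import annotations

import numpy as np


def fd_hessian(fun, x, step=1e-3):
    """Symmetric central-difference Hessian of a scalar function.

    ``step`` may be a scalar or per-coordinate array; steps are absolute
    (the callers work on log/logit scales where unit magnitudes are O(1)).
    """
    x = np.asarray(x, dtype=float)
    d = x.size
    h = np.broadcast_to(np.asarray(step, dtype=float), (d,)).copy()
    H = np.empty((d, d))
    f0 = fun(x)
    # diagonal
    for i in range(d):
        e = np.zeros(d)
        e[i] = h[i]
        H[i, i] = (fun(x + e) - 2.0 * f0 + fun(x - e)) / h[i] ** 2
    # off-diagonal
    for i in range(d):
        for j in range(i + 1, d):
            ei = np.zeros(d)
            ej = np.zeros(d)
            ei[i] = h[i]
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                fun(x + ei + ej) - fun(x + ei - ej) - fun(x - ei + ej) + fun(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H
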