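"""The Jones-Taylor-Thornton (1992) amino-acid substitution model.

Published exchangeability counts (lower triangle) and equilibrium
frequencies, in the conventional ARNDCQEGHILKMFPSTWYV residue order.  The
rate matrix is assembled as Q[i,j] = s[i,j] * pi[j], the diagonal set so
rows sum to zero, and the whole matrix scaled so the expected substitution
rate at equilibrium is one, i.e. branch lengths are expected
substitutions per site.
"""

from __future__ import annotations

import numpy as np

PAML_ORDER = "ARNDCQEGHILKMFPSTWYV"

# Lower-triangle exchangeabilities, column-major (column A vs R..V, then
# column R vs N..V, ...).
_JTT_LOWER = [
    58, 54, 81, 56, 57, 105, 179, 27, 36, 30, 35, 54, 15, 194, 378, 475, 9,
    11, 298, 45, 16, 113, 310, 29, 137, 328, 22, 38, 646, 44, 5, 74, 101,
    64, 126, 20, 17, 528, 34, 86, 58, 81, 391, 47, 12, 263, 30, 10, 15,
    503, 232, 8, 70, 16, 10, 49, 767, 130, 112, 11, 7, 26, 15, 4, 15, 59,
    38, 4, 46, 31, 9, 5, 59, 69, 17, 23, 7, 31, 78, 14, 223, 42, 115, 209,
    62, 323, 26, 597, 9, 72, 292, 43, 4, 164, 53, 51, 18, 24, 20, 119, 26,
    12, 9, 181, 18, 5, 18, 30, 32, 10, 7, 45, 23, 6, 6, 27, 14, 5, 24, 201,
    33, 55, 8, 47, 16, 56, 45, 33, 40, 115, 73, 46, 8, 573, 11, 229, 21,
    479, 89, 10, 40, 245, 9, 32, 961, 14, 388, 248, 102, 59, 25, 52, 24,
    180, 65, 4, 21, 47, 103, 10, 8, 14, 43, 16, 29, 226, 24, 18, 323, 17,
    92, 12, 53, 536, 62, 285, 118, 6, 10, 23, 477, 35, 63, 38, 12, 21, 112,
    71, 25, 16,
]

JTT_FREQS_PAML = np.array([
    0.076748, 0.051691, 0.042645, 0.051544, 0.019803, 0.040752, 0.061830,
    0.073152, 0.022944, 0.053761, 0.091904, 0.058676, 0.023826, 0.040126,
    0.050901, 0.068765, 0.058565, 0.014261, 0.032102, 0.066005,
])


def _exchangeabilities() -> np.ndarray:
    s = np.zeros((20, 20))
    it = iter(_JTT_LOWER)
    for j in range(19):
        for i in range(j + 1, 20):
            s[i, j] = s[j, i] = next(it)
    return s


def jtt_matrices(order: str = PAML_ORDER) -> tuple[np.ndarray, np.ndarray]:
    """(Q, pi) in the requested residue order, normalized to rate 1."""
    s = _exchangeabilities()
    pi = JTT_FREQS_PAML.copy()
    pi /= pi.sum()
    q = s * pi[None, :]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    rate = -float(np.sum(pi * np.diag(q)))
    q /= rate
    if order != PAML_ORDER:
        idx = [PAML_ORDER.index(a) for a in order]
        q = q[np.ix_(idx, idx)]
        pi = pi[idx]
    return q, pi


class JttModel:
    """Eigendecomposed JTT model for fast transition matrices P(t)."""

    def __init__(self, order: str = PAML_ORDER):
        self.order = order
        self.q, self.pi = jtt_matrices(order)
        sqrt_pi = np.sqrt(self.pi)
        b = (sqrt_pi[:, None] * self.q) / sqrt_pi[None, :]
        w, v = np.linalg.eigh((b + b.T) / 2)
        self._eigval = w
        self._left = v.T * sqrt_pi[None, :]
        self._right = v / sqrt_pi[:, None]

    def transition(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); rows sum to one."""
        if t < 0:
            raise ValueError("branch length must be non-negative")
        p = (self._right * np.exp(self._eigval * t)[None, :]) @ self._left
        return np.clip(p, 0.0, None)
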