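"""Jones–Taylor–Thornton (JTT) amino-acid substitution model constants.

The lower-triangle exchangeabilities and equilibrium frequencies below are the
published JTT (1992) values in the standard one-letter alphabet order
``ARNDCQEGHILKMFPSTWYV``.  :func:`jtt_rate_matrix` assembles the reversible
rate matrix Q with rows summing to zero and normalises it so that one unit of
time corresponds to one expected substitution per site.
"""

from __future__ import annotations

import numpy as np

AA_ORDER = "ARNDCQEGHILKMFPSTWYV"

# Lower triangle (row i, columns 0..i-1) of the symmetric exchangeability
# matrix, read row by row for i = 1..19.
_JTT_LOWER = [
    58, 54, 81, 56, 57, 105, 179, 27, 36, 30, 35, 54, 15, 194, 378, 475, 9,
    11, 298, 45, 16, 113, 310, 29, 137, 328, 22, 38, 646, 44, 5, 74, 101, 64,
    126, 20, 17, 528, 34, 86, 58, 81, 391, 47, 12, 263, 30, 10, 15, 503, 232,
    8, 70, 16, 10, 49, 767, 130, 112, 11, 7, 26, 15, 4, 15, 59, 38, 4, 46,
    31, 9, 5, 59, 69, 17, 23, 7, 31, 78, 14, 223, 42, 115, 209, 62, 323, 26,
    597, 9, 72, 292, 43, 4, 164, 53, 51, 18, 24, 20, 119, 26, 12, 9, 181, 18,
    5, 18, 30, 32, 10, 7, 45, 23, 6, 6, 27, 14, 5, 24, 201, 33, 55, 8, 47,
    16, 56, 45, 33, 40, 115, 73, 46, 8, 573, 11, 229, 21, 479, 89, 10, 40,
    245, 9, 32, 961, 14, 388, 248, 102, 59, 25, 52, 24, 180, 65, 4, 21, 47,
    103, 10, 8, 14, 43, 16, 29, 226, 24, 18, 323, 17, 92, 12, 53, 536, 62,
    285, 118, 6, 10, 23, 477, 35, 63, 38, 12, 21, 112, 71, 25, 16,
]

JTT_FREQS = np.array([
    0.076748, 0.051691, 0.042645, 0.051544, 0.019803, 0.040752, 0.061830,
    0.073152, 0.022944, 0.053761, 0.091904, 0.058676, 0.023826, 0.040126,
    0.050901, 0.068765, 0.058565, 0.014261, 0.032102, 0.066005,
])
JTT_FREQS = JTT_FREQS / JTT_FREQS.sum()


def jtt_rate_matrix() -> np.ndarray:
    """Return the JTT instantaneous rate matrix, scaled to 1 sub/site/unit time."""
    n = 20
    s = np.zeros((n, n))
    k = 0
    for i in range(1, n):
        for j in range(i):
            s[i, j] = s[j, i] = _JTT_LOWER[k]
            k += 1
    q = s * JTT_FREQS[None, :]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    # normalise: expected rate = -sum_i pi_i q_ii = 1
    rate = -(JTT_FREQS * np.diag(q)).sum()
    return q / rate
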