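"""Jones-Taylor-Thornton (JTT) empirical amino-acid substitution model.

The JTT model is a general time-reversible Markov model over the 20 amino
acids whose exchangeabilities were estimated from a large set of closely
related protein pairs.  The constants below are the published pairwise
substitution counts (lower triangle of the symmetric exchangeability
matrix) and the equilibrium amino-acid frequencies, in the canonical
``ARNDCQEGHILKMFPSTWYV`` residue order.

The instantaneous rate matrix is built as ``Q[i, j] = S[i, j] * pi[j]``
with rows summing to zero, then normalised so that the expected number of
substitutions per site per unit time is one.  Transition probability
matrices ``P(t) = expm(Q t)`` are computed through the eigendecomposition
of the symmetrised rate matrix, which is exact for a reversible model and
much faster than a generic matrix exponential.
"""

from __future__ import annotations

import numpy as np

#: Canonical residue order for all JTT arrays.
AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"

AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

# Lower triangle (row-major, rows 1..19, columns 0..row-1) of the symmetric
# exchangeability matrix: the published JTT pairwise substitution counts.
_JTT_LOWER = [
    58,
    54, 45,
    81, 16, 528,
    56, 113, 34, 10,
    57, 310, 86, 49, 9,
    105, 29, 58, 767, 5, 323,
    179, 137, 81, 130, 59, 26, 119,
    27, 328, 391, 112, 69, 597, 26, 23,
    36, 22, 47, 11, 17, 9, 12, 6, 16,
    30, 38, 12, 7, 23, 72, 9, 6, 56, 229,
    35, 646, 263, 26, 7, 292, 181, 27, 45, 21, 14,
    54, 44, 30, 15, 31, 43, 18, 14, 33, 479, 388, 65,
    15, 5, 10, 4, 78, 4, 5, 5, 40, 89, 248, 4, 43,
    194, 74, 15, 15, 14, 164, 18, 24, 115, 10, 102, 21, 16, 17,
    378, 101, 503, 59, 223, 53, 30, 201, 73, 40, 59, 47, 29, 92, 285,
    475, 64, 232, 38, 42, 51, 32, 33, 46, 245, 25, 103, 226, 12, 118, 477,
    9, 126, 8, 4, 115, 18, 10, 55, 8, 9, 52, 10, 24, 53, 6, 35, 12,
    11, 20, 70, 46, 209, 24, 7, 8, 573, 32, 24, 8, 18, 536, 10, 63, 21, 71,
    298, 17, 16, 31, 62, 20, 45, 47, 11, 961, 180, 14, 323, 62, 23, 38, 112, 25, 16,
]

#: JTT equilibrium amino-acid frequencies (sum to 1).
JTT_FREQUENCIES = np.array([
    0.076748, 0.051691, 0.042645, 0.051544, 0.019803,
    0.040752, 0.061830, 0.073152, 0.022944, 0.053761,
    0.091904, 0.058676, 0.023826, 0.040126, 0.050901,
    0.068765, 0.058565, 0.014261, 0.032102, 0.066005,
])
JTT_FREQUENCIES = JTT_FREQUENCIES / JTT_FREQUENCIES.sum()


def exchangeability_matrix() -> np.ndarray:
    """Symmetric 20x20 JTT exchangeability matrix (zero diagonal)."""
    s = np.zeros((20, 20))
    it = iter(_JTT_LOWER)
    for i in range(1, 20):
        for j in range(i):
            s[i, j] = s[j, i] = next(it)
    return s


def rate_matrix() -> np.ndarray:
    """JTT rate matrix Q normalised to one expected substitution per site.

    Q is reversible with stationary distribution :data:`JTT_FREQUENCIES`;
    rows sum to zero.
    """
    pi = JTT_FREQUENCIES
    q = exchangeability_matrix() * pi[np.newaxis, :]
    np.fill_diagonal(q, -q.sum(axis=1))
    mu = -(pi * np.diag(q)).sum()
    return q / mu


class _Eigensystem:
    """Cached spectral decomposition of the symmetrised JTT rate matrix."""

    def __init__(self) -> None:
        pi = JTT_FREQUENCIES
        q = rate_matrix()
        sqrt_pi = np.sqrt(pi)
        sym = (sqrt_pi[:, None] * q) / sqrt_pi[None, :]
        sym = (sym + sym.T) / 2.0  # guard against round-off asymmetry
        eigval, eigvec = np.linalg.eigh(sym)
        self.eigval = eigval
        self.left = eigvec / sqrt_pi[:, None]     # D^{-1/2} U
        self.right = (eigvec * sqrt_pi[:, None]).T  # U^T D^{1/2}


_EIG = _Eigensystem()


def transition_matrix(t: float) -> np.ndarray:
    """Transition probability matrix P(t) = expm(Q t), rows = ancestral state.

    Parameters
    ----------
    t : float
        Branch length in expected substitutions per site (t >= 0).
    """
    if t < 0:
        raise ValueError(f"branch length must be non-negative, got {t}")
    p = (_EIG.left * np.exp(_EIG.eigval * t)) @ _EIG.right
    np.clip(p, 0.0, None, out=p)
    # renormalise rows: clipping tiny negative round-off perturbs row sums
    p /= p.sum(axis=1, keepdims=True)
    return p
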