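"""WAG amino-acid substitution model.

Empirical exchangeabilities and equilibrium frequencies of Whelan & Goldman
(2001), in PAML amino-acid order (ARNDCQEGHILKMFPSTWYV).  The rate matrix is
normalised so that one unit of time equals one expected substitution per
site; one PAM unit equals 0.01 expected substitutions per site.
"""

from __future__ import annotations

import numpy as np

AA_ORDER = "ARNDCQEGHILKMFPSTWYV"
N_AA = 20

#: expected substitutions per site per PAM unit
SUBS_PER_PAM = 0.01

# Lower triangle of the symmetric exchangeability matrix, column-major:
# (R,A), (N,A), ..., (V,A), (N,R), (Q,R), ... (Whelan & Goldman 2001).
_EXCH_LOWER = np.array([
    0.551571, 0.509848, 0.738998, 1.027040, 0.908598, 1.582850, 1.416720,
    0.316954, 0.193335, 0.397915, 0.906265, 0.893496, 0.210494, 1.438550,
    3.370790, 2.121110, 0.113133, 0.240735, 2.006010, 0.635346, 0.147304,
    0.528191, 3.035500, 0.439157, 0.584665, 2.137150, 0.186979, 0.497671,
    5.351420, 0.683162, 0.102711, 0.679489, 1.224190, 0.554413, 1.163920,
    0.381533, 0.251849, 5.429420, 0.265256, 1.543640, 0.947198, 1.125560,
    3.956290, 0.554236, 0.131528, 3.012010, 0.198221, 0.0961621, 0.195081,
    3.974230, 2.030060, 0.0719167, 1.086000, 0.196246, 0.0302949, 0.616783,
    6.174160, 0.865584, 0.930676, 0.039437, 0.0848047, 0.479855, 0.103754,
    0.0467304, 0.423984, 1.071760, 0.374866, 0.129767, 0.325711, 0.152335,
    0.0988179, 0.021352, 0.306674, 0.248972, 0.170135, 0.384287, 0.0740339,
    0.390482, 0.398020, 0.109404, 1.407660, 0.512984, 0.717070, 0.543833,
    1.002140, 5.469470, 0.330052, 4.294110, 0.113917, 0.869489, 3.894900,
    1.545260, 0.0999208, 0.933372, 1.028870, 0.857928, 0.215737, 0.227710,
    0.301281, 0.567717, 0.570025, 0.127395, 0.154263, 2.584430, 0.315124,
    0.0811339, 0.682355, 0.704939, 0.822765, 0.156557, 0.196303, 0.588731,
    0.249410, 0.0304501, 0.0613037, 0.373558, 0.174100, 0.049931, 0.243570,
    1.341820, 0.225833, 0.336983, 0.103604, 0.187247, 0.138190, 0.499462,
    0.890432, 0.404141, 0.679371, 0.696198, 0.740169, 0.473307, 0.262569,
    3.873440, 0.118358, 3.170970, 0.323832, 4.257460, 1.059470, 0.0999288,
    0.319440, 1.458160, 0.212483, 0.420170, 7.821300, 0.257555, 4.854020,
    2.115170, 0.415844, 0.344739, 0.326622, 0.665309, 0.398618, 1.800340,
    0.934276, 0.088836, 0.556896, 0.967130, 1.386980, 0.137505, 0.133264,
    0.305434, 1.190630, 0.171329, 0.493905, 1.516120, 0.515706, 0.428437,
    2.058450, 0.161444, 0.545931, 0.171903, 1.529640, 6.454280, 0.649892,
    1.613280, 0.795384, 0.139405, 0.216046, 0.314887, 4.378020, 0.523742,
    0.786993, 0.232739, 0.110864, 0.291148, 1.388230, 2.485390, 0.365369,
    0.314730,
])

FREQS = np.array([
    0.0866279, 0.043972, 0.0390894, 0.0570451, 0.0193078, 0.0367281,
    0.0580589, 0.0832518, 0.0244313, 0.048466, 0.086209, 0.0620286,
    0.0195027, 0.0384319, 0.0457631, 0.0695179, 0.0610127, 0.0143859,
    0.0352742, 0.0708956,
])
FREQS = FREQS / FREQS.sum()


def exchangeability_matrix() -> np.ndarray:
    """Symmetric 20x20 exchangeability matrix S (zero diagonal)."""
    s = np.zeros((N_AA, N_AA))
    k = 0
    for j in range(N_AA - 1):
        for i in range(j + 1, N_AA):
            s[i, j] = s[j, i] = _EXCH_LOWER[k]
            k += 1
    return s


def rate_matrix() -> np.ndarray:
    """WAG generator Q with rows summing to zero, normalised to one
    expected substitution per site per unit time."""
    s = exchangeability_matrix()
    q = s * FREQS[np.newaxis, :]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    rate = -np.dot(FREQS, np.diag(q))
    return q / rate


class WagModel:
    """Cached spectral decomposition of the WAG generator.

    Time is measured in expected substitutions per site; helpers accept PAM
    via :data:`SUBS_PER_PAM`.  Because Q is reversible it is similar to a
    symmetric matrix, so transition matrices are computed from a real
    eigendecomposition.
    """

    def __init__(self) -> None:
        self.freqs = FREQS
        self.q = rate_matrix()
        sqrt_pi = np.sqrt(FREQS)
        # reversibility: D^{1/2} Q D^{-1/2} is exactly symmetric
        b = (self.q * sqrt_pi[:, np.newaxis]) / sqrt_pi[np.newaxis, :]
        b = (b + b.T) / 2.0  # symmetric up to round-off
        evals, u = np.linalg.eigh(b)
        self._evals = evals
        self._left = u / sqrt_pi[:, np.newaxis]
        self._right = (u * sqrt_pi[:, np.newaxis]).T

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt) for t in expected substitutions per site."""
        p = (self._left * np.exp(self._evals * t)) @ self._right
        np.clip(p, 1e-300, None, out=p)
        rows = p.sum(axis=1, keepdims=True)
        return p / rows

    def transition_matrices(self, ts: np.ndarray) -> np.ndarray:
        """Stacked P(t) for a vector of times, shape (len(ts), 20, 20)."""
        e = np.exp(np.multiply.outer(ts, self._evals))  # (m, 20)
        p = np.einsum("ae,me,eb->mab", self._left, e, self._right)
        np.clip(p, 1e-300, None, out=p)
        return p / p.sum(axis=2, keepdims=True)


_MODEL: WagModel | None = None


def wag_model() -> WagModel:
    global _MODEL
    if _MODEL is None:
        _MODEL = WagModel()
    return _MODEL
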