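"""The WAG empirical amino-acid substitution model.

Whelan & Goldman's (2001) general reversible rate matrix, estimated from a
large database of globular protein families, is the standard empirical
model for protein phylogenetics. The constants below are the published
exchangeabilities (lower triangle, residue order ARNDCQEGHILKMFPSTWYV) and
equilibrium frequencies; they are identical across the standard
distributions of ``wag.dat``.

The rate matrix Q is assembled as q_ij = s_ij * pi_j, the diagonal set so
rows sum to zero, and the whole matrix scaled so that the expected number
of substitutions per site per unit time is one; distances are therefore in
expected substitutions per site. Transition probabilities P(t) = exp(Qt)
are computed through the symmetric eigendecomposition of
B = diag(sqrt(pi)) Q diag(1/sqrt(pi)), which is numerically stable and
makes repeated evaluations cheap.
"""

from __future__ import annotations

import numpy as np

from .profiles import AA

#: Residue order of the published matrix.
WAG_ORDER = "ARNDCQEGHILKMFPSTWYV"

#: Lower-triangular exchangeabilities s_ij (row-major, i > j).
WAG_EXCHANGEABILITIES = [
    0.551571,
    0.509848, 0.635346,
    0.738998, 0.147304, 5.429420,
    1.027040, 0.528191, 0.265256, 0.030295,
    0.908598, 3.035500, 1.543640, 0.616783, 0.098818,
    1.582850, 0.439157, 0.947198, 6.174160, 0.021352, 5.469470,
    1.416720, 0.584665, 1.125560, 0.865584, 0.306674, 0.330052, 0.567717,
    0.316954, 2.137150, 3.956290, 0.930676, 0.248972, 4.294110, 0.570025,
    0.249410,
    0.193335, 0.186979, 0.554236, 0.039437, 0.170135, 0.113917, 0.127395,
    0.030450, 0.138190,
    0.397915, 0.497671, 0.131528, 0.084805, 0.384287, 0.869489, 0.154263,
    0.061304, 0.499462, 3.170970,
    0.906265, 5.351420, 3.012010, 0.479855, 0.074034, 3.894900, 2.584430,
    0.373558, 0.890432, 0.323832, 0.257555,
    0.893496, 0.683162, 0.198221, 0.103754, 0.390482, 1.545260, 0.315124,
    0.174100, 0.404141, 4.257460, 4.854020, 0.934276,
    0.210494, 0.102711, 0.096162, 0.046730, 0.398020, 0.099921, 0.081134,
    0.049931, 0.679371, 1.059470, 2.115170, 0.088836, 1.190630,
    1.438550, 0.679489, 0.195081, 0.423984, 0.109404, 0.933372, 0.682355,
    0.243570, 0.696198, 0.099929, 0.415844, 0.556896, 0.171329, 0.161444,
    3.370790, 1.224190, 3.974230, 1.071760, 1.407660, 1.028870, 0.704939,
    1.341820, 0.740169, 0.319440, 0.344739, 0.967130, 0.493905, 0.545931,
    1.613280,
    2.121110, 0.554413, 2.030060, 0.374866, 0.512984, 0.857928, 0.822765,
    0.225833, 0.473307, 1.458160, 0.326622, 1.386980, 1.516120, 0.171903,
    0.795384, 4.378020,
    0.113133, 1.163920, 0.071917, 0.129767, 0.717070, 0.215737, 0.156557,
    0.336983, 0.262569, 0.212483, 0.665309, 0.137505, 0.515706, 1.529640,
    0.139405, 0.523742, 0.110864,
    0.240735, 0.381533, 1.086000, 0.325711, 0.543833, 0.227710, 0.196303,
    0.103604, 3.873440, 0.420170, 0.398618, 0.133264, 0.428437, 6.454280,
    0.216046, 0.786993, 0.291148, 2.485390,
    2.006010, 0.251849, 0.196246, 0.152335, 1.002140, 0.301281, 0.588731,
    0.187247, 0.118358, 7.821300, 1.800340, 0.305434, 2.058450, 0.649892,
    0.314887, 0.232739, 1.388230, 0.365369, 0.314730,
]

#: Equilibrium frequencies pi_i (same order).
WAG_FREQUENCIES = [
    0.0866279, 0.0439720, 0.0390894, 0.0570451, 0.0193078, 0.0367281,
    0.0580589, 0.0832518, 0.0244313, 0.0484660, 0.0862090, 0.0620286,
    0.0195027, 0.0384319, 0.0457631, 0.0695179, 0.0610127, 0.0143859,
    0.0352742, 0.0708956,
]


def _reorder(matrix: np.ndarray, freqs: np.ndarray,
             order_from: str, order_to: str) -> tuple[np.ndarray, np.ndarray]:
    idx = [order_from.index(a) for a in order_to]
    return matrix[np.ix_(idx, idx)], freqs[idx]


class WAGModel:
    """WAG rate matrix with cached eigendecomposition.

    All public arrays use the package's canonical residue order
    (:data:`gpcrmine.profiles.AA`).
    """

    def __init__(self) -> None:
        n = 20
        s = np.zeros((n, n))
        k = 0
        for i in range(1, n):
            for j in range(i):
                s[i, j] = s[j, i] = WAG_EXCHANGEABILITIES[k]
                k += 1
        pi = np.array(WAG_FREQUENCIES)
        pi = pi / pi.sum()
        s, pi = _reorder(s, pi, WAG_ORDER, AA)
        q = s * pi[None, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        # normalise to one expected substitution per site per unit time
        scale = -(pi * np.diag(q)).sum()
        q /= scale
        self.pi = pi
        self.q = q
        sqrt_pi = np.sqrt(pi)
        b = (q * sqrt_pi[:, None]) / sqrt_pi[None, :]
        b = (b + b.T) / 2.0  # symmetrise against round-off
        self._eigval, self._eigvec = np.linalg.eigh(b)
        self._left = self._eigvec.T * sqrt_pi[None, :]
        self._right = self._eigvec / sqrt_pi[:, None]

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); rows sum to one."""
        if t < 0:
            raise ValueError("branch length must be >= 0")
        p = (self._right * np.exp(self._eigval * t)[None, :]) @ self._left
        return np.clip(p, 1e-300, None)


_MODEL: WAGModel | None = None


def default_model() -> WAGModel:
    """Shared singleton; the decomposition is computed once per process."""
    global _MODEL
    if _MODEL is None:
        _MODEL = WAGModel()
    return _MODEL
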