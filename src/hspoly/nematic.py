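"""Global (long-range) orientational order of chain systems.

Each chain's long axis is the eigenvector of the smallest eigenvalue of
its inertia tensor (unit masses, center-of-mass-relative coordinates).
The second-order orientational tensor

    Q = (1/N_ch) * sum_i (u_i u_i - delta/3)

is symmetric and traceless; sorting its eigenvalues by decreasing
magnitude, the scalar nematic order parameter is q = (3/2) lambda_1 and
the director n is the corresponding eigenvector.  q -> 1 for a perfect
prolate mesogen (all long axes parallel), q -> -1/2 for a perfect oblate
mesogen (long axes uniformly spread in a plane), q -> 0 for an isotropic
system.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chain_model import Configuration

__all__ = [
    "ChainOrientation",
    "QTensorResult",
    "chain_inertia_tensor",
    "chain_axis",
    "chain_orientations",
    "order_tensor",
    "scalar_order",
    "classify_mesophase",
    "nematic_order",
    "moving_average",
    "Q_PRO",
    "Q_OBL",
    "Q_ISO",
]

#: ideal reference tensors (preferred axis along x)
Q_PRO = np.diag([2.0 / 3.0, -1.0 / 3.0, -1.0 / 3.0])
Q_OBL = np.diag([-1.0 / 3.0, 1.0 / 6.0, 1.0 / 6.0])
Q_ISO = np.zeros((3, 3))

#: classification cutoffs: prolate if q >= PRO_CUT, oblate if q <= OBL_CUT
PRO_CUT = 0.4
OBL_CUT = -0.25


@dataclass(frozen=True)
class ChainOrientation:
    u: np.ndarray  # unit 3-vector, sign-ambiguous


@dataclass(frozen=True)
class QTensorResult:
    Q: np.ndarray
    eigenvalues: np.ndarray   # ordered by decreasing |lambda|
    q: float
    director: np.ndarray
    label: str                # ISO | PRO | OBL
    biaxiality: float         # |lambda_2 - lambda_3| diagnostic


def chain_inertia_tensor(coords: np.ndarray, masses=None) -> np.ndarray:
    """Inertia tensor of one chain about its center of mass.

    Uses relative coordinates ``x_i - x_cm`` in both the scalar and the
    dyadic term, which is the translation-invariant form whose principal
    axes are the chain's own:

        I = sum_i m_i * (|x_i - x_cm|^2 delta - (x_i - x_cm)(x_i - x_cm))

    ``coords`` must be unwrapped; masses default to 1.
    """
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    if len(coords) < 2:
        raise ValueError("need at least 2 monomers")
    m = np.ones(len(coords)) if masses is None else np.asarray(masses, float)
    cm = np.average(coords, axis=0, weights=m)
    rel = coords - cm
    if np.allclose(rel, 0.0):
        raise ValueError("degenerate chain: all monomers coincident")
    r2 = np.einsum("ij,ij->i", rel, rel)
    return np.einsum("i,i->", m, r2) * np.eye(3) - np.einsum("i,ij,ik->jk", m, rel, rel)


def chain_axis(inertia: np.ndarray) -> ChainOrientation:
    """Unit eigenvector of the smallest inertia eigenvalue (the long axis).

    Deterministic choices: `eigh` ascending order (smallest eigenvalue
    first); the sign is fixed so that the largest-magnitude component of
    u is positive.
    """
    w, v = np.linalg.eigh(np.asarray(inertia, dtype=float))
    u = v[:, 0]
    u = u / np.linalg.norm(u)
    k = int(np.argmax(np.abs(u)))
    if u[k] < 0:
        u = -u
    return ChainOrientation(u=u)


def chain_orientations(config: Configuration) -> np.ndarray:
    """(N_ch, 3) array of chain long axes from unwrapped coordinates."""
    return np.array([chain_axis(chain_inertia_tensor(c)).u for c in config.chains])


def order_tensor(orientations: np.ndarray) -> np.ndarray:
    """Q tensor averaged over chain axes; invariant under u -> -u."""
    u = np.asarray(orientations, dtype=float).reshape(-1, 3)
    if len(u) == 0:
        raise ValueError("need at least one orientation")
    u = u / np.linalg.norm(u, axis=1, keepdims=True)
    Q = np.einsum("ij,ik->jk", u, u) / len(u) - np.eye(3) / 3.0
    return Q


def scalar_order(Q: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Scalar order parameter, director and |.|-ordered eigenvalues of Q.

    Eigenvalues are sorted by decreasing magnitude (ties broken by signed
    value descending); q = (3/2) lambda_1 and the director is the
    eigenvector of lambda_1 with its largest-magnitude component positive.
    """
    Q = np.asarray(Q, dtype=float)
    w, v = np.linalg.eigh(Q)
    order = sorted(range(3), key=lambda i: (-abs(w[i]), -w[i]))
    w = w[order]
    v = v[:, order]
    n = v[:, 0]
    k = int(np.argmax(np.abs(n)))
    if n[k] < 0:
        n = -n
    return 1.5 * w[0], n, w


def classify_mesophase(q_avg: float, pro_cut: float = PRO_CUT,
                       obl_cut: float = OBL_CUT) -> str:
    """ISO / PRO / OBL label from the (averaged) scalar order parameter."""
    if q_avg >= pro_cut:
        return "PRO"
    if q_avg <= obl_cut:
        return "OBL"
    return "ISO"


def nematic_order(config: Configuration) -> QTensorResult:
    """Full Q-tensor analysis of one configuration."""
    Q = order_tensor(chain_orientations(config))
    q, n, w = scalar_order(Q)
    return QTensorResult(Q=Q, eigenvalues=w, q=q, director=n,
                         label=classify_mesophase(q),
                         biaxiality=abs(w[1] - w[2]))


def moving_average(series, alpha: float) -> np.ndarray:
    """Exponential moving average: s_t = alpha x_t + (1 - alpha) s_{t-1}."""
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("empty series")
    if not (0.0 < alpha <= 1.0):
        raise ValueError("alpha must be in (0, 1]")
    out = np.empty_like(x)
    out[0] = x[0]
    for t in range(1, len(x)):
        out[t] = alpha * x[t] + (1.0 - alpha) * out[t - 1]
    return out
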