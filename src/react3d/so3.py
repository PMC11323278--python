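"""Real spherical harmonics and SO(3) representation machinery.

Conventions
-----------
* degree ``l = 0``: the constant 1 (one component);
* degree ``l = 1``: components ordered ``(x, y, z)``, so the Wigner-D matrix
  at ``l = 1`` is the rotation matrix itself;
* degree ``l = 2``: components ordered ``(xy, yz, 3z^2 - r^2, xz, x^2 - y^2)``.

"Component" normalization is used throughout: each harmonic has unit mean
square over the unit sphere, so that feature magnitudes are comparable
across degrees.

The coupling tensors ``w3j(l1, l2, l3)`` (real Clebsch–Gordan intertwiners)
are obtained numerically as the one-dimensional null space of the
equivariance constraint ``D3(R) T = T (D1(R) ⊗ D2(R))`` stacked over a few
fixed generic rotations, normalized to unit Frobenius norm with a
deterministic sign.  For valid degree triples this intertwiner is unique up
to scale, which fixes the tensor completely.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

__all__ = ["sph_harm", "wigner_d", "w3j", "random_rotation", "dim"]


def dim(l: int) -> int:
    return 2 * l + 1


def sph_harm(vectors: np.ndarray, l: int) -> np.ndarray:
    """Evaluate the real spherical harmonics of degree ``l``.

    Parameters
    ----------
    vectors : (..., 3) array of nonzero vectors (normalized internally).
    l : degree, 0 <= l <= 2.

    Returns
    -------
    (..., 2l+1) array.
    """
    v = np.asarray(vectors, dtype=np.float64)
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    if np.any(n < 1e-12):
        raise ValueError("zero-length vector passed to sph_harm "
                         "(coincident atoms?)")
    u = v / n
    x, y, z = u[..., 0], u[..., 1], u[..., 2]
    if l == 0:
        return np.ones(u.shape[:-1] + (1,))
    if l == 1:
        return np.sqrt(3.0) * u
    if l == 2:
        s15 = np.sqrt(15.0)
        return np.stack(
            [
                s15 * x * y,
                s15 * y * z,
                np.sqrt(5.0) / 2.0 * (3.0 * z * z - 1.0),
                s15 * x * z,
                s15 / 2.0 * (x * x - y * y),
            ],
            axis=-1,
        )
    raise ValueError(f"degree l={l} not supported (max 2)")


# fixed generic unit vectors used to solve for Wigner-D matrices
_PROBE = np.array(
    [
        [0.267, 0.535, 0.802],
        [0.922, -0.131, 0.364],
        [-0.477, 0.823, -0.308],
        [0.186, -0.655, 0.733],
        [-0.724, -0.332, 0.604],
        [0.555, 0.712, -0.430],
        [-0.111, 0.445, 0.889],
        [0.814, 0.377, -0.442],
    ]
)
_PROBE = _PROBE / np.linalg.norm(_PROBE, axis=1, keepdims=True)


def wigner_d(l: int, R: np.ndarray) -> np.ndarray:
    """Wigner-D matrix of a rotation ``R`` in the real basis of degree ``l``.

    Satisfies ``Y_l(R v) = D_l(R) Y_l(v)`` with this module's component
    ordering.
    """
    R = np.asarray(R, dtype=np.float64)
    if l == 0:
        return np.ones((1, 1))
    if l == 1:
        return R.copy()
    if l == 2:
        A = sph_harm(_PROBE, 2)            # (8, 5)
        B = sph_harm(_PROBE @ R.T, 2)      # (8, 5): rows Y(R v_i)
        # B = A @ D^T  =>  D^T = lstsq(A, B)
        Dt, *_ = np.linalg.lstsq(A, B, rcond=None)
        return Dt.T
    raise ValueError(f"degree l={l} not supported (max 2)")


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """A Haar-random proper rotation matrix."""
    M = rng.normal(size=(3, 3))
    Q, Rr = np.linalg.qr(M)
    Q = Q * np.sign(np.diag(Rr))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


@lru_cache(maxsize=None)
def w3j(l1: int, l2: int, l3: int) -> np.ndarray:
    """Real coupling tensor C with shape (2l3+1, 2l1+1, 2l2+1).

    The returned tensor satisfies, for every rotation R,
    ``D3 C = C (D1 ⊗ D2)`` when contracted as ``C[k, i, j]``, i.e.
    ``sum_ij C[k,i,j] a_i b_j`` transforms as degree l3 when a, b transform
    as degrees l1, l2.  Unit Frobenius norm; first component of magnitude
    above 1e-8 is positive.
    """
    if not (abs(l1 - l2) <= l3 <= l1 + l2):
        raise ValueError(f"degree triple ({l1},{l2},{l3}) violates the "
                         "triangle inequality")
    d1, d2, d3 = dim(l1), dim(l2), dim(l3)
    rng = np.random.default_rng(20240715)
    rows = []
    for _ in range(3):
        R = random_rotation(rng)
        D1, D2, D3 = wigner_d(l1, R), wigner_d(l2, R), wigner_d(l3, R)
        K = np.kron(D1, D2)  # acts on flattened (i, j)
        # constraint on T (d3, d1*d2):  D3 T - T K = 0
        rows.append(np.kron(D3, np.eye(d1 * d2)) - np.kron(np.eye(d3), K.T))
    M = np.concatenate(rows, axis=0)
    _, s, Vt = np.linalg.svd(M)
    null_mask = s < 1e-8 * s[0]
    n_null = int(null_mask.sum()) + (Vt.shape[0] < M.shape[1])
    if n_null != 1:
        # tolerate numerically tiny singular values at the tail
        tail = s[-1]
        if tail > 1e-8 * s[0] or (len(s) > 1 and s[-2] < 1e-8 * s[0]):
            raise RuntimeError(
                f"intertwiner for ({l1},{l2},{l3}) is not one-dimensional")
    t = Vt[-1]
    t = t / np.linalg.norm(t)
    for c in t:
        if abs(c) > 1e-8:
            if c < 0:
                t = -t
            break
    C = t.reshape(d3, d1, d2)
    C.setflags(write=False)
    return C
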