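"""Small shared numerical helpers."""

from __future__ import annotations

import numpy as np

#: eigenvalue floor used when projecting to the nearest correlation matrix
EIG_FLOOR = 1e-6


def child_seeds(master_seed: int, n: int) -> list[int]:
    """Derive ``n`` independent 31-bit stage seeds from one master seed.

    Uses numpy's SeedSequence spawning so that stages are decoupled:
    changing how many seeds one stage consumes never shifts another
    stage's stream.
    """
    ss = np.random.SeedSequence(int(master_seed))
    return [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n)]


def nearest_correlation(mat: np.ndarray, eig_floor: float = EIG_FLOOR) -> np.ndarray:
    """Project a symmetric matrix to a valid correlation matrix.

    Symmetrizes, clips eigenvalues from below at ``eig_floor``, then
    rescales to unit diagonal. A single clip-and-rescale pass is enough
    for the mild perturbations used here; the result is symmetric
    positive definite with ones on the diagonal.
    """
    a = np.asarray(mat, dtype=float)
    a = (a + a.T) / 2.0
    w, v = np.linalg.eigh(a)
    w = np.clip(w, eig_floor, None)
    a = (v * w) @ v.T
    d = np.sqrt(np.diag(a))
    a = a / np.outer(d, d)
    np.fill_diagonal(a, 1.0)
    return (a + a.T) / 2.0


def validate_correlation_matrix(mat: np.ndarray) -> np.ndarray:
    """Check that ``mat`` is a symmetric PD correlation matrix; return it.

    Raises ValueError on asymmetry, off-unit diagonal, off-diagonal
    entries outside [-1, 1], or failure of positive definiteness.
    """
    a = np.asarray(mat, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(a), 1.0, atol=1e-10):
        raise ValueError("correlation matrix must have unit diagonal")
    off = a[~np.eye(a.shape[0], dtype=bool)]
    if off.size and (np.abs(off) > 1.0 + 1e-12).any():
        raise ValueError("correlation entries must lie in [-1, 1]")
    try:
        np.linalg.cholesky(a)
    except np.linalg.LinAlgError as exc:
        raise ValueError("correlation matrix must be positive definite") from exc
    return a
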