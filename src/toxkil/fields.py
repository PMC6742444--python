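"""Quasi-steady-state concentration fields on the periodic lattice.

Both secreted molecules (the density cue and the toxin) obey a
production--degradation--diffusion balance.  Because molecular dynamics
are assumed much faster than the birth--death dynamics of the cells, the
concentration grid is recomputed from the *current* production pattern at
every time step by solving the discrete steady state

    P[i,j] - d*c[i,j] - 4*D*c[i,j]
           + D*(c[i-1,j] + c[i+1,j] + c[i,j-1] + c[i,j+1]) = 0,

with all indices modulo N.  Writing the left-hand side as a circular
convolution ``c (*) G = -P`` with the degradation--diffusion kernel G
(``-4D - d`` at the origin, ``D`` at the four orthogonal neighbours), the
solution is obtained by elementwise division in Fourier space:
``F(c) = -F(P) / F(G)``.  The kernel transform depends only on
``(N, d, D)`` and is cached across calls.

A dense direct solver over the explicit N^2 x N^2 linear system is
provided as an independent cross-check for small lattices.
"""

from __future__ import annotations

import numpy as np
from numpy.fft import irfft2, rfft2
from scipy.sparse import csr_matrix
from scipy.sparse.linalg import spsolve

__all__ = [
    "build_kernel",
    "solve_steady_state",
    "solve_steady_state_dense_oracle",
    "production_grids",
    "add_cue_noise",
    "clear_kernel_cache",
]

#: residual tolerance of the Fourier solve, relative to max(1, max P)
RESIDUAL_TOL = 1e-8


class FieldError(ValueError):
    pass


def _check_rates(N: int, d: float, D: float) -> None:
    if N < 3:
        raise FieldError(
            f"lattice side must be >= 3 so the four neighbour offsets are "
            f"distinct (got N = {N})"
        )
    if d <= 0:
        raise FieldError(f"degradation rate must be > 0, got {d}")
    if D < 0:
        raise FieldError(f"diffusion rate must be >= 0, got {D}")


def build_kernel(N: int, d: float, D: float) -> np.ndarray:
    """Degradation--diffusion kernel: ``-4D - d`` at the origin, ``D`` at
    the four orthogonal neighbours (periodic wrap), zero elsewhere.

    The entries sum to ``-d``.
    """
    _check_rates(N, d, D)
    G = np.zeros((N, N))
    G[0, 0] = -4.0 * D - d
    G[1, 0] = G[-1, 0] = G[0, 1] = G[0, -1] = D
    return G


# (N, d, D) -> rfft2 of the kernel
_kernel_fft_cache: dict[tuple[int, float, float], np.ndarray] = {}


def clear_kernel_cache() -> None:
    _kernel_fft_cache.clear()


def _kernel_fft(N: int, d: float, D: float) -> np.ndarray:
    key = (N, float(d), float(D))
    FG = _kernel_fft_cache.get(key)
    if FG is None:
        FG = rfft2(build_kernel(N, d, D))
        if np.any(FG == 0):  # cannot occur for d > 0
            raise FieldError("singular degradation-diffusion operator")
        _kernel_fft_cache[key] = FG
    return FG


def solve_steady_state(P: np.ndarray, d: float, D: float) -> np.ndarray:
    """Solve the periodic steady state for production grid ``P``.

    Returns the concentration grid ``c`` with ``F(c) = F(-P)/F(G)``.
    For ``P >= 0`` the result is nonnegative (up to rounding) and bounded
    by ``max(P)/d``.
    """
    P = np.asarray(P, dtype=float)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise FieldError(f"production grid must be square, got {P.shape}")
    N = P.shape[0]
    FG = _kernel_fft(N, d, D)
    c = irfft2(rfft2(-P) / FG, s=P.shape)
    return c


def solve_steady_state_dense_oracle(
    P: np.ndarray, d: float, D: float
) -> np.ndarray:
    """Direct sparse-elimination solve of the explicit linear system.

    Independent of the Fourier path; limited to ``N <= 32`` (the system
    matrix has N^2 rows).  Use :func:`solve_steady_state` for larger
    lattices.
    """
    P = np.asarray(P, dtype=float)
    N = P.shape[0]
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise FieldError(f"production grid must be square, got {P.shape}")
    if N > 32:
        raise FieldError(
            f"dense oracle limited to N <= 32 (got {N}); "
            "use solve_steady_state for larger lattices"
        )
    _check_rates(N, d, D)
    idx = np.arange(N * N).reshape(N, N)
    rows, cols, vals = [], [], []
    centre = idx.ravel()
    rows.append(centre)
    cols.append(centre)
    vals.append(np.full(N * N, -4.0 * D - d))
    for shift in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        rows.append(centre)
        cols.append(np.roll(idx, shift, axis=(0, 1)).ravel())
        vals.append(np.full(N * N, D))
    A = csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(N * N, N * N),
    )
    c = spsolve(A, -P.ravel())
    return c.reshape(N, N)


def residual(c: np.ndarray, P: np.ndarray, d: float, D: float) -> float:
    """Max absolute defect of the steady-state balance at any site."""
    lap = (
        np.roll(c, 1, axis=0)
        + np.roll(c, -1, axis=0)
        + np.roll(c, 1, axis=1)
        + np.roll(c, -1, axis=1)
        - 4.0 * c
    )
    return float(np.max(np.abs(P - d * c + D * lap)))


def production_grids(lattice, raw) -> tuple[np.ndarray, np.ndarray]:
    """Cue and toxin production grids for the current lattice state.

    Every occupied site produces cue at rate ``p_cue``.  Sites whose cell
    currently expresses toxin production (phenotype ``phi_T = 1``) produce
    toxin at ``pi_T * d_tox * tox_production_scale``, so that under the
    default normalisation a fully producing lattice reaches toxin
    concentration ``pi_T``.
    """
    occ = lattice.occupied
    if lattice.phi_t.shape != occ.shape:
        raise FieldError("phenotype grid shape mismatch")
    cue = occ * raw.p_cue
    tox_rate = raw.d_tox * raw.tox_production_scale
    tox = (occ & lattice.phi_t) * (lattice.pi_t * tox_rate)
    return cue, tox


def add_cue_noise(
    field: np.ndarray, sigma_noise: float, rng: np.random.Generator
) -> np.ndarray:
    """Add i.i.d. Gaussian noise per site and clamp at zero.

    Negative concentrations are physically meaningless and would turn the
    toxin death term into a survival bonus, so noisy values are clipped at
    0.  ``sigma_noise = 0`` returns the input unchanged.
    """
    if sigma_noise < 0:
        raise FieldError(f"sigma_noise must be >= 0, got {sigma_noise}")
    if sigma_noise == 0:
        return field
    noisy = field + rng.normal(0.0, sigma_noise, size=field.shape)
    return np.clip(noisy, 0.0, None)
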