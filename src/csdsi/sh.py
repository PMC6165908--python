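"""Real symmetric spherical harmonics (even orders only).

The basis is the standard real SH used for antipodally-symmetric spherical
functions in diffusion MRI: for m > 0 sqrt(2) * (-1)^m * Re(Y_l^m), for
m < 0 sqrt(2) * (-1)^m * Im(Y_l^|m|), Y_l^0 for m = 0; only even l, so
antipodal symmetry holds by construction.  Orthonormal on the sphere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import sph_harm_y

__all__ = ["sh_index_pairs", "real_sym_sh_basis", "fit_sh",
           "SphericalHarmonicFunction"]


def sh_index_pairs(order: int) -> list[tuple[int, int]]:
    """(l, m) pairs for even l up to ``order``, m = -l..l."""
    return [(l, m) for l in range(0, order + 1, 2) for m in range(-l, l + 1)]


def real_sym_sh_basis(order: int, directions: np.ndarray) -> np.ndarray:
    """Design matrix (n_dirs, n_coeffs) of the real symmetric SH basis."""
    d = np.asarray(directions, dtype=float)
    d = d / np.linalg.norm(d, axis=1, keepdims=True)
    theta = np.arccos(np.clip(d[:, 2], -1.0, 1.0))  # polar
    phi = np.arctan2(d[:, 1], d[:, 0])              # azimuth
    cols = []
    for l, m in sh_index_pairs(order):
        y = sph_harm_y(l, abs(m), theta, phi)
        if m > 0:
            cols.append(np.sqrt(2.0) * (-1.0) ** m * y.real)
        elif m < 0:
            cols.append(np.sqrt(2.0) * (-1.0) ** m * y.imag)
        else:
            cols.append(y.real)
    return np.stack(cols, axis=1)


@dataclass
class SphericalHarmonicFunction:
    """Even-order real SH coefficient vector, indexed by sh_index_pairs."""

    coeffs: np.ndarray
    order: int

    def __post_init__(self) -> None:
        expected = len(sh_index_pairs(self.order))
        if len(self.coeffs) != expected:
            raise ValueError(
                f"order {self.order} needs {expected} coefficients, "
                f"got {len(self.coeffs)}")
        self.coeffs = np.asarray(self.coeffs, dtype=float)

    def evaluate(self, directions: np.ndarray) -> np.ndarray:
        return real_sym_sh_basis(self.order, directions) @ self.coeffs

    def anisotropic_part(self) -> np.ndarray:
        """Coefficients with the l=0 (isotropic mean) term removed."""
        mask = np.array([l > 0 for l, _ in sh_index_pairs(self.order)])
        return self.coeffs[mask]


def fit_sh(directions: np.ndarray, values: np.ndarray,
           order: int = 8) -> SphericalHarmonicFunction:
    """Least-squares even-order SH fit of samples on the sphere."""
    B = real_sym_sh_basis(order, directions)
    coeffs, *_ = np.linalg.lstsq(B, np.asarray(values, dtype=float), rcond=None)
    return SphericalHarmonicFunction(coeffs=coeffs, order=order)
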