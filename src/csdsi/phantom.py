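"""Multi-tensor diffusion phantoms with known ground truth.

Synthetic voxels are mixtures of Gaussian diffusion compartments
(axially-symmetric tensors for fiber bundles, an isotropic tensor for
CSF-like regions) with optional Rician noise — the magnitude-MRI noise
model, with sigma defined at S0 so SNR = S0/sigma.  What the phantoms do
NOT emulate: susceptibility or eddy-current distortion, subject motion,
spatially-correlated noise, partial-volume geometry beyond block regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .qspace import SamplingScheme

__all__ = [
    "Compartment",
    "PhantomConfig",
    "GroundTruth",
    "tensor_from_eigen",
    "fa_from_eigenvalues",
    "simulate_voxel_signal",
    "make_phantom_volume",
    "trt_replicates",
]

# standard healthy white-matter eigenvalues; CSF-like free diffusivity
FIBER_EIGS = (1.7e-3, 0.3e-3, 0.3e-3)  # mm^2/s
CSF_DIFFUSIVITY = 3.0e-3  # mm^2/s


def tensor_from_eigen(direction: Sequence[float],
                      eigenvalues: Sequence[float]) -> np.ndarray:
    """3x3 diffusion tensor with principal axis ``direction``."""
    e1 = np.asarray(direction, dtype=float)
    e1 = e1 / np.linalg.norm(e1)
    # any orthonormal completion; the two radial eigenvalues may differ
    helper = np.array([1.0, 0.0, 0.0]) if abs(e1[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e2 = np.cross(e1, helper)
    e2 /= np.linalg.norm(e2)
    e3 = np.cross(e1, e2)
    lam = np.asarray(eigenvalues, dtype=float)
    V = np.stack([e1, e2, e3], axis=1)
    return V @ np.diag(lam) @ V.T


def fa_from_eigenvalues(eigenvalues: Sequence[float]) -> float:
    """Fractional anisotropy from tensor eigenvalues (closed form)."""
    lam = np.asarray(eigenvalues, dtype=float)
    md = lam.mean()
    num = np.sum((lam - md) ** 2)
    den = np.sum(lam**2)
    if den == 0:
        return 0.0
    return float(np.sqrt(1.5 * num / den))


@dataclass
class Compartment:
    direction: np.ndarray
    fraction: float
    eigenvalues: tuple[float, float, float] = FIBER_EIGS

    def __post_init__(self) -> None:
        self.direction = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(self.direction)
        if n == 0:
            raise ValueError("compartment direction must be nonzero")
        self.direction = self.direction / n
        lam = self.eigenvalues
        if any(l <= 0 for l in lam):
            raise ValueError("eigenvalues must be positive")
        if lam[0] < max(lam[1], lam[2]):
            raise ValueError("axial eigenvalue must be >= radial eigenvalues")

    @property
    def tensor(self) -> np.ndarray:
        return tensor_from_eigen(self.direction, self.eigenvalues)


def isotropic_compartment(fraction: float = 1.0,
                          diffusivity: float = CSF_DIFFUSIVITY) -> Compartment:
    return Compartment(direction=np.array([1.0, 0.0, 0.0]), fraction=fraction,
                       eigenvalues=(diffusivity, diffusivity, diffusivity))


@dataclass
class PhantomConfig:
    """Multi-tensor voxel specification with noise level and seed."""

    compartments: list[Compartment]
    S0: float = 1.0
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(c.fraction for c in self.compartments)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"compartment fractions sum to {total}, not 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    @property
    def tensors(self) -> list[np.ndarray]:
        return [c.tensor for c in self.compartments]

    @property
    def fractions(self) -> np.ndarray:
        return np.array([c.fraction for c in self.compartments])


@dataclass
class GroundTruth:
    """Closed-form truth for a phantom voxel or per-region maps."""

    directions: np.ndarray
    fractions: np.ndarray
    eigenvalues: np.ndarray  # (n_comp, 3)
    fa: float
    md: float
    ad: float
    rd: float

    @classmethod
    def from_config(cls, config: PhantomConfig) -> "GroundTruth":
        # Gaussian-average tensor of the mixture: D_bar = sum f_i D_i.
        # Its eigen-derived FA/MD/AD/RD is the truth a tensor fit at b->0
        # converges to.
        D = sum(f * T for f, T in zip(config.fractions, config.tensors))
        lam = np.sort(np.linalg.eigvalsh(D))[::-1]
        return cls(
            directions=np.array([c.direction for c in config.compartments]),
            fractions=config.fractions,
            eigenvalues=np.array([c.eigenvalues for c in config.compartments]),
            fa=fa_from_eigenvalues(lam),
            md=float(lam.mean()),
            ad=float(lam[0]),
            rd=float((lam[1] + lam[2]) / 2),
        )

    def apparent_diffusivity(self, g: np.ndarray) -> float:
        """Mixture-averaged apparent diffusivity along unit direction g."""
        ds = [g @ tensor_from_eigen(d, e) @ g
              for d, e in zip(self.directions, self.eigenvalues)]
        return float(np.dot(self.fractions, ds))

    def apparent_kurtosis(self, g: np.ndarray) -> float:
        """Directional kurtosis 3 Var(D_g)/E[D_g]^2 of the mixture."""
        ds = np.array([g @ tensor_from_eigen(d, e) @ g
                       for d, e in zip(self.directions, self.eigenvalues)])
        mean = float(np.dot(self.fractions, ds))
        var = float(np.dot(self.fractions, (ds - mean) ** 2))
        return 3.0 * var / mean**2


def noise_free_attenuation(config: PhantomConfig, bvals: np.ndarray,
                           bvecs: np.ndarray) -> np.ndarray:
    """E(g, b) = sum_i f_i exp(-b g^T D_i g)."""
    E = np.zeros(len(bvals))
    for c in config.compartments:
        D = c.tensor
        quad = np.einsum("ij,jk,ik->i", bvecs, D, bvecs)
        E += c.fraction * np.exp(-bvals * quad)
    return E


def add_rician_noise(signal: np.ndarray, sigma: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Magnitude of the complex signal with i.i.d. Gaussian channel noise."""
    n1 = rng.normal(0.0, sigma, size=signal.shape)
    n2 = rng.normal(0.0, sigma, size=signal.shape)
    return np.sqrt((signal + n1) ** 2 + n2**2)


def simulate_voxel_signal(config: PhantomConfig, scheme: SamplingScheme,
                          noise: bool = False,
                          rng: np.random.Generator | None = None) -> np.ndarray:
    """Simulate one signal value per scheme entry (b=0 entries give S0)."""
    bvals = scheme.bvals
    bvecs = scheme.bvecs
    E = noise_free_attenuation(config, bvals, bvecs)
    S = config.S0 * E
    if noise and config.noise_sigma > 0:
        if rng is None:
            rng = np.random.default_rng(config.seed)
        S = add_rician_noise(S, config.noise_sigma, rng)
    return S


@dataclass
class RegionSpec:
    """A labelled block of voxels sharing one PhantomConfig."""

    name: str
    slices: tuple[slice, slice, slice]
    config: PhantomConfig


def make_phantom_volume(layout: Sequence[RegionSpec], scheme: SamplingScheme,
                        shape: tuple[int, int, int], seed: int = 0,
                        noise: bool = False):
    """Assemble a 4D phantom volume plus per-voxel ground-truth maps.

    Returns ``(data, labels, truth)``: data is (x, y, z, n_entries) in
    scheme order, labels an integer region map (0 = background), truth a
    dict of region name -> GroundTruth.  Regions must not overlap.
    """
    labels = np.zeros(shape, dtype=int)
    for i, region in enumerate(layout, start=1):
        block = labels[region.slices]
        if np.any(block != 0):
            raise ValueError(f"region '{region.name}' overlaps a previous region")
        labels[region.slices] = i

    data = np.zeros(shape + (len(scheme),))
    rng = np.random.default_rng(seed)
    truth: dict[str, GroundTruth] = {}
    for i, region in enumerate(layout, start=1):
        clean = simulate_voxel_signal(region.config, scheme, noise=False)
        mask = labels == i
        data[mask] = clean
        if noise and region.config.noise_sigma > 0:
            noisy = add_rician_noise(
                np.broadcast_to(clean, (int(mask.sum()), len(scheme))).copy(),
                region.config.noise_sigma, rng)
            data[mask] = noisy
        truth[region.name] = GroundTruth.from_config(region.config)
    return data, labels, truth


@dataclass
class TRTDataset:
    """Paired scan/rescan parameter samples with generating variances."""

    scan: np.ndarray     # (n_subjects,)
    rescan: np.ndarray
    mu: float
    sigma_between: float
    sigma_within: float

    @property
    def true_icc(self) -> float:
        b2, w2 = self.sigma_between**2, self.sigma_within**2
        return b2 / (b2 + w2) if (b2 + w2) > 0 else 1.0

    @property
    def true_wscv(self) -> float:
        return self.sigma_within / self.mu * 100.0


def trt_replicates(mu: float, sigma_between: float, sigma_within: float,
                   n_subjects: int = 5, seed: int = 0) -> TRTDataset:
    """Simulate a test-retest study under the one-way random-effects model.

    Each subject draws a latent level mu + N(0, sigma_between^2); scan and
    rescan add independent N(0, sigma_within^2) measurement noise.  The
    generating variance components are returned so reliability statistics
    can be validated against their closed forms.  The default n_subjects=5
    mirrors a small same-day rescan subgroup.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    if min(sigma_between, sigma_within) < 0:
        raise ValueError("variance components must be >= 0")
    rng = np.random.default_rng(seed)
    level = mu + rng.normal(0.0, sigma_between, size=n_subjects)
    scan = level + rng.normal(0.0, sigma_within, size=n_subjects)
    rescan = level + rng.normal(0.0, sigma_within, size=n_subjects)
    if sigma_within == 0:
        rescan = scan.copy()
    return TRTDataset(scan=scan, rescan=rescan, mu=mu,
                      sigma_between=sigma_between, sigma_within=sigma_within)
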