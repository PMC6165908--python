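"""Q-space sampling schemes for diffusion MRI.

Diffusion spectrum imaging (DSI) samples q-space on a Cartesian lattice
truncated to a sphere; the diffusion-weighting b-value grows with the
squared lattice radius.  Compressed-sensing DSI (CS-DSI) measures only a
subset of the lattice and recovers the rest by l1-regularized
reconstruction.  Multi-shell (HARDI) protocols instead place directions
on a few spheres of constant b.  This module builds all three kinds of
scheme with deterministic, seedable construction rules.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ProtocolMeta",
    "CartesianQGrid",
    "SchemeEntry",
    "SamplingScheme",
    "build_grid",
    "select_by_bvalue",
    "generate_cs_scheme",
    "generate_multishell_scheme",
    "repulsion_energy",
]


@dataclass(frozen=True)
class ProtocolMeta:
    """Acquisition timing metadata.

    Parameters
    ----------
    TE, TR : float
        Echo and repetition time in ms.
    Delta : float
        Gradient pulse separation in ms.
    delta : float
        Gradient pulse duration in ms (must be < Delta).
    n_b0 : int
        Number of interleaved b=0 volumes.
    """

    TE: float = 101.4
    TR: float = 5300.0
    Delta: float = 49.5
    delta: float = 19.7
    n_b0: int = 0

    def __post_init__(self) -> None:
        if min(self.TE, self.TR, self.Delta, self.delta) <= 0:
            raise ValueError("timing parameters must be positive")
        if self.delta >= self.Delta:
            raise ValueError("pulse duration delta must be < separation Delta")
        if self.n_b0 < 0:
            raise ValueError("n_b0 must be >= 0")

    @property
    def tau(self) -> float:
        """Effective diffusion time Delta - delta/3, in seconds."""
        return (self.Delta - self.delta / 3.0) * 1e-3


def _canonical_representative(p: np.ndarray) -> bool:
    """True if p is the antipodal representative: first nonzero coord > 0."""
    for c in p:
        if c != 0:
            return c > 0
    return True  # origin is self-paired


@dataclass(frozen=True)
class CartesianQGrid:
    """Integer q-space lattice truncated to a sphere.

    ``points`` holds every lattice triple with squared norm <= radius**2 in
    lexicographic (qz, qy, qx) order.  ``b_max`` is the b-value at the grid
    boundary |q| = radius, so b(q) = b_max * |q|^2 / radius^2.
    """

    radius: int
    b_max: float
    points: np.ndarray = field(repr=False)

    def b_of(self, point: Sequence[int]) -> float:
        p = np.asarray(point, dtype=float)
        if self.radius == 0:
            return 0.0
        return self.b_max * float(p @ p) / self.radius**2

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def unique_points(self) -> np.ndarray:
        """Antipodally-unique points (first nonzero coordinate positive)."""
        keep = [i for i, p in enumerate(self.points) if _canonical_representative(p)]
        return self.points[keep]

    @property
    def unique_nonzero_points(self) -> np.ndarray:
        up = self.unique_points
        return up[np.any(up != 0, axis=1)]

    def contains(self, point: Sequence[int]) -> bool:
        p = np.asarray(point, dtype=int)
        return int(p @ p) <= self.radius**2


def build_grid(radius: int, b_max: float) -> CartesianQGrid:
    """Enumerate the truncated-sphere Cartesian q-space lattice.

    For the standard DSI grid (radius 5, 11x11x11 extent) this yields 515
    lattice points, 258 antipodally-unique samples and 257 unique nonzero
    diffusion-weighted samples.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if b_max <= 0:
        raise ValueError("b_max must be > 0")
    r2 = radius * radius
    pts = [
        (x, y, z)
        for z in range(-radius, radius + 1)
        for y in range(-radius, radius + 1)
        for x in range(-radius, radius + 1)
        if x * x + y * y + z * z <= r2
    ]
    return CartesianQGrid(radius=radius, b_max=float(b_max),
                          points=np.array(pts, dtype=int))


@dataclass
class SchemeEntry:
    """One gradient-table line: direction, b-value, optional lattice index."""

    direction: np.ndarray
    bval: float
    grid_index: tuple[int, int, int] | None = None
    measured: bool = True

    def __post_init__(self) -> None:
        self.direction = np.asarray(self.direction, dtype=float)
        if self.bval > 0:
            n = np.linalg.norm(self.direction)
            if abs(n - 1.0) > 1e-6:
                raise ValueError("non-b0 direction must be unit norm")
        else:
            if np.any(self.direction != 0):
                raise ValueError("b=0 entry must have a zero direction vector")


@dataclass
class SamplingScheme:
    """Ordered gradient table serving both CS-DSI and shell protocols."""

    entries: list[SchemeEntry]
    protocol_id: str = "custom"
    meta: ProtocolMeta = field(default_factory=ProtocolMeta)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def bvals(self) -> np.ndarray:
        return np.array([e.bval for e in self.entries])

    @property
    def bvecs(self) -> np.ndarray:
        """Directions as an (n, 3) array; zero rows at b=0."""
        return np.array([e.direction for e in self.entries])

    @property
    def n_dwis(self) -> int:
        """Number of diffusion-weighted (b > 0) entries."""
        return int(np.sum(self.bvals > 0))

    @property
    def n_measured(self) -> int:
        return sum(1 for e in self.entries if e.measured and e.bval > 0)

    def measured_subset(self) -> "SamplingScheme":
        return SamplingScheme(
            entries=[e for e in self.entries if e.measured],
            protocol_id=self.protocol_id + "-measured",
            meta=self.meta,
        )

    def to_json_dict(self) -> dict:
        return {
            "protocol_id": self.protocol_id,
            "meta": asdict(self.meta),
            "entries": [
                {
                    "direction": [float(v) for v in e.direction],
                    "bval": float(e.bval),
                    "grid_index": list(e.grid_index) if e.grid_index is not None else None,
                    "measured": bool(e.measured),
                }
                for e in self.entries
            ],
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "SamplingScheme":
        meta = ProtocolMeta(**d["meta"])
        entries = [
            SchemeEntry(
                direction=np.array(e["direction"], dtype=float),
                bval=e["bval"],
                grid_index=tuple(e["grid_index"]) if e.get("grid_index") else None,
                measured=e.get("measured", True),
            )
            for e in d["entries"]
        ]
        return cls(entries=entries, protocol_id=d.get("protocol_id", "custom"), meta=meta)

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=1)

    @classmethod
    def load_json(cls, path) -> "SamplingScheme":
        with open(path) as fh:
            return cls.from_json_dict(json.load(fh))


def _entry_from_grid_point(grid: CartesianQGrid, p: np.ndarray,
                           measured: bool = True) -> SchemeEntry:
    b = grid.b_of(p)
    if b == 0:
        return SchemeEntry(direction=np.zeros(3), bval=0.0,
                           grid_index=(0, 0, 0), measured=measured)
    d = p / np.linalg.norm(p)
    return SchemeEntry(direction=d, bval=b, grid_index=tuple(int(c) for c in p),
                       measured=measured)


def select_by_bvalue(scheme_or_grid, b_lo: float, b_hi: float) -> SamplingScheme:
    """Antipodally-unique nonzero samples with b_lo <= b <= b_hi.

    Accepts either a :class:`CartesianQGrid` (selection over its unique
    nonzero lattice points) or a :class:`SamplingScheme` (selection over
    its diffusion-weighted entries, order preserved; b=0 entries are
    retained so the subset stays fit-ready).
    """
    if b_lo > b_hi:
        raise ValueError("b_lo must be <= b_hi")
    if isinstance(scheme_or_grid, CartesianQGrid):
        grid = scheme_or_grid
        entries = [
            _entry_from_grid_point(grid, p)
            for p in grid.unique_nonzero_points
            if b_lo <= grid.b_of(p) <= b_hi
        ]
        if not entries:
            warnings.warn("b-value selection is empty", stacklevel=2)
        return SamplingScheme(entries=entries, protocol_id="grid-subset")
    scheme: SamplingScheme = scheme_or_grid
    entries = [e for e in scheme.entries
               if e.bval == 0 or (b_lo <= e.bval <= b_hi)]
    if not any(e.bval > 0 for e in entries):
        warnings.warn("b-value selection is empty", stacklevel=2)
    return SamplingScheme(entries=entries, protocol_id=scheme.protocol_id + "-subset",
                          meta=scheme.meta)


def _direction_lines(points: np.ndarray) -> dict[tuple, list[int]]:
    """Group antipodally-unique lattice points by their direction line.

    Key is the primitive integer triple of the line; value lists indices of
    grid points (radial positions) sharing that line.
    """
    lines: dict[tuple, list[int]] = {}
    for i, p in enumerate(points):
        g = math.gcd(math.gcd(abs(int(p[0])), abs(int(p[1]))), abs(int(p[2])))
        key = tuple(int(c) // g for c in p)
        lines.setdefault(key, []).append(i)
    return lines


def generate_cs_scheme(grid: CartesianQGrid, accel: float, seed: int,
                       meta: ProtocolMeta | None = None) -> SamplingScheme:
    """Build a CS-DSI undersampling scheme on the DSI grid.

    ceil(n_unique_nonzero / accel) lattice samples are marked as measured,
    one per antipodal pair.  Direction lines are chosen by greedy
    farthest-point selection on the sphere (uniform angular coverage); the
    radial position on each chosen line is drawn uniformly at random among
    the lattice points on that line, seeded.  All remaining unique samples
    are kept in the scheme flagged ``measured=False`` (to be recovered by
    CS reconstruction).  At the standard 2.3-fold acceleration on the
    radius-5 grid this yields 112 measured diffusion-weighted images.
    """
    uniq = grid.unique_nonzero_points
    n_uniq = len(uniq)
    if not (1.0 <= accel <= n_uniq):
        raise ValueError(f"accel must lie in [1, {n_uniq}]")
    n_meas = math.ceil(n_uniq / accel)
    rng = np.random.default_rng(seed)

    lines = _direction_lines(uniq)
    keys = sorted(lines.keys())
    units = np.array([np.asarray(k, float) / np.linalg.norm(k) for k in keys])

    # greedy farthest-point over direction lines (line metric: angle via |dot|)
    start = int(rng.integers(len(keys)))
    chosen: list[int] = [start]
    # min angular proximity (|cos|) of every candidate to the chosen set
    prox = np.abs(units @ units[start])
    n_lines = min(n_meas, len(keys))
    for _ in range(n_lines - 1):
        prox[chosen] = np.inf
        nxt = int(np.argmin(prox))
        chosen.append(nxt)
        prox = np.minimum(prox, np.abs(units @ units[nxt]))

    measured_idx: set[int] = set()
    for li in chosen:
        cands = lines[keys[li]]
        measured_idx.add(int(rng.choice(cands)))
    # if more samples are requested than there are direction lines, top up
    # with seeded draws from the not-yet-measured pool
    remaining = [i for i in range(n_uniq) if i not in measured_idx]
    while len(measured_idx) < n_meas:
        pick = int(rng.choice(len(remaining)))
        measured_idx.add(remaining.pop(pick))

    if meta is None:
        meta = ProtocolMeta(n_b0=8)
    entries = [_entry_from_grid_point(grid, p, measured=(i in measured_idx))
               for i, p in enumerate(uniq)]
    # interleave the b=0 volumes evenly through the table
    if meta.n_b0 > 0:
        stride = max(1, len(entries) // meta.n_b0)
        for k in range(meta.n_b0):
            entries.insert(min(k * (stride + 1), len(entries)),
                           SchemeEntry(direction=np.zeros(3), bval=0.0,
                                       grid_index=(0, 0, 0), measured=True))
    return SamplingScheme(entries=entries, protocol_id=f"cs-dsi-accel{accel}",
                          meta=meta)


def repulsion_energy(units: np.ndarray, shell_ids: np.ndarray,
                     cross_weight: float = 0.5) -> float:
    """Antipodally-symmetric electrostatic energy of a stacked direction set.

    Pairwise 1/|u_i - u_j| + 1/|u_i + u_j|; pairs on different shells are
    down-weighted by ``cross_weight`` (staggered multi-shell design).
    """
    n = len(units)
    diff = units[:, None, :] - units[None, :, :]
    summ = units[:, None, :] + units[None, :, :]
    with np.errstate(divide="ignore"):
        e = 1.0 / np.linalg.norm(diff, axis=2) + 1.0 / np.linalg.norm(summ, axis=2)
    w = np.where(shell_ids[:, None] == shell_ids[None, :], 1.0, cross_weight)
    iu = np.triu_indices(n, k=1)
    return float(np.sum(e[iu] * w[iu]))


def _repulsion_grad(units: np.ndarray, shell_ids: np.ndarray,
                    cross_weight: float) -> np.ndarray:
    diff = units[:, None, :] - units[None, :, :]
    summ = units[:, None, :] + units[None, :, :]
    nd = np.linalg.norm(diff, axis=2)
    ns = np.linalg.norm(summ, axis=2)
    np.fill_diagonal(nd, np.inf)
    np.fill_diagonal(ns, np.inf)
    w = np.where(shell_ids[:, None] == shell_ids[None, :], 1.0, cross_weight)
    gd = -diff / nd[..., None] ** 3
    gs = -summ / ns[..., None] ** 3
    return np.sum(w[..., None] * (gd + gs), axis=1)


def generate_multishell_scheme(shells: Sequence[tuple[float, int]], seed: int,
                               meta: ProtocolMeta | None = None,
                               cross_weight: float = 0.5,
                               max_iter: int = 2000,
                               tol: float = 1e-10,
                               energy_trace: list | None = None) -> SamplingScheme:
    """Staggered multi-shell scheme by electrostatic repulsion.

    Directions on each shell minimize an antipodally-symmetric Coulomb
    energy; a down-weighted cross-shell term staggers the shells jointly so
    the union also covers the sphere uniformly.  Projected gradient descent
    with backtracking from a seeded random start guarantees a monotone
    energy decrease.  The standard 3-shell protocol (30/40/50 directions at
    b = 1000/2000/3000) yields 120 diffusion-weighted images.
    """
    shells = list(shells)
    if not shells or any(b <= 0 or n < 1 for b, n in shells):
        raise ValueError("each shell needs b > 0 and n >= 1")
    rng = np.random.default_rng(seed)
    shell_ids = np.concatenate([np.full(n, i) for i, (_, n) in enumerate(shells)])
    n_total = len(shell_ids)
    u = rng.standard_normal((n_total, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)

    energy = repulsion_energy(u, shell_ids, cross_weight)
    if energy_trace is not None:
        energy_trace.append(energy)
    step = 1e-3
    for _ in range(max_iter):
        g = _repulsion_grad(u, shell_ids, cross_weight)
        # project gradient onto the tangent plane of each direction
        g -= np.sum(g * u, axis=1, keepdims=True) * u
        improved = False
        while step > 1e-14:
            cand = u - step * g
            cand /= np.linalg.norm(cand, axis=1, keepdims=True)
            e_new = repulsion_energy(cand, shell_ids, cross_weight)
            if e_new < energy:
                improved = True
                break
            step *= 0.5
        if not improved:
            break
        u, de = cand, energy - e_new
        energy = e_new
        if energy_trace is not None:
            energy_trace.append(energy)
        step *= 1.3
        if de < tol * max(abs(energy), 1.0):
            break

    if meta is None:
        meta = ProtocolMeta(n_b0=14)
    entries: list[SchemeEntry] = []
    k = 0
    for i, (b, n) in enumerate(shells):
        for _ in range(n):
            entries.append(SchemeEntry(direction=u[k], bval=float(b)))
            k += 1
    if meta.n_b0 > 0:
        stride = max(1, len(entries) // meta.n_b0)
        for j in range(meta.n_b0):
            entries.insert(min(j * (stride + 1), len(entries)),
                           SchemeEntry(direction=np.zeros(3), bval=0.0))
    label = "multishell-" + "-".join(f"{int(b)}x{n}" for b, n in shells)
    return SamplingScheme(entries=entries, protocol_id=label, meta=meta)
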