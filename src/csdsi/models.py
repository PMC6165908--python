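"""Diffusion tensor and kurtosis model fitting.

Both models are fit to the log-signal by weighted linear least squares
(weights = squared noise-free signal predictions, two-pass — the standard
WLLS scheme).  The kurtosis fit uses the cumulant form

    ln S(g, b) = ln S0 - b D(g) + (b^2/6) MD^2 W(g)

with D a symmetric 3x3 tensor and W a fully-symmetric 4th-order tensor
(15 unique elements); the apparent kurtosis along g is
K(g) = W(g) MD^2 / D(g)^2.  For robustness to noise the fit can enforce
Kmin <= K(g) <= Kmax and D(g) >= 0 on the fitted directions (projected
refit, activated only when the unconstrained solution violates them).

Protocol-specific sample selection mirrors the comparison design: on the
CS-DSI grid the tensor model uses lattice samples with |q|^2 <= 5
(b up to ~1360), the kurtosis model b <= 3000; on the 3-shell scheme the
tensor model uses the b=1000 shell, the kurtosis model all shells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .phantom import fa_from_eigenvalues
from .qspace import SamplingScheme, select_by_bvalue
from .sphere import icosphere

__all__ = [
    "TensorFit",
    "KurtosisFit",
    "select_model_subset",
    "fit_dti",
    "fit_dki",
]

# index pairs of the 6 unique tensor elements, with off-diagonal doubling
_D_IDX = [(0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)]
_D_MULT = np.array([1.0, 1.0, 1.0, 2.0, 2.0, 2.0])


def _w_index_mult():
    """15 unique elements of a fully-symmetric 4th-order tensor with their
    multinomial multiplicities."""
    from itertools import combinations_with_replacement
    from math import factorial
    idx, mult = [], []
    for c in combinations_with_replacement(range(3), 4):
        idx.append(c)
        counts = [c.count(i) for i in range(3)]
        mult.append(factorial(4) // (factorial(counts[0]) * factorial(counts[1])
                                     * factorial(counts[2])))
    return idx, np.array(mult, dtype=float)


_W_IDX, _W_MULT = _w_index_mult()


def _d_design(bvecs: np.ndarray) -> np.ndarray:
    """(n, 6) quadratic-form design: rows g_i g_j with multiplicity."""
    cols = [bvecs[:, i] * bvecs[:, j] for i, j in _D_IDX]
    return np.stack(cols, axis=1) * _D_MULT


def _w_design(bvecs: np.ndarray) -> np.ndarray:
    """(n, 15) quartic-form design with multinomial multiplicity."""
    cols = [bvecs[:, a] * bvecs[:, b] * bvecs[:, c] * bvecs[:, d]
            for a, b, c, d in _W_IDX]
    return np.stack(cols, axis=1) * _W_MULT


def d_vec_to_matrix(dvec: np.ndarray) -> np.ndarray:
    D = np.zeros((3, 3))
    for (i, j), v in zip(_D_IDX, dvec):
        D[i, j] = D[j, i] = v
    return D


def _apparent(dvec: np.ndarray, g: np.ndarray) -> float:
    return float((_d_design(g[None]) @ dvec)[0])


@dataclass
class TensorFit:
    """Fitted diffusion tensor with derived scalar metrics."""

    D: np.ndarray
    S0_est: float
    nmse: float
    negative_eigenvalues_clamped: bool = False

    @property
    def eigenvalues(self) -> np.ndarray:
        return np.sort(np.linalg.eigvalsh(self.D))[::-1]

    @property
    def principal_direction(self) -> np.ndarray:
        w, V = np.linalg.eigh(self.D)
        return V[:, -1]

    def _metric_eigs(self) -> np.ndarray:
        return np.maximum(self.eigenvalues, 0.0)

    @property
    def fa(self) -> float:
        return fa_from_eigenvalues(self._metric_eigs())

    @property
    def md(self) -> float:
        return float(self._metric_eigs().mean())

    @property
    def ad(self) -> float:
        return float(self._metric_eigs()[0])

    @property
    def rd(self) -> float:
        lam = self._metric_eigs()
        return float((lam[1] + lam[2]) / 2)


@dataclass
class KurtosisFit(TensorFit):
    """Tensor + fully-symmetric kurtosis tensor (15 unique elements)."""

    W: np.ndarray = field(default_factory=lambda: np.zeros(15))

    def apparent_kurtosis(self, g) -> float:
        g = np.asarray(g, dtype=float)
        g = g / np.linalg.norm(g)
        dvec = np.array([self.D[i, j] for i, j in _D_IDX])
        dg = _apparent(dvec, g)
        wg = float((_w_design(g[None]) @ self.W)[0])
        return wg * self.md**2 / dg**2

    @property
    def mk(self) -> float:
        """Mean kurtosis: K(g) averaged over a uniform direction set."""
        dirs, _, _, _ = icosphere(2)  # 162 directions
        return float(np.mean([self.apparent_kurtosis(g) for g in dirs]))

    @property
    def ak(self) -> float:
        return self.apparent_kurtosis(self.principal_direction)

    @property
    def rk(self) -> float:
        e1 = self.principal_direction
        helper = np.array([1.0, 0, 0]) if abs(e1[0]) < 0.9 else np.array([0, 1.0, 0])
        e2 = np.cross(e1, helper)
        e2 /= np.linalg.norm(e2)
        e3 = np.cross(e1, e2)
        angles = np.linspace(0, np.pi, 36, endpoint=False)
        return float(np.mean([
            self.apparent_kurtosis(np.cos(a) * e2 + np.sin(a) * e3)
            for a in angles]))


def select_model_subset(scheme: SamplingScheme, model: str) -> SamplingScheme:
    """Protocol-aware b-value subset for a diffusion model.

    ``model`` is 'dt' or 'kurtosis'.  Grid schemes (entries carry lattice
    indices) use the lattice rules |q|^2 <= 5 (DT) or b <= 3000
    (kurtosis); shell schemes use the innermost ~1000 shell (DT) or all
    shells (kurtosis).
    """
    is_grid = any(e.grid_index is not None and e.bval > 0 for e in scheme.entries)
    if model == "dt":
        if is_grid:
            entries = [e for e in scheme.entries
                       if e.bval == 0 or
                       (e.grid_index is not None
                        and sum(c * c for c in e.grid_index) <= 5)]
            return SamplingScheme(entries=entries,
                                  protocol_id=scheme.protocol_id + "-dt",
                                  meta=scheme.meta)
        return select_by_bvalue(scheme, 900.0, 1100.0)
    if model == "kurtosis":
        if is_grid:
            return select_by_bvalue(scheme, 0.0, 3000.0)
        return select_by_bvalue(scheme, 0.0, np.inf)
    raise ValueError(f"unknown model {model!r}; expected 'dt' or 'kurtosis'")


def _check_design_rank(X: np.ndarray, need: int, what: str) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < need:
        raise ValueError(
            f"rank-deficient design for {what}: rank {rank} < {need}; "
            "need b=0 plus non-coplanar gradient directions")


def _wlls(X: np.ndarray, logs: np.ndarray) -> np.ndarray:
    """Two-pass weighted linear least squares on the log signal."""
    beta = np.linalg.lstsq(X, logs, rcond=None)[0]
    w = np.exp(X @ beta)  # noise-free signal prediction
    Xw = X * w[:, None]
    return np.linalg.lstsq(Xw, logs * w, rcond=None)[0]


def fit_dti(signals: np.ndarray, scheme: SamplingScheme) -> TensorFit:
    """Weighted linear least-squares diffusion tensor fit."""
    signals = np.asarray(signals, dtype=float)
    if len(signals) != len(scheme):
        raise ValueError("signal count does not match scheme length")
    if len(signals) < 7:
        raise ValueError("tensor fit needs at least 7 samples")
    bvals, bvecs = scheme.bvals, scheme.bvecs
    # work in ms/um^2 units internally so all parameters are O(1)
    X = np.column_stack([np.ones(len(bvals)),
                         -(bvals[:, None] * 1e-3) * _d_design(bvecs)])
    _check_design_rank(X, 7, "tensor fit")
    pos = signals > 0
    if not np.all(pos):
        warnings.warn("non-positive signals excluded from log-linear fit",
                      stacklevel=2)
    logs = np.log(signals[pos])
    beta = _wlls(X[pos], logs)
    D = d_vec_to_matrix(beta[1:7] * 1e-3)
    pred = np.exp(X @ beta)
    nmse = float(np.sum((pred - signals) ** 2) / np.sum(signals**2))
    clamped = bool(np.any(np.linalg.eigvalsh(D) < 0))
    if clamped:
        warnings.warn("negative tensor eigenvalues clamped for metrics",
                      stacklevel=2)
    return TensorFit(D=D, S0_est=float(np.exp(beta[0])), nmse=nmse,
                     negative_eigenvalues_clamped=clamped)


def fit_dki(signals: np.ndarray, scheme: SamplingScheme,
            constraints: tuple[float, float] | None = (0.0, 3.0)) -> KurtosisFit:
    """Constrained weighted linear least-squares kurtosis fit.

    ``constraints = (Kmin, Kmax)`` bounds the apparent kurtosis on every
    fitted direction (and keeps D(g) >= 0); pass None to disable.  Raises
    if the scheme has fewer than 2 distinct nonzero b-values (kurtosis is
    then unidentifiable) or fewer than 22 samples.
    """
    signals = np.asarray(signals, dtype=float)
    if len(signals) != len(scheme):
        raise ValueError("signal count does not match scheme length")
    bvals, bvecs = scheme.bvals, scheme.bvecs
    if len(np.unique(bvals[bvals > 0])) < 2:
        raise ValueError("kurtosis is unidentifiable from a single shell: "
                         "need >= 2 distinct nonzero b-values")
    if len(signals) < 22:
        raise ValueError("kurtosis fit needs at least 22 samples")
    Xd = _d_design(bvecs)
    Xw = _w_design(bvecs)
    bs = bvals[:, None] * 1e-3  # ms/um^2 units keep the design well-scaled
    X = np.column_stack([np.ones(len(bvals)),
                         -bs * Xd,
                         (bs**2 / 6.0) * Xw])
    _check_design_rank(X, 22, "kurtosis fit")
    logs = np.log(signals)
    beta = _wlls(X, logs)

    def unpack(b):
        dvec, vvec = b[1:7], b[7:22]
        md = float(np.trace(d_vec_to_matrix(dvec)) / 3)
        return dvec, vvec, md

    if constraints is not None:
        kmin, kmax = constraints
        dirs = bvecs[bvals > 0]
        # deduplicate direction lines for the constraint set
        uniq = []
        for g in dirs:
            if all(abs(g @ u) < 1 - 1e-10 for u in uniq):
                uniq.append(g)
        G = np.array(uniq)
        Ad = _d_design(G)          # D(g) = Ad @ dvec
        Aw = _w_design(G)          # MD^2 W(g) = Aw @ vvec

        def violations(b):
            dvec, vvec, _ = unpack(b)
            dg = Ad @ dvec
            kg = (Aw @ vvec) / np.maximum(dg, 1e-12) ** 2
            return (np.min(dg), np.min(kg - kmin), np.min(kmax - kg))

        if min(violations(beta)) < -1e-9:
            w = np.exp(X @ beta)
            Xw_w, y_w = X * w[:, None], logs * w

            def obj(b):
                r = Xw_w @ b - y_w
                return 0.5 * float(r @ r)

            def jac(b):
                return Xw_w.T @ (Xw_w @ b - y_w)

            cons = [
                {"type": "ineq", "fun": lambda b: Ad @ b[1:7]},
                {"type": "ineq",
                 "fun": lambda b: Aw @ b[7:22] - kmin * (Ad @ b[1:7]) ** 2},
                {"type": "ineq",
                 "fun": lambda b: kmax * (Ad @ b[1:7]) ** 2 - Aw @ b[7:22]},
            ]
            res = minimize(obj, beta, jac=jac, method="SLSQP",
                           constraints=cons,
                           options={"maxiter": 500, "ftol": 1e-14})
            beta = res.x

    dvec, vvec, md = unpack(beta)
    # back to mm^2/s; W = V/MD^2 is dimensionless, so the scaled md cancels
    D = d_vec_to_matrix(dvec * 1e-3)
    W = vvec / md**2 if md > 0 else np.zeros(15)
    pred = np.exp(X @ beta)
    nmse = float(np.sum((pred - signals) ** 2) / np.sum(signals**2))
    clamped = bool(np.any(np.linalg.eigvalsh(D) < 0))
    return KurtosisFit(D=D, S0_est=float(np.exp(beta[0])), nmse=nmse,
                       negative_eigenvalues_clamped=clamped, W=W)
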