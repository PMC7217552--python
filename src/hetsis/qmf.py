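"""Quenched mean-field (QMF) theory for SIS with heterogeneous recovery.

Neglecting dynamical correlations, the per-node infection probabilities
obey ``dy_i/dt = -delta_i y_i + (1 - y_i) sum_j lambda_ij A_ij y_j``.  The
linearization around the disease-free state is governed by
``Q = Delta^-1 (A o W)``, whose entries are the expected number of
contacts a node makes before recovering; the epidemic threshold is
``lambda_c = 1 / Lambda_max(Q)``.

For both supported schemes Q is a positive diagonal row scaling of the
symmetric adjacency matrix, ``Q = S^-1 A`` with ``s_i = delta_i / w_i``
(``w_i`` the per-edge rate leaving node i at unit lambda).  Q is therefore
similar to the symmetric matrix ``S^-1/2 A S^-1/2``, which the eigensolver
exploits: same spectrum, Lanczos robustness, and a Perron eigenvector
recovered by back-scaling.

Two a-priori bounds accompany the threshold.  A matrix-norm sandwich,
``min(s_i)/Lambda_max(A) <= lambda_c <= max(s_i)/Lambda_max(A)``, relates
it to the homogeneous prediction, and the Gershgorin infinity-norm bound
``Lambda_max(Q) <= max_i k_i / s_i`` gives a structure-dynamics lower
bound on the threshold that stays finite when rates grow with degree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.integrate import solve_ivp

from .netgen import Network
from .rates import RecoveryRates, SpreadingScheme

__all__ = [
    "QMFReport",
    "build_Q",
    "leading_eigenpair",
    "critical_point",
    "integrate_qmf_ode",
    "qmf_steady_state",
]

_DENSE_CUTOFF = 64  # below this, ARPACK is unreliable; use dense eig


@dataclass(frozen=True)
class QMFReport:
    """Spectral threshold prediction and localization diagnostics."""

    lambda_max: float
    critical_point: float
    leading_vector: np.ndarray = field(repr=False)
    bound_low: float
    bound_high: float
    inf_norm_bound: float
    ipr: float

    def to_dict(self) -> dict:
        return {
            "lambda_max": self.lambda_max,
            "critical_point": self.critical_point,
            "bound_low": self.bound_low,
            "bound_high": self.bound_high,
            "inf_norm_bound": self.inf_norm_bound,
            "ipr": self.ipr,
        }


def _effective_scale(net: Network, rates: RecoveryRates, scheme: SpreadingScheme) -> np.ndarray:
    """s_i = delta_i / w_i so that Q = S^-1 A at unit lambda."""
    w = SpreadingScheme(scheme.kind, 1.0).edge_rates_out(net.degrees)
    if np.any(w <= 0):
        raise ValueError("scheme assigns zero out-rate (isolated node?)")
    return rates.delta / w


def build_Q(net: Network, rates: RecoveryRates, scheme: SpreadingScheme | None = None) -> sp.csr_array:
    """Contacts-before-recovery matrix Q_ij = lambda_ij A_ij / delta_i at lambda = 1.

    The spreading rate enters only as a global scale, so Q is built at
    unit lambda and thresholds are reported in lambda units.
    """
    scheme = scheme or SpreadingScheme("uniform", 1.0)
    if rates.n_nodes != net.n_nodes:
        raise ValueError("rates length does not match network size")
    if not net.is_connected():
        raise ValueError("network must be connected (irreducible Q required)")
    s = _effective_scale(net, rates, scheme)
    a = net.adjacency.astype(np.float64)
    return sp.csr_array(sp.diags(1.0 / s) @ a)


def leading_eigenpair(
    matrix: sp.spmatrix | np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 100_000,
    sym_scale: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Dominant eigenvalue and right eigenvector of a nonnegative matrix.

    When ``sym_scale`` s is given the matrix is known to be ``S^-1 A`` with
    A symmetric; the spectrum is then computed from the similar symmetric
    matrix ``S^-1/2 A S^-1/2`` and the right eigenvector recovered as
    ``S^-1/2 u``.  The returned vector has unit Euclidean norm and
    nonnegative entries (Perron–Frobenius for an irreducible matrix).
    """
    n = matrix.shape[0]
    if sym_scale is not None:
        s_sqrt = np.sqrt(np.asarray(sym_scale, dtype=np.float64))
        s_inv_sqrt = 1.0 / s_sqrt
        # S^1/2 (S^-1 A) S^-1/2 = S^-1/2 A S^-1/2, symmetric and similar
        sym = sp.diags(s_sqrt) @ matrix @ sp.diags(s_inv_sqrt)
        sym = (sym + sym.T) / 2.0
        if n < _DENSE_CUTOFF:
            vals, vecs = np.linalg.eigh(np.asarray(sym.todense()))
            lam, u = vals[-1], vecs[:, -1]
        else:
            vals, vecs = spla.eigsh(sym, k=1, which="LA", tol=tol, maxiter=max_iter)
            lam, u = vals[0], vecs[:, 0]
        v = s_inv_sqrt * u
    else:
        if n < _DENSE_CUTOFF:
            dense = matrix.todense() if sp.issparse(matrix) else np.asarray(matrix)
            vals, vecs = np.linalg.eig(np.asarray(dense))
            idx = int(np.argmax(vals.real))
            lam, v = vals[idx].real, vecs[:, idx].real
        else:
            vals, vecs = spla.eigs(matrix.astype(np.float64), k=1, which="LR",
                                   tol=tol, maxiter=max_iter)
            lam, v = vals[0].real, vecs[:, 0].real
    if v.sum() < 0:
        v = -v
    v = np.abs(v)  # kill sign noise in numerically-zero entries
    v /= np.linalg.norm(v)
    residual = np.linalg.norm(matrix @ v - lam * v)
    if not np.isfinite(lam) or residual > max(1e-6, 100 * tol) * max(abs(lam), 1.0):
        raise RuntimeError(f"eigensolver residual {residual:.2e} too large for lambda={lam}")
    return float(lam), v


def critical_point(
    net: Network,
    rates: RecoveryRates,
    scheme: SpreadingScheme | None = None,
    tol: float = 1e-10,
    max_iter: int = 100_000,
) -> QMFReport:
    """Full spectral report: threshold, sandwich bounds, Gershgorin bound, IPR."""
    scheme = scheme or SpreadingScheme("uniform", 1.0)
    q = build_Q(net, rates, scheme)
    s = _effective_scale(net, rates, scheme)
    lam_max, v = leading_eigenpair(q, tol=tol, max_iter=max_iter, sym_scale=s)
    a = net.adjacency.astype(np.float64)
    if net.n_nodes < _DENSE_CUTOFF:
        lam_max_a = float(np.linalg.eigvalsh(np.asarray(a.todense()))[-1])
    else:
        lam_max_a = float(spla.eigsh(a, k=1, which="LA", tol=tol,
                                     return_eigenvectors=False)[0])
    tau_std = 1.0 / lam_max_a
    inf_norm = float(np.max(net.degrees / s))
    return QMFReport(
        lambda_max=lam_max,
        critical_point=1.0 / lam_max,
        leading_vector=v,
        bound_low=float(s.min()) * tau_std,
        bound_high=float(s.max()) * tau_std,
        inf_norm_bound=inf_norm,
        ipr=float(np.sum(v**4)),
    )


def _qmf_rhs(net: Network, rates: RecoveryRates, scheme: SpreadingScheme):
    a = net.adjacency.astype(np.float64).tocsr()
    w_in = scheme.edge_rates_out(net.degrees)  # rate on edges *leaving* each source
    delta = rates.delta

    def rhs(_t, y):
        inflow = a @ (w_in * y)
        return -delta * y + (1.0 - y) * inflow

    return rhs


def integrate_qmf_ode(
    net: Network,
    rates: RecoveryRates,
    lam: float,
    y0: np.ndarray,
    t_max: float,
    scheme_kind: str = "uniform",
    n_eval: int = 200,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate the mean-field ODE; returns (times, trajectory).

    The region [0, 1]^N is invariant under the dynamics; solutions are
    clamped to it to absorb solver overshoot.
    """
    y0 = np.asarray(y0, dtype=np.float64)
    if np.any(y0 < 0) or np.any(y0 > 1):
        raise ValueError("initial probabilities must lie in [0, 1]")
    scheme = SpreadingScheme(scheme_kind, lam)
    rhs = _qmf_rhs(net, rates, scheme)
    sol = solve_ivp(rhs, (0.0, t_max), y0, method="LSODA",
                    t_eval=np.linspace(0.0, t_max, n_eval), rtol=1e-8, atol=1e-10)
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    return sol.t, np.clip(sol.y.T, 0.0, 1.0)


def qmf_steady_state(
    net: Network,
    rates: RecoveryRates,
    lam: float,
    y0: np.ndarray | None = None,
    scheme_kind: str = "uniform",
    deriv_tol: float = 1e-10,
    t_chunk: float = 50.0,
    max_chunks: int = 200,
) -> np.ndarray:
    """Integrate until ``||dy/dt||_inf < deriv_tol`` and return the fixed point."""
    y = np.full(net.n_nodes, 0.5) if y0 is None else np.asarray(y0, dtype=np.float64)
    scheme = SpreadingScheme(scheme_kind, lam)
    rhs = _qmf_rhs(net, rates, scheme)
    for _ in range(max_chunks):
        sol = solve_ivp(rhs, (0.0, t_chunk), y, method="LSODA", rtol=1e-10, atol=1e-12)
        if not sol.success:
            raise RuntimeError(f"ODE integration failed: {sol.message}")
        y = np.clip(sol.y[:, -1], 0.0, 1.0)
        if np.max(np.abs(rhs(0.0, y))) < deriv_tol:
            return y
    raise RuntimeError("steady state not reached within the integration budget")
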