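"""Linear distributed inverse solvers: wMNE and sLORETA.

Both are linear operators applied to the (possibly channel-weighted) EEG.
The full-dimension lead field is always used — channels excluded by a
selection chromosome arrive as all-zero rows of the data, never as deleted
rows of the operator — so the inverse kernel can be precomputed once per
(lead field, regularization) pair and reused across thousands of candidate
evaluations.

wMNE: depth-weighted Tikhonov solution
    x_hat = W^-1 M^T (M W^-1 M^T + lambda I)^-1 y,
    W = diag(||m_j||^(2p)) with p the depth exponent (p=0 gives plain MNE).

sLORETA: minimum-norm estimate standardized by the square root of the
diagonal of the resolution-derived variance R = M^T (M M^T + lambda I)^-1 M.
For a single noiseless dipole the standardized power peaks exactly at the
true vertex for any lambda >= 0 (Cauchy-Schwarz on the PSD matrix R).

Additional solvers can be registered through :func:`register_solver`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
import scipy.linalg

from .headmodel import LeadField

__all__ = [
    "SolverConfig",
    "SourceEstimate",
    "wmne",
    "sloreta",
    "solve",
    "make_kernel",
    "register_solver",
    "average_reference_operator",
]


@dataclass(frozen=True)
class SolverConfig:
    """Inverse solver settings.

    ``lambda_rule="snr_based"`` sets the Tikhonov parameter from the assumed
    data SNR: lambda = trace(M W^-1 M^T) / (d * 10^(snr_db/10)), i.e. the
    mean eigenvalue of the (weighted) Gram matrix divided by the linear SNR.
    ``lambda_rule="fixed"`` uses ``lambda_value`` as given.
    """

    method: str = "sloreta"
    lambda_rule: str = "snr_based"
    lambda_value: float | None = None
    depth_exponent: float = 1.0
    snr_db: float = 0.0
    average_reference: bool = True

    def __post_init__(self) -> None:
        if self.lambda_rule not in ("fixed", "snr_based"):
            raise ValueError(f"unknown lambda rule {self.lambda_rule!r}")
        if self.lambda_rule == "fixed":
            if self.lambda_value is None or self.lambda_value < 0:
                raise ValueError("fixed lambda rule requires lambda_value >= 0")
        if not 0.0 <= self.depth_exponent <= 2.0:
            raise ValueError("depth_exponent must be in [0, 2]")


@dataclass(frozen=True)
class SourceEstimate:
    """Estimated source activity, one row per source vertex."""

    x_hat: np.ndarray  # (n, K)
    method: str
    lambda_used: float
    used_pseudoinverse: bool = False

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.x_hat)):
            raise ValueError("source estimate contains non-finite values")


def average_reference_operator(d: int) -> np.ndarray:
    """Common-average-reference projector H = I - 11^T/d."""
    return np.eye(d) - np.ones((d, d)) / d


def _prepared_matrix(leadfield: LeadField, config: SolverConfig) -> np.ndarray:
    m = leadfield.matrix
    if config.average_reference:
        m = m - m.mean(axis=0, keepdims=True)
    return m


def _lambda_value(m: np.ndarray, w_inv: np.ndarray, config: SolverConfig) -> float:
    if config.lambda_rule == "fixed":
        return float(config.lambda_value)
    gram_trace = float(np.einsum("dj,j,dj->", m, w_inv, m))
    return gram_trace / (m.shape[0] * 10.0 ** (config.snr_db / 10.0))


def _regularized_inverse(gram: np.ndarray, lam: float) -> tuple[np.ndarray, bool]:
    """(gram + lam I)^-1, falling back to the pseudo-inverse if singular."""
    d = gram.shape[0]
    a = gram + lam * np.eye(d)
    try:
        cho = scipy.linalg.cho_factor(a)
        return scipy.linalg.cho_solve(cho, np.eye(d)), False
    except scipy.linalg.LinAlgError:
        warnings.warn("regularized Gram matrix is singular; using the pseudo-inverse", RuntimeWarning)
        return np.linalg.pinv(a), True


def _wmne_kernel(leadfield: LeadField, config: SolverConfig) -> tuple[np.ndarray, float, bool]:
    m = _prepared_matrix(leadfield, config)
    col_norms = np.linalg.norm(m, axis=0)
    w = np.maximum(col_norms, np.finfo(float).tiny) ** (2.0 * config.depth_exponent)
    w_inv = 1.0 / w
    lam = _lambda_value(m, w_inv, config)
    gram = (m * w_inv) @ m.T
    inv, used_pinv = _regularized_inverse(gram, lam)
    kernel = (w_inv[:, None] * m.T) @ inv
    if config.average_reference:
        kernel = kernel - kernel.mean(axis=1, keepdims=True)  # fold H into the kernel
    return kernel, lam, used_pinv


def _sloreta_kernel(leadfield: LeadField, config: SolverConfig) -> tuple[np.ndarray, float, bool]:
    m = _prepared_matrix(leadfield, config)
    lam = _lambda_value(m, np.ones(m.shape[1]), config)
    inv, used_pinv = _regularized_inverse(m @ m.T, lam)
    kernel_mn = m.T @ inv
    # variance of the estimate: diagonal of R = M^T (M M^T + lam I)^-1 M
    r_diag = np.einsum("nd,dn->n", kernel_mn, m)
    bad = r_diag <= np.finfo(float).eps * max(r_diag.max(), 1.0)
    if np.any(bad):
        warnings.warn(
            f"{int(bad.sum())} sources are invisible to the montage; their standardized activity is set to 0",
            RuntimeWarning,
        )
    scale = np.zeros_like(r_diag)
    scale[~bad] = 1.0 / np.sqrt(r_diag[~bad])
    kernel = scale[:, None] * kernel_mn
    if config.average_reference:
        kernel = kernel - kernel.mean(axis=1, keepdims=True)
    return kernel, lam, used_pinv


_KERNELS: dict[str, Callable[[LeadField, SolverConfig], tuple[np.ndarray, float, bool]]] = {
    "wmne": _wmne_kernel,
    "sloreta": _sloreta_kernel,
}


def register_solver(name: str, kernel_factory: Callable[[LeadField, SolverConfig], tuple[np.ndarray, float, bool]]) -> None:
    """Register a third-party linear solver.

    ``kernel_factory(leadfield, config)`` must return ``(kernel, lambda_used,
    used_pseudoinverse)`` with kernel of shape (n_sources, n_channels); the
    estimate is then ``kernel @ y``.
    """
    _KERNELS[name] = kernel_factory


def make_kernel(leadfield: LeadField, config: SolverConfig) -> tuple[np.ndarray, float, bool]:
    """Precompute the (n x d) inverse kernel for the configured method."""
    try:
        factory = _KERNELS[config.method]
    except KeyError:
        raise ValueError(f"unknown inverse method {config.method!r}; registered: {sorted(_KERNELS)}") from None
    return factory(leadfield, config)


def _apply(leadfield: LeadField, config: SolverConfig, y: np.ndarray, method: str) -> SourceEstimate:
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if y.shape[0] != leadfield.n_channels:
        raise ValueError(f"y has {y.shape[0]} rows but the lead field has {leadfield.n_channels} channels")
    kernel, lam, used_pinv = make_kernel(leadfield, config)
    if config.average_reference:
        y = y - y.mean(axis=0, keepdims=True)
    return SourceEstimate(kernel @ y, method, lam, used_pinv)


def wmne(y: np.ndarray, leadfield: LeadField, config: SolverConfig | None = None) -> SourceEstimate:
    """Depth-weighted minimum-norm (Tikhonov) estimate of source activity."""
    config = config or SolverConfig(method="wmne")
    if config.method != "wmne":
        config = SolverConfig(**{**config.__dict__, "method": "wmne"})
    return _apply(leadfield, config, y, "wmne")


def sloreta(y: np.ndarray, leadfield: LeadField, config: SolverConfig | None = None) -> SourceEstimate:
    """Standardized low-resolution tomography estimate."""
    config = config or SolverConfig(method="sloreta")
    if config.method != "sloreta":
        config = SolverConfig(**{**config.__dict__, "method": "sloreta"})
    return _apply(leadfield, config, y, "sloreta")


def solve(y_w: np.ndarray, leadfield: LeadField, config: SolverConfig) -> SourceEstimate:
    """Dispatch the configured solver on a (weighted) full-dimension epoch.

    ``y_w`` must have one row per lead-field channel; channels excluded by a
    selection chromosome are all-zero rows.  The operator is never subsetted.
    """
    return _apply(leadfield, config, y_w, config.method)
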