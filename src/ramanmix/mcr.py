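"""Constrained multivariate curve resolution by alternating least squares.

Factorizes a mixture matrix ``D (I x J)`` as ``C (I x A) . S (A x J) + E``
under non-negativity (exact NNLS subproblems), equal-spectral-area closure on
the free component spectra (scale absorbed into C, so the fit is unchanged),
and optional equality constraints fixing selected spectra to known profiles
(NaN rows in ``fixed_spectra`` mark free components).  Initial spectral
estimates come from a SIMPLISMA-style purest-row selection.

Stopping: relative change in the SD of the residual entries below
``conv_tol_pct`` percent (converged), ``max_iter`` reached, or the residual
SD increasing for ``divergence_patience`` consecutive iterations (diverged;
the best-so-far model is returned).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.optimize

from .spectra import SpectraMatrix

__all__ = [
    "MCRConfig",
    "ComponentModel",
    "FitMetrics",
    "simplisma_init",
    "nnls",
    "apply_closure",
    "apply_equality",
    "fit_mcr",
    "fit_with_basis",
    "compute_metrics",
]


@dataclass(frozen=True)
class MCRConfig:
    """All solver knobs.

    ``fixed_spectra`` has ``n_components`` rows; rows that are all-NaN mark
    free components, numeric rows are held exactly.
    """

    n_components: int
    allowed_noise_pct: float = 10.0
    max_iter: int = 150
    conv_tol_pct: float = 0.1
    closure: str = "equal_area"
    nonneg: bool = True
    fixed_spectra: np.ndarray | None = None
    divergence_patience: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if not 0.0 < self.allowed_noise_pct < 100.0:
            raise ValueError("allowed_noise_pct must be in (0, 100)")
        if self.max_iter < 0:
            raise ValueError("max_iter must be >= 0")
        if not self.conv_tol_pct > 0:
            raise ValueError("conv_tol_pct must be positive")
        if self.closure not in ("equal_area", "none"):
            raise ValueError("closure must be 'equal_area' or 'none'")
        if self.fixed_spectra is not None:
            fixed = np.atleast_2d(np.asarray(self.fixed_spectra, dtype=float))
            if fixed.shape[0] != self.n_components:
                raise ValueError("fixed_spectra must have n_components rows")
            object.__setattr__(self, "fixed_spectra", fixed)

    @property
    def fixed_mask(self) -> np.ndarray:
        if self.fixed_spectra is None:
            return np.zeros(self.n_components, dtype=bool)
        return ~np.isnan(self.fixed_spectra).any(axis=1)


@dataclass
class FitMetrics:
    """Residual-based fit quality.

    ``lack_of_fit_pct = 100 * sqrt(sum E^2 / sum D^2)`` and
    ``explained_variation_pct = 100 * (1 - sum E^2 / sum D^2)``; the two are
    linked by ``explained = 100 * (1 - (lof/100)^2)``.
    """

    lack_of_fit_pct: float
    explained_variation_pct: float


@dataclass
class ComponentModel:
    """Resolved factorization with its iteration trace."""

    concentrations: np.ndarray  # I x A
    spectra: np.ndarray  # A x J
    fixed_mask: np.ndarray  # A
    residual: np.ndarray  # I x J
    n_iter_run: int
    converged: bool
    diverged: bool
    trace: list  # per-iteration dicts: iteration, residual_sd, rss, lack_of_fit_pct


def nnls(a_matrix: np.ndarray, b_vector: np.ndarray) -> np.ndarray:
    """Exact non-negative least squares: argmin ||a x - b||^2 s.t. x >= 0."""
    a = np.asarray(a_matrix, dtype=float)
    b = np.asarray(b_vector, dtype=float).ravel()
    if a.ndim != 2 or a.shape[0] != b.size:
        raise ValueError(f"shape mismatch: a {a.shape}, b {b.shape}")
    x, _ = scipy.optimize.nnls(a, b)
    return x


def _nnls_columns(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Column-wise NNLS: minimize ||a X - b|| with X >= 0; returns X."""
    x = np.empty((a.shape[1], b.shape[1]))
    for j in range(b.shape[1]):
        x[:, j] = scipy.optimize.nnls(a, b[:, j])[0]
    return x


def simplisma_init(
    spectra: SpectraMatrix | np.ndarray,
    n_components: int,
    allowed_noise_pct: float = 10.0,
) -> tuple[np.ndarray, np.ndarray]:
    """SIMPLISMA purest-row selection for initial spectral estimates.

    Purity of row i is ``sigma_i / (mu_i + alpha)`` with the offset
    ``alpha = (allowed_noise_pct / 100) * max(mu)``.  After the first pick,
    candidate purities are weighted by the determinant of the
    correlation-around-origin matrix of the already-selected rows plus the
    candidate, which suppresses rows collinear with earlier picks.

    Returns ``(initial_spectra, indices)``; the initial estimates are the
    selected rows clipped at zero.
    """
    d = spectra.values if isinstance(spectra, SpectraMatrix) else np.atleast_2d(spectra)
    n_rows, n_cols = d.shape
    if not 1 <= n_components <= n_rows:
        raise ValueError("n_components must be between 1 and the number of rows")
    mu = d.mean(axis=1)
    sigma = d.std(axis=1)
    alpha = (allowed_noise_pct / 100.0) * mu.max()
    purity = sigma / (mu + alpha)

    # rows scaled for the correlation-around-origin determinant weighting
    scale = np.sqrt(mu**2 + (sigma + alpha) ** 2)
    scale[scale == 0] = 1.0
    z = d / (scale[:, None] * np.sqrt(n_cols))
    coo = z @ z.T  # n_rows x n_rows correlation-around-origin matrix

    chosen: list[int] = []
    for _ in range(n_components):
        weights = np.empty(n_rows)
        for i in range(n_rows):
            if i in chosen:
                weights[i] = -np.inf
                continue
            idx = chosen + [i]
            weights[i] = np.linalg.det(coo[np.ix_(idx, idx)])
        score = np.where(np.isfinite(weights), weights * purity, -np.inf)
        best = int(np.argmax(score))  # ties resolved to the lowest index
        if not np.isfinite(score[best]) or (chosen and weights[best] <= 1e-12):
            raise ValueError(
                f"only {len(chosen)} numerically independent rows available "
                f"for {n_components} components"
            )
        chosen.append(best)
    indices = np.array(chosen)
    return np.clip(d[indices], 0.0, None), indices


def apply_closure(
    spectra_rows: np.ndarray, free_mask: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Scale each free row to unit sum; return (rows, scale factors).

    The factors let the caller rescale C so that ``C . S`` is unchanged.
    """
    s = np.array(np.atleast_2d(spectra_rows), dtype=float, copy=True)
    if free_mask is None:
        free_mask = np.ones(s.shape[0], dtype=bool)
    factors = np.ones(s.shape[0])
    sums = s.sum(axis=1)
    for a in np.flatnonzero(free_mask):
        if sums[a] <= 0:
            raise ValueError(f"component {a} has zero spectral area (collapsed)")
        s[a] /= sums[a]
        factors[a] = sums[a]
    return s, factors


def apply_equality(
    spectra_rows: np.ndarray,
    fixed_spectra: np.ndarray | None,
    nonneg: bool = True,
) -> np.ndarray:
    """Overwrite constrained rows with their fixed values; free (NaN) rows pass through."""
    s = np.array(np.atleast_2d(spectra_rows), dtype=float, copy=True)
    if fixed_spectra is None:
        return s
    fixed = np.atleast_2d(np.asarray(fixed_spectra, dtype=float))
    if fixed.shape != s.shape:
        raise ValueError("fixed_spectra shape must match the spectra estimate")
    mask = ~np.isnan(fixed).any(axis=1)
    if nonneg and np.any(fixed[mask] < 0):
        raise ValueError("fixed spectra contain negative values with non-negativity on")
    s[mask] = fixed[mask]
    return s


def compute_metrics(
    spectra: SpectraMatrix | np.ndarray, model_or_residual
) -> FitMetrics:
    """Lack of fit and explained variation of a model against D."""
    d = spectra.values if isinstance(spectra, SpectraMatrix) else np.atleast_2d(spectra)
    e = (
        model_or_residual.residual
        if isinstance(model_or_residual, ComponentModel)
        else np.atleast_2d(model_or_residual)
    )
    ss_d = float(np.sum(d**2))
    if ss_d == 0.0:
        raise ValueError("sum of squares of D is zero; metrics undefined")
    ratio = float(np.sum(e**2)) / ss_d
    return FitMetrics(
        lack_of_fit_pct=100.0 * np.sqrt(ratio),
        explained_variation_pct=100.0 * (1.0 - ratio),
    )


def _solve_c(d: np.ndarray, s: np.ndarray, nonneg: bool) -> np.ndarray:
    """Exact least-squares update of C given S (row-wise NNLS when constrained)."""
    if not nonneg:
        return np.linalg.lstsq(s.T, d.T, rcond=None)[0].T
    a = s.T  # J x A
    c = np.empty((d.shape[0], s.shape[0]))
    for i in range(d.shape[0]):
        c[i] = scipy.optimize.nnls(a, d[i])[0]
    return c


def fit_mcr(
    spectra: SpectraMatrix | np.ndarray,
    config: MCRConfig,
    init: np.ndarray | None = None,
) -> tuple[ComponentModel, FitMetrics]:
    """Run the constrained ALS loop.

    Each iteration: (i) C from NNLS given S, (ii) free rows of S from NNLS
    given C (on the residual left by the fixed components), (iii) equality
    constraints re-imposed, (iv) closure with the scale absorbed into C.
    Both half-steps are exact constrained least-squares solves, so the
    residual sum of squares is non-increasing.
    """
    d = spectra.values if isinstance(spectra, SpectraMatrix) else np.atleast_2d(spectra)
    if not np.any(d):
        raise ValueError("mixture matrix is identically zero")
    n_rows, n_cols = d.shape
    a_comp = config.n_components
    fixed_mask = config.fixed_mask
    free_mask = ~fixed_mask
    use_closure = config.closure == "equal_area"

    if init is None:
        s, _ = simplisma_init(d, a_comp, config.allowed_noise_pct)
    else:
        s = np.array(np.atleast_2d(init), dtype=float, copy=True)
        if s.shape != (a_comp, n_cols):
            raise ValueError(f"init must have shape ({a_comp}, {n_cols})")
    s = apply_equality(s, config.fixed_spectra, config.nonneg)
    if use_closure:
        s, _ = apply_closure(s, free_mask)

    trace: list[dict] = []
    rms_d = float(np.sqrt(np.mean(d**2)))
    best = None  # (rss, C, S, E)
    sd_prev = None
    rising = 0
    converged = diverged = False
    n_iter_run = 0
    c = np.zeros((n_rows, a_comp))

    for it in range(1, config.max_iter + 1):
        n_iter_run = it
        c = _solve_c(d, s, config.nonneg)

        if free_mask.any():
            if fixed_mask.any():
                resid_fixed = d - c[:, fixed_mask] @ s[fixed_mask]
            else:
                resid_fixed = d
            if config.nonneg:
                s_free = _nnls_columns(c[:, free_mask], resid_fixed)
            else:
                s_free = np.linalg.lstsq(c[:, free_mask], resid_fixed, rcond=None)[0]
            s[free_mask] = s_free
            s = apply_equality(s, config.fixed_spectra, config.nonneg)
            if use_closure:
                s, factors = apply_closure(s, free_mask)
                c = c * factors[None, :]

        e = d - c @ s
        rss = float(np.sum(e**2))
        sd = float(np.std(e))
        lof = 100.0 * np.sqrt(rss / float(np.sum(d**2)))
        trace.append(
            {"iteration": it, "residual_sd": sd, "rss": rss, "lack_of_fit_pct": lof}
        )
        if best is None or rss <= best[0]:
            best = (rss, c.copy(), s.copy(), e.copy())

        # an (essentially) exact factorization: stop before numerical jitter
        # in the last digits masquerades as divergence
        if sd <= 1e-12 * rms_d:
            converged = True
            break
        if sd_prev is not None:
            if sd > sd_prev:
                rising += 1
                if rising >= config.divergence_patience:
                    diverged = True
                    warnings.warn(
                        "residual SD increased for "
                        f"{config.divergence_patience} consecutive iterations; "
                        "returning best-so-far model",
                        RuntimeWarning,
                        stacklevel=2,
                    )
                    break
            else:
                rising = 0
            if sd_prev == 0.0 or abs(sd_prev - sd) / sd_prev * 100.0 <= config.conv_tol_pct:
                converged = True
                break
        sd_prev = sd

    if best is None:  # max_iter == 0: report the (un-iterated) initial model
        e = d - c @ s
        best = (float(np.sum(e**2)), c, s, e)
    _, c, s, e = best

    model = ComponentModel(
        concentrations=c,
        spectra=s,
        fixed_mask=fixed_mask,
        residual=e,
        n_iter_run=n_iter_run,
        converged=converged,
        diverged=diverged,
        trace=trace,
    )
    return model, compute_metrics(d, e)


def fit_with_basis(
    spectra: SpectraMatrix | np.ndarray,
    basis_spectra: np.ndarray,
    n_free: int,
    config: MCRConfig | None = None,
) -> tuple[ComponentModel, FitMetrics]:
    """Equality-constrained fit: ``basis`` rows held fixed plus ``n_free`` free ones.

    Basis rows are area-normalized once on input and then held exact.  Free
    components are initialized by SIMPLISMA on the residual of D after a
    non-negative projection onto the basis.
    """
    d = spectra.values if isinstance(spectra, SpectraMatrix) else np.atleast_2d(spectra)
    basis = np.atleast_2d(np.asarray(basis_spectra, dtype=float))
    if np.any(basis < 0):
        raise ValueError("basis spectra must be non-negative on the working grid")
    if n_free < 0:
        raise ValueError("n_free must be >= 0")
    basis_norm, _ = apply_closure(basis)
    n_fixed = basis_norm.shape[0]
    a_comp = n_fixed + n_free

    fixed = np.full((a_comp, d.shape[1]), np.nan)
    fixed[:n_fixed] = basis_norm
    base_cfg = config or MCRConfig(n_components=a_comp)
    cfg = replace(base_cfg, n_components=a_comp, fixed_spectra=fixed)

    c_basis = _solve_c(d, basis_norm, cfg.nonneg)
    residual = d - c_basis @ basis_norm
    init = np.empty((a_comp, d.shape[1]))
    init[:n_fixed] = basis_norm
    if n_free:
        free_init, _ = simplisma_init(residual, n_free, cfg.allowed_noise_pct)
        # a residual row can be ~0 after clipping; fall back to a flat guess
        for k in range(n_free):
            if not np.any(free_init[k] > 0):
                free_init[k] = 1.0
        init[n_fixed:] = free_init
    return fit_mcr(d, cfg, init=init)
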