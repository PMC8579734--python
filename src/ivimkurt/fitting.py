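"""Voxel-wise estimation of IVIM-kurtosis parameters and two-point ADC.

The estimator is a bound-constrained nonlinear least-squares inversion of

    S(b)/S0 = f·exp(−b·D*) + (1−f)·exp(−b·D + (b·D)²·K/6)

jointly over all b-values of the scheme, with S0 fixed to the measured
b = 0 signal by default (configurable to a free parameter).

The objective is multi-modal (notably along a near-degenerate valley where
the perfusion and tissue compartments exchange roles when D* ≈ D, and where
a slow perfusion plateau mimics the kurtosis upturn). Start selection
therefore uses a variable-projection coarse grid: f is conditionally linear
in the model, so for every (D, D*, K) grid combination the optimal f has a
closed form, and the grid cost is evaluated vectorized. The best candidates
— kept diverse across decades of D* — seed the trust-region polishes
(default 6 starts); the best converged start is retained. When the best
cost indicates effectively noiseless data but is still above the exact-fit
floor, a deterministic escalation kicks in: a compartment-swap start, a
denser D* grid, and seeded random restarts, until the exact fit is found or
the budget is exhausted. Everything is deterministic given input + options.

The monoexponential ADC map uses the exact two-point inverse on the
b = 50 and b = 1500 s/mm² volumes; voxels whose log-ratio would be
negative are clamped to ADC = 0 and flagged.

The statsmodels-style surface — ``IVIMKurtosisModel(series).fit()``
returning :class:`IVIMKurtosisResults` — wraps the per-voxel functions
``fit_ivim_kurtosis_voxel`` / ``fit_maps`` / ``compute_adc_map``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .exceptions import ConfigurationError, ValidationError
from .series import BValueScheme, DWISeries, DEFAULT_SCHEME
from .signal_models import DiffusionParams

__all__ = [
    "DWISeries",
    "FitOptions",
    "FitDiagnostics",
    "ParameterMaps",
    "fit_ivim_kurtosis_voxel",
    "fit_maps",
    "compute_adc_map",
    "IVIMKurtosisModel",
    "IVIMKurtosisResults",
    "MonoexponentialModel",
    "MonoexponentialResults",
    "STATUS_CONVERGED",
    "STATUS_EXCLUDED",
    "STATUS_FAILED",
    "STATUS_UNFITTED",
]

STATUS_UNFITTED = 0
STATUS_CONVERGED = 1
STATUS_EXCLUDED = 2
STATUS_FAILED = 3

_STATUS_NAMES = {0: "unfitted", 1: "converged", 2: "excluded", 3: "failed"}


@dataclass(frozen=True)
class FitOptions:
    """Configuration of the voxel-wise IVIM-kurtosis fit.

    Attributes
    ----------
    bounds : mapping of parameter name to (lo, hi)
        Box constraints; defaults D ∈ [0, 4e-3], D* ∈ [0, 0.5] mm²/s,
        f ∈ [0, 1], K ∈ [0, 30]. Wide enough to represent the published
        per-class percentile ranges.
    multistart : int
        Number of polished starts drawn from the variable-projection grid
        (≥ 1), kept diverse across D* decades.
    s0_mode : {"fixed-to-b0", "free"}
        Fix S0 to the mean of the b = 0 acquisitions, or fit it.
    noise_floor : float
        Voxels whose mean signal at b ≥ 1000 falls below this (absolute)
        level are excluded rather than fitted.
    ftol, xtol, gtol : float
        Trust-region convergence tolerances.
    refine_threshold : float
        Residual cost (Σr², normalized signal) below which the data are
        treated as effectively noiseless and the exact-fit escalation runs.
    refine_target : float
        Escalation stops once the cost falls below this exact-fit floor.
    refine_rounds : int
        Maximum seeded random-restart rounds during escalation.
    """

    bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "D": (0.0, 4.0e-3),
            "Dstar": (0.0, 0.5),
            "f": (0.0, 1.0),
            "K": (0.0, 30.0),
        }
    )
    multistart: int = 6
    s0_mode: str = "fixed-to-b0"
    noise_floor: float = 0.0
    ftol: float = 1e-10
    xtol: float = 1e-10
    gtol: float = 1e-10
    max_nfev: int | None = 50
    refine_threshold: float = 3e-5
    refine_target: float = 1e-24
    refine_rounds: int = 4
    engine: str = "batched"
    batch_iters: int = 60

    def __post_init__(self) -> None:
        if self.multistart < 1:
            raise ValidationError("multistart must be >= 1")
        if self.s0_mode not in ("fixed-to-b0", "free"):
            raise ValidationError(f"unknown s0_mode {self.s0_mode!r}")
        for p in ("D", "Dstar", "f", "K"):
            lo, hi = self.bounds[p]
            if not lo < hi:
                raise ValidationError(f"empty bound interval for {p}")
        if not 0.0 <= self.bounds["f"][0] and self.bounds["f"][1] <= 1.0:
            raise ValidationError("f bounds must nest inside [0, 1]")
        if self.engine not in ("batched", "voxel"):
            raise ValidationError(f"unknown engine {self.engine!r}")


@dataclass(frozen=True)
class FitDiagnostics:
    """Per-voxel fit metadata: status, residual 2-norm, winning start index,
    total residual evaluations."""

    status: int
    residual_norm: float
    start_index: int
    nfev: int

    @property
    def status_name(self) -> str:
        return _STATUS_NAMES[self.status]


def _model_and_jac(theta: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """IVIM-kurtosis model values and Jacobian wrt (D, D*, f, K)."""
    D, Ds, f, K = theta
    bD = b * D
    e1 = np.exp(-b * Ds)
    e2 = np.exp(-bD + bD * bD * K / 6.0)
    m = f * e1 + (1.0 - f) * e2
    jac = np.empty((b.size, 4))
    jac[:, 0] = (1.0 - f) * e2 * (b * bD * K / 3.0 - b)  # d/dD
    jac[:, 1] = -f * b * e1  # d/dD*
    jac[:, 2] = e1 - e2  # d/df
    jac[:, 3] = (1.0 - f) * e2 * bD * bD / 6.0  # d/dK
    return m, jac


class _StartGrid:
    """Cached variable-projection start grid for one b-value vector.

    f enters the model linearly: S/S0 = e2 + f·(e1 − e2) with
    e1 = exp(−b·D*) and e2 = exp(−b·D + (b·D)²K/6). For every (D, K, D*)
    grid combination the least-squares-optimal f is closed-form, so the
    whole coarse cost surface is evaluated vectorized.
    """

    def __init__(self, b: np.ndarray, n_dstar: int = 20):
        self.b = b
        self.D_grid = np.geomspace(1e-4, 3.5e-3, 24)
        self.Ds_grid = np.geomspace(1e-5, 0.1, n_dstar)
        self.K_grid = np.array([0.0, 0.3, 0.7, 1.2, 2.0, 3.5, 6.0, 9.0, 15.0])
        self.E1 = np.exp(-np.outer(self.Ds_grid, b))
        bD = np.outer(self.D_grid, b)
        # clamp the kurtosis upturn: combos whose model explodes at high b
        # are useless starts, and unclamped they wreck the quadratic-in-f
        # cost expansion through catastrophic cancellation
        self.E2 = np.minimum(
            np.exp(-bD[:, None, :] + (bD**2)[:, None, :] * self.K_grid[None, :, None] / 6.0),
            10.0,
        )
        # (nd, nk, nds, nb) difference tensor, shared across voxels
        self.diff = self.E1[None, None, :, :] - self.E2[:, :, None, :]
        self.den = np.maximum(np.einsum("dksb,dksb->dks", self.diff, self.diff), 1e-30)

    def candidates(self, y: np.ndarray, top: int) -> list[np.ndarray]:
        """Best (D, D*, f, K) start per D* region, diverse across decades."""
        resid0 = np.broadcast_to(y[None, None, None, :] - self.E2[:, :, None, :], self.diff.shape)
        f = np.clip(np.einsum("dksb,dksb->dks", self.diff, resid0) / self.den, 0.0, 1.0)
        model = self.E2[:, :, None, :] + f[..., None] * self.diff
        cost = np.sum((model - y[None, None, None, :]) ** 2, axis=-1)
        nds = cost.shape[2]
        flat = cost.reshape(-1, nds)
        best_dk = flat.argmin(axis=0)
        order = np.argsort(flat.min(axis=0))
        chosen: list[int] = []
        out: list[np.ndarray] = []
        min_sep = np.log(2.5)
        for s_i in order:
            if any(abs(np.log(self.Ds_grid[s_i] / self.Ds_grid[c])) < min_sep for c in chosen):
                continue
            d_i, k_i = np.unravel_index(best_dk[s_i], cost.shape[:2])
            out.append(
                np.array([self.D_grid[d_i], self.Ds_grid[s_i], f[d_i, k_i, s_i], self.K_grid[k_i]])
            )
            chosen.append(s_i)
            if len(out) == top:
                break
        return out


_GRID_CACHE: dict[tuple, _StartGrid] = {}


def _start_grid(b: np.ndarray, n_dstar: int = 20) -> _StartGrid:
    key = (tuple(b), n_dstar)
    if key not in _GRID_CACHE:
        if len(_GRID_CACHE) > 8:  # bound memory for exotic schemes
            _GRID_CACHE.clear()
        _GRID_CACHE[key] = _StartGrid(b, n_dstar)
    return _GRID_CACHE[key]


def _model_batch(X: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Model values (N, nb) and Jacobians (N, nb, 4) for a parameter batch."""
    D = X[:, 0:1]
    Ds = X[:, 1:2]
    f = X[:, 2:3]
    K = X[:, 3:4]
    bD = b[None, :] * D
    e1 = np.exp(-b[None, :] * Ds)
    e2 = np.exp(-bD + bD * bD * K / 6.0)
    m = f * e1 + (1.0 - f) * e2
    J = np.empty(X.shape[:1] + (b.size, 4))
    J[:, :, 0] = (1.0 - f) * e2 * (b[None, :] * bD * K / 3.0 - b[None, :])
    J[:, :, 1] = -f * b[None, :] * e1
    J[:, :, 2] = e1 - e2
    J[:, :, 3] = (1.0 - f) * e2 * bD * bD / 6.0
    return m, J


def _batch_candidates(Y: np.ndarray, grid: _StartGrid, top: int) -> np.ndarray:
    """Diverse VP-grid starts for every voxel; returns (N, top, 4).

    Same selection rule as :meth:`_StartGrid.candidates`, evaluated for a
    whole chunk of voxels at once using the expanded quadratic-in-f cost
    (no large intermediate tensors).
    """
    E2 = grid.E2  # (nd, nk, nb)
    diff = grid.diff  # (nd, nk, nds, nb)
    den = grid.den  # (nd, nk, nds)
    r0 = Y[:, None, None, :] - E2[None, :, :, :]  # (N, nd, nk, nb)
    a0 = np.sum(r0 * r0, axis=-1)  # (N, nd, nk)
    num = np.einsum("cdkb,dksb->cdks", r0, diff)
    f = np.clip(num / den[None], 0.0, 1.0)
    cost = a0[..., None] - 2.0 * f * num + f * f * den[None]
    N = Y.shape[0]
    nds = cost.shape[3]
    flat = cost.reshape(N, -1, nds)
    best_dk = flat.argmin(axis=1)  # (N, nds)
    cost_s = flat.min(axis=1)
    order = np.argsort(cost_s, axis=1)
    log_ds = np.log(grid.Ds_grid)
    min_sep = np.log(2.5)
    out = np.empty((N, top, 4))
    for c in range(N):
        chosen: list[int] = []
        k_out = 0
        for s_i in order[c]:
            if any(abs(log_ds[s_i] - log_ds[j]) < min_sep for j in chosen):
                continue
            d_i, k_i = np.unravel_index(best_dk[c, s_i], cost.shape[1:3])
            out[c, k_out] = (
                grid.D_grid[d_i], grid.Ds_grid[s_i], f[c, d_i, k_i, s_i], grid.K_grid[k_i]
            )
            chosen.append(s_i)
            k_out += 1
            if k_out == top:
                break
        while k_out < top:  # degenerate: repeat the best start
            out[c, k_out] = out[c, 0]
            k_out += 1
    return out


def _batch_lm(
    Y: np.ndarray, b: np.ndarray, starts: np.ndarray,
    lo: np.ndarray, hi: np.ndarray, n_iter: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Bound-constrained batched Levenberg–Marquardt over all voxels at once.

    Box constraints are enforced through per-parameter sigmoid transforms —
    on the log scale for the rate parameters D and D* (which span decades)
    and on the linear scale for f and K; damping is adapted per voxel.
    Returns the best (params, cost) over the provided start sets.
    Fully deterministic.
    """
    N, S, _ = starts.shape
    log_scale = np.array([True, True, False, False])
    lo_eff = np.where(log_scale, np.maximum(lo, 1e-7), lo)
    a = np.where(log_scale, np.log(np.where(log_scale, lo_eff, 1.0)), lo_eff)
    bb = np.where(log_scale, np.log(np.where(log_scale, hi, 1.0)), hi)
    span = bb - a

    def to_u(X):
        w = np.where(log_scale, np.log(np.maximum(X, 1e-300)), X)
        z = np.clip((w - a) / span, 0.02, 0.98)
        return np.log(z / (1.0 - z))

    def to_x(U):
        w = a + span / (1.0 + np.exp(-U))
        return np.where(log_scale, np.exp(w), w)

    def dx_du(X):
        w = np.where(log_scale, np.log(np.maximum(X, 1e-300)), X)
        z = (w - a) / span
        dz = span * z * (1.0 - z)
        return np.where(log_scale, X * dz, dz)

    best_x = np.empty((N, 4))
    best_cost = np.full(N, np.inf)
    eye = np.eye(4)
    for s in range(S):
        U = to_u(starts[:, s, :])
        X = to_x(U)
        m, J = _model_batch(X, b)
        r = m - Y
        cost = np.sum(r * r, axis=1)
        lam = np.full(N, 1e-3)
        for _ in range(n_iter):
            sig = dx_du(X)
            Ju = J * sig[:, None, :]
            JTJ = np.einsum("nbi,nbj->nij", Ju, Ju)
            g = np.einsum("nbi,nb->ni", Ju, r)
            diag = np.einsum("nii->ni", JTJ)
            A = JTJ + lam[:, None, None] * (diag[:, None, :] * eye[None]) + 1e-12 * eye[None]
            try:
                delta = np.linalg.solve(A, -g[..., None])[..., 0]
            except np.linalg.LinAlgError:
                break
            U_new = np.clip(U + delta, -40.0, 40.0)
            X_new = to_x(U_new)
            m_new, J_new = _model_batch(X_new, b)
            r_new = m_new - Y
            cost_new = np.sum(r_new * r_new, axis=1)
            improved = cost_new < cost
            U = np.where(improved[:, None], U_new, U)
            X = to_x(U)
            J = np.where(improved[:, None, None], J_new, J)
            r = np.where(improved[:, None], r_new, r)
            cost = np.where(improved, cost_new, cost)
            lam = np.where(improved, lam / 3.0, lam * 4.0)
            lam = np.clip(lam, 1e-10, 1e8)
        better = cost < best_cost
        best_x[better] = X[better]
        best_cost[better] = cost[better]
    return best_x, best_cost


def fit_ivim_kurtosis_voxel(
    signals, scheme: BValueScheme, opts: FitOptions = FitOptions()
) -> tuple[DiffusionParams | None, FitDiagnostics]:
    """Fit one voxel's signal vector; never raises for bad data mid-map.

    Returns ``(params, diagnostics)``; ``params`` is ``None`` when the voxel
    is excluded (all-zero / negative-dominated / below the noise floor) or
    when no start converges (status ``failed``).
    """
    sig = np.asarray(signals, dtype=float)
    b = scheme.b
    if sig.shape != b.shape:
        raise ValidationError("signal vector length must equal the scheme length")
    if not np.all(np.isfinite(sig)):
        return None, FitDiagnostics(STATUS_EXCLUDED, np.nan, -1, 0)
    if (sig > 0).sum() < 5 or np.all(sig <= 0):
        return None, FitDiagnostics(STATUS_EXCLUDED, np.nan, -1, 0)

    if opts.s0_mode == "fixed-to-b0":
        b0 = np.isclose(b, 0.0)
        if not b0.any():
            raise ConfigurationError("s0_mode='fixed-to-b0' requires a b=0 acquisition")
        S0 = float(sig[b0].mean())
        if S0 <= 0:
            return None, FitDiagnostics(STATUS_EXCLUDED, np.nan, -1, 0)
    else:
        S0 = float(max(sig.max(), 1e-12))

    high_b = b >= 1000
    if high_b.any() and sig[high_b].mean() < opts.noise_floor:
        return None, FitDiagnostics(STATUS_EXCLUDED, np.nan, -1, 0)

    y = sig / S0
    lo = np.array([opts.bounds[p][0] for p in ("D", "Dstar", "f", "K")])
    hi = np.array([opts.bounds[p][1] for p in ("D", "Dstar", "f", "K")])
    free_s0 = opts.s0_mode == "free"
    if free_s0:
        lo = np.append(lo, 1e-6)
        hi = np.append(hi, 10.0)

    def resid(theta):
        m, _ = _model_and_jac(theta[:4], b)
        scale = theta[4] if free_s0 else 1.0
        return scale * m - y

    def jac(theta):
        m, j = _model_and_jac(theta[:4], b)
        if free_s0:
            j = np.column_stack([theta[4] * j, m])
        return j

    x_scale = np.array([1e-3, 1e-2, 0.1, 1.0])
    if free_s0:
        x_scale = np.append(x_scale, 1.0)

    eps = 1e-15

    def polish(x0_core: np.ndarray, tight: bool = False):
        x0 = np.asarray(x0_core, dtype=float)
        if free_s0 and x0.size == 4:
            x0 = np.append(x0, 1.0)
        x0 = np.clip(x0, lo + eps, hi - eps)
        tol = np.finfo(float).eps if tight else None
        try:
            return least_squares(
                resid, x0, jac=jac, bounds=(lo, hi), method="trf",
                ftol=tol or opts.ftol, xtol=tol or opts.xtol, gtol=tol or opts.gtol,
                x_scale=x_scale,
                max_nfev=1000 if tight else opts.max_nfev,
            )
        except Exception:
            return None

    grid = _start_grid(b)
    best = None
    best_cost = np.inf
    best_start = -1
    nfev = 0
    # 2·cost on normalized signals; the VP grid works on Σr² directly
    for si, x0 in enumerate(grid.candidates(y, opts.multistart)):
        res = polish(x0)
        if res is None:
            continue
        nfev += res.nfev
        if res.cost < best_cost:
            best_cost, best, best_start = res.cost, res, si
        if best_cost < opts.refine_target:
            break

    if best is not None and best_cost <= 10.0 * opts.refine_threshold:
        # settle the incumbent at machine tolerance before judging whether
        # the data admit an exact fit
        res = polish(best.x[:4] if not free_s0 else best.x, tight=True)
        if res is not None:
            nfev += res.nfev
            if res.cost < best_cost:
                best_cost, best = res.cost, res

    # Exact-fit escalation for effectively noiseless data: the flat valley
    # where the compartments exchange roles hides the zero-residual optimum
    # from coarse starts; resolve it with a swap start, a denser D* profile,
    # a valley walk along the flattest Jacobian directions and seeded
    # (deterministic) random restarts. All polishing here runs at machine
    # tolerance so the exact-fit floor is reachable.
    if best is not None and opts.refine_target < best_cost <= opts.refine_threshold:

        def try_starts(starts) -> None:
            nonlocal best, best_cost, nfev
            for x0 in starts:
                res = polish(x0, tight=True)
                if res is None:
                    continue
                nfev += res.nfev
                if res.cost < best_cost:
                    best_cost, best = res.cost, res
                if best_cost < opts.refine_target:
                    return

        def valley_walk(max_iter: int = 20) -> None:
            """Greedy basin hops along the two flattest (scaled) Jacobian
            singular directions of the incumbent solution."""
            nonlocal best, best_cost, nfev
            for _ in range(max_iter):
                if best_cost < opts.refine_target:
                    return
                J = jac(best.x) * x_scale[None, :]
                try:
                    _, _, Vt = np.linalg.svd(J, full_matrices=False)
                except np.linalg.LinAlgError:
                    return
                cands = [
                    best.x + sgn * h * v * x_scale
                    for v in (Vt[-1], Vt[-2])
                    for h in (0.05, 0.15, 0.5, 1.5)
                    for sgn in (1.0, -1.0)
                ]
                results = [polish(c[:4] if not free_s0 else c, tight=True) for c in cands]
                results = [r for r in results if r is not None]
                nfev += sum(r.nfev for r in results)
                if not results:
                    return
                rbest = min(results, key=lambda r: r.cost)
                if rbest.cost < best_cost:
                    best_cost, best = rbest.cost, rbest
                else:
                    return

        xb = best.x[:4]
        swap: list[np.ndarray] = [xb]
        if lo[0] <= xb[1] <= hi[0] and lo[1] <= xb[0] <= hi[1]:
            swap.append(np.array([xb[1], xb[0], 1.0 - xb[2], xb[3]]))
        try_starts(swap)
        if best_cost >= opts.refine_target:
            try_starts(_start_grid(b, 64).candidates(y, 10))
        if best_cost >= opts.refine_target:
            valley_walk()
        rng = np.random.default_rng(1234567)
        for _round in range(opts.refine_rounds):
            if best_cost < opts.refine_target:
                break
            try_starts(
                np.array(
                    [
                        np.exp(rng.uniform(np.log(5e-5), np.log(3.9e-3))),
                        np.exp(rng.uniform(np.log(1e-5), np.log(0.1))),
                        rng.uniform(0.0, 0.9),
                        rng.uniform(0.0, 10.0),
                    ]
                )
                for _ in range(24)
            )
            if best_cost >= opts.refine_target:
                valley_walk(6)
        res = polish(best.x[:4] if not free_s0 else best.x, tight=True)
        if res is not None and res.cost < best_cost:
            best_cost, best = res.cost, res

    if best is None:
        return None, FitDiagnostics(STATUS_FAILED, np.nan, -1, nfev)

    best_cost = best.cost
    D, Ds, f, K = best.x[:4]
    s0_fit = float(best.x[4] * S0) if free_s0 else S0
    params = DiffusionParams(
        D=float(np.clip(D, 0.0, None)),
        Dstar=float(np.clip(Ds, 0.0, None)),
        f=float(np.clip(f, 0.0, 1.0)),
        K=float(np.clip(K, 0.0, None)),
        S0=s0_fit,
    )
    resid_norm = float(np.sqrt(2.0 * best_cost))
    return params, FitDiagnostics(STATUS_CONVERGED, resid_norm, best_start, nfev)


@dataclass
class ParameterMaps:
    """Whole-volume fitted maps plus per-voxel status and residual norm.

    Quantities are 3-D arrays on the input grid, NaN outside fitted voxels
    (never silent zeros). ``status`` uses the module's STATUS_* codes.
    ``adc_clamped`` flags voxels whose two-point log-ratio was negative.
    """

    D: np.ndarray
    Dstar: np.ndarray
    f: np.ndarray
    K: np.ndarray
    S0: np.ndarray
    status: np.ndarray
    residual_norm: np.ndarray
    ADC: np.ndarray | None = None
    adc_clamped: np.ndarray | None = None
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    _UNIT_SCALE = {"D": 1e3, "Dstar": 1e3, "ADC": 1e3}

    def get(self, name: str, scaled: bool = False) -> np.ndarray:
        """A parameter map by name; ``scaled=True`` applies the ×10³
        display convention to D, D* and ADC."""
        arr = getattr(self, name)
        if arr is None:
            raise KeyError(f"map {name!r} was not computed")
        if scaled and name in self._UNIT_SCALE:
            return arr * self._UNIT_SCALE[name]
        return arr

    def to_niftis(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = {}
        for name in ("D", "Dstar", "f", "K", "S0", "ADC", "residual_norm"):
            arr = getattr(self, name)
            if arr is None:
                continue
            img = nib.Nifti1Image(np.asarray(arr, dtype=np.float64), self.affine)
            scale = self._UNIT_SCALE.get(name)
            img.header["descrip"] = (
                f"{name} x1e-3 mm^2/s (stored in mm^2/s)" if scale else name
            ).encode()[:79]
            p = outdir / f"{name}.nii"
            nib.save(img, str(p))
            written[name] = p
        img = nib.Nifti1Image(self.status.astype(np.int16), self.affine)
        p = outdir / "status.nii"
        nib.save(img, str(p))
        written["status"] = p
        return written


def _fit_mask_batched(series: DWISeries, mask: np.ndarray, opts: FitOptions, maps, status):
    """Batched-LM engine over all in-mask voxels, with automatic per-voxel
    exact-fit refinement where the residual indicates noiseless data."""
    b = series.scheme.b
    idx = np.argwhere(mask)
    sig = series.data[mask]  # (N, nb)
    b0 = np.isclose(b, 0.0)
    if not b0.any():
        raise ConfigurationError("the batched engine requires a b=0 acquisition")
    S0 = sig[:, b0].mean(axis=1)
    pos_ok = (sig > 0).sum(axis=1) >= 5
    high_b = b >= 1000
    floor_ok = (
        sig[:, high_b].mean(axis=1) >= opts.noise_floor if high_b.any() else np.ones(len(sig), bool)
    )
    valid = pos_ok & (S0 > 0) & floor_ok
    for i, j, k in idx[~valid]:
        status[i, j, k] = STATUS_EXCLUDED
    if valid.any():
        Y = sig[valid] / S0[valid, None]
        lo = np.array([opts.bounds[p][0] for p in ("D", "Dstar", "f", "K")])
        hi = np.array([opts.bounds[p][1] for p in ("D", "Dstar", "f", "K")])
        grid = _start_grid(b)
        X = np.empty((len(Y), 4))
        cost = np.empty(len(Y))
        for c0 in range(0, len(Y), 256):  # chunk to bound candidate-tensor memory
            sl = slice(c0, min(c0 + 256, len(Y)))
            starts = _batch_candidates(Y[sl], grid, opts.multistart)
            X[sl], cost[sl] = _batch_lm(Y[sl], b, starts, lo, hi, opts.batch_iters)
        vi = np.flatnonzero(valid)
        # Exact-fit refinement: when the whole map is effectively noiseless
        # (median residual at the exact-fit floor) every near-exact voxel is
        # worth escalating; in a noisy map only a fluke voxel would qualify,
        # so the bar is much stricter there.
        half_cost = 0.5 * cost
        map_thr = opts.refine_threshold if np.median(half_cost) <= 1e-8 else 1e-7
        for n, v in enumerate(vi):
            i, j, k = idx[v]
            if half_cost[n] <= map_thr:
                # effectively noiseless: hand over to the exact per-voxel path
                params, diag = fit_ivim_kurtosis_voxel(series.data[i, j, k, :], series.scheme, opts)
                status[i, j, k] = diag.status
                maps["residual_norm"][i, j, k] = diag.residual_norm
                if params is not None:
                    for name, val in (("D", params.D), ("Dstar", params.Dstar),
                                      ("f", params.f), ("K", params.K), ("S0", params.S0)):
                        maps[name][i, j, k] = val
                continue
            status[i, j, k] = STATUS_CONVERGED
            maps["D"][i, j, k] = X[n, 0]
            maps["Dstar"][i, j, k] = X[n, 1]
            maps["f"][i, j, k] = X[n, 2]
            maps["K"][i, j, k] = X[n, 3]
            maps["S0"][i, j, k] = S0[v]
            maps["residual_norm"][i, j, k] = np.sqrt(cost[n])


def fit_maps(
    series: DWISeries, mask: np.ndarray | None = None, opts: FitOptions = FitOptions()
) -> ParameterMaps:
    """Apply the voxel-wise IVIM-kurtosis fit to every in-mask voxel.

    ``mask`` may be boolean or integer-labelled (non-zero = fit) or ``None``
    for the whole volume. Deterministic given inputs and options. The
    default "batched" engine runs a vectorized bound-constrained
    Levenberg–Marquardt over all voxels at once (voxels consistent with an
    exact fit are handed to the per-voxel escalating path); the "voxel"
    engine runs the per-voxel path everywhere.
    """
    grid = series.grid_shape
    if mask is None:
        mask = np.ones(grid, dtype=bool)
    mask = np.asarray(mask)
    if mask.shape != grid:
        raise ValidationError("mask grid does not match the series grid")
    mask = mask != 0
    if not mask.any():
        raise ValidationError("empty mask")

    maps = {n: np.full(grid, np.nan) for n in ("D", "Dstar", "f", "K", "S0", "residual_norm")}
    status = np.zeros(grid, dtype=np.int8)
    if opts.engine == "batched" and opts.s0_mode == "fixed-to-b0":
        _fit_mask_batched(series, mask, opts, maps, status)
    else:
        for i, j, k in np.argwhere(mask):
            params, diag = fit_ivim_kurtosis_voxel(series.data[i, j, k, :], series.scheme, opts)
            status[i, j, k] = diag.status
            maps["residual_norm"][i, j, k] = diag.residual_norm
            if params is not None:
                maps["D"][i, j, k] = params.D
                maps["Dstar"][i, j, k] = params.Dstar
                maps["f"][i, j, k] = params.f
                maps["K"][i, j, k] = params.K
                maps["S0"][i, j, k] = params.S0

    out = ParameterMaps(
        D=maps["D"],
        Dstar=maps["Dstar"],
        f=maps["f"],
        K=maps["K"],
        S0=maps["S0"],
        status=status,
        residual_norm=maps["residual_norm"],
        affine=series.affine,
    )
    if series.scheme.contains(50) and series.scheme.contains(1500):
        adc, clamped = compute_adc_map(series, mask=mask)
        out.ADC = adc
        out.adc_clamped = clamped
    return out


def compute_adc_map(
    series: DWISeries,
    b_low: float = 50.0,
    b_high: float = 1500.0,
    mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-point monoexponential ADC map from the b_low and b_high volumes.

    Returns ``(adc, clamped)``: ADC in mm²/s (NaN outside the mask or where
    either signal is non-positive) and a boolean flag map of voxels whose
    negative log-ratio was clamped to ADC = 0.
    """
    if not (series.scheme.contains(b_low) and series.scheme.contains(b_high)):
        raise ConfigurationError(
            f"scheme must contain b={b_low} and b={b_high} s/mm² for the two-point ADC"
        )
    s_low = series.volume(b_low)
    s_high = series.volume(b_high)
    if mask is None:
        mask = np.ones(series.grid_shape, dtype=bool)
    mask = np.asarray(mask) != 0

    adc = np.full(series.grid_shape, np.nan)
    clamped = np.zeros(series.grid_shape, dtype=bool)
    valid = mask & (s_low > 0) & (s_high > 0)
    with np.errstate(divide="ignore"):
        raw = np.log(s_low[valid] / s_high[valid]) / (b_high - b_low)
    neg = raw < 0
    raw[neg] = 0.0
    adc[valid] = raw
    clamped[valid] = neg
    return adc, clamped


class IVIMKurtosisModel:
    """Joint IVIM-kurtosis model of a multi-b series (statsmodels-style).

    Parameters
    ----------
    series : DWISeries
        The 4-D data with its acquisition scheme.
    mask : ndarray, optional
        Boolean or labelled mask of voxels to fit; whole volume if omitted.
    options : FitOptions, optional
    """

    def __init__(self, series: DWISeries, mask: np.ndarray | None = None,
                 options: FitOptions | None = None):
        self.series = series
        self.mask = mask
        self.options = options or FitOptions()

    @classmethod
    def from_signals(cls, signals, bvalues, nex=None, **kw) -> "IVIMKurtosisModel":
        """Build a single-voxel model from a plain signal vector."""
        signals = np.asarray(signals, dtype=float)
        scheme = BValueScheme(tuple(bvalues), tuple(nex) if nex is not None else (1,) * len(bvalues))
        series = DWISeries(signals.reshape(1, 1, 1, -1), scheme)
        return cls(series, **kw)

    def fit(self) -> "IVIMKurtosisResults":
        maps = fit_maps(self.series, self.mask, self.options)
        return IVIMKurtosisResults(self, maps)


class IVIMKurtosisResults:
    """Fitted parameter maps with diagnostics and a summary table."""

    def __init__(self, model: IVIMKurtosisModel, maps: ParameterMaps):
        self.model = model
        self.maps = maps

    @property
    def n_converged(self) -> int:
        return int((self.maps.status == STATUS_CONVERGED).sum())

    @property
    def n_excluded(self) -> int:
        return int((self.maps.status == STATUS_EXCLUDED).sum())

    @property
    def n_failed(self) -> int:
        return int((self.maps.status == STATUS_FAILED).sum())

    def params_frame(self) -> pd.DataFrame:
        """One row per fitted voxel: indices, parameters, residual norm."""
        rows = []
        conv = np.argwhere(self.maps.status == STATUS_CONVERGED)
        for i, j, k in conv:
            rows.append(
                dict(
                    i=i, j=j, k=k,
                    D=self.maps.D[i, j, k],
                    Dstar=self.maps.Dstar[i, j, k],
                    f=self.maps.f[i, j, k],
                    K=self.maps.K[i, j, k],
                    S0=self.maps.S0[i, j, k],
                    residual_norm=self.maps.residual_norm[i, j, k],
                )
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Text summary in the spirit of a statsmodels results table."""
        df = self.params_frame()
        lines = [
            "IVIM-kurtosis voxel-wise fit",
            "=" * 60,
            f"voxels converged: {self.n_converged}   excluded: {self.n_excluded}"
            f"   failed: {self.n_failed}",
            f"S0 handling: {self.model.options.s0_mode}   "
            f"multistart: {self.model.options.multistart}",
            "-" * 60,
        ]
        if len(df):
            stats = df[["D", "Dstar", "f", "K"]].agg(["mean", "std", "min", "max"])
            for p in ("D", "Dstar", "f", "K"):
                scale = 1e3 if p in ("D", "Dstar") else 1.0
                unit = " x1e-3 mm^2/s" if p in ("D", "Dstar") else ""
                lines.append(
                    f"{p:>6}: mean {stats.loc['mean', p] * scale:8.4f}  "
                    f"sd {stats.loc['std', p] * scale:8.4f}  "
                    f"range [{stats.loc['min', p] * scale:.4f}, "
                    f"{stats.loc['max', p] * scale:.4f}]{unit}"
                )
        return "\n".join(lines)

    def plot_fit(self, voxel: tuple[int, int, int], ax=None):
        """Overlay the fitted decay curve on one voxel's measured signals."""
        import matplotlib.pyplot as plt

        from .signal_models import ivim_kurtosis_signal

        i, j, k = voxel
        if ax is None:
            _, ax = plt.subplots()
        b = self.model.series.scheme.b
        sig = self.model.series.data[i, j, k, :]
        ax.plot(b, sig, "o", label="measured")
        p = DiffusionParams(
            D=self.maps.D[i, j, k], Dstar=self.maps.Dstar[i, j, k],
            f=self.maps.f[i, j, k], K=self.maps.K[i, j, k], S0=self.maps.S0[i, j, k],
        )
        bb = np.linspace(b.min(), b.max(), 200)
        ax.plot(bb, p.S0 * np.asarray(ivim_kurtosis_signal(bb, p)), "-", label="fit")
        ax.set_xlabel("b (s/mm²)")
        ax.set_ylabel("signal")
        ax.legend()
        return ax


class MonoexponentialModel:
    """Two-point monoexponential ADC model of a multi-b series."""

    def __init__(self, series: DWISeries, mask: np.ndarray | None = None,
                 b_low: float = 50.0, b_high: float = 1500.0):
        self.series = series
        self.mask = mask
        self.b_low = b_low
        self.b_high = b_high

    def fit(self) -> "MonoexponentialResults":
        adc, clamped = compute_adc_map(self.series, self.b_low, self.b_high, self.mask)
        return MonoexponentialResults(self, adc, clamped)


class MonoexponentialResults:
    def __init__(self, model: MonoexponentialModel, adc: np.ndarray, clamped: np.ndarray):
        self.model = model
        self.ADC = adc
        self.clamped = clamped

    def summary(self) -> str:
        vals = self.ADC[np.isfinite(self.ADC)]
        return (
            "Two-point monoexponential ADC "
            f"(b = {self.model.b_low:g}/{self.model.b_high:g} s/mm²)\n"
            f"voxels: {vals.size}   clamped: {int(self.clamped.sum())}\n"
            f"ADC mean {vals.mean() * 1e3:.4f} sd {vals.std() * 1e3:.4f} x1e-3 mm^2/s"
            if vals.size
            else "Two-point ADC: no valid voxels"
        )
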