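"""Bounded nonlinear least-squares estimation of the diffusion model parameters.

Each decay is fitted by trust-region-reflective least squares with physical
bounds and a fixed multi-start grid over the nonlinear shape parameters (the
objectives of the stretched-exponential, fractional-order and random-walk
models are non-convex). Residuals are weighted by the per-b number of signal
averages, since averaged points have proportionally lower variance. s0 is a
free parameter in every fit rather than being pinned to the observed S(0).

The monoexponential (ADC) fit is restricted to the protocol's mono_b_subset
(study default b = 0, 600, 1000 s/mm²); the four non-Gaussian models use all
b-values, mirroring the study protocol.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
from scipy.optimize import least_squares, minimize

from .containers import DwiVolume, ParameterMap, VoiMask
from .exceptions import (
    DegenerateDataError,
    DomainError,
    InsufficientDataError,
)
from .models import (
    MODEL_MARKERS,
    MODEL_PARAM_NAMES,
    PARAM_BOUNDS,
    ModelParams,
    mittag_leffler,
)
from .protocol import AcquisitionProtocol, GradientTiming, b_internal

__all__ = [
    "FitOptions",
    "FitResult",
    "fit_decay",
    "fit_volume",
    "resolve_froc_gradient",
    "froc_composite_amplitude",
]

#: fixed multi-start grids per nonlinear shape parameter
_START_GRIDS = {
    "DKI": {"K": (0.3, 0.8, 1.5)},
    "SEM": {"alpha": (0.5, 0.75, 0.95)},
    "FROC": {"beta": (0.5, 0.75, 0.95), "mu": (1.5, 3.5, 8.0)},
}

# The CTRW objective has well-separated local minima (small-α/large-D decays
# are mimicked by mid-α/mid-D ones to ~0.1%), so a fixed 3-point start grid
# provably misses basins. Starts are instead chosen by a deterministic coarse
# grid over (α, β) with D profiled on a log grid and s0 solved linearly; the
# best few candidates seed the local optimizer.
_CTRW_ALPHA_GRID = np.array([0.1, 0.15, 0.22, 0.3, 0.4, 0.55, 0.7, 0.85, 0.97])
_CTRW_BETA_GRID = np.array([0.12, 0.2, 0.3, 0.42, 0.55, 0.7, 0.85, 0.97])
_CTRW_D_GRID = np.geomspace(0.02, 4.9, 18)
_CTRW_TOP_K = 16


@dataclass(frozen=True)
class FitOptions:
    """Options controlling :func:`fit_decay`.

    weighted : weight residuals by the protocol's per-b averages.
    multi_start : use the fixed start grid (deterministic); single start else.
    xtol, ftol, gtol : trust-region stopping tolerances.
    """

    weighted: bool = True
    multi_start: bool = True
    xtol: float = 1e-14
    ftol: float = 1e-14
    gtol: float = 1e-14
    max_nfev: int = 400
    polish_rounds: int = 6


@dataclass
class FitResult:
    """Outcome of a single-decay fit."""

    model_id: str
    estimates: ModelParams
    residual_sse: float
    n_points: int
    converged: bool
    flags: List[str] = field(default_factory=list)

    def markers(self) -> Dict[str, float]:
        """Estimates keyed by reported marker name (e.g. DKI_K)."""
        names = MODEL_MARKERS[self.model_id]
        params = MODEL_PARAM_NAMES[self.model_id]
        return {m: self.estimates[p] for m, p in zip(names, params)}


def resolve_froc_gradient(b_s_per_mm2, timing: GradientTiming):
    """Diffusion gradient amplitude G_d (mT/μm) back-solved from b.

    Thin wrapper over :meth:`GradientTiming.gradient_amplitude`; round-trips
    through ``timing.b_value`` to better than 1e-9 relative.
    """
    return timing.gradient_amplitude(b_s_per_mm2)


def froc_composite_amplitude(d: float, beta: float, mu: float,
                             timing: GradientTiming) -> float:
    """The identifiable FROC amplitude ``A = D μ^{2(β−1)} (Δ−c_β δ)/(Δ−δ/3)^β``.

    With G_d derived from b at a single (Δ, δ) pair the FROC exponent is
    exactly ``−A·b'^β``: D and μ enter the signal only through A and cannot be
    separated by any fit. A (together with β and s0) is what multi-b data
    determine.
    """
    td = timing.effective_diffusion_time
    c_beta = (2 * beta - 1) / (2 * beta + 1)
    t_beta = timing.big_delta - c_beta * timing.small_delta
    return d * mu ** (2.0 * (beta - 1.0)) * t_beta / td ** beta


# ---------------------------------------------------------------------------
# model evaluation on the internal b' grid, vectorized over b'
# ---------------------------------------------------------------------------

def _predict(model_id: str, theta: np.ndarray, bp: np.ndarray,
             timing: GradientTiming) -> np.ndarray:
    s0 = theta[0]
    if model_id == "MONO":
        return s0 * np.exp(-bp * theta[1])
    if model_id == "DKI":
        d, k = theta[1], theta[2]
        return s0 * np.exp(-bp * d + bp * bp * d * d * k / 6.0)
    if model_id == "SEM":
        ddc, alpha = theta[1], theta[2]
        return s0 * np.exp(-((bp * ddc) ** alpha))
    if model_id == "FROC":
        d, beta, mu = theta[1], theta[2], theta[3]
        td = timing.effective_diffusion_time
        t_beta = timing.big_delta - (2 * beta - 1) / (2 * beta + 1) * timing.small_delta
        expo = d * mu ** (2.0 * (beta - 1.0)) * (bp / td) ** beta * t_beta
        return s0 * np.exp(-expo)
    if model_id == "CTRW":
        d, alpha, beta = theta[1], theta[2], theta[3]
        return s0 * mittag_leffler(alpha, -((bp * d) ** beta))
    raise DomainError(f"unknown model_id {model_id!r}")


def _loglinear_init(bp: np.ndarray, signals: np.ndarray, w: np.ndarray):
    """Weighted log-linear slope/intercept: ln S = ln s0 − b'·D."""
    y = np.log(signals)
    coef = np.polynomial.polynomial.polyfit(bp, y, 1, w=np.sqrt(w))
    s0 = math.exp(min(coef[0], 700.0))
    d = -coef[1]
    return s0, d


def _ctrw_candidate_starts(bp: np.ndarray, s: np.ndarray, w: np.ndarray):
    """Deterministic CTRW starting points: (s0, D, α, β) triples ranked by SSE.

    For each (α, β) on a coarse grid, D runs over a fixed log grid, s0 is the
    weighted linear least-squares amplitude, and the best-SSE D is kept; the
    top candidates over all (α, β) seed the local optimizer.
    """
    cands = []
    for alpha in _CTRW_ALPHA_GRID:
        for beta in _CTRW_BETA_GRID:
            zz = -((bp[None, :] * _CTRW_D_GRID[:, None]) ** beta)
            m = mittag_leffler(alpha, zz)  # (nD, nb)
            denom = np.sum(w * m * m, axis=1)
            s0s = np.sum(w * m * s, axis=1) / np.maximum(denom, 1e-300)
            sse = np.sum(w * (s0s[:, None] * m - s) ** 2, axis=1)
            i = int(np.argmin(sse))
            cands.append((float(sse[i]), float(s0s[i]), float(_CTRW_D_GRID[i]),
                          float(alpha), float(beta)))
    cands.sort(key=lambda c: c[0])
    return [np.array([c[1], c[2], c[3], c[4]]) for c in cands[:_CTRW_TOP_K]]


def _clip_to_bounds(x, lo, hi):
    # strict interior start: trf requires x0 within bounds
    span = hi - lo
    return np.clip(x, lo + 1e-9 * span, hi - 1e-9 * span)


def fit_decay(
    model_id: str,
    b_values,
    signals,
    protocol: Optional[AcquisitionProtocol] = None,
    options: FitOptions = FitOptions(),
) -> FitResult:
    """Fit one model to a single (b, S) decay.

    Parameters
    ----------
    model_id : one of MONO, DKI, SEM, FROC, CTRW.
    b_values : b in s/mm².
    signals : positive measured signals, same length.
    protocol : supplies per-b weights (averages), the mono-fit b subset and
        the FROC gradient timing. When None, unit weights, all b-values and
        default timing are used.
    """
    if model_id not in MODEL_PARAM_NAMES:
        raise DomainError(f"unknown model_id {model_id!r}")
    b = np.asarray(b_values, dtype=float)
    s = np.asarray(signals, dtype=float)
    if b.shape != s.shape or b.ndim != 1:
        raise DomainError("b_values and signals must be equal-length 1D")
    if np.any(s <= 0):
        raise DomainError("signals must be positive")

    timing = protocol.timing if protocol is not None else GradientTiming()

    # per-b weights from the protocol's averages
    w = np.ones_like(b)
    if protocol is not None and options.weighted:
        lookup = {float(bb): float(av)
                  for bb, av in zip(protocol.b_values, protocol.averages)}
        w = np.array([lookup.get(float(bb), 1.0) for bb in b])

    if model_id == "MONO" and protocol is not None:
        subset = set(map(float, protocol.mono_b_subset))
        keep = np.array([float(bb) in subset for bb in b])
        if keep.any():
            b, s, w = b[keep], s[keep], w[keep]

    param_names = MODEL_PARAM_NAMES[model_id]
    n_free = 1 + len(param_names)
    if b.size < n_free + 1:
        raise InsufficientDataError(
            f"{model_id} needs at least {n_free + 1} points, got {b.size}"
        )
    if np.ptp(s) == 0:
        raise DegenerateDataError("all signals are equal; no decay to fit")

    bp = b_internal(b)
    sqrt_w = np.sqrt(w)

    # normalize the decay to unit scale: keeps the trust-region solver's
    # conditioning independent of the scanner's arbitrary signal units
    s_scale = float(s.max())
    s = s / s_scale

    bounds_map = PARAM_BOUNDS[model_id]
    s_max = float(s.max())
    lo = np.array([1e-3 * s_max] + [bounds_map[p][0] for p in param_names])
    hi = np.array([10.0 * s_max] + [bounds_map[p][1] for p in param_names])

    s0_init, d_init = _loglinear_init(bp, s, w)
    diff_name = param_names[0]  # ADC / D / DDC
    base = {"s0": s0_init, diff_name: d_init}

    if model_id == "FROC":
        return _fit_froc(b, bp, s, s_scale, sqrt_w, timing, lo, hi, options)

    # assemble deterministic starting points
    starts: List[np.ndarray] = []
    if model_id == "CTRW" and options.multi_start:
        for cand in _ctrw_candidate_starts(bp, s, w):
            starts.append(cand)  # (s0, D, alpha, beta)
    else:
        grid = _START_GRIDS.get(model_id, {})
        if options.multi_start and grid:
            keys = list(grid)
            combos = list(itertools.product(*(grid[k] for k in keys)))
        else:
            keys = list(grid)
            combos = [tuple(grid[k][1] for k in keys)] if grid else [()]
        for combo in combos:
            start = dict(base)
            start.update(dict(zip(keys, combo)))
            starts.append(np.array([start["s0"]] + [
                start.get(p, 0.5 * (bounds_map[p][0] + bounds_map[p][1]))
                for p in param_names
            ]))

    def residual(theta):
        return sqrt_w * (_predict(model_id, theta, bp, timing) - s)

    best = None
    best_start = -1
    for i, x0 in enumerate(starts):
        res = least_squares(
            residual, _clip_to_bounds(x0, lo, hi), bounds=(lo, hi), method="trf",
            x_scale=np.maximum(np.abs(x0), 1e-3),
            xtol=options.xtol, ftol=options.ftol, gtol=options.gtol,
            max_nfev=options.max_nfev,
        )
        if best is None or res.cost < best.cost - 1e-15 * max(best.cost, 1.0):
            best = res
            best_start = i
        # adaptive early exit: an essentially exact fit cannot improve, and
        # on noisy data the deep start list only buys precision that the
        # noise floor makes meaningless
        if best.cost < 1e-19:
            break
        if i + 1 >= 8 and best.cost > 1e-10:
            break

    # polish from the winning start; restarting resets the trust region, which
    # lets the solver keep traversing the curved, nearly-flat valleys of the
    # CTRW/FROC objectives instead of stopping on xtol
    for _ in range(options.polish_rounds):
        polish = least_squares(
            residual, _clip_to_bounds(best.x, lo, hi), bounds=(lo, hi),
            method="trf", x_scale="jac", xtol=options.xtol, ftol=options.ftol,
            gtol=options.gtol, max_nfev=options.max_nfev,
        )
        improved = polish.cost < best.cost * (1.0 - 1e-3) - 1e-300
        if polish.cost <= best.cost:
            best = polish
        if not improved:
            break

    # Near-exact CTRW fits sit in a curved, nearly flat valley that the
    # trust-region solver cannot traverse to the floor; a short Nelder-Mead
    # creep from its solution recovers several more digits. Only worthwhile
    # when the residual is already at noise-free levels.
    if model_id == "CTRW" and 1e-21 < 2.0 * best.cost < 1e-6:
        def nm_obj(th):
            clipped = np.clip(th, lo, hi)
            penalty = float(np.sum((th - clipped) ** 2))
            return float(np.sum(residual(clipped) ** 2)) + 1e3 * penalty

        for _ in range(2):
            nm = minimize(
                nm_obj, best.x, method="Nelder-Mead",
                options=dict(maxfev=2000, xatol=1e-16, fatol=1e-300,
                             adaptive=True),
            )
            x_nm = np.clip(nm.x, lo, hi)
            sse_nm = float(np.sum(residual(x_nm) ** 2))
            improved = sse_nm < 2.0 * best.cost * (1.0 - 1e-3)
            if sse_nm < 2.0 * best.cost:
                best.x = x_nm
                best.cost = 0.5 * sse_nm
            if not improved:
                break

    theta = best.x
    flags = [f"start={best_start}"]
    span = hi - lo
    if np.any(theta - lo < 1e-6 * span) or np.any(hi - theta < 1e-6 * span):
        flags.append("bound_constrained")
    if model_id == "DKI":
        d, k = theta[1], theta[2]
        if k > 0 and bp.max() * d * k > 3.0:
            flags.append("dki_validity_bound")

    estimates = ModelParams(
        model_id=model_id,
        s0=float(theta[0]) * s_scale,
        values={p: float(v) for p, v in zip(param_names, theta[1:])},
    )
    return FitResult(
        model_id=model_id,
        estimates=estimates,
        residual_sse=float(2.0 * best.cost) * s_scale ** 2,
        n_points=int(b.size),
        converged=bool(best.success and np.isfinite(best.cost)),
        flags=flags,
    )


_FROC_BETA_STARTS = (0.15, 0.35, 0.55, 0.75, 0.95)
#: reference spatial constant (μm) used to place the fitted point on the
#: D-μ ridge; D and μ are reported but only their composite is measured
_FROC_MU_REF = 3.5


def _fit_froc(b, bp, s, s_scale, sqrt_w, timing: GradientTiming,
              lo_full, hi_full, options: FitOptions) -> FitResult:
    """FROC fit in its identifiable parametrization.

    The signal depends on (D, μ) only through the composite amplitude
    ``A = D μ^{2(β−1)} (Δ−c_β δ)/(Δ−δ/3)^β`` (the exponent is −A·b'^β), so
    the fit estimates (s0, A, β) and then reports the (D, μ) pair on the
    equivalence ridge with μ fixed at a reference value, falling back to
    adjusting μ when the implied D leaves its physical bounds.
    """
    d_lo, d_hi = PARAM_BOUNDS["FROC"]["D"]
    mu_lo, mu_hi = PARAM_BOUNDS["FROC"]["mu"]
    beta_lo, beta_hi = PARAM_BOUNDS["FROC"]["beta"]
    lo = np.array([lo_full[0], 1e-5, beta_lo])
    hi = np.array([hi_full[0], 1e4, beta_hi])

    def residual(theta):
        s0, a, beta = theta
        return sqrt_w * (s0 * np.exp(-a * bp ** beta) - s)

    s0_init, d_init = _loglinear_init(bp, s, np.ones_like(bp))
    a_init = min(max(d_init, 1e-4), 1e3)
    betas = _FROC_BETA_STARTS if options.multi_start else (0.75,)

    best = None
    best_start = -1
    for i, beta0 in enumerate(betas):
        x0 = _clip_to_bounds(np.array([s0_init, a_init, beta0]), lo, hi)
        res = least_squares(
            residual, x0, bounds=(lo, hi), method="trf",
            x_scale=np.maximum(np.abs(x0), 1e-3),
            xtol=options.xtol, ftol=options.ftol, gtol=options.gtol,
            max_nfev=options.max_nfev,
        )
        if best is None or res.cost < best.cost - 1e-15 * max(best.cost, 1.0):
            best = res
            best_start = i
    polish = least_squares(
        residual, _clip_to_bounds(best.x, lo, hi), bounds=(lo, hi),
        method="trf", x_scale="jac", xtol=options.xtol, ftol=options.ftol,
        gtol=options.gtol, max_nfev=options.max_nfev,
    )
    if polish.cost <= best.cost:
        best = polish

    s0_hat, a_hat, beta_hat = best.x
    flags = [f"start={best_start}", "froc_ridge_convention"]

    td = timing.effective_diffusion_time
    t_beta = timing.big_delta - (2 * beta_hat - 1) / (2 * beta_hat + 1) * timing.small_delta
    mu_hat = _FROC_MU_REF
    d_hat = a_hat * td ** beta_hat / (mu_hat ** (2.0 * (beta_hat - 1.0)) * t_beta)
    if not d_lo <= d_hat <= d_hi:
        d_hat = min(max(d_hat, d_lo), d_hi)
        if beta_hat < 1.0 - 1e-12:
            mu_hat = (a_hat * td ** beta_hat / (d_hat * t_beta)) ** (
                1.0 / (2.0 * (beta_hat - 1.0))
            )
        if not mu_lo <= mu_hat <= mu_hi:
            mu_hat = min(max(mu_hat, mu_lo), mu_hi)
            flags.append("froc_amplitude_clipped")

    estimates = ModelParams(
        model_id="FROC",
        s0=float(s0_hat) * s_scale,
        values={"D": float(d_hat), "beta": float(beta_hat), "mu": float(mu_hat)},
    )
    return FitResult(
        model_id="FROC",
        estimates=estimates,
        residual_sse=float(2.0 * best.cost) * s_scale ** 2,
        n_points=int(bp.size),
        converged=bool(best.success and np.isfinite(best.cost)),
        flags=flags,
    )


def fit_volume(
    model_id: str,
    dwi: DwiVolume,
    mask: VoiMask,
    protocol: Optional[AcquisitionProtocol] = None,
    options: FitOptions = FitOptions(),
) -> Dict[str, ParameterMap]:
    """Apply :func:`fit_decay` to every masked voxel of a 4D volume.

    Returns one :class:`ParameterMap` per reported marker of the model (e.g.
    DKI → DKI_D and DKI_K). Voxels whose fit fails to converge are flagged in
    the maps' ``converged`` grid, not dropped. Deterministic: the multi-start
    grid is fixed and there is no randomness.
    """
    protocol = protocol or dwi.protocol
    mask.check_aligned(dwi)
    b = np.asarray(protocol.b_values, dtype=float)

    marker_names = MODEL_MARKERS[model_id]
    shape = dwi.spatial_shape
    values = {m: np.full(shape, np.nan) for m in marker_names}
    converged = np.zeros(shape, dtype=bool)

    idx = np.argwhere(mask.data)
    for (i, j, k) in idx:
        decay = dwi.data[i, j, k, :]
        try:
            fr = fit_decay(model_id, b, decay, protocol, options)
        except (DegenerateDataError, DomainError):
            continue
        for m, val in fr.markers().items():
            values[m][i, j, k] = val
        converged[i, j, k] = fr.converged

    return {
        m: ParameterMap(name=m, values=values[m], mask=mask.data.copy(),
                        converged=converged.copy())
        for m in marker_names
    }
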