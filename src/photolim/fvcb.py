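"""Farquhar–von Caemmerer–Berry (FvCB) C3 photosynthesis model.

The net assimilation rate is the minimum of two enzyme-limited rates,

    A_c = V_cmax (C_c − Γ*) / (C_c + K_m) − R_d,      K_m = K_c (1 + O/K_o)
    A_j = J (C_c − Γ*) / (4 C_c + 8 Γ*) − R_d,

with a hard (non-smoothed) transition between the Rubisco-limited and
RuBP-regeneration-limited states.  Potential electron transport J
follows the non-rectangular hyperbola light response, the smaller root
of  θ J² − (α Q + J_max) J + α Q J_max = 0.

Kinetic constants default to a chloroplastic-CO2-basis parameterization
at 25 °C (Γ* = 37.43, K_c = 272.38 μmol mol⁻¹, K_o = 165.82 mmol mol⁻¹,
O = 210 mmol mol⁻¹).  No temperature scaling is applied: constants are
taken at the measurement temperature, and all-state analysis here
assumes a 25 °C block temperature.  Triose-phosphate-utilization
limitation is not modeled; points that look TPU-limited (assimilation
decreasing at the highest C_a steps) are excluded from fitting with a
logged count.

Module surface: :func:`j_light_response`, :func:`net_assimilation`,
:func:`solve_steady_state` (closes the diffusion chain
A = g_sc (C_a − C_i) = g_m (C_i − C_c) = FvCB(C_c)), and
:func:`fit_aci` (deterministic V_cmax / J_max estimation from an A–C_i
curve with self-consistent limitation-state assignment).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import NamedTuple, Optional

import numpy as np
from scipy.optimize import brentq

from .errors import ConvergenceError, DomainError, UnderdeterminedError
from .types import ACiCurve

log = logging.getLogger(__name__)

RUBISCO = "Rubisco"
RUBP = "RuBP-regeneration"


@dataclass(frozen=True)
class FvCBParams:
    """Biochemical parameter set of the FvCB model.

    Units: rates in μmol m⁻² s⁻¹; ``Gamma_star`` and ``K_c`` in
    μmol mol⁻¹; ``K_o`` and ``O`` in mmol mol⁻¹; ``theta`` and ``alpha``
    dimensionless (``alpha`` in e⁻ per incident photon).
    """

    V_cmax: float
    J_max: float
    R_d: float = 1.0
    Gamma_star: float = 37.43
    K_c: float = 272.38
    K_o: float = 165.82
    O: float = 210.0
    theta: float = 0.9
    alpha: float = 0.3

    def __post_init__(self):
        if self.V_cmax < 0 or self.J_max < 0:
            raise DomainError("V_cmax and J_max must be non-negative")
        if self.R_d < 0:
            raise DomainError("R_d must be non-negative")
        for name in ("Gamma_star", "K_c", "K_o", "O"):
            if not getattr(self, name) > 0:
                raise DomainError(f"{name} must be positive")
        if not 0 <= self.theta <= 1:
            raise DomainError(f"theta must lie in [0, 1], got {self.theta}")
        if not 0 < self.alpha < 1:
            raise DomainError(f"alpha must lie in (0, 1), got {self.alpha}")

    @property
    def K_m(self) -> float:
        """Effective Michaelis constant K_c (1 + O/K_o), μmol mol⁻¹."""
        return self.K_c * (1.0 + self.O / self.K_o)


class Assimilation(NamedTuple):
    """Net assimilation with the active limitation state."""

    A_N: float
    A_c: float
    A_j: float
    state: str


class SteadyState(NamedTuple):
    """Solution of the coupled diffusion–biochemistry balance."""

    A_N: float
    C_i: float
    C_c: float
    state: str


def j_light_response(PPFD: float, J_max: float, alpha: float, theta: float) -> float:
    """Potential electron transport from the non-rectangular hyperbola.

    Returns the smaller root of θJ² − (αQ + J_max)J + αQ·J_max = 0;
    θ = 0 degenerates to the rectangular hyperbola αQ·J_max/(αQ + J_max).
    """
    if PPFD < 0:
        raise DomainError(f"PPFD must be non-negative, got {PPFD}")
    aq = alpha * PPFD
    if aq == 0 or J_max == 0:
        return 0.0
    if theta == 0:
        return aq * J_max / (aq + J_max)
    b = aq + J_max
    disc = b * b - 4.0 * theta * aq * J_max
    return (b - math.sqrt(max(disc, 0.0))) / (2.0 * theta)


def invert_light_response(J: float, PPFD: float, alpha: float, theta: float) -> float:
    """J_max implied by a realized potential J at irradiance PPFD.

    Inverts the non-rectangular hyperbola:
    J_max = J (αQ − θJ) / (αQ − J).  Requires J < αQ.
    """
    aq = alpha * PPFD
    if not 0 < J < aq:
        raise DomainError(f"J must lie in (0, alpha*PPFD) = (0, {aq:.4g}), got {J}")
    return J * (aq - theta * J) / (aq - J)


def rubisco_limited(C_c, params: FvCBParams):
    """Rubisco-limited (carboxylation-limited) net rate A_c."""
    return params.V_cmax * (C_c - params.Gamma_star) / (C_c + params.K_m) - params.R_d


def rubp_limited(C_c, J, params: FvCBParams):
    """RuBP-regeneration-limited net rate A_j at electron transport J."""
    return J * (C_c - params.Gamma_star) / (4.0 * C_c + 8.0 * params.Gamma_star) - params.R_d


def net_assimilation(C_c: float, params: FvCBParams, J: Optional[float] = None,
                     PPFD: Optional[float] = None) -> Assimilation:
    """Net assimilation min(A_c, A_j) at chloroplastic CO2 ``C_c``.

    ``J`` is the realized electron transport; when omitted it is taken
    from the light response at ``PPFD``.  Ties go to the Rubisco state.
    """
    if not C_c > 0:
        raise DomainError(f"C_c must be positive, got {C_c}")
    if J is None:
        if PPFD is None:
            raise DomainError("either J or PPFD must be supplied")
        J = j_light_response(PPFD, params.J_max, params.alpha, params.theta)
    a_c = rubisco_limited(C_c, params)
    a_j = rubp_limited(C_c, J, params)
    state = RUBISCO if a_c <= a_j else RUBP
    return Assimilation(A_N=min(a_c, a_j), A_c=a_c, A_j=a_j, state=state)


def consumption_j(A_N: float, R_d: float, C_c: float, Gamma_star: float) -> float:
    """Actual linear electron transport sustaining a given net rate.

    Inverts the RuBP-regeneration expression at the operating C_c:
    J = (A_N + R_d)(4C_c + 8Γ*)/(C_c − Γ*).  In the RuBP-limited state
    this equals the potential J; under Rubisco limitation the actual
    flow is below potential (photochemistry is down-regulated), which is
    what a fluorometer sees.
    """
    if not C_c > Gamma_star:
        raise DomainError(f"C_c ({C_c}) must exceed Gamma_star ({Gamma_star})")
    return (A_N + R_d) * (4.0 * C_c + 8.0 * Gamma_star) / (C_c - Gamma_star)


def solve_steady_state(
    C_a: float,
    g_sc: float,
    g_m: float,
    params: FvCBParams,
    PPFD: float,
    J: Optional[float] = None,
) -> SteadyState:
    """Solve A = g_sc(C_a − C_i) = g_m(C_i − C_c) = FvCB(C_c).

    The two diffusion steps in series give the total conductance
    g_tot = (1/g_sc + 1/g_m)⁻¹ and a single scalar root problem in C_c,
    solved by bracketed root finding.  The returned triple satisfies all
    three balance equations to |residual| < 1e−9 μmol m⁻² s⁻¹.
    """
    if not (g_sc > 0 and g_m > 0):
        raise DomainError("conductances must be positive")
    if not C_a > 0:
        raise DomainError(f"C_a must be positive, got {C_a}")
    if J is None:
        J = j_light_response(PPFD, params.J_max, params.alpha, params.theta)
    g_tot = 1.0 / (1.0 / g_sc + 1.0 / g_m)

    def f(cc):
        return g_tot * (C_a - cc) - net_assimilation(cc, params, J=J).A_N

    lo = min(1e-9, C_a * 1e-12)
    hi = C_a + (params.R_d + 1.0) / g_tot
    flo, fhi = f(lo), f(hi)
    if not (flo > 0 > fhi):
        raise ConvergenceError(
            "no steady-state root bracketed in (0, C_a + R_d/g_tot]",
            diagnostics={"C_a": C_a, "g_sc": g_sc, "g_m": g_m, "f_lo": flo, "f_hi": fhi},
        )
    cc = brentq(f, lo, hi, xtol=1e-12, rtol=8.9e-16, maxiter=200)
    asm = net_assimilation(cc, params, J=J)
    a = asm.A_N
    resid = abs(g_tot * (C_a - cc) - a)
    # 1e-9 absolute for physiological conductances; near the
    # infinite-conductance limit the flux resolution of a double-precision
    # C_c (g_tot * ulp(C_c)) dominates and the tolerance scales with it.
    tol = max(1e-9, 1e4 * g_tot * np.spacing(max(cc, C_a)))
    if resid > tol:
        raise ConvergenceError(
            f"steady-state residual {resid:.3g} exceeds {tol:.3g}",
            diagnostics={"C_a": C_a, "C_c": cc},
        )
    ci = C_a - a / g_sc
    return SteadyState(A_N=a, C_i=ci, C_c=cc, state=asm.state)


# ----------------------------------------------------------------------
# A–C_i fitting
# ----------------------------------------------------------------------

@dataclass
class FitConfig:
    """Settings for :func:`fit_aci`.

    ``r_d`` is either a fixed value (float) or the string ``"fit"`` to
    estimate it jointly.  ``ci_threshold`` seeds the limitation-state
    assignment (points with C_i below it start Rubisco-limited).
    ``allow_single_state`` permits a valid fit when every point sits in
    one limitation state; the other state's parameter is then reported
    as unidentifiable instead of raising.
    """

    r_d: float | str = 1.0
    ci_threshold: float = 300.0
    max_iter: int = 50
    allow_single_state: bool = False
    template: FvCBParams = field(
        default_factory=lambda: FvCBParams(V_cmax=1.0, J_max=1.0)
    )


@dataclass
class FitResult:
    """Outcome of an A–C_i fit.

    ``basis`` records whether V_cmax/J_max refer to chloroplastic
    (``"C_c"``, finite mesophyll conductance supplied) or intercellular
    (``"C_i"``) CO2.  ``jmax_identifiable`` is False when no point of
    the curve expresses RuBP-regeneration limitation, in which case
    ``params.J_max`` is NaN.
    """

    params: FvCBParams
    rmse: float
    state_assignment: list
    n_points_per_state: dict
    basis: str
    n_tpu_excluded: int = 0
    jmax_identifiable: bool = True
    vcmax_identifiable: bool = True
    n_iterations: int = 0


def _tpu_mask(c_a: np.ndarray, a_n: np.ndarray) -> np.ndarray:
    """True for points kept; drops TPU-like points among the 3 highest C_a."""
    keep = np.ones(c_a.size, dtype=bool)
    order = np.argsort(c_a)
    top = order[-3:]
    for rank, idx in enumerate(order):
        if idx in top and rank > 0:
            prev = order[rank - 1]
            if a_n[idx] < a_n[prev] - 1e-12:
                keep[idx] = False
    return keep


def fit_aci(
    curve: ACiCurve,
    g_m: Optional[float] = None,
    config: Optional[FitConfig] = None,
) -> FitResult:
    """Fit V_cmax and J_max to an A–C_i curve by least squares.

    The curve is mapped to a chloroplastic-CO2 basis when a finite
    ``g_m`` is given (C_c = C_i − A_N/g_m), otherwise fitted on a C_i
    basis.  Each point carries a limitation-state label; labels are
    seeded by a C_i threshold and iterated to a self-consistent fixed
    point (the label of every point equals the minimum state of the
    fitted model there; ties toward Rubisco).  Within an assignment both
    parameters have closed-form least-squares solutions, so the whole
    procedure is deterministic with no random restarts.
    """
    config = config or FitConfig()
    ci = curve.C_i
    a_n = curve.A_N
    c_a = curve.C_a
    if np.unique(ci).size < 5:
        raise UnderdeterminedError(
            f"curve {curve.leaf_id!r} has {np.unique(ci).size} distinct C_i points; "
            "at least 5 are required"
        )

    keep = _tpu_mask(c_a, a_n)
    n_tpu = int((~keep).sum())
    if n_tpu:
        log.info("curve %s: excluded %d TPU-like point(s)", curve.leaf_id, n_tpu)
    ci, a_n = ci[keep], a_n[keep]

    basis = "C_i"
    cc = ci.copy()
    if g_m is not None and np.isfinite(g_m):
        if not g_m > 0:
            raise DomainError(f"g_m must be positive, got {g_m}")
        cc = ci - a_n / g_m
        basis = "C_c"
    p = config.template
    usable = cc > p.Gamma_star
    cc, a_n, ci = cc[usable], a_n[usable], ci[usable]
    if cc.size < 5:
        raise UnderdeterminedError("fewer than 5 points above the compensation point")

    ppfd = float(np.median(curve.PPFD))
    fit_rd = config.r_d == "fit"
    rd = 0.0 if fit_rd else float(config.r_d)

    x = (cc - p.Gamma_star) / (cc + p.K_m)          # A_c = V_cmax * x - R_d
    y = (cc - p.Gamma_star) / (4.0 * cc + 8.0 * p.Gamma_star)  # A_j = J * y - R_d

    is_rubisco = ci < config.ci_threshold
    vcmax = jj = float("nan")
    n_it = 0
    for n_it in range(1, config.max_iter + 1):
        vcmax, jj, rd_hat = _solve_states(a_n, x, y, is_rubisco, rd, fit_rd)
        pred_c = vcmax * x - rd_hat if np.isfinite(vcmax) else np.full_like(x, np.inf)
        pred_j = jj * y - rd_hat if np.isfinite(jj) else np.full_like(y, np.inf)
        new_assign = pred_c <= pred_j  # ties toward Rubisco
        if np.array_equal(new_assign, is_rubisco):
            is_rubisco = new_assign
            break
        is_rubisco = new_assign
    rd_out = rd_hat if fit_rd else rd

    n_rub = int(is_rubisco.sum())
    n_rubp = int((~is_rubisco).sum())
    vc_ok = n_rub >= 2 and np.isfinite(vcmax)
    j_ok = n_rubp >= 2 and np.isfinite(jj)
    if not config.allow_single_state:
        if not vc_ok:
            raise UnderdeterminedError(
                f"only {n_rub} Rubisco-limited point(s): V_cmax under-determined",
                parameter="V_cmax",
            )
        if not j_ok:
            raise UnderdeterminedError(
                f"only {n_rubp} RuBP-regeneration-limited point(s): J_max under-determined",
                parameter="J_max",
            )

    jmax = float("nan")
    if j_ok:
        jmax = invert_light_response(jj, ppfd, p.alpha, p.theta)

    pred = np.where(is_rubisco, vcmax * x, jj * y) - rd_out
    if not j_ok:
        pred = vcmax * x - rd_out
    if not vc_ok:
        pred = jj * y - rd_out
    rmse = float(np.sqrt(np.mean((pred - a_n) ** 2)))

    params = replace(
        p,
        V_cmax=vcmax if vc_ok else float("nan"),
        J_max=jmax,
        R_d=rd_out,
    )
    labels = [RUBISCO if r else RUBP for r in is_rubisco]
    return FitResult(
        params=params,
        rmse=rmse,
        state_assignment=labels,
        n_points_per_state={RUBISCO: n_rub, RUBP: n_rubp},
        basis=basis,
        n_tpu_excluded=n_tpu,
        jmax_identifiable=j_ok,
        vcmax_identifiable=vc_ok,
        n_iterations=n_it,
    )


def _solve_states(a_n, x, y, is_rubisco, rd_fixed, fit_rd):
    """Closed-form least squares for (V_cmax, J[, R_d]) given labels."""
    rub, reg = is_rubisco, ~is_rubisco
    if fit_rd:
        # columns: [x on rubisco pts, y on rubp pts, -1]
        cols = []
        if rub.any():
            cols.append(np.where(rub, x, 0.0))
        if reg.any():
            cols.append(np.where(reg, y, 0.0))
        cols.append(-np.ones_like(x))
        design = np.column_stack(cols)
        sol, *_ = np.linalg.lstsq(design, a_n, rcond=None)
        i = 0
        vcmax = sol[i] if rub.any() else float("nan")
        i += 1 if rub.any() else 0
        jj = sol[i] if reg.any() else float("nan")
        rd = sol[-1]
        return float(vcmax), float(jj), float(rd)
    t = a_n + rd_fixed
    vcmax = float(np.dot(t[rub], x[rub]) / np.dot(x[rub], x[rub])) if rub.any() else float("nan")
    jj = float(np.dot(t[reg], y[reg]) / np.dot(y[reg], y[reg])) if reg.any() else float("nan")
    return vcmax, jj, rd_fixed
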