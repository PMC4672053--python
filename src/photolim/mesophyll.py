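"""Variable-J mesophyll conductance and Laisk day respiration.

The variable-J method combines gas exchange with the fluorescence-based
electron transport rate J_flu.  Inverting the RuBP-regeneration
expression of the FvCB model at the (unknown) chloroplastic CO2 gives

    C_c = Γ* (J_flu + 8 (A_N + R_d)) / (J_flu − 4 (A_N + R_d))
    g_m = A_N / (C_i − C_c)

Per-point conductances are averaged over a C_i window (default the
closed interval [100, 300] μmol mol⁻¹) to yield one g_m per leaf; that
scalar is reused for every C_c = C_i − A_N/g_m computation of the leaf.

Day respiration R_d is a *required* input of the inversion — the
formula is sensitive to it — and comes either from configuration or
from the Laisk intersection method (:func:`laisk_rd`): linear fits to
the low-C_i portions of A–C_i curves measured at several irradiances
intersect at C_i*, where the common net rate equals −R_d.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import (
    DomainError,
    EmptyWindowError,
    IllConditionedError,
    InvalidPointError,
    SingularityError,
    UnderdeterminedError,
)
from .types import ACiCurve
from . import fluorescence as fluo

log = logging.getLogger(__name__)

#: Default C_i averaging window, closed on both ends, μmol mol⁻¹.
DEFAULT_WINDOW = (100.0, 300.0)


@dataclass(frozen=True)
class MesophyllEstimate:
    """Windowed variable-J mesophyll conductance for one leaf."""

    g_m_points: tuple      # per-point g_m inside the window, mol m⁻² s⁻¹
    g_m_mean: float        # arithmetic mean of the valid points
    window: tuple          # (lower, upper) C_i bounds used
    C_c: tuple             # implied chloroplastic CO2 of the window points
    n_used: int
    n_invalid: int         # flagged points excluded from the mean


@dataclass(frozen=True)
class RdEstimate:
    """Laisk-method day respiration."""

    R_d: float
    C_i_star: float
    n_curves: int


def implied_cc(A_N: float, J_flu: float, R_d: float, Gamma_star: float) -> float:
    """Chloroplastic CO2 implied by A_N and J_flu (variable-J inversion)."""
    s = A_N + R_d
    denom = J_flu - 4.0 * s
    if denom <= 1e-9 * max(1.0, abs(J_flu)):
        raise SingularityError(
            f"J_flu ({J_flu:.4g}) must exceed 4(A_N + R_d) ({4 * s:.4g}): "
            "electron transport inconsistent with gross assimilation"
        )
    return Gamma_star * (J_flu + 8.0 * s) / denom


def variable_j_gm(
    A_N: float,
    C_i: float,
    J_flu: float,
    R_d: float,
    Gamma_star: float = 37.43,
) -> float:
    """Single-point mesophyll conductance by the variable-J method.

    Requires A_N > 0 and J_flu > 4(A_N + R_d); the implied C_c must fall
    strictly between Γ* and C_i, otherwise the point is flagged invalid
    (:class:`InvalidPointError`).
    """
    if not A_N > 0:
        raise DomainError(f"A_N must be positive for the inversion, got {A_N}")
    cc = implied_cc(A_N, J_flu, R_d, Gamma_star)
    if not (Gamma_star < cc < C_i):
        raise InvalidPointError(
            f"implied C_c ({cc:.4g}) outside (Gamma_star, C_i) = "
            f"({Gamma_star:.4g}, {C_i:.4g}): conductance undefined"
        )
    return A_N / (C_i - cc)


def compute_cc(C_i: float, A_N: float, g_m: float) -> float:
    """Chloroplastic CO2 from the leaf-level g_m: C_c = C_i − A_N/g_m."""
    if not g_m > 0:
        raise DomainError(f"g_m must be positive, got {g_m}")
    cc = C_i - A_N / g_m
    if cc <= 0:
        raise InvalidPointError(f"C_c = {cc:.4g} is non-positive: physically invalid")
    return cc


def gm_curve_average(
    curve: ACiCurve,
    R_d: float,
    Gamma_star: float = 37.43,
    window: tuple = DEFAULT_WINDOW,
    J_flu: Optional[Sequence] = None,
    f_psii: float = fluo.F_PSII,
    absorptance: float = fluo.ABSORPTANCE,
) -> MesophyllEstimate:
    """Average variable-J g_m over the C_i window of one curve.

    ``J_flu`` may be supplied pre-computed (one value per point);
    otherwise it is derived from the curve's fluorescence signals.
    Flagged-invalid points (artifact fluorescence, singular inversion,
    inadmissible implied C_c, non-positive A_N) are excluded and
    counted; the mean is the arithmetic mean of the survivors and is
    invariant to point order.
    """
    lo, hi = window
    if not lo < hi:
        raise DomainError(f"window lower bound must be below upper, got {window}")
    ci = curve.C_i
    a_n = curve.A_N
    if J_flu is None:
        derived = fluo.derive_curve(curve, f_psii=f_psii, absorptance=absorptance)
        jf = np.array([d.J_flu for d in derived])
    else:
        jf = np.asarray(J_flu, dtype=float)
        if jf.size != ci.size:
            raise DomainError("J_flu length must match the number of curve points")

    in_window = (ci >= lo) & (ci <= hi)
    if not in_window.any():
        raise EmptyWindowError(
            f"curve {curve.leaf_id!r}: no point with C_i in [{lo}, {hi}]"
        )
    gms, ccs, n_invalid = [], [], 0
    for i in np.flatnonzero(in_window):
        if not np.isfinite(jf[i]):
            n_invalid += 1
            continue
        try:
            gm = variable_j_gm(a_n[i], ci[i], jf[i], R_d, Gamma_star)
        except (DomainError, InvalidPointError):
            n_invalid += 1
            continue
        gms.append(gm)
        ccs.append(implied_cc(a_n[i], jf[i], R_d, Gamma_star))
    if not gms:
        raise EmptyWindowError(
            f"curve {curve.leaf_id!r}: all {int(in_window.sum())} window point(s) invalid"
        )
    if n_invalid:
        log.info("curve %s: %d invalid window point(s) excluded", curve.leaf_id, n_invalid)
    return MesophyllEstimate(
        g_m_points=tuple(gms),
        g_m_mean=float(np.mean(gms)),
        window=(lo, hi),
        C_c=tuple(ccs),
        n_used=len(gms),
        n_invalid=n_invalid,
    )


def laisk_rd(
    curves: Sequence[ACiCurve],
    ci_ceiling: float = 150.0,
    min_points: int = 3,
    slope_spread_tol: float = 1e-3,
) -> RdEstimate:
    """Day respiration from the common intersection of low-C_i lines.

    Each curve (measured at a distinct irradiance) contributes a
    least-squares line A_N = a·C_i + b over its points with
    C_i ≤ ``ci_ceiling``.  The least-squares common intersection
    (C_i*, A*) of all lines gives R_d = −A*.
    """
    if len(curves) < 2:
        raise UnderdeterminedError(
            f"Laisk method needs at least 2 curves at distinct PPFDs, got {len(curves)}"
        )
    ppfds = [float(np.median(c.PPFD)) for c in curves]
    if len(set(ppfds)) < len(ppfds):
        raise DomainError("curves must be measured at distinct PPFDs")
    slopes, intercepts = [], []
    for c in curves:
        mask = c.C_i <= ci_ceiling
        if mask.sum() < min_points:
            raise UnderdeterminedError(
                f"curve {c.leaf_id!r}: only {int(mask.sum())} point(s) with "
                f"C_i <= {ci_ceiling}; need {min_points}"
            )
        a, b = np.polyfit(c.C_i[mask], c.A_N[mask], 1)
        slopes.append(a)
        intercepts.append(b)
    slopes = np.asarray(slopes)
    intercepts = np.asarray(intercepts)
    if np.ptp(slopes) < slope_spread_tol:
        raise IllConditionedError(
            f"slope spread {np.ptp(slopes):.3g} below tolerance "
            f"{slope_spread_tol}: lines are near-parallel"
        )
    # minimize sum_i (a_i x - y + b_i)^2 over (x, y)
    design = np.column_stack([slopes, -np.ones_like(slopes)])
    sol, *_ = np.linalg.lstsq(design, -intercepts, rcond=None)
    ci_star, a_star = float(sol[0]), float(sol[1])
    return RdEstimate(R_d=-a_star, C_i_star=ci_star, n_curves=len(curves))
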