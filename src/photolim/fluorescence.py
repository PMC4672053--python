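"""Pulse-modulated chlorophyll-fluorescence parameters.

Implements the standard PAM quantities: the operating efficiency of
photosystem II, ΦPSII = (F_m′ − F_s)/F_m′; photochemical quenching,
qP = (F_m′ − F_s)/(F_m′ − F_o′); the dark-adapted maximum quantum
efficiency F_v/F_m = (F_m − F_o)/F_m; and the fluorescence-based linear
electron transport rate J_flu = ΦPSII · PPFD · f_PSII · α_leaf, with
f_PSII the fraction of absorbed quanta reaching PSII (0.5 for an even
PSII/PSI split) and α_leaf the leaf absorptance (0.85 by default).

A steady-state signal exceeding F_m′ is a measurement artifact; the
resulting negative ΦPSII is *propagated with a warning*, never clipped,
so that downstream window averaging can exclude flagged points
reproducibly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DomainError
from .types import ACiCurve

#: Fraction of absorbed quanta partitioned to photosystem II.
F_PSII = 0.5
#: Leaf absorptance of incident photons.
ABSORPTANCE = 0.85


@dataclass(frozen=True)
class FluorescenceDerived:
    """Derived fluorescence parameters for one measurement point."""

    qP: float | None
    PhiPSII: float
    J_flu: float
    FvFm: float | None
    flagged: bool  # True when ΦPSII < 0 (F_s > F_m′ artifact)


def compute_phipsii(F_s: float, F_m_prime: float) -> float:
    """Operating PSII photochemical efficiency (F_m′ − F_s)/F_m′.

    Negative results (F_s > F_m′) are returned as-is with a
    ``UserWarning`` rather than being clipped.
    """
    if not F_m_prime > 0:
        raise DomainError(f"F_m_prime must be positive, got {F_m_prime}")
    phi = (F_m_prime - F_s) / F_m_prime
    if phi < 0:
        warnings.warn(
            f"F_s ({F_s}) exceeds F_m_prime ({F_m_prime}): negative PhiPSII "
            f"{phi:.4g} flagged as measurement artifact",
            stacklevel=2,
        )
    return phi


def compute_qp(F_s: float, F_m_prime: float, F_o_prime: float) -> float:
    """Photochemical quenching (F_m′ − F_s)/(F_m′ − F_o′)."""
    if not F_m_prime > F_o_prime:
        raise DomainError(
            f"F_m_prime ({F_m_prime}) must exceed F_o_prime ({F_o_prime})"
        )
    return (F_m_prime - F_s) / (F_m_prime - F_o_prime)


def compute_jflu(
    PhiPSII: float,
    PPFD: float,
    f_psii: float = F_PSII,
    absorptance: float = ABSORPTANCE,
) -> float:
    """Fluorescence-based electron transport rate, μmol e⁻ m⁻² s⁻¹.

    J_flu = ΦPSII · PPFD · f_psii · absorptance.
    """
    if not 0 <= PhiPSII <= 1:
        raise DomainError(f"PhiPSII must lie in [0, 1], got {PhiPSII}")
    if PPFD < 0:
        raise DomainError(f"PPFD must be non-negative, got {PPFD}")
    return PhiPSII * PPFD * f_psii * absorptance


def compute_fvfm(F_o: float, F_m: float) -> float:
    """Dark-adapted maximum PSII quantum efficiency (F_m − F_o)/F_m."""
    if not F_m > 0:
        raise DomainError(f"F_m must be positive, got {F_m}")
    if F_o < 0:
        raise DomainError(f"F_o must be non-negative, got {F_o}")
    if F_o > F_m:
        raise DomainError(f"F_o ({F_o}) must not exceed F_m ({F_m})")
    return (F_m - F_o) / F_m


def derive_point(
    F_s: float,
    F_m_prime: float,
    PPFD: float,
    F_o_prime: float | None = None,
    F_o: float | None = None,
    F_m: float | None = None,
    f_psii: float = F_PSII,
    absorptance: float = ABSORPTANCE,
) -> FluorescenceDerived:
    """All derived parameters for one point; artifacts flagged, not dropped."""
    phi = compute_phipsii(F_s, F_m_prime)
    flagged = phi < 0
    jflu = float("nan") if flagged else compute_jflu(phi, PPFD, f_psii, absorptance)
    qp = None
    if F_o_prime is not None:
        qp = compute_qp(F_s, F_m_prime, F_o_prime)
    fvfm = None
    if F_o is not None and F_m is not None:
        fvfm = compute_fvfm(F_o, F_m)
    return FluorescenceDerived(qP=qp, PhiPSII=phi, J_flu=jflu, FvFm=fvfm, flagged=flagged)


def derive_curve(
    curve: ACiCurve,
    f_psii: float = F_PSII,
    absorptance: float = ABSORPTANCE,
) -> list[FluorescenceDerived]:
    """Per-point derived fluorescence parameters for a whole curve."""
    out = []
    for gas, fluo in curve.points:
        if fluo is None:
            raise DomainError(
                f"curve {curve.leaf_id!r} has a point without fluorescence signals"
            )
        out.append(
            derive_point(
                fluo.F_s,
                fluo.F_m_prime,
                gas.PPFD,
                F_o_prime=fluo.F_o_prime,
                F_o=fluo.F_o,
                F_m=fluo.F_m,
                f_psii=f_psii,
                absorptance=absorptance,
            )
        )
    return out
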