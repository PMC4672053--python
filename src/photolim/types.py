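"""Core domain containers for combined gas-exchange / fluorescence data.

The unit conventions follow standard leaf-level ecophysiology practice:
fluxes per unit (one-sided) leaf area, CO2 as mole fractions
(μmol mol⁻¹), conductances in mol m⁻² s⁻¹.  Stomatal conductance is
stored on a *water-vapor* basis (``g_sw``); the conversion to a CO2
basis (division by 1.6, the ratio of diffusivities of water vapor and
CO2 in air) happens exactly once, inside the diffusion computations,
never at the storage layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import DomainError

#: Ratio of diffusivities of H2O and CO2 in air; g_sc = g_sw / 1.6.
GSW_TO_GSC = 1.6


@dataclass(frozen=True)
class GasExchangeRecord:
    """One instantaneous gas-exchange measurement point.

    Attributes
    ----------
    A_N : float
        Net CO2 assimilation rate, μmol CO2 m⁻² s⁻¹ (may be negative).
    C_a : float
        Ambient (cuvette) CO2 mole fraction, μmol mol⁻¹.
    C_i : float
        Intercellular CO2 mole fraction, μmol mol⁻¹.
    g_sw : float
        Stomatal conductance to water vapor, mol H2O m⁻² s⁻¹.
    PPFD : float
        Photosynthetic photon flux density, μmol m⁻² s⁻¹.
    T_r : float, optional
        Transpiration rate, mmol H2O m⁻² s⁻¹.
    T_leaf : float, optional
        Leaf temperature, °C.
    VPD : float, optional
        Leaf-to-air vapor pressure deficit, kPa.
    """

    A_N: float
    C_a: float
    C_i: float
    g_sw: float
    PPFD: float
    T_r: Optional[float] = None
    T_leaf: Optional[float] = None
    VPD: Optional[float] = None

    def __post_init__(self):
        if not self.C_a > 0:
            raise DomainError(f"C_a must be positive, got {self.C_a}")
        if self.C_i < 0:
            raise DomainError(f"C_i must be non-negative, got {self.C_i}")
        if self.g_sw < 0:
            raise DomainError(f"g_sw must be non-negative, got {self.g_sw}")
        if self.PPFD < 0:
            raise DomainError(f"PPFD must be non-negative, got {self.PPFD}")
        if self.VPD is not None and self.VPD < 0:
            raise DomainError(f"VPD must be non-negative, got {self.VPD}")

    @property
    def g_sc(self) -> float:
        """Stomatal conductance on a CO2 basis, mol CO2 m⁻² s⁻¹."""
        return self.g_sw / GSW_TO_GSC


@dataclass(frozen=True)
class FluorescenceRecord:
    """Pulse-amplitude-modulated fluorescence signals for one point.

    Light-adapted signals (``F_s``, ``F_m_prime``, ``F_o_prime``) are
    recorded per measurement point; dark-adapted values (``F_o``,
    ``F_m``) are per leaf and optional.  Missing optional signals are
    represented as ``None``, never as zero.
    """

    F_s: float
    F_m_prime: float
    F_o_prime: Optional[float] = None
    F_o: Optional[float] = None
    F_m: Optional[float] = None

    def __post_init__(self):
        for name in ("F_s", "F_m_prime", "F_o_prime", "F_o", "F_m"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise DomainError(f"{name} must be positive where present, got {v}")
        if self.F_o_prime is not None and not self.F_m_prime > self.F_o_prime:
            raise DomainError(
                f"F_m_prime ({self.F_m_prime}) must exceed F_o_prime ({self.F_o_prime})"
            )
        if self.F_o is not None and self.F_m is not None and not self.F_m > self.F_o:
            raise DomainError(f"F_m ({self.F_m}) must exceed F_o ({self.F_o})")


@dataclass
class ACiCurve:
    """An ordered CO2-response curve with concurrent fluorescence.

    ``points`` is a list of ``(GasExchangeRecord, FluorescenceRecord | None)``
    pairs in protocol order.  All points belong to one leaf of one
    treatment cell.
    """

    leaf_id: str
    treatment: str
    day: int
    points: list = field(default_factory=list)

    def __post_init__(self):
        if len(self.points) < 2:
            raise DomainError(
                f"curve {self.leaf_id!r} needs at least 2 points, got {len(self.points)}"
            )

    def __len__(self) -> int:
        return len(self.points)

    # -- columnar views -------------------------------------------------
    def _gas(self, attr: str) -> np.ndarray:
        return np.array([getattr(g, attr) for g, _ in self.points], dtype=float)

    @property
    def A_N(self) -> np.ndarray:
        return self._gas("A_N")

    @property
    def C_a(self) -> np.ndarray:
        return self._gas("C_a")

    @property
    def C_i(self) -> np.ndarray:
        return self._gas("C_i")

    @property
    def g_sw(self) -> np.ndarray:
        return self._gas("g_sw")

    @property
    def PPFD(self) -> np.ndarray:
        return self._gas("PPFD")

    @property
    def has_fluorescence(self) -> bool:
        return all(f is not None for _, f in self.points)

    def fluorescence(self, attr: str) -> np.ndarray:
        """Columnar view of a fluorescence signal (NaN where absent)."""
        out = np.full(len(self.points), np.nan)
        for i, (_, f) in enumerate(self.points):
            if f is not None and getattr(f, attr) is not None:
                out[i] = getattr(f, attr)
        return out
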