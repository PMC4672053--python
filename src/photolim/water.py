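"""Leaf and soil water-status indices.

Relative water content of a leaf sample from fresh (FW), turgid (TW)
and dry (DW) weights, RWC(%) = (FW − DW)/(TW − DW) × 100, and
gravimetric soil moisture content, SMC(%) = (FW − DW)/DW × 100 (which
can exceed 100% for organic-rich substrates).  Replicates are
aggregated as the arithmetic mean of per-sample indices (mean of
ratios, not ratio of means).
"""

from __future__ import annotations

import warnings

import pandas as pd

from .errors import DomainError


def rwc(FW: float, TW: float, DW: float) -> float:
    """Leaf relative water content, %.

    Values outside [DW, TW] for FW are physically suspect; the result
    is returned with a warning rather than clipped.
    """
    if not TW > DW:
        raise DomainError(f"turgid weight ({TW}) must exceed dry weight ({DW})")
    if not (DW <= FW <= TW):
        warnings.warn(
            f"FW ({FW}) outside [DW, TW] = [{DW}, {TW}]: RWC out of range",
            stacklevel=2,
        )
    return (FW - DW) / (TW - DW) * 100.0


def smc(FW: float, DW: float) -> float:
    """Gravimetric soil moisture content, %."""
    if not DW > 0:
        raise DomainError(f"dry weight must be positive, got {DW}")
    if FW < DW:
        warnings.warn(f"FW ({FW}) below DW ({DW}): negative SMC", stacklevel=2)
    return (FW - DW) / DW * 100.0


def rwc_table(weights: pd.DataFrame, by: str | None = "replication") -> pd.DataFrame:
    """Per-replication mean RWC from a table with FW/TW/DW columns."""
    out = weights.copy()
    out["RWC"] = [rwc(r.FW, r.TW, r.DW) for r in out.itertuples()]
    if by and by in out.columns:
        return out.groupby(by, as_index=False)["RWC"].mean()
    return out[["RWC"]]


def smc_table(weights: pd.DataFrame, by: str | None = "replication") -> pd.DataFrame:
    """Per-replication mean SMC from a table with FW/DW columns."""
    out = weights.copy()
    out["SMC"] = [smc(r.FW, r.DW) for r in out.itertuples()]
    if by and by in out.columns:
        return out.groupby(by, as_index=False)["SMC"].mean()
    return out[["SMC"]]
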