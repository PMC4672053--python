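"""Synthetic gas-exchange + fluorescence data generator.

Emulates the measurement campaign the analysis expects: for each
treatment × day cell, leaves with known (true) stomatal conductance,
mesophyll conductance, V_cmax, J_max and R_d are driven through a
13-step ambient-CO2 protocol (50–2000 μmol mol⁻¹) at saturating light
(PPFD = 1000 μmol m⁻² s⁻¹, 25 °C).  Every point is the exact steady
state of the coupled diffusion–FvCB model, so before noise
A = g_sc (C_a − C_i) = g_m (C_i − C_c) holds to solver precision.

Fluorescence signals are constructed to be *consistent with the gas
exchange*: the generating electron transport at each point is the
actual (consumption) rate J = (A_N + R_d)(4C_c + 8Γ*)/(C_c − Γ*) —
equal to the potential light-response rate whenever RuBP regeneration
limits, lower when Rubisco limits, exactly as a fluorometer reports —
and is folded into F_s through ΦPSII = J/(PPFD·0.5·0.85) at an
arbitrary F_m′ scale.  Measurement noise is multiplicative Gaussian on
A_N and F_s only; CO2 set-points and PPFD are treated as exact.
Stomatal conductance is held fixed within a curve (no stomatal drift
during the protocol).

The default scenario mirrors the published treatment means (see
:mod:`photolim.tables`) with R_d = 1 μmol m⁻² s⁻¹ and 2% noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import fluorescence as fluo
from . import tables
from .errors import DomainError, ScenarioError
from .fvcb import FvCBParams, consumption_j, solve_steady_state
from .types import GSW_TO_GSC, ACiCurve, FluorescenceRecord, GasExchangeRecord

#: The 13 ambient-CO2 set-points of the response-curve protocol, μmol mol⁻¹.
DEFAULT_PROTOCOL = (50, 100, 150, 200, 250, 300, 400, 600, 800, 1000, 1200, 1600, 2000)

# arbitrary but fixed fluorescence scale (a.u.)
_FM_PRIME = 2000.0
_FO_PRIME = 400.0
_FO_DARK = 300.0
_FM_DARK = 1700.0  # F_v/F_m ≈ 0.824, a healthy dark-adapted leaf


@dataclass(frozen=True)
class CellSpec:
    """True parameters of one treatment × day cell."""

    treatment: str
    day: int
    g_sw: float     # stomatal conductance to water vapor, mol m⁻² s⁻¹
    g_m: float      # mesophyll conductance, mol CO2 m⁻² s⁻¹
    V_cmax: float
    J_max: float
    R_d: float = 1.0

    def __post_init__(self):
        for name in ("g_sw", "g_m", "V_cmax", "J_max", "R_d"):
            if not getattr(self, name) > 0:
                raise DomainError(f"{name} must be positive")


@dataclass(frozen=True)
class ScenarioSpec:
    """A full simulated measurement campaign."""

    cells: tuple
    protocol: tuple = DEFAULT_PROTOCOL
    PPFD: float = 1000.0
    noise_sd: float = 0.02
    n_leaves: int = 4
    seed: int = 0
    params: FvCBParams = field(default_factory=lambda: FvCBParams(V_cmax=1.0, J_max=1.0))

    def __post_init__(self):
        if len(self.protocol) < 5:
            raise DomainError("protocol needs at least 5 CO2 set-points")
        if self.noise_sd < 0:
            raise DomainError("noise_sd must be non-negative")
        if self.n_leaves < 1:
            raise DomainError("n_leaves must be at least 1")


def default_scenario(noise_sd: float = 0.02, n_leaves: int = 4, seed: int = 0) -> ScenarioSpec:
    """Scenario mirroring the published treatment means.

    One cell per published row (controls included, paired by day), true
    g_m / V_cmax / J_max equal to the published means and true g_sw the
    published CO2-basis stomatal conductance times 1.6; R_d = 1.
    """
    cells = []
    for r in tables.treatment_means().itertuples():
        cells.append(
            CellSpec(
                treatment=r.treatment,
                day=int(r.day),
                g_sw=r.g_sc * GSW_TO_GSC,
                g_m=r.g_m,
                V_cmax=r.V_cmax,
                J_max=r.J_max,
                R_d=1.0,
            )
        )
    return ScenarioSpec(
        cells=tuple(cells), noise_sd=noise_sd, n_leaves=n_leaves, seed=seed
    )


def generate(spec: ScenarioSpec) -> tuple[list[ACiCurve], pd.DataFrame]:
    """Generate curves and the truth table for a scenario.

    Returns ``(curves, truth)`` where ``truth`` has one row per leaf
    with the generating parameters.  Identical spec (including seed)
    gives bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    p0 = spec.params
    curves, truth_rows = [], []
    for cell in spec.cells:
        params = replace(p0, V_cmax=cell.V_cmax, J_max=cell.J_max, R_d=cell.R_d)
        g_sc = cell.g_sw / GSW_TO_GSC
        for k in range(spec.n_leaves):
            leaf_id = f"{cell.treatment}{cell.day}_L{k}"
            points = []
            for c_a in spec.protocol:
                try:
                    ss = solve_steady_state(c_a, g_sc, cell.g_m, params, spec.PPFD)
                except Exception as exc:  # noqa: BLE001 - re-raise with cell context
                    raise ScenarioError(
                        f"steady state failed for cell {cell.treatment}({cell.day}) "
                        f"at C_a={c_a}: {exc}"
                    ) from exc
                j_true = consumption_j(ss.A_N, cell.R_d, ss.C_c, params.Gamma_star)
                phi = j_true / (spec.PPFD * fluo.F_PSII * fluo.ABSORPTANCE)
                if not 0 < phi < 1:
                    raise ScenarioError(
                        f"cell {cell.treatment}({cell.day}): PhiPSII={phi:.3g} "
                        f"outside (0,1) at C_a={c_a}"
                    )
                f_s = _FM_PRIME * (1.0 - phi)
                a_obs = ss.A_N
                if spec.noise_sd > 0:
                    a_obs = a_obs * (1.0 + spec.noise_sd * rng.standard_normal())
                    f_s = f_s * (1.0 + spec.noise_sd * rng.standard_normal())
                    f_s = min(max(f_s, 1.0), _FM_PRIME * 0.999)
                gas = GasExchangeRecord(
                    A_N=a_obs, C_a=float(c_a), C_i=ss.C_i, g_sw=cell.g_sw, PPFD=spec.PPFD
                )
                fl = FluorescenceRecord(
                    F_s=f_s,
                    F_m_prime=_FM_PRIME,
                    F_o_prime=_FO_PRIME,
                    F_o=_FO_DARK,
                    F_m=_FM_DARK,
                )
                points.append((gas, fl))
            curves.append(
                ACiCurve(leaf_id=leaf_id, treatment=cell.treatment, day=cell.day, points=points)
            )
            truth_rows.append(
                {
                    "leaf_id": leaf_id,
                    "treatment": cell.treatment,
                    "day": cell.day,
                    "g_sw": cell.g_sw,
                    "g_sc": g_sc,
                    "g_m": cell.g_m,
                    "V_cmax": cell.V_cmax,
                    "J_max": cell.J_max,
                    "R_d": cell.R_d,
                    "PPFD": spec.PPFD,
                    "noise_sd": spec.noise_sd,
                }
            )
    return curves, pd.DataFrame(truth_rows)


def curves_to_frame(curves: list[ACiCurve]) -> pd.DataFrame:
    """Flatten curves into the canonical points table."""
    rows = []
    for c in curves:
        for gas, fl in c.points:
            row = {
                "leaf_id": c.leaf_id,
                "treatment": c.treatment,
                "day": c.day,
                "A_N": gas.A_N,
                "C_a": gas.C_a,
                "C_i": gas.C_i,
                "g_sw": gas.g_sw,
                "PPFD": gas.PPFD,
            }
            if fl is not None:
                row.update(
                    F_s=fl.F_s,
                    F_m_prime=fl.F_m_prime,
                    F_o_prime=fl.F_o_prime,
                    F_o=fl.F_o,
                    F_m=fl.F_m,
                )
            rows.append(row)
    return pd.DataFrame(rows)


def write_scenario(
    spec: ScenarioSpec, outdir: str | Path
) -> tuple[Path, Path]:
    """Generate a scenario and write ``curves.csv`` + ``truth.csv``.

    The generator seed is recorded in a comment header of both files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    curves, truth = generate(spec)
    paths = []
    for name, df in (("curves.csv", curves_to_frame(curves)), ("truth.csv", truth)):
        path = outdir / name
        with open(path, "w") as fh:
            fh.write(f"# seed={spec.seed} noise_sd={spec.noise_sd} n_leaves={spec.n_leaves}\n")
            df.to_csv(fh, index=False)
        paths.append(path)
    return tuple(paths)
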