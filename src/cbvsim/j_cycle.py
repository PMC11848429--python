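"""The J-cycle: three interconvertible nutrient variants.

Each variant receives a constant abiotic influx and a level-proportional
abiotic outflux; four biologically driven Michaelis--Menten reactions
interconvert the variants (A: J1->J2, B: J2->J1, C: J1->J3, D: J3->J2).
Reactions A and B leak a fraction ``eps_X`` of their throughput to the
X-cycle as byproducts.  Cycling ratios and the two cycle-biota-variant
(CBV) abundance indices are derived here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .params import ModelParams

__all__ = ["JState", "CBVMetrics", "reaction_rate", "j_derivatives", "cbv_metrics"]


@dataclass
class JState:
    J1: float
    J2: float
    J3: float

    def clamped(self) -> "JState":
        return JState(max(self.J1, 0.0), max(self.J2, 0.0), max(self.J3, 0.0))

    @property
    def total(self) -> float:
        return self.J1 + self.J2 + self.J3


@dataclass
class CBVMetrics:
    """Cycling ratios and CBV abundance indices.

    ``cbv_AB`` is the geometric mean of (cycling ratio x performer frequency)
    over the two reactions of the AB pathway; ``cbv_CDB`` the analogue over
    the three reactions of the CDB pathway.  The normalized shares sum to 1;
    when both raw indices are 0 the shares are reported as (0.5, 0.5) so the
    time series stays defined at degenerate states.
    """

    CR1: float
    CR2: float
    CR3: float
    cbv_AB: float
    cbv_CDB: float
    cbv_AB_norm: float
    cbv_CDB_norm: float


def reaction_rate(J_substrate: float, n_p: float, params: ModelParams) -> float:
    """Michaelis--Menten rate with biological enhancement.

    The performer population enhances effective substrate availability by
    BE = min(omega, n_p * rn_bar); the reaction then runs at
    Rmax * (J*BE) / (Km + J*BE).  Zero performers or zero substrate give a
    zero rate; the rate saturates strictly below Rmax.
    """
    BE = min(params.omega, n_p * params.rn_bar)
    if BE <= 0.0 or J_substrate <= 0.0:
        return 0.0
    JB = J_substrate * BE
    return params.Rmax * JB / (params.Km + JB)


def j_derivatives(
    state: JState,
    R_A: float,
    R_B: float,
    R_C: float,
    R_D: float,
    params: ModelParams,
) -> tuple[float, float, float]:
    """Deterministic (dJ1/dt, dJ2/dt, dJ3/dt).

    Only reactions A and B divert the byproduct fraction ``eps_X``; with
    eps_X = 0 and abiotic fluxes off, the reactions conserve total J.
    """
    Fin, Fout, e = params.Fin0, params.Fout0, params.eps_X
    dJ1 = Fin - state.J1 * Fout - R_A + R_B * (1.0 - e) - R_C
    dJ2 = Fin - state.J2 * Fout + R_A * (1.0 - e) - R_B + R_D
    dJ3 = Fin - state.J3 * Fout + R_C - R_D
    return dJ1, dJ2, dJ3


def cbv_metrics(
    state: JState,
    p_A: float,
    p_B: float,
    p_C: float,
    p_D: float,
    params: ModelParams,
) -> CBVMetrics:
    """Cycling ratios, raw CBV indices and their normalized shares."""
    CR1 = state.J1 / params.Ji0
    CR2 = state.J2 / params.Ji0
    CR3 = state.J3 / params.Ji0
    ab = CR1 * p_A * CR2 * p_B
    cbv_AB = math.sqrt(ab) if ab > 0.0 else 0.0
    cdb = CR1 * p_C * CR3 * p_D * CR2 * p_B
    cbv_CDB = cdb ** (1.0 / 3.0) if cdb > 0.0 else 0.0
    tot = cbv_AB + cbv_CDB
    if tot > 0.0:
        ab_norm = cbv_AB / tot
        cdb_norm = cbv_CDB / tot
    else:
        ab_norm = cdb_norm = 0.5
    return CBVMetrics(CR1, CR2, CR3, cbv_AB, cbv_CDB, ab_norm, cdb_norm)
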