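"""The X-cycle: byproduct pools, reservoir titration/release, bistable
feedback, and the suppression function alpha(X).

Byproducts XA and XB of reactions A and B react together (flux Xvar) and
"titrate" an initially unavailable solid-state reservoir Xres.  Material
titrated from Xres passes through a transition pool Xres2 and is released
into the main X pool only once Xres is exhausted -- the release then pushes
X into the upper branch of an inherently bistable feedback, where the
suppression function alpha(X) switches on and imposes per-capita mortality
on species C (the coupling that lets one cycle-biota variant displace the
other).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .params import ModelParams

__all__ = [
    "XState",
    "xvar_flux",
    "byproduct_derivatives",
    "reservoir_step",
    "feedback_flux",
    "suppression_alpha",
    "x_derivative",
]


@dataclass
class XState:
    X: float        # main pool
    XA: float       # byproduct pool of reaction A
    XB: float       # byproduct pool of reaction B
    Xres: float     # unreleased solid-state reservoir (non-increasing)
    Xres2: float    # transition pool between titration and release


def xvar_flux(XA: float, XB: float, params: ModelParams) -> float:
    """Byproduct-reaction flux: Xvar0*Rmax*(XA*XB)/(Km + XA*XB).

    One unit of XA and one of XB react to one unit of X-cycle material;
    the flux vanishes when either pool is empty and saturates below
    Xvar0*Rmax.
    """
    prod = XA * XB
    if prod <= 0.0:
        return 0.0
    return params.Xvar0 * params.Rmax * prod / (params.Km + prod)


def byproduct_derivatives(
    XA: float, XB: float, R_A: float, R_B: float, Xvar: float, params: ModelParams
) -> tuple[float, float]:
    """(dXA/dt, dXB/dt): byproduct input minus removal minus reaction draw."""
    dXA = params.eps_X * R_A - params.Xout0 * XA - Xvar
    dXB = params.eps_X * R_B - params.Xout0 * XB - Xvar
    return dXA, dXB


def reservoir_step(
    Xres: float, Xres2: float, Xvar: float, params: ModelParams
) -> tuple[float, float, float]:
    """(dXres/dt, dXres2/dt, Xrelease).

    The reservoir is consumed at rate Xvar*Xres; its material accumulates in
    the transition pool.  Release is gated: zero while any reservoir
    remains, then Xrel0*(Xres2 + Xvar) -- all titrated material plus the
    incoming flux passes through.  The exhaustion test treats levels below
    ``xres_eps`` as zero (the trajectory decays multiplicatively and would
    otherwise never reach zero exactly).
    """
    dXres = -Xvar * Xres
    if Xres > 0.0:
        Xrelease = 0.0
    else:
        Xrelease = params.Xrel0 * (Xres2 + Xvar)
    dXres2 = -dXres - Xrelease
    return dXres, dXres2, Xrelease


def feedback_flux(X: float, params: ModelParams) -> float:
    """Bistable feedback input, nonzero essentially only for Xon < X < Xoff.

    Product of a rising sigmoid at Xon and a falling sigmoid at Xoff, scaled
    by Xfeedback0; with the abiotic in/out fluxes this gives the X pool two
    stable states separated by an unstable region.
    """
    lo = 1.0 / (1.0 + math.exp(-params.a * (X - params.Xon)))
    hi = 1.0 / (1.0 + math.exp(params.b * (X - params.Xoff)))
    return params.Xfeedback0 * lo * hi


def suppression_alpha(X: float, params: ModelParams) -> float:
    """Suppression function alpha(X): 0 below Xsuppress, sigmoidal above.

    At the threshold itself alpha = alpha0/2; the steepness ``k_alpha``
    smooths what would otherwise be a discontinuous switch.
    """
    if X < params.Xsuppress:
        return 0.0
    return params.alpha0 / (1.0 + math.exp(-params.k_alpha * (X - params.Xsuppress)))


def x_derivative(
    X: float, Xrelease: float, Xfeedback: float, params: ModelParams
) -> float:
    """dX/dt = Xin0 - Xout0*X + Xrelease + Xfeedback."""
    return params.Xin0 - params.Xout0 * X + Xrelease + Xfeedback
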