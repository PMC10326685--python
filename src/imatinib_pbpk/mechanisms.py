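"""Closed-form pharmacokinetic primitives.

Saturable plasma protein binding to alpha-1-acid glycoprotein (AAG),
abundance-scaled unbound intrinsic clearance, the well-stirred liver
model and GFR-scaled renal clearance.  These are the building blocks the
ODE engine evaluates at every right-hand-side call, so they are written
as scalar functions of plain floats.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .config import (DomainError, DrugModel, SystemDefaults,
                     HEPATIC_ENZYMES, TRANSPORTERS)

__all__ = [
    "BindingState",
    "unbound_fraction",
    "binding_state",
    "hepatic_intrinsic_clearance",
    "well_stirred_hepatic_clearance",
    "renal_clearance_individual",
]


@dataclass
class BindingState:
    """Plasma binding equilibrium at one total drug concentration."""
    c_total: float    # mg/L
    aag: float        # g/L
    fu: float         # unbound fraction
    c_unbound: float  # mg/L


def unbound_fraction(c_total: float, aag: float, kd_app: float,
                     capacity: float = 1.0,
                     mw_drug: float = 493.6,
                     mw_aag: float = 44000.0) -> float:
    """Unbound fraction from one-site saturable AAG binding.

    The equilibrium ``drug + site <-> complex`` with total site
    concentration ``capacity * aag`` gives a quadratic in the unbound
    drug concentration; the physical (positive) root is taken.  In the
    dilute-drug limit this reduces to the linear form
    ``fu = 1 / (1 + capacity * aag / kd_app)``, which is how ``kd_app``
    (g/L of AAG scale) is calibrated from a measured reference fu.

    fu is non-decreasing in ``c_total`` (binding saturates) and
    non-increasing in ``aag``.
    """
    if c_total < 0.0 or aag < 0.0:
        raise DomainError("concentrations must be non-negative")
    if kd_app <= 0.0:
        raise DomainError(f"kd_app must be positive, got {kd_app!r}")
    if aag == 0.0:
        return 1.0
    # molar scale: kd_app in g/L of AAG corresponds to kd_app/mw_aag mol/L
    kd = kd_app / mw_aag
    sites = capacity * aag / mw_aag
    ct = c_total * 1e-3 / mw_drug  # mg/L -> mol/L
    if ct <= 0.0 or ct < 1e-12 * sites:
        return kd / (kd + sites)
    # cu^2 + cu*(kd + sites - ct) - kd*ct = 0
    b = kd + sites - ct
    cu = 0.5 * (-b + math.sqrt(b * b + 4.0 * kd * ct))
    return cu / ct


def binding_state(c_total: float, aag: float, kd_app: float,
                  capacity: float = 1.0, mw_drug: float = 493.6,
                  mw_aag: float = 44000.0) -> BindingState:
    fu = unbound_fraction(c_total, aag, kd_app, capacity, mw_drug, mw_aag)
    return BindingState(c_total=c_total, aag=aag, fu=fu, c_unbound=fu * c_total)


def hepatic_intrinsic_clearance(ind, drug: DrugModel,
                                enzyme_activity: dict | None = None) -> dict:
    """Unbound hepatic intrinsic clearance, L/h, by pathway.

    Metabolic pathways scale linearly with enzyme abundance (pmol/mg
    microsomal protein), relative activity, MPPGL (mg/g liver) and liver
    weight (g); the fixed minor-CYP pathway scales with liver size only.
    Biliary (P-gp / BCRP) intrinsic clearance scales with transporter
    abundance and relative liver size.  Returns a dict with one entry per
    pathway plus ``"total"``.
    """
    act = enzyme_activity or {}
    scale = ind.mppgl * ind.liver_weight * 60.0e-6  # uL/min -> L/h
    out = {}
    for enz in HEPATIC_ENZYMES:
        if enz == "other_CYP":
            abundance = 1.0  # fixed pseudo-abundance, non-inhibitable
            activity = 1.0
        else:
            abundance = ind.enzyme_abundance[enz]
            activity = act.get(enz, 1.0)
        if activity < 0:
            raise DomainError(f"negative activity for {enz}")
        out[enz] = drug.clint_per_pmol[enz] * abundance * activity * scale
    liver_scale = ind.liver_weight / ind.liver_weight_ref
    for t in TRANSPORTERS:
        out[f"biliary_{t}"] = (drug.clint_biliary_per_abundance[t]
                               * ind.transporter_abundance[t] * liver_scale)
    out["total"] = sum(out.values())
    return out


def well_stirred_hepatic_clearance(qh: float, fu_blood: float,
                                   clint_u: float) -> float:
    """Well-stirred liver model: CLh = Qh*fub*CLint / (Qh + fub*CLint).

    ``fu_blood`` is the unbound fraction in blood, i.e. fu plasma divided
    by the blood:plasma concentration ratio.  Monotone non-decreasing in
    every argument; approaches Qh as fub*CLint grows (flow limit).
    """
    if qh < 0 or fu_blood < 0 or clint_u < 0:
        raise DomainError("well-stirred inputs must be non-negative")
    x = fu_blood * clint_u
    if qh == 0.0:
        return 0.0
    return qh * x / (qh + x)


def renal_clearance_individual(ind, drug: DrugModel,
                               egfr_ref: float = 100.0,
                               bsa_ref: float = 1.73,
                               fu_scaling: bool | None = None) -> float:
    """Individual renal clearance scaled from the reference patient value.

    The reference clearance (measured in patients) is scaled by absolute
    glomerular filtration: the normalized eGFR times body surface area
    relative to 1.73 m^2.  Optionally it also scales with the individual's
    dilute-drug unbound fraction relative to the reference fu (filtration
    of unbound drug only); the shipped configuration disables this because
    the empirical patient value is applied per unit GFR.
    """
    if ind.egfr is None:
        raise DomainError("individual has no eGFR set")
    if fu_scaling is None:
        fu_scaling = drug.renal_fu_scaling
    cl = drug.cl_renal_ref * (ind.egfr / egfr_ref) * (ind.bsa / bsa_ref)
    if fu_scaling:
        cl *= ind.fu_baseline / drug.fu_ref
    return max(cl, 0.0)
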