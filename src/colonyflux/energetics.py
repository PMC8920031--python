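"""Activity-based daily energy expenditure.

DEE_act = sum over behaviours of MR_b * T_b, where MR_b is the
activity-specific metabolic rate (ml CO2 g^-1 day^-1) and T_b the
proportion of time in behaviour b; respired CO2 converts to energy with
the caloric equivalent (default 27.63 J per ml CO2), giving a
mass-specific DEE in kJ g^-1 day^-1.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .config import BEHAVIOURS, MRConfig
from .containers import DeeEstimate, TimeActivityBudget


def convert_co2_to_joules(volume_ml, caloric_equivalent: float = 27.63):
    """Energy (J) from a respired CO2 volume (ml)."""
    v = np.asarray(volume_ml, float)
    if (v < 0).any():
        raise ValueError("CO2 volume must be non-negative")
    if caloric_equivalent <= 0:
        raise ValueError("caloric equivalent must be positive")
    out = v * caloric_equivalent
    return float(out) if np.isscalar(volume_ml) else out


def compute_dee(
    budget: TimeActivityBudget,
    mr: MRConfig,
    body_mass_g: Optional[float] = None,
) -> DeeEstimate:
    """Mass-specific DEE for one bird; absolute DEE too if mass given."""
    errs = mr.validate()
    if errs:
        raise ValueError("; ".join(errs))
    ml_co2 = float(budget.proportions @ mr.as_vector())  # ml CO2 g^-1 day^-1
    dee = convert_co2_to_joules(ml_co2, mr.caloric_equivalent) / 1000.0  # kJ g^-1 d^-1
    absolute = dee * body_mass_g if body_mass_g is not None else None
    return DeeEstimate(dee_act=dee, bird_id=budget.bird_id, dee_absolute=absolute)


def solve_mr_from_stage_means(
    stage_budgets: np.ndarray,
    stage_dee_means: np.ndarray,
    caloric_equivalent: float = 27.63,
    cond_max: float = 1e8,
) -> MRConfig:
    """Calibrate activity-specific metabolic rates from stage summaries.

    Solves the 3x3 linear system DEE_stage = B_stage . MR for the three
    rates, where each row of ``stage_budgets`` is a stage's
    (flight, colony, water) budget and ``stage_dee_means`` the matching
    mass-specific DEE means in kJ g^-1 day^-1.  Rejects singular systems
    and non-positive solutions.
    """
    B = np.asarray(stage_budgets, float)
    d = np.asarray(stage_dee_means, float)
    if B.shape != (3, 3) or d.shape != (3,):
        raise ValueError("need a 3x3 budget matrix and 3 stage DEE means")
    cond = np.linalg.cond(B)
    if not np.isfinite(cond) or cond > cond_max:
        raise ValueError(f"stage budget system is singular (condition number {cond:.3g})")
    mr_kj = np.linalg.solve(B, d)  # kJ g^-1 day^-1 per behaviour
    if (mr_kj <= 0).any():
        raise ValueError(
            "calibration produced a non-positive metabolic rate "
            f"(condition number {cond:.3g}): " +
            ", ".join(f"{b}={v:.4g}" for b, v in zip(BEHAVIOURS, mr_kj))
        )
    mr_ml = mr_kj * 1000.0 / caloric_equivalent
    return MRConfig(
        mr_flight=float(mr_ml[0]),
        mr_colony=float(mr_ml[1]),
        mr_water=float(mr_ml[2]),
        caloric_equivalent=caloric_equivalent,
    )
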