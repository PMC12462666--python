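"""Two-step stochastic kinetic model of nucleoid supercompaction.

Cells progress irreversibly through compaction states

    multifocal -> quarter -> {midcell | periseptal}

after a deterministic lag.  Both transitions are first-order (exponential
waiting times with rates ``k1`` and ``k2`` per minute); the terminal branch
is periseptal with probability ``p_periseptal`` (a forming septum blocks
complete convergence at the cell center) and midcell otherwise.  Drug dose
maps to rate through a Hill function, which makes progression monotonically
faster with dose.

The closed-form occupancy of the terminal states ("endpoint fraction") for
lag ``T`` and elapsed time ``t`` with ``tau = t - T > 0`` is the classic
two-stage sequential-exponential result

    P_end(t) = 1 - (k2 e^{-k1 tau} - k1 e^{-k2 tau}) / (k2 - k1)

with the ``k1 == k2 == k`` limit ``1 - e^{-k tau} (1 + k tau)``.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from pydantic import BaseModel, Field, model_validator
from scipy.optimize import brentq

# Integer state codes, ordered: transitions never decrease the code.
MULTIFOCAL, QUARTER, MIDCELL, PERISEPTAL = 0, 1, 2, 3
STATE_NAMES = {0: "multifocal", 1: "quarter", 2: "midcell", 3: "periseptal"}
ENDPOINT_STATES = (MIDCELL, PERISEPTAL)


class KineticsConfig(BaseModel):
    """Rates and dose-response parameters of the supercompaction process.

    With ``use_dose_response=True`` both step rates are replaced by
    ``k_eff = k_max * dose^hill / (dose^hill + ec50^hill)``.
    """

    k1_per_min: float = Field(default=0.25, ge=0)
    k2_per_min: float = Field(default=0.35, ge=0)
    lag_min: float = Field(default=8.0, ge=0)
    p_periseptal: float = Field(default=0.15, ge=0, le=1)
    dose: float = Field(default=0.0, ge=0)
    k_max_per_min: float = Field(default=0.5, gt=0)
    ec50: float = Field(default=1.0, gt=0)
    hill: float = Field(default=2.0, gt=0)
    use_dose_response: bool = False

    @model_validator(mode="after")
    def _check(self):
        return self


def effective_rates(kin: KineticsConfig) -> tuple[float, float]:
    """(k1, k2) in 1/min after applying the dose-response mapping if enabled."""
    if not kin.use_dose_response:
        return kin.k1_per_min, kin.k2_per_min
    d, h = kin.dose, kin.hill
    if d == 0.0:
        k = 0.0
    else:
        dh = d**h
        k = kin.k_max_per_min * dh / (dh + kin.ec50**h)
    return k, k


def advance_states(
    states: np.ndarray,
    dt_min: float,
    kin: KineticsConfig,
    rng: np.random.Generator,
    t_min: float = 0.0,
) -> np.ndarray:
    """Advance per-cell states over one time step of ``dt_min`` minutes.

    ``t_min`` is the elapsed time at the start of the step; only the part of
    the step after ``lag_min`` contributes to transition probability, so the
    lag is honoured exactly regardless of frame alignment.
    """
    if dt_min <= 0:
        raise ValueError("dt_min must be positive")
    states = np.asarray(states, dtype=np.int64).copy()
    dt_eff = max(0.0, (t_min + dt_min) - max(t_min, kin.lag_min))
    if dt_eff == 0.0:
        return states
    k1, k2 = effective_rates(kin)
    p1 = 1.0 - np.exp(-k1 * dt_eff)
    p2 = 1.0 - np.exp(-k2 * dt_eff)

    u = rng.random(states.shape)
    # Order matters: evaluate the quarter->endpoint step before promoting
    # multifocal cells, so no cell takes two steps within one dt.
    quarter = states == QUARTER
    moving = quarter & (u < p2)
    branch = rng.random(states.shape) < kin.p_periseptal
    states[moving & branch] = PERISEPTAL
    states[moving & ~branch] = MIDCELL

    multi = states == MULTIFOCAL
    states[multi & (u < p1)] = QUARTER
    return states


def endpoint_fraction(t_min, kin: KineticsConfig):
    """Closed-form probability of having reached an endpoint state by ``t_min``."""
    k1, k2 = effective_rates(kin)
    t = np.asarray(t_min, dtype=float)
    tau = np.clip(t - kin.lag_min, 0.0, None)
    if k1 == 0.0 or k2 == 0.0:
        out = np.zeros_like(tau)
    elif np.isclose(k1, k2, rtol=1e-12, atol=0.0):
        out = 1.0 - np.exp(-k1 * tau) * (1.0 + k1 * tau)
    else:
        out = 1.0 - (k2 * np.exp(-k1 * tau) - k1 * np.exp(-k2 * tau)) / (k2 - k1)
    out = np.clip(out, 0.0, 1.0)
    return float(out) if np.isscalar(t_min) else out


def state_occupancies(t_min: float, kin: KineticsConfig) -> dict[str, float]:
    """Expected fractions of the three macro-stages at time ``t_min``."""
    k1, k2 = effective_rates(kin)
    tau = max(0.0, t_min - kin.lag_min)
    p_multi = float(np.exp(-k1 * tau)) if k1 > 0 else 1.0
    p_end = endpoint_fraction(t_min, kin)
    p_quarter = max(0.0, 1.0 - p_multi - p_end)
    return {
        "multifocal": p_multi,
        "quarter": p_quarter,
        "midcell": p_end * (1.0 - kin.p_periseptal),
        "periseptal": p_end * kin.p_periseptal,
    }


def crossing_time_analytic(
    kin: KineticsConfig, threshold: float = 0.10, t_max_min: float = 1e4
) -> Optional[float]:
    """Time (min) at which the closed-form endpoint fraction crosses ``threshold``.

    Returns None when the threshold is never reached (e.g. zero rates).
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    k1, k2 = effective_rates(kin)
    if k1 == 0.0 or k2 == 0.0:
        return None
    f = lambda t: endpoint_fraction(t, kin) - threshold
    if f(t_max_min) < 0:
        return None
    return float(brentq(f, kin.lag_min, t_max_min, xtol=1e-10))
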