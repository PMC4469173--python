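"""Normal-tissue complication probability models for lung.

Three models of pneumonitis risk are implemented:

* the Lyman-Kutcher-Burman (LKB) probit model on the mean lung dose,
* the relative-seriality model on the per-FSU damage probability, and
* a tissue-rescue-unit (TRU) model in which complication arises when all
  TRUs in every lung shell are killed (a Poisson product over shells with a
  partial-volume factor v^c on the lethality exponent).

The LKB model takes the physical mean lung dose; the seriality model takes
the mean lung BED; the TRU model takes the full radial lung BED profile.
Mixing dose and BED between models mirrors how the parameter sets were
originally reported for each model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .radiobiology import BEDProfile, BiologicalParams

__all__ = [
    "LKBParams",
    "SerialityParams",
    "TRUParams",
    "ntcp_lkb",
    "ntcp_relative_seriality",
    "ntcp_tru",
]

#: total FSU count of a 5000 cm^3 lung divided into 250 um radius subunits
K_LUNG_TOTAL = 76_394_192


@dataclass(frozen=True)
class LKBParams:
    """LKB probit parameters (external-beam pneumonitis values)."""

    td50: float = 30.8  # [Gy]
    m: float = 0.37  # slope

    def __post_init__(self) -> None:
        if self.td50 <= 0 or self.m <= 0:
            raise ValueError("td50 and m must be positive")


@dataclass(frozen=True)
class SerialityParams:
    """Relative-seriality parameters for the whole lung."""

    s: float = 0.0061  # seriality; near zero = parallel organ
    k_lung: int = K_LUNG_TOTAL  # total FSU count

    def __post_init__(self) -> None:
        if self.s == 0:
            raise ValueError("seriality s must be non-zero")
        if self.k_lung < 1:
            raise ValueError("k_lung must be >= 1")


@dataclass(frozen=True)
class TRUParams:
    """Tissue-rescue-unit model parameters."""

    c: float = -0.98  # volume-effect exponent
    v: float = 1.0  # fractional partial volume (N_tot / N_lung)

    def __post_init__(self) -> None:
        if self.v <= 0 or self.v > 1:
            raise ValueError("partial volume v must lie in (0, 1]")


def ntcp_lkb(mld: float, params: LKBParams = LKBParams()) -> float:
    """LKB complication probability at mean lung dose ``mld`` [Gy]."""
    if mld < 0:
        raise ValueError("mean lung dose must be non-negative")
    t = (mld - params.td50) / (params.m * params.td50)
    return float(norm.cdf(t))


def ntcp_relative_seriality(p_fsu: float,
                            params: SerialityParams = SerialityParams()) -> float:
    """Relative-seriality NTCP: [1 - (1 - p^s)^K]^(1/s), evaluated in log space."""
    if not 0.0 <= p_fsu <= 1.0:
        raise ValueError("p_fsu must lie in [0, 1]")
    if p_fsu == 0.0:
        return 0.0
    if p_fsu == 1.0:
        return 1.0
    s, k = params.s, params.k_lung
    log_p_s = s * math.log(p_fsu)  # log(p^s)
    p_s = math.exp(log_p_s)
    if p_s >= 1.0:  # underflow guard for s*log(p) ~ 0
        return 1.0
    log_inner = k * math.log1p(-p_s)  # log((1 - p^s)^K)
    if log_inner < -745.0:  # exp underflows; NTCP -> 1
        return 1.0
    inner = math.exp(log_inner)
    if log_inner == 0.0:  # p^s underflowed; 1 - (1-p^s)^K ~ K p^s
        log_one_minus = math.log(k) + log_p_s
    elif inner >= 1.0:  # 1 - inner underflows; use 1 - e^x ~ -x for tiny x
        log_one_minus = math.log(-log_inner)
    else:
        log_one_minus = math.log1p(-inner)
    return float(math.exp(log_one_minus / s))


def ntcp_tru(
    bed_lung,
    n_tru_per_shell: np.ndarray,
    lung_bio: BiologicalParams,
    params: TRUParams = TRUParams(),
    reading: str = "exponent",
) -> float:
    """TRU-model NTCP from the per-shell lung BED profile.

    ``n_tru_per_shell`` gives the initial TRU count in each lung tally shell
    (zero inside the tumour).  The default ``reading`` applies the
    partial-volume factor ``v^c`` as a multiplier on the Poisson lethality
    exponent,

        NTCP = prod_r exp(-N_r * exp(-alpha * BED(r)) * v^c)

    (note that raising the completed product to ``v^c`` is algebraically the
    same choice); ``reading='inner'`` instead scales the kill exponent,
    ``exp(-alpha * BED * v^c)``.  The published form is typographically
    ambiguous, so both readings are kept behind this single switch.
    """
    values = np.asarray(getattr(bed_lung, "values", bed_lung), dtype=float)
    n_tru = np.asarray(n_tru_per_shell, dtype=float)
    if len(values) < len(n_tru) and np.any(n_tru[len(values):] > 0):
        raise ValueError("BED profile does not cover all lung shells")
    values = values[: len(n_tru)]
    vc = params.v ** params.c
    if reading == "exponent":
        surv = n_tru * np.exp(-lung_bio.alpha * values) * vc
    elif reading == "inner":
        surv = n_tru * np.exp(-lung_bio.alpha * values * vc)
    else:
        raise ValueError("reading must be 'exponent' or 'inner'")
    return float(np.exp(-np.sum(surv)))
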