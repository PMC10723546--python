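"""Two-phase mutation-rate chronology: molecular time <-> years before sampling.

The clonal mutation rate is ``clock_rate`` (mutations/Mb/year) from birth until
``initiation_lead`` years before sampling, then ``acceleration`` times that
until sampling. Molecular time t is the fraction of the final clonal burden
accrued before a copy-number event; inverting the cumulative-rate function
converts it to a chronological event age and hence a lead time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from ..cohort_io.model import InvalidInputError

logger = logging.getLogger(__name__)


@dataclass
class RateModel:
    """Piecewise-constant somatic clock."""

    clock_rate: float = 0.05  # mutations per Mb per year, pre-initiation
    acceleration: float = 5.0  # post-initiation rate multiplier, >= 1
    initiation_lead: float = 10.0  # years before sampling at which acceleration starts

    def __post_init__(self) -> None:
        if self.clock_rate <= 0:
            raise InvalidInputError("clock_rate must be positive")
        if self.acceleration < 1:
            raise InvalidInputError("acceleration must be >= 1")
        if self.initiation_lead < 0:
            raise InvalidInputError("initiation_lead must be >= 0")

    def total_burden(self, age: float) -> float:
        """Expected clonal burden per Mb at sampling for a tumour of this age."""
        if self.initiation_lead > age:
            raise InvalidInputError("initiation_lead exceeds age at sampling")
        tau = self.initiation_lead
        return self.clock_rate * (age - tau) + self.acceleration * self.clock_rate * tau


def chronological_lead_time(
    t: float,
    age: float,
    model: RateModel,
    burden_per_mb: float | None = None,
    rescale_tolerance: float = 0.2,
) -> float:
    """Years between a copy-number event at molecular time ``t`` and sampling.

    If the observed ``burden_per_mb`` disagrees with the model-implied burden
    by more than ``rescale_tolerance`` (relative), the clock rate is rescaled
    so the model reproduces the observed burden (logged).
    """
    if not (0.0 <= t <= 1.0):
        raise InvalidInputError(f"molecular time must be in [0,1], got {t}")
    model_burden = model.total_burden(age)
    r0 = model.clock_rate
    if burden_per_mb is not None:
        rel = abs(burden_per_mb - model_burden) / model_burden
        if rel > rescale_tolerance:
            scale = burden_per_mb / model_burden
            logger.warning(
                "observed burden %.3g/Mb deviates %.0f%% from model; rescaling clock rate by %.3g",
                burden_per_mb, 100 * rel, scale,
            )
            r0 = r0 * scale
            model_burden = burden_per_mb
    B = model_burden
    tau = model.initiation_lead
    a = model.acceleration
    pre_burden = t * B
    slow_burden = r0 * (age - tau)  # burden accrued by initiation
    if pre_burden <= slow_burden:
        gain_age = pre_burden / r0
    else:
        gain_age = (age - tau) + (pre_burden - slow_burden) / (a * r0)
    lead = age - gain_age
    return max(0.0, min(age, lead))


def molecular_time_of_lead(lead: float, age: float, model: RateModel) -> float:
    """Inverse of :func:`chronological_lead_time` under the model-implied burden."""
    if not (0.0 <= lead <= age):
        raise InvalidInputError("lead time must be in [0, age]")
    tau = model.initiation_lead
    r0 = model.clock_rate
    a = model.acceleration
    B = model.total_burden(age)
    gain_age = age - lead
    if gain_age <= age - tau:
        pre_burden = r0 * gain_age
    else:
        pre_burden = r0 * (age - tau) + a * r0 * (gain_age - (age - tau))
    return pre_burden / B
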