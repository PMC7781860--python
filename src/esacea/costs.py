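"""Cost inputs, currency conversion, and per-arm annual cost aggregation.

All internal computation is carried in USD at full float precision; rounding
happens only at rendering (2 decimals, half-up).  The Saudi Riyal conversion
uses the study-period rate of 3.77 SAR per USD by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

from .exceptions import CurrencyError, ValidationError

__all__ = [
    "MoneyAmount",
    "ArmCostProfile",
    "SAR_PER_USD",
    "sar_to_usd",
    "usd_to_sar",
    "annual_arm_cost",
    "cost_saving",
    "round_half_up",
    "STAFFING_ITEMS",
    "DARBEPOETIN_COST_PROFILE",
    "EPOETIN_COST_PROFILE",
]

SAR_PER_USD = 3.77


@dataclass(frozen=True)
class MoneyAmount:
    value: float
    currency: str  # "SAR" | "USD"

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValidationError("money amounts must be non-negative")
        if self.currency not in ("SAR", "USD"):
            raise CurrencyError(f"unsupported currency {self.currency!r}")


def sar_to_usd(amount: MoneyAmount, rate: float = SAR_PER_USD) -> MoneyAmount:
    """Convert Saudi Riyals to US Dollars at ``rate`` SAR per USD."""
    if amount.currency != "SAR":
        raise CurrencyError(f"expected SAR, got {amount.currency}")
    if rate <= 0:
        raise ValidationError("conversion rate must be positive")
    return MoneyAmount(amount.value / rate, "USD")


def usd_to_sar(amount: MoneyAmount, rate: float = SAR_PER_USD) -> MoneyAmount:
    if amount.currency != "USD":
        raise CurrencyError(f"expected USD, got {amount.currency}")
    if rate <= 0:
        raise ValidationError("conversion rate must be positive")
    return MoneyAmount(amount.value * rate, "SAR")


@dataclass(frozen=True)
class ArmCostProfile:
    """Direct medical cost components for one arm, USD per patient per year."""

    arm: str
    staffing: tuple[tuple[str, float], ...] = ()
    drug_cost: float = 0.0
    hospitalization: float = 0.0

    def __post_init__(self) -> None:
        if self.drug_cost < 0 or self.hospitalization < 0:
            raise ValidationError("cost components must be non-negative")
        for label, v in self.staffing:
            if v < 0:
                raise ValidationError(f"negative staffing cost for {label!r}")


def annual_arm_cost(profile: ArmCostProfile, include_hospitalization: bool = True,
                    include_drug: bool = True) -> float:
    """Sum of the included cost components, USD per patient per year."""
    total = sum(v for _, v in profile.staffing)
    if include_drug:
        total += profile.drug_cost
    if include_hospitalization:
        total += profile.hospitalization
    return total


def cost_saving(cost_a: float, cost_b: float) -> float:
    """Signed difference cost_a - cost_b, USD."""
    return cost_a - cost_b


def round_half_up(x: float, decimals: int = 2) -> float:
    q = Decimal(1).scaleb(-decimals) if decimals > 0 else Decimal(1)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


# Base-case direct medical cost items, USD per patient per year.  The staffing
# block is shared between arms; drug and hospitalization costs are arm-specific.
STAFFING_ITEMS: tuple[tuple[str, float], ...] = (
    ("medical_consultant", 3405.6),
    ("medical_specialist", 2311.2),
    ("nutritional_specialist", 1542.0),
    ("pharmacist", 1455.6),
    ("social_specialist", 1180.8),
)

DARBEPOETIN_COST_PROFILE = ArmCostProfile(
    arm="darbepoetin-alfa",
    staffing=STAFFING_ITEMS,
    drug_cost=6638.1,
    hospitalization=19050.759,
)

EPOETIN_COST_PROFILE = ArmCostProfile(
    arm="epoetin-beta",
    staffing=STAFFING_ITEMS,
    drug_cost=915.2,
    hospitalization=19155.7984,
)
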