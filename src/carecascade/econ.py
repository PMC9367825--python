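"""Cost, cost-utility, and cost-threshold analysis for clinic-level incentive programs.

The economic evaluation asks three questions per clinic:

1. What did the program cost, from the societal perspective (all resources
   consumed, including client-borne costs) and from the payor's perspective
   (societal minus client-related costs)?
2. What health did it buy?  The net number of participants who became
   virally suppressed is treated as person-years of suppression; infections
   averted ``A`` follow from the annual transmission rate of an unsuppressed
   person; QALYs saved combine improved individual health (Q1) and averted
   onward infections (Q2).
3. Was it worth it?  The cost-utility ratio R = (C - A*T) / (A*Q) gives the
   net cost per QALY (negative R means the program is dominant, i.e. cost
   saving), and threshold quantities C/T and C/W give the number of averted
   transmissions or saved QALYs at which the program breaks even.

All monetary arithmetic is exact-to-the-cent :class:`decimal.Decimal`; the
derived quantities A, Q1, Q2 are rounded to 2 decimals *before* entering the
ratio, which is the convention under which the bundled worked example
reproduces to the printed cent.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date
from decimal import Decimal, ROUND_HALF_UP
from typing import Literal

__all__ = [
    "EconConstants",
    "CostInputs",
    "CostUtilityResult",
    "total_cost",
    "unit_costs",
    "infections_averted",
    "qalys_saved",
    "cost_utility_ratio",
    "thresholds",
    "analyze_clinic",
    "example_cost_inputs",
    "example_net_suppressed",
    "to_money",
]

CENT = Decimal("0.01")


def to_money(value) -> Decimal:
    """Coerce a number or numeric string to an exact-cent Decimal (half-up)."""
    return Decimal(str(value)).quantize(CENT, rounding=ROUND_HALF_UP)


def _round2(value: Decimal) -> Decimal:
    return value.quantize(CENT, rounding=ROUND_HALF_UP)


@dataclass(frozen=True)
class EconConstants:
    """Literature-derived constants of the cost-utility model.

    lifetime_treatment_cost
        T, discounted lifetime medical cost of one HIV infection (USD).
    wtp_per_qaly
        W, societal willingness to pay for one QALY (USD).
    transmission_rate
        Expected annual onward transmissions from one unsuppressed person.
    qaly_per_py_suppressed
        QALYs gained per person-year of viral suppression (Q1 weight).
    qaly_per_averted_infection
        QALYs gained per averted HIV infection (Q2 weight).
    conservative_threshold
        A commonly used conservative cost-effectiveness bar (USD/QALY).
    """

    lifetime_treatment_cost: Decimal = Decimal("382954")
    wtp_per_qaly: Decimal = Decimal("195838.58")
    transmission_rate: Decimal = Decimal("0.061")
    qaly_per_py_suppressed: Decimal = Decimal("0.039")
    qaly_per_averted_infection: Decimal = Decimal("5.83")
    conservative_threshold: Decimal = Decimal("100000")

    def __post_init__(self):
        for name in (
            "lifetime_treatment_cost",
            "wtp_per_qaly",
            "transmission_rate",
            "qaly_per_py_suppressed",
            "qaly_per_averted_infection",
            "conservative_threshold",
        ):
            object.__setattr__(self, name, Decimal(str(getattr(self, name))))
            if getattr(self, name) <= 0:
                raise ValueError(f"EconConstants.{name} must be positive")


@dataclass(frozen=True)
class CostInputs:
    """Per-clinic micro-costing inputs over one analysis period."""

    clinic_id: str
    n_clients: int
    n_contacts: int
    client_costs: Decimal
    staff_costs: Decimal
    materials_costs: Decimal
    period_start: date | None = None
    period_end: date | None = None

    def __post_init__(self):
        for name in ("client_costs", "staff_costs", "materials_costs"):
            object.__setattr__(self, name, to_money(getattr(self, name)))
            if getattr(self, name) < 0:
                raise ValueError(f"{self.clinic_id}: {name} must be non-negative")
        if self.n_clients < 1:
            raise ValueError(f"{self.clinic_id}: n_clients must be >= 1")
        if self.n_contacts < 0:
            raise ValueError(f"{self.clinic_id}: n_contacts must be >= 0")


@dataclass(frozen=True)
class CostUtilityResult:
    """Full per-clinic output of the cost / cost-utility / threshold chain."""

    clinic_id: str
    C_societal: Decimal
    C_payor: Decimal
    per_client_societal: Decimal
    per_contact_societal: Decimal
    per_client_payor: Decimal
    per_contact_payor: Decimal
    net_suppressed: int
    A: Decimal
    Q1: Decimal
    Q2: Decimal
    Q: Decimal
    R_signed: Decimal
    R_reported: Decimal
    dominant: bool
    cost_saving_threshold: Decimal
    cost_effectiveness_threshold: Decimal
    stated_threshold: Decimal
    cost_effective: bool
    cost_effective_conservative: bool


Perspective = Literal["societal", "payor"]


def total_cost(inputs: CostInputs, perspective: Perspective = "societal") -> Decimal:
    """Total program cost from a perspective.

    Societal cost sums client-, staff-, and materials-related resources;
    the payor's perspective excludes the client-borne component.
    """
    societal = inputs.client_costs + inputs.staff_costs + inputs.materials_costs
    if perspective == "societal":
        return _round2(societal)
    if perspective == "payor":
        return _round2(societal - inputs.client_costs)
    raise ValueError(f"unknown perspective: {perspective!r}")


def unit_costs(total: Decimal, n_clients: int, n_contacts: int) -> dict[str, Decimal]:
    """Cost per enrolled client and per program contact, to the cent."""
    if n_clients < 1 or n_contacts < 1:
        raise ValueError("n_clients and n_contacts must be >= 1 for unit costs")
    total = Decimal(str(total))
    return {
        "per_client": _round2(total / n_clients),
        "per_contact": _round2(total / n_contacts),
    }


def infections_averted(net_suppressed: int, constants: EconConstants = EconConstants()) -> Decimal:
    """A = net_suppressed * annual transmission rate, rounded to 2 decimals."""
    if net_suppressed < 0:
        raise ValueError("net_suppressed must be >= 0")
    return _round2(Decimal(net_suppressed) * constants.transmission_rate)


def qalys_saved(
    net_suppressed: int,
    A: Decimal | None = None,
    constants: EconConstants = EconConstants(),
) -> dict[str, Decimal]:
    """QALYs from improved health (Q1), averted infections (Q2), and their sum.

    Q2 is computed from the already-rounded ``A`` so that the chain matches
    published per-step rounding exactly.
    """
    if net_suppressed < 0:
        raise ValueError("net_suppressed must be >= 0")
    if A is None:
        A = infections_averted(net_suppressed, constants)
    A = Decimal(str(A))
    q1 = _round2(constants.qaly_per_py_suppressed * Decimal(net_suppressed))
    q2 = _round2(constants.qaly_per_averted_infection * A)
    return {"Q1": q1, "Q2": q2, "Q": q1 + q2}


def cost_utility_ratio(
    C: Decimal,
    A: Decimal,
    Q: Decimal,
    constants: EconConstants = EconConstants(),
) -> dict:
    """Net cost per QALY, R = (C - A*T) / (A*Q), on 2-dp-rounded A and Q.

    ``R_signed`` keeps the algebraic sign (negative when averted lifetime
    treatment costs exceed program cost: the program dominates). ``R_reported``
    is the magnitude, the form in which such ratios are usually printed.
    """
    C, A, Q = Decimal(str(C)), Decimal(str(A)), Decimal(str(Q))
    if A <= 0 or Q <= 0:
        raise ZeroDivisionError("cost-utility ratio undefined for A == 0 or Q == 0")
    r_signed = _round2((C - A * constants.lifetime_treatment_cost) / (A * Q))
    r_reported = abs(r_signed)
    return {
        "R_signed": r_signed,
        "R_reported": r_reported,
        "dominant": r_signed < 0,
        "cost_effective": r_reported < constants.wtp_per_qaly,
        "cost_effective_conservative": r_reported < constants.conservative_threshold,
    }


def thresholds(
    C: Decimal,
    constants: EconConstants = EconConstants(),
    Q: Decimal | None = None,
) -> dict[str, Decimal]:
    """Break-even thresholds implied by program cost C.

    ``cost_saving`` (C/T): transmissions that must be averted before the
    program pays for itself in averted lifetime treatment costs.
    ``cost_effectiveness`` (C/W): QALYs that must be saved at society's
    willingness to pay.
    ``stated`` (C/(T + Q*W)): a combined form; Q defaults to the QALYs per
    averted infection since the combined denominator prices one averted
    infection plus its QALY stream.
    """
    C = Decimal(str(C))
    if C < 0:
        raise ValueError("cost must be non-negative")
    if Q is None:
        Q = constants.qaly_per_averted_infection
    Q = Decimal(str(Q))
    return {
        "cost_saving": _round2(C / constants.lifetime_treatment_cost),
        "cost_effectiveness": _round2(C / constants.wtp_per_qaly),
        "stated": _round2(C / (constants.lifetime_treatment_cost + Q * constants.wtp_per_qaly)),
    }


def analyze_clinic(
    inputs: CostInputs,
    net_suppressed: int,
    constants: EconConstants = EconConstants(),
) -> CostUtilityResult:
    """Run the full cost -> utility -> threshold chain for one clinic."""
    c_soc = total_cost(inputs, "societal")
    c_pay = total_cost(inputs, "payor")
    u_soc = unit_costs(c_soc, inputs.n_clients, inputs.n_contacts)
    u_pay = unit_costs(c_pay, inputs.n_clients, inputs.n_contacts)
    A = infections_averted(net_suppressed, constants)
    q = qalys_saved(net_suppressed, A, constants)
    ratio = cost_utility_ratio(c_soc, A, q["Q"], constants)
    thr = thresholds(c_soc, constants)
    return CostUtilityResult(
        clinic_id=inputs.clinic_id,
        C_societal=c_soc,
        C_payor=c_pay,
        per_client_societal=u_soc["per_client"],
        per_contact_societal=u_soc["per_contact"],
        per_client_payor=u_pay["per_client"],
        per_contact_payor=u_pay["per_contact"],
        net_suppressed=net_suppressed,
        A=A,
        Q1=q["Q1"],
        Q2=q["Q2"],
        Q=q["Q"],
        R_signed=ratio["R_signed"],
        R_reported=ratio["R_reported"],
        dominant=ratio["dominant"],
        cost_saving_threshold=thr["cost_saving"],
        cost_effectiveness_threshold=thr["cost_effectiveness"],
        stated_threshold=thr["stated"],
        cost_effective=ratio["cost_effective"],
        cost_effective_conservative=ratio["cost_effective_conservative"],
    )


def regional_index(cost: Decimal, factor: Decimal = Decimal("1")) -> Decimal:
    """Regional cost indexing hook; identity by default."""
    return _round2(Decimal(str(cost)) * Decimal(str(factor)))


def example_cost_inputs() -> list[CostInputs]:
    """Bundled three-clinic worked example of per-clinic cost inputs.

    These are the published micro-costing figures of a multi-site
    conditional-incentive program over one calendar year. Clinics B and C's
    materials components are the residuals of their published societal
    totals minus their client and staff components (the published component
    cells do not sum to the totals); contact counts are the ones implied by
    the published per-contact costs.
    """
    return [
        CostInputs("A", n_clients=214, n_contacts=642,
                   client_costs=Decimal("15515.00"),
                   staff_costs=Decimal("164781.00"),
                   materials_costs=Decimal("216614.00")),
        CostInputs("B", n_clients=106, n_contacts=700,
                   client_costs=Decimal("1303.80"),
                   staff_costs=Decimal("5819.24"),
                   materials_costs=Decimal("10075.01")),
        CostInputs("C", n_clients=227, n_contacts=454,
                   client_costs=Decimal("822.88"),
                   staff_costs=Decimal("18287.84"),
                   materials_costs=Decimal("5230.32")),
    ]


def example_net_suppressed() -> dict[str, int]:
    """Net newly-suppressed participant counts matching :func:`example_cost_inputs`."""
    return {"A": 22, "B": 6, "C": 9}
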