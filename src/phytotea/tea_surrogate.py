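"""Transparent surrogate of the field-to-product techno-economic model.

A deterministic batch mass balance (field growth -> extraction -> plate &
frame clarification -> UF/DF tangential-flow filtration -> cation-exchange
chromatography) and an economics layer producing the four forecast
variables: IRR after tax, cost of goods sold, annual throughput and product
purity.

Equipment is sized for the static base case, so stochastic inputs can
exceed rated capacities; following the fixed-sizing convention, yield and
recovery are then reduced to "effective" values — stream volume is clamped
at the field stage and product mass at the CEX stage — and every clamping
event is logged on the batch result.

Every structural constant (nominal biomass, volume ratios, membrane areas,
cost rates) lives in :class:`ProcessConfig` / :class:`EconomicsConfig` with
documented defaults chosen to give a plausible ultra-large-scale base case
(~100 t fresh weight per batch, COGS of a few $/g, double-digit base-case
IRR).  None of these constants reproduces any specific commercial facility.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "ProcessInputs",
    "EquipmentSpec",
    "ProcessConfig",
    "EconomicsConfig",
    "BatchResult",
    "EconomicsResult",
    "effective_clamp",
    "run_batch",
    "batch_duration",
    "economics",
    "cost_breakdown_at",
    "npv",
    "irr",
    "DEFAULT_SELLING_PRICES",
]

#: Three selling prices ($/g) spanning a pessimistic-to-optimistic market range.
DEFAULT_SELLING_PRICES = (4.0, 6.0, 8.0)

INPUT_NAMES = (
    "field_growth_yield",
    "field_growth_time",
    "expression_level",
    "harvest_time",
    "pf_recovery",
    "pf_flux",
    "tff_recovery",
    "tff_flux",
    "cex_recovery",
)


@dataclass(frozen=True)
class ProcessInputs:
    """One trial's sampled process inputs.

    field_growth_yield : fraction of nominal biomass actually harvested
    field_growth_time  : day, pre-induction field residence
    expression_level   : g product per kg fresh weight
    harvest_time       : h, mechanical harvesting duration
    pf_recovery/flux   : plate & frame clarification recovery (fraction) and
                         filtrate flux (L/m2/h)
    tff_recovery/flux  : UF/DF tangential-flow filtration recovery and flux
    cex_recovery       : cation-exchange chromatography recovery (fraction)
    """

    field_growth_yield: float
    field_growth_time: float
    expression_level: float
    harvest_time: float
    pf_recovery: float
    pf_flux: float
    tff_recovery: float
    tff_flux: float
    cex_recovery: float

    def __post_init__(self) -> None:
        for frac in ("field_growth_yield", "pf_recovery", "tff_recovery", "cex_recovery"):
            v = getattr(self, frac)
            if not 0 < v <= 1:
                raise ValueError(f"{frac} must be in (0, 1], got {v}")
        for pos in ("field_growth_time", "expression_level", "harvest_time", "pf_flux", "tff_flux"):
            v = getattr(self, pos)
            if not (v > 0 and math.isfinite(v)):
                raise ValueError(f"{pos} must be positive and finite, got {v}")

    @classmethod
    def from_mapping(cls, m: Mapping[str, float]) -> "ProcessInputs":
        return cls(**{k: float(m[k]) for k in INPUT_NAMES})


@dataclass(frozen=True)
class EquipmentSpec:
    """Fixed rated capacities of the base-case facility.

    ``oversize_factor`` scales both capacity caps multiplicatively (the
    facility-oversizing scenario family); the CEX product-mass cap
    additionally scales with the column cross-section,
    (cex_column_diameter / base_cex_diameter)^2.
    """

    max_stream_volume: float = 250_000.0  # L/batch, largest vessel/stream
    max_product_mass: float = 120.0  # kg/batch through the base CEX column
    cex_column_diameter: float = 1.0  # m
    base_cex_diameter: float = 1.0  # m, diameter the mass cap was rated at
    oversize_factor: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "max_stream_volume",
            "max_product_mass",
            "cex_column_diameter",
            "base_cex_diameter",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.oversize_factor < 1:
            raise ValueError("oversize_factor must be >= 1")

    @property
    def stream_volume_cap(self) -> float:
        return self.max_stream_volume * self.oversize_factor

    @property
    def product_mass_cap(self) -> float:
        area_ratio = (self.cex_column_diameter / self.base_cex_diameter) ** 2
        return self.max_product_mass * self.oversize_factor * area_ratio


@dataclass(frozen=True)
class ProcessConfig:
    """Structural constants of the surrogate mass balance."""

    nominal_biomass: float = 100_000.0  # kg FW/batch at 100% field yield
    extract_volume_ratio: float = 3.0  # L extraction buffer per kg FW
    pf_volume_fraction: float = 0.9  # clarified filtrate fraction of extract volume
    tff_concentration_factor: float = 10.0  # volume reduction across UF/DF
    pf_area: float = 200.0  # m2 plate & frame filter area
    tff_area: float = 100.0  # m2 TFF membrane area
    fixed_stage_hours: float = 24.0  # extraction + turnaround, flux-independent
    cex_hours: float = 8.0  # chromatography cycle time
    initial_purity: float = 0.05  # product fraction of total soluble protein in extract
    pf_enrichment: float = 1.6
    tff_enrichment: float = 2.5
    cex_enrichment: float = 4.5


@dataclass(frozen=True)
class EconomicsConfig:
    """Cost-model constants: capex, opex rates, tax and project horizon."""

    capex_base: float = 80e6  # $ installed facility cost at base sizing
    capex_oversize_exponent: float = 0.6  # six-tenths capacity scale law
    cex_cost_per_m2: float = 2.0e6  # $ per m2 of CEX column cross-section
    annual_operating_days: float = 330.0
    maintenance_frac: float = 0.08  # of capex, per year
    labor_cost: float = 6.0e6  # $/yr
    biomass_cost: float = 0.10  # $/kg FW at the base growth time
    base_growth_time: float = 42.0  # day; field cost scales with residence time
    consumable_cost: float = 2000.0  # $/kg purified product
    utility_cost_per_L: float = 0.005  # $/L of extract volume processed
    tax_rate: float = 0.21
    project_years: int = 10

    @property
    def annual_hours(self) -> float:
        return self.annual_operating_days * 24.0


@dataclass(frozen=True)
class BatchResult:
    """Mass balance of one batch, with per-stage product masses and volumes."""

    biomass_kg: float
    product_kg: dict  # stage -> kg product leaving the stage
    stream_volume_l: dict  # stage -> L
    purity: float
    clamp_events: tuple

    def __post_init__(self) -> None:
        masses = list(self.product_kg.values())
        if any(b > a + 1e-9 for a, b in zip(masses, masses[1:])):
            raise ValueError("product mass must be non-increasing through stages")
        if not 0 < self.purity <= 1:
            raise ValueError(f"purity must be in (0, 1], got {self.purity}")

    @property
    def final_product_kg(self) -> float:
        return self.product_kg["cex"]

    @property
    def clamped(self) -> bool:
        return len(self.clamp_events) > 0


@dataclass(frozen=True)
class EconomicsResult:
    irr_after_tax: float  # fraction/yr; NaN when undefined
    irr_defined: bool
    cogs: float  # $/g
    annual_throughput_kg: float
    capex: float
    n_batches_per_year: int
    annual_opex: float
    breakdown: dict = field(default_factory=dict)  # section -> {item -> $/yr}
    cash_flows: tuple = ()  # after-tax, year 0 = -capex

    def __post_init__(self) -> None:
        total = sum(v for sec in self.breakdown.values() for v in sec.values())
        if self.breakdown and abs(total - self.annual_opex) > 1e-6 * max(self.annual_opex, 1.0):
            raise ValueError("cost breakdown does not reconcile with annual opex")


def effective_clamp(value: float, cap: float) -> tuple[float, bool]:
    """Reduce a quantity to its rated cap; returns (effective value, clamped?)."""
    if cap <= 0:
        raise ValueError(f"cap must be positive, got {cap}")
    if value > cap:
        return cap, True
    return value, False


def run_batch(
    inputs: ProcessInputs,
    equipment: EquipmentSpec = EquipmentSpec(),
    config: ProcessConfig = ProcessConfig(),
) -> BatchResult:
    """Propagate one trial's inputs through the batch mass balance.

    Harvested biomass is nominal biomass x field growth yield, clamped so
    the extraction stream fits the rated stream volume (the field-stage
    effective-yield fix).  Product then follows
    biomass x expression x pf_recovery x tff_recovery x cex_recovery with a
    product-mass clamp at the CEX stage (the effective-recovery fix).
    """
    clamps = []
    vol_cap = equipment.stream_volume_cap

    biomass_raw = config.nominal_biomass * inputs.field_growth_yield
    biomass_cap = vol_cap / config.extract_volume_ratio
    biomass, hit = effective_clamp(biomass_raw, biomass_cap)
    if hit:
        clamps.append("field_stream_volume")

    extract_vol = biomass * config.extract_volume_ratio
    pf_vol, hit = effective_clamp(extract_vol * config.pf_volume_fraction, vol_cap)
    if hit:
        clamps.append("pf_stream_volume")
    tff_vol, hit = effective_clamp(pf_vol / config.tff_concentration_factor, vol_cap)
    if hit:
        clamps.append("tff_stream_volume")

    product = {}
    product["extract"] = biomass * inputs.expression_level / 1000.0  # g/kg -> kg
    product["pf"] = product["extract"] * inputs.pf_recovery
    product["tff"] = product["pf"] * inputs.tff_recovery
    cex_out = product["tff"] * inputs.cex_recovery
    cex_out, hit = effective_clamp(cex_out, equipment.product_mass_cap)
    if hit:
        clamps.append("cex_product_mass")
    product["cex"] = cex_out

    purity = min(
        config.initial_purity * config.pf_enrichment * config.tff_enrichment * config.cex_enrichment,
        1.0,
    )
    return BatchResult(
        biomass_kg=biomass,
        product_kg=product,
        stream_volume_l={"extract": extract_vol, "pf": pf_vol, "tff": tff_vol},
        purity=purity,
        clamp_events=tuple(clamps),
    )


def batch_duration(
    inputs: ProcessInputs,
    equipment: EquipmentSpec = EquipmentSpec(),
    config: ProcessConfig = ProcessConfig(),
    batch: BatchResult | None = None,
) -> float:
    """Total facility occupation time of one batch, in hours.

    Sum of harvest time, a fixed extraction/turnaround block, the two
    filtration stage times (stage volume / (flux x membrane area)) and the
    chromatography cycle.  Field growth happens on the field in parallel and
    does not occupy the facility.
    """
    if config.pf_area <= 0 or config.tff_area <= 0:
        raise ValueError("membrane areas must be positive")
    if batch is None:
        batch = run_batch(inputs, equipment, config)
    pf_time = batch.stream_volume_l["pf"] / (inputs.pf_flux * config.pf_area)
    # UF/DF processes the clarified filtrate volume
    tff_time = batch.stream_volume_l["pf"] / (inputs.tff_flux * config.tff_area)
    return float(
        inputs.harvest_time + config.fixed_stage_hours + pf_time + tff_time + config.cex_hours
    )


def npv(rate: float, cash_flows: np.ndarray) -> float:
    """Net present value of a cash-flow vector indexed from year 0."""
    cf = np.asarray(cash_flows, dtype=float)
    t = np.arange(cf.size)
    return float(np.sum(cf / (1.0 + rate) ** t))


def irr(cash_flows, lo: float = -0.99, hi: float = 10.0, tol: float = 1e-10) -> float:
    """Internal rate of return: the root of NPV on [lo, hi].

    Raises ValueError when NPV does not change sign on the bracket (IRR
    undefined for the given cash flows).
    """
    cf = np.asarray(cash_flows, dtype=float)
    f_lo, f_hi = npv(lo, cf), npv(hi, cf)
    if f_lo == 0.0:
        return lo
    if f_hi == 0.0:
        return hi
    if f_lo * f_hi > 0:
        raise ValueError("NPV has no sign change on the bracket; IRR undefined")
    return float(brentq(lambda r: npv(r, cf), lo, hi, xtol=tol))


def economics(
    batch: BatchResult,
    duration_h: float,
    price: float,
    econ: EconomicsConfig = EconomicsConfig(),
    equipment: EquipmentSpec = EquipmentSpec(),
    growth_time: float | None = None,
) -> EconomicsResult:
    """Annualize one batch and evaluate profitability at a selling price.

    Batches per year = floor(annual operating hours / batch duration);
    capex follows a capacity scale law in the oversize factor plus the CEX
    column cost (proportional to cross-sectional area); after-tax cash
    flows over the project horizon (straight-line depreciation, single tax
    rate, no salvage) give the IRR.
    """
    if price <= 0:
        raise ValueError("price must be positive")
    if duration_h <= 0:
        raise ValueError("batch duration must be positive")

    n_batches = int(econ.annual_hours // duration_h)
    annual_product_kg = batch.final_product_kg * n_batches
    annual_biomass_kg = batch.biomass_kg * n_batches
    annual_volume_l = batch.stream_volume_l["extract"] * n_batches

    cex_area = math.pi / 4.0 * equipment.cex_column_diameter**2
    capex = (
        econ.capex_base * equipment.oversize_factor**econ.capex_oversize_exponent
        + econ.cex_cost_per_m2 * cex_area
    )

    gt = econ.base_growth_time if growth_time is None else growth_time
    field_cost = econ.biomass_cost * annual_biomass_kg * (gt / econ.base_growth_time)
    breakdown = {
        "facility": {
            "maintenance": econ.maintenance_frac * capex,
            "labor": econ.labor_cost,
            "utilities": econ.utility_cost_per_L * annual_volume_l,
        },
        "field": {"biomass_production": field_cost},
        "downstream": {"consumables": econ.consumable_cost * annual_product_kg},
    }
    annual_opex = sum(v for sec in breakdown.values() for v in sec.values())

    annual_product_g = annual_product_kg * 1000.0
    cogs = math.inf if annual_product_g == 0 else annual_opex / annual_product_g

    revenue = price * annual_product_g
    depreciation = capex / econ.project_years
    ebitda = revenue - annual_opex
    tax = max(0.0, (ebitda - depreciation)) * econ.tax_rate
    cf_year = ebitda - tax
    cash_flows = np.concatenate([[-capex], np.full(econ.project_years, cf_year)])
    try:
        rate = irr(cash_flows)
        defined = True
    except ValueError:
        rate, defined = float("nan"), False

    return EconomicsResult(
        irr_after_tax=rate,
        irr_defined=defined,
        cogs=cogs,
        annual_throughput_kg=annual_product_kg,
        capex=capex,
        n_batches_per_year=n_batches,
        annual_opex=annual_opex,
        breakdown=breakdown,
        cash_flows=tuple(cash_flows),
    )


def cost_breakdown_at(
    inputs: ProcessInputs,
    equipment: EquipmentSpec = EquipmentSpec(),
    price: float = DEFAULT_SELLING_PRICES[1],
    config: ProcessConfig = ProcessConfig(),
    econ: EconomicsConfig = EconomicsConfig(),
) -> EconomicsResult:
    """Deterministic re-run of one trial with the full itemized cost breakdown."""
    batch = run_batch(inputs, equipment, config)
    dur = batch_duration(inputs, equipment, config, batch=batch)
    return economics(batch, dur, price, econ, equipment, growth_time=inputs.field_growth_time)
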