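"""Cell-biomass budget of a sewer network in COD units.

Sewer biofilm carries on the order of 10 g of cell biomass (as chemical
oxygen demand, COD) per square meter of wetted pipe wall; expressed per
meter of pipeline this is ~4.2 g COD/m for the network considered here.
Multiplying by the gravity-sewer length (mains minus pressure mains, plus
branch pipes) gives the standing stock of sewer-grown cell biomass, which
can be compared with the daily influx of cell biomass to the treatment
plant (a fixed fraction of the influent COD load) and with the
activated-sludge inventory.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass
class SewerNetworkSpec:
    """Pipe lengths (km) and areal/linear biomass densities of a network.

    Defaults describe the Aalborg municipal network: 2216 km of mains (222 km
    of which are pressure pipes), 460 km of branch pipes.
    """

    main_pipe_km: float = 2216.0
    branch_pipe_km: float = 460.0
    pressure_pipe_km: float = 222.0
    areal_biomass_g_per_m2: float = 10.0
    linear_biomass_g_per_m: float = 4.2

    def __post_init__(self) -> None:
        for name in ("main_pipe_km", "branch_pipe_km", "pressure_pipe_km"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.pressure_pipe_km > self.main_pipe_km:
            raise ValueError("pressure pipes cannot exceed main pipes")


@dataclass
class PlantLoadSpec:
    """Influent organic load of a treatment plant.

    influent_cod_kg_per_day: average COD load (default: 30 000 kg/day).
    cell_fraction_of_cod: fraction of the influent COD that is cell biomass
        (default 10%).
    as_inventory_kg_cod: activated-sludge biomass inventory, optional.
    """

    influent_cod_kg_per_day: float = 30_000.0
    cell_fraction_of_cod: float = 0.10
    as_inventory_kg_cod: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.cell_fraction_of_cod <= 1:
            raise ValueError("cell_fraction_of_cod must be in [0, 1]")
        if self.influent_cod_kg_per_day < 0:
            raise ValueError("influent COD load must be non-negative")


def gravity_length_m(spec: SewerNetworkSpec) -> float:
    """Length of gravity sewers in meters: (mains - pressure + branches) * 1000."""
    km = spec.main_pipe_km - spec.pressure_pipe_km + spec.branch_pipe_km
    if km < 0:
        raise ValueError("negative gravity length")
    return km * 1000.0


def network_cell_biomass_kg(spec: SewerNetworkSpec) -> float:
    """Standing cell biomass across all gravity sewers, kg COD."""
    return gravity_length_m(spec) * spec.linear_biomass_g_per_m / 1000.0


def daily_cell_input_kg(load: PlantLoadSpec) -> float:
    """Daily influx of cell biomass to the plant, kg COD/day."""
    return load.influent_cod_kg_per_day * load.cell_fraction_of_cod


def input_fraction_of_as(daily_input_kg: float, as_inventory_kg: float | None):
    """Daily cell input as a fraction of the AS inventory (per day).

    Returns ``None`` when the inventory is not supplied (it is a
    plant-specific measurement, not derivable from the load spec).
    """
    if as_inventory_kg is None:
        return None
    if as_inventory_kg <= 0:
        raise ValueError("AS inventory must be positive")
    if daily_input_kg < 0:
        raise ValueError("daily input must be non-negative")
    return daily_input_kg / as_inventory_kg


def budget_report(network: SewerNetworkSpec, plant: PlantLoadSpec) -> dict:
    """All budget quantities in one JSON-ready dict."""
    daily = daily_cell_input_kg(plant)
    return {
        "gravity_length_m": gravity_length_m(network),
        "network_cell_biomass_kg_cod": network_cell_biomass_kg(network),
        "daily_cell_input_kg_cod": daily,
        "input_fraction_of_as_per_day": input_fraction_of_as(
            daily, plant.as_inventory_kg_cod
        ),
    }
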