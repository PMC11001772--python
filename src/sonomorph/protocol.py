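"""Wet-lab protocol configuration and derived-quantity arithmetic.

The patterning protocol mixes a fibrinogen working solution 1:1 with a
thrombin-medium-cell suspension, so final gel concentrations are the
working concentrations scaled by the mixing ratio; confocal scan volumes
are scan area times Z-depth.  Drive frequency (54 Hz) and vertical
acceleration (1.2 g) are recorded as metadata only — they select the
chamber mode experimentally, while the simulation is parameterized directly
by the mode indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

from .exceptions import ConfigError

__all__ = ["ProtocolConfig", "protocol_arithmetic"]


@dataclass(frozen=True)
class ProtocolConfig:
    """Protocol parameters with the study's defaults."""

    fibrinogen_working_mg_ml: float = 5.0
    thrombin_working_iu_ml: float = 0.5
    mix_ratio: tuple[float, float] = (1.0, 1.0)  # fibrinogen : cell suspension
    cell_suspension_density_per_ml: float = 3.0e6
    cell_ratio_huvec_pericyte: float = 10.0
    chamber_round_diameter_mm: float = 21.0
    chamber_square_side_mm: float = 15.0
    drive_frequency_hz: float = 54.0
    drive_acceleration_g: float = 1.2
    scan_area_round_mm2: float = 543.0
    scan_area_square_mm2: float = 350.0
    z_depth_um: float = 350.0
    slice_thickness_um: float = 30.0

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if name == "mix_ratio":
                if len(value) != 2 or min(value) <= 0:
                    raise ConfigError("mix_ratio must be two positive parts")
            elif value <= 0:
                raise ConfigError(f"{name} must be positive, got {value}")


def protocol_arithmetic(config: ProtocolConfig) -> dict[str, float]:
    """Derived protocol quantities.

    A ``mix_ratio`` of (a, b) dilutes the fibrinogen working solution by
    a/(a+b) and the cell suspension by b/(a+b); scan volumes convert the
    Z-depth from µm to mm.
    """
    a, b = config.mix_ratio
    frac_fib = a / (a + b)
    frac_cells = b / (a + b)
    depth_mm = config.z_depth_um / 1000.0
    return {
        "final_fibrinogen_mg_ml": config.fibrinogen_working_mg_ml * frac_fib,
        "final_thrombin_iu_ml": config.thrombin_working_iu_ml * frac_cells,
        "final_cell_density_per_ml":
            config.cell_suspension_density_per_ml * frac_cells,
        "scan_volume_round_mm3": config.scan_area_round_mm2 * depth_mm,
        "scan_volume_square_mm3": config.scan_area_square_mm2 * depth_mm,
        "n_slices": config.z_depth_um / config.slice_thickness_um,
    }
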