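"""Default equilibration/production recipe for liquid-solution MD runs.

The standard protocol is: two-stage energy minimization (steepest descent
then conjugate gradient), an NPT equilibration at the target state point, a
melt to 500.15 K followed by a quench back to 298.15 K (so molecules are not
trapped in a metastable packing), and an NVT production run whose trajectory
is sampled at a fixed interval.  Defaults: NPT 1 ns at 298.15 K / 1 atm,
melt 500 ps at 500.15 K, quench 2 ns to 298.15 K, production 5 ns sampled
every 50 ps — i.e. 100 stored configurations.

:func:`emit_md_recipe` renders the stage list as an engine-syntax control
script (Nose-Hoover thermostat/barostat directives, 1 fs timestep).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Union

ENSEMBLES = ("min_sd", "min_cg", "npt", "nvt")

#: integration timestep used to convert stage durations to step counts (fs)
TIMESTEP_FS = 1.0


@dataclass
class RecipeStage:
    """One stage of the MD protocol; durations and intervals in ps."""

    name: str
    ensemble: str
    temp_start: Optional[float] = None  # K
    temp_end: Optional[float] = None  # K
    pressure: Optional[float] = None  # atm
    duration: float = 0.0  # ps (ignored for minimization stages)
    sampling_interval: Optional[float] = None  # ps; enables trajectory dump

    def __post_init__(self) -> None:
        if self.ensemble not in ENSEMBLES:
            raise ValueError(
                f"unknown ensemble {self.ensemble!r}; expected one of {ENSEMBLES}"
            )
        if self.ensemble in ("npt", "nvt") and self.duration <= 0:
            raise ValueError(f"stage {self.name!r}: duration must be positive")


@dataclass
class RecipeSpec:
    """Ordered stage list describing the full protocol."""

    stages: List[RecipeStage]

    def __post_init__(self) -> None:
        if not self.stages:
            raise ValueError("a recipe needs at least one stage")

    @classmethod
    def default(cls) -> "RecipeSpec":
        return cls(
            stages=[
                RecipeStage(name="min-sd", ensemble="min_sd"),
                RecipeStage(name="min-cg", ensemble="min_cg"),
                RecipeStage(
                    name="npt-equilibration", ensemble="npt",
                    temp_start=298.15, temp_end=298.15, pressure=1.0,
                    duration=1000.0,
                ),
                RecipeStage(
                    name="melt", ensemble="npt",
                    temp_start=500.15, temp_end=500.15, pressure=1.0,
                    duration=500.0,
                ),
                RecipeStage(
                    name="quench", ensemble="npt",
                    temp_start=500.15, temp_end=298.15, pressure=1.0,
                    duration=2000.0,
                ),
                RecipeStage(
                    name="nvt-production", ensemble="nvt",
                    temp_start=298.15, temp_end=298.15,
                    duration=5000.0, sampling_interval=50.0,
                ),
            ]
        )

    def production_samples(self) -> int:
        """Stored configurations from the last sampled stage (duration/interval)."""
        for stage in reversed(self.stages):
            if stage.sampling_interval:
                return int(round(stage.duration / stage.sampling_interval))
        raise ValueError("no stage has a sampling interval")


def emit_md_recipe(
    spec: RecipeSpec, dest: Optional[Union[str, Path]] = None
) -> str:
    """Render the recipe as an engine control script; returns the text."""
    steps_per_ps = 1000.0 / TIMESTEP_FS
    lines = [
        "# control script generated by liqprop",
        "units real",
        "atom_style full",
        f"timestep {TIMESTEP_FS:g}",
        "",
    ]
    for k, stage in enumerate(spec.stages):
        lines.append(f"# stage {k + 1}: {stage.name} ({stage.ensemble})")
        if stage.ensemble == "min_sd":
            lines += ["min_style sd", "minimize 1.0e-4 1.0e-6 1000 10000", ""]
            continue
        if stage.ensemble == "min_cg":
            lines += ["min_style cg", "minimize 1.0e-6 1.0e-8 10000 100000", ""]
            continue
        n_steps = int(round(stage.duration * steps_per_ps))
        fix_id = f"stage{k + 1}"
        if stage.ensemble == "npt":
            lines.append(
                f"fix {fix_id} all npt temp {stage.temp_start:g} "
                f"{stage.temp_end:g} 100.0 iso {stage.pressure:g} "
                f"{stage.pressure:g} 1000.0"
            )
        else:
            lines.append(
                f"fix {fix_id} all nvt temp {stage.temp_start:g} "
                f"{stage.temp_end:g} 100.0"
            )
        if stage.sampling_interval:
            dump_every = int(round(stage.sampling_interval * steps_per_ps))
            lines.append(
                f"dump traj{k + 1} all custom {dump_every} dump.{stage.name}"
                ".lammpstrj id type mol q x y z ix iy iz"
            )
        lines.append(f"run {n_steps}")
        lines.append(f"unfix {fix_id}")
        if stage.sampling_interval:
            lines.append(f"undump traj{k + 1}")
        lines.append("")
    text = "\n".join(lines)
    if dest is not None:
        Path(dest).write_text(text)
    return text
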