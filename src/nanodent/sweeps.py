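"""Parameter-sweep drivers: crystal size, unloading rate, indenter spacing.

Each sweep repeats the full indentation + Oliver-Pharr pipeline over a value
grid with several independent seeds and reports per-value means with
standard errors (n - 1 denominator), mirroring the replicate-error-bar
convention of instrumented-indentation studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .contact_mechanics import analyze_curve
from .crystal_builder import add_vacuum_and_template, make_toy_crystal
from .indentation import (
    IndentationProtocol,
    Indenter,
    block_average,
    run_indentation,
    spacing_ratio,
)
from .md_engine import Thermostat

__all__ = ["SweepSpec", "SweepResult", "run_sweep", "desk_protocol", "SIZE_SCHEMES"]


def desk_protocol(**overrides) -> IndentationProtocol:
    """Desk-scale indentation schedule for the Lennard-Jones toy crystal.

    Rates are far above instrumented-indentation practice, in proportion to
    the far smaller crystal: what matters for the sweeps is the ratio between
    loading and unloading timescales, not their absolute values.  The bath at
    24 K (0.2 epsilon/k_B for the argon-like potential) keeps the crystal
    well below melting while leaving enough thermal activity for relaxation;
    the strong friction (5 ps^-1) stands in for the internal dissipation
    channels that a desk-scale crystal lacks and carries the viscoelastic
    rate sensitivity of the contact.
    """
    base = dict(
        penetration_rate=0.08,  # nm/ps
        max_depth=0.45,  # nm; deep enough to nucleate plasticity under the tip
        hold_duration=8.0,  # ps
        unloading_rate=0.04,  # nm/ps
        dt=0.008,  # ps (~tau/270 for argon-like LJ)
        thermostat=Thermostat(target_temperature=24.0, friction=5.0),
        equilibration=2.0,  # ps
        standoff=0.1,  # nm
    )
    base.update(overrides)
    return IndentationProtocol(**base)

#: replication scheme of the size sweep: multipliers on the base reps
#: (lateral x, lateral y, depth z) for each labelled size
SIZE_SCHEMES = {
    "N0": (1, 1, 1),
    "2N0": (1, 1, 2),  # depth doubled
    "4N0": (2, 2, 1),  # footprint doubled in both lateral directions
    "8N0": (2, 2, 2),  # doubled in all directions
}


@dataclass
class SweepSpec:
    """One sweep: which knob to vary, its values, and the fixed baseline.

    kind ``size``: values are labels from :data:`SIZE_SCHEMES`;
    kind ``unload_rate``: values are unloading rates in nm/ps;
    kind ``spacing``: values are indenter radii in nm at fixed lateral box.
    Seeds are mandatory (no silent entropy).
    """

    kind: str
    values: list
    seeds: list[int]
    preset: str = "lj_fcc"
    base_reps: tuple[int, int, int] = (6, 6, 6)
    radius: float = 1.2  # nm (fixed except for spacing sweeps)
    protocol: IndentationProtocol = field(default_factory=desk_protocol)
    vacuum: float = 4.0  # nm
    template_layers: int = 2
    nu_sample: float = 0.30

    def __post_init__(self) -> None:
        if self.kind not in ("size", "unload_rate", "spacing"):
            raise ValueError(f"unknown sweep kind {self.kind!r}")
        if len(self.values) < 2:
            raise ValueError("a sweep needs at least 2 values")
        if len(self.seeds) < 1:
            raise ValueError("a sweep needs at least 1 seed")
        if self.kind == "size":
            bad = [v for v in self.values if v not in SIZE_SCHEMES]
            if bad:
                raise ValueError(f"unknown size labels {bad}; valid: {list(SIZE_SCHEMES)}")


@dataclass
class SweepResult:
    """Per-run and aggregated fitted moduli."""

    runs: pd.DataFrame  # value, seed, modulus_gpa, error
    aggregate: pd.DataFrame  # value, mean, standard error, n_ok
    spec: SweepSpec
    n_failed: int = 0


def _single_run(spec: SweepSpec, value, seed: int) -> dict:
    import dataclasses

    reps = spec.base_reps
    radius = spec.radius
    protocol = dataclasses.replace(spec.protocol, seed=int(seed))
    if spec.kind == "size":
        mx, my, mz = SIZE_SCHEMES[value]
        reps = (reps[0] * mx, reps[1] * my, reps[2] * mz)
    elif spec.kind == "unload_rate":
        protocol = dataclasses.replace(protocol, unloading_rate=float(value))
    elif spec.kind == "spacing":
        radius = float(value)
        # depth must remain valid for the smallest tip in the sweep
        protocol = dataclasses.replace(
            protocol, max_depth=min(protocol.max_depth, 0.45 * radius)
        )
    kwargs = {}
    if spec.preset == "lj_fcc":
        # build at the bath temperature's stress-free lattice constant
        kwargs["temperature"] = protocol.thermostat.target_temperature
    slab, ff = make_toy_crystal(spec.preset, reps, seed=int(seed), **kwargs)
    slab = add_vacuum_and_template(slab, spec.vacuum, spec.template_layers)
    tip = Indenter(radius=radius, center=np.zeros(3))
    curve, _ = run_indentation(slab, ff, tip, protocol)
    smooth = block_average(curve, 50)
    result = analyze_curve(smooth, radius=radius, nu_sample=spec.nu_sample)
    return {
        "modulus_gpa": result.e_sample,
        "e_reduced_gpa": result.e_reduced,
        "n_particles": slab.n_particles,
        "spacing_ratio": spacing_ratio(slab.box, radius),
    }


def run_sweep(spec: SweepSpec, progress: bool = False) -> SweepResult:
    """Run every (value, seed) combination; failures are recorded, not fatal."""
    rows = []
    n_failed = 0
    for value in spec.values:
        for seed in spec.seeds:
            row = {"value": value, "seed": seed}
            try:
                row.update(_single_run(spec, value, seed))
                row["error"] = ""
            except Exception as err:  # noqa: BLE001 - sweep must continue
                row.update(modulus_gpa=np.nan, error=f"{type(err).__name__}: {err}")
                n_failed += 1
            rows.append(row)
            if progress:
                print(f"[sweep {spec.kind}] value={value} seed={seed} "
                      f"E={row.get('modulus_gpa', float('nan')):.3g} GPa")
    runs = pd.DataFrame(rows)
    grouped = runs.groupby("value", sort=False)["modulus_gpa"]
    aggregate = pd.DataFrame(
        {
            "mean_gpa": grouped.mean(),
            "se_gpa": grouped.sem(ddof=1),
            "n_ok": grouped.count(),
        }
    ).reset_index()
    return SweepResult(runs=runs, aggregate=aggregate, spec=spec, n_failed=n_failed)
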