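"""Synthetic FT-IR spectrum generator with known class structure.

Real mid-IR fingerprints of dried root powder are a sum of broad,
overlapping absorption bands riding on baseline drift and multiplicative
scatter, measured as several analytical replicates of the same powder.
This module emulates that structure with Gaussian bands at the major
assignment wavenumbers of a ginseng-root spectrum, class-dependent band
amplitudes (cultivation age and plant part), lognormal between-plant
amplitude variation, per-replicate scatter/baseline/noise, and artifact
bands inside the standard exclusion windows (water vapor, CO2).  Band
positions and which constituents carry age/part information follow the
published assignment table; effect sizes are synthetic, chosen only to
give the pipeline a recoverable but non-trivial signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .spectra import SpectrumSet


@dataclass
class BandSpec:
    """One Gaussian absorption band and its class-dependent amplitude."""

    center: float                 # cm^-1
    fwhm: float                   # cm^-1
    base_amplitude: float         # absorbance units at band max
    age_multipliers: dict = field(default_factory=dict)   # e.g. {"5yr": 1, "6yr": 1.2}
    part_multipliers: dict = field(default_factory=dict)
    assignment_label: str = ""

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError("fwhm must be positive")
        if self.base_amplitude < 0:
            raise ValueError("base_amplitude must be non-negative")
        for mult in list(self.age_multipliers.values()) + list(self.part_multipliers.values()):
            if mult <= 0:
                raise ValueError("class multipliers must be positive")

    def multiplier(self, age: str | None, part: str | None) -> float:
        return (self.age_multipliers.get(age, 1.0)
                * self.part_multipliers.get(part, 1.0))


@dataclass
class SyntheticDesign:
    """Full description of one simulated study."""

    grid_start: float = 4000.0
    grid_stop: float = 652.0
    grid_step: float = 4.0
    bands: list = field(default_factory=list)
    artifact_bands: list = field(default_factory=list)
    n_plants_per_group: int = 12
    ages: tuple = ("5yr", "6yr")
    parts: tuple = ("tap_root", "rhizome", "lateral_root")
    n_replicates: int = 6
    plant_amplitude_cv: float = 0.07
    replicate_noise_sd: float = 0.0015
    scatter_sd: float = 0.05
    baseline_offset_sd: float = 0.004
    baseline_slope_sd: float = 1.5e-6
    output_mode: str = "absorbance"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_plants_per_group < 1 or self.n_replicates < 1:
            raise ValueError("counts must be >= 1")
        if self.grid_step <= 0:
            raise ValueError("grid_step must be positive")
        for sd in (self.plant_amplitude_cv, self.replicate_noise_sd,
                   self.scatter_sd, self.baseline_offset_sd, self.baseline_slope_sd):
            if sd < 0:
                raise ValueError("noise magnitudes must be non-negative")

    @property
    def wavenumbers(self) -> np.ndarray:
        span = self.grid_start - self.grid_stop
        n_steps = span / self.grid_step
        if abs(n_steps - round(n_steps)) > 1e-9:
            raise ValueError("grid_step does not divide the grid range")
        wn = self.grid_start - self.grid_step * np.arange(int(round(n_steps)) + 1)
        return wn

    @property
    def n_samples(self) -> int:
        return (self.n_plants_per_group * len(self.ages) * len(self.parts)
                * self.n_replicates)


def default_design() -> SyntheticDesign:
    """Default study design: 12 plants per age group (5yr, 6yr), three
    parts per plant, 6 analytical replicates, on a 4000-652 cm^-1 grid at
    4 cm^-1 spacing (838 points).

    Age information is carried by the polysaccharide band at 1018 cm^-1
    and the ginsenoside-associated bands at 3335 and 2923 cm^-1; part
    information by the calcium-oxalate band at 1621 cm^-1 and the 1018
    band.  Artifact bands sit inside each standard exclusion window.
    """
    bands = [
        BandSpec(3335, 40, 0.45, age_multipliers={"6yr": 0.80},
                 assignment_label="O-H/N-H stretch: ginsenoside hydroxyls, amide A"),
        BandSpec(2923, 35, 0.30, age_multipliers={"6yr": 0.70},
                 assignment_label="C-H stretch: ginsenosides, lipids, proteins"),
        BandSpec(1733, 25, 0.10,
                 assignment_label="C=O stretch: carbonyl/lipids"),
        BandSpec(1621, 35, 0.20,
                 part_multipliers={"tap_root": 1.0, "rhizome": 1.40,
                                   "lateral_root": 0.65},
                 assignment_label="asym OC=O stretch: calcium oxalate; amide I"),
        BandSpec(1417, 25, 0.10,
                 assignment_label="asym CH3 stretch: lipids, aromatics"),
        BandSpec(1373, 20, 0.10,
                 assignment_label="sym COO- stretch / CH3 bend: lipids, proteins"),
        BandSpec(1253, 25, 0.12,
                 assignment_label="amide III: proteins"),
        BandSpec(1018, 45, 0.50, age_multipliers={"6yr": 1.20},
                 part_multipliers={"tap_root": 1.10, "lateral_root": 0.80},
                 assignment_label="C-O-C / C-O stretch: polysaccharides"),
    ]
    artifacts = [
        BandSpec(3700, 150, 0.020, assignment_label="water vapor (excluded region)"),
        BandSpec(2350, 40, 0.030, assignment_label="CO2 stretch (excluded region)"),
        BandSpec(670, 30, 0.020, assignment_label="CO2 bend (excluded region)"),
    ]
    return SyntheticDesign(bands=bands, artifact_bands=artifacts)


def _gaussian(wn: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return np.exp(-0.5 * ((wn - center) / sigma) ** 2)


def generate_spectra(design: SyntheticDesign, seed: int | None = None) -> SpectrumSet:
    """Simulate one study.

    Per biological sample (plant x part) the band amplitudes are drawn
    lognormally around ``base_amplitude x age_multiplier x
    part_multiplier`` with coefficient of variation
    ``plant_amplitude_cv``.  Each analytical replicate is
    ``scatter x sum(bands) + baseline(offset + slope*nu) + noise``, with
    artifact bands redrawn per replicate.  Deterministic under the seed.
    """
    if seed is None:
        seed = design.seed
    rng = np.random.default_rng(seed)
    wn = design.wavenumbers
    shapes = np.stack([_gaussian(wn, b.center, b.fwhm) for b in design.bands]) \
        if design.bands else np.zeros((0, wn.size))
    art_shapes = np.stack([_gaussian(wn, b.center, b.fwhm)
                           for b in design.artifact_bands]) \
        if design.artifact_bands else np.zeros((0, wn.size))

    cv = design.plant_amplitude_cv
    ln_sigma = np.sqrt(np.log(1.0 + cv ** 2)) if cv > 0 else 0.0

    rows, meta = [], []
    for age in design.ages:
        for plant_no in range(1, design.n_plants_per_group + 1):
            plant_id = f"p{age[0]}-{plant_no:02d}"
            for part in design.parts:
                mean_amp = np.array([b.base_amplitude * b.multiplier(age, part)
                                     for b in design.bands])
                draw = rng.lognormal(mean=-0.5 * ln_sigma ** 2, sigma=ln_sigma,
                                     size=mean_amp.size) if ln_sigma > 0 else 1.0
                amps = mean_amp * draw
                clean = amps @ shapes
                for rep in range(1, design.n_replicates + 1):
                    scatter = rng.lognormal(mean=0.0, sigma=design.scatter_sd) \
                        if design.scatter_sd > 0 else 1.0
                    offset = rng.normal(0.0, design.baseline_offset_sd)
                    slope = rng.normal(0.0, design.baseline_slope_sd)
                    spec = scatter * clean + offset + slope * wn
                    if art_shapes.size:
                        art_amp = np.array([
                            b.base_amplitude * rng.lognormal(0.0, 0.5)
                            for b in design.artifact_bands])
                        spec = spec + art_amp @ art_shapes
                    spec = spec + rng.normal(0.0, design.replicate_noise_sd, wn.size)
                    rows.append(spec)
                    meta.append({
                        "sample_id": f"{plant_id}_{part}_r{rep}",
                        "plant_id": plant_id, "age_class": age, "part": part,
                        "replicate_index": rep,
                    })

    intens = np.vstack(rows)
    mode = "absorbance"
    if design.output_mode == "percent_transmittance":
        intens = 100.0 * np.power(10.0, -intens)
        mode = "percent_transmittance"
    elif design.output_mode != "absorbance":
        raise ValueError(f"unknown output_mode {design.output_mode!r}")
    return SpectrumSet(wn, intens, mode, pd.DataFrame(meta))


def truth_table(design: SyntheticDesign) -> dict[str, list[tuple[float, float]]]:
    """Ground-truth discriminating wavenumber windows per task.

    For the ``age`` task, the windows (center - fwhm, center + fwhm) of
    every band whose age multipliers differ between the design's age
    classes; analogously for ``part``.  Used to score VIP recovery.
    """
    def windows(differs) -> list[tuple[float, float]]:
        out = []
        for b in design.bands:
            if differs(b):
                out.append((b.center - b.fwhm, b.center + b.fwhm))
        return out

    def age_differs(b: BandSpec) -> bool:
        vals = {b.age_multipliers.get(a, 1.0) for a in design.ages}
        return len(vals) > 1

    def part_differs(b: BandSpec) -> bool:
        vals = {b.part_multipliers.get(p, 1.0) for p in design.parts}
        return len(vals) > 1

    return {"age": windows(age_differs), "part": windows(part_differs)}


def null_design() -> SyntheticDesign:
    """Default design with every class multiplier set to 1 (no signal)."""
    d = default_design()
    bands = [replace(b, age_multipliers={}, part_multipliers={}) for b in d.bands]
    return replace(d, bands=bands)
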