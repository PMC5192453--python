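"""Synthetic 1H-NMR cohort generation.

Renders frequency-domain spectra as sums of Lorentzian lines on a uniform
ppm axis, with per-sample multiplicative dilution, a broad water artifact,
additive baseline noise and group-wise concentration fold-changes, so the
whole downstream pipeline can be exercised without any measured data.

Within-group biological variation is modelled as one latent "metabolic
state" factor per sample with metabolite-specific log-loadings, plus a
small independent log-normal jitter per metabolite.  The shared factor
makes metabolite levels co-vary within a sample, which is both the
realistic regime and the structured y-orthogonal variation that orthogonal
components are meant to capture.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .preprocess import Spectrum, write_spectrum

__all__ = [
    "MetaboliteSpec",
    "CohortDesign",
    "GROUPS",
    "default_axis",
    "default_library",
    "default_design",
    "null_design",
    "SURVIVOR_PLANTED",
    "render_spectrum",
    "generate_cohort",
    "write_cohort",
]

GROUPS = ("unmanipulated", "sham", "sepsis_survivor")

#: Default Lorentzian half-width at half-maximum, in ppm.
DEFAULT_LINEWIDTH = 0.003

#: Water artifact: broad Gaussian centered in the excluded 4.6-5.0 ppm window.
WATER_CENTER = 4.8
WATER_SIGMA = 0.10
WATER_AMPLITUDE = 5000.0


@dataclass(frozen=True)
class MetaboliteSpec:
    """A metabolite's line positions: (center_ppm, relative_area) pairs."""

    name: str
    peaks: tuple[tuple[float, float], ...]
    linewidth: float = DEFAULT_LINEWIDTH

    def __post_init__(self) -> None:
        if self.linewidth <= 0:
            raise ValueError(f"{self.name}: linewidth must be positive")
        total = sum(a for _, a in self.peaks)
        if not (np.isfinite(total) and total > 0):
            raise ValueError(f"{self.name}: relative areas must sum to a positive number")
        if any(a < 0 for _, a in self.peaks):
            raise ValueError(f"{self.name}: negative relative area")


@dataclass
class CohortDesign:
    """Sampling plan for a synthetic cohort.

    ``group_effects[(group, metabolite)]`` are multiplicative fold-changes
    applied to ``base_concentrations``; unlisted pairs default to 1.
    ``state_sd``/``state_loadings`` parameterize the shared within-group
    covariation factor, ``within_group_cv`` the independent residual jitter.
    """

    groups: list[tuple[str, int]]
    base_concentrations: dict[str, float]
    group_effects: dict[tuple[str, str], float] = field(default_factory=dict)
    dilution_sd: float = 0.0
    noise_sd: float = 0.0
    within_group_cv: float = 0.0
    state_sd: float = 0.0
    state_loadings: dict[str, float] = field(default_factory=dict)
    water_artifact: bool = True
    seed: int = 0

    def validate(self, for_modelling: bool = False) -> None:
        for label, n in self.groups:
            if label not in GROUPS:
                raise ValueError(f"unknown group label {label!r}; expected one of {GROUPS}")
            if n < 1 or (for_modelling and n < 2):
                raise ValueError(f"group {label!r} needs at least {'2' if for_modelling else '1'} samples")
        for (g, m), fold in self.group_effects.items():
            if g not in GROUPS:
                raise ValueError(f"group effect on unknown group {g!r}")
            if not (np.isfinite(fold) and fold > 0):
                raise ValueError(f"fold-change for ({g}, {m}) must be strictly positive")
        for m, c in self.base_concentrations.items():
            if c < 0:
                raise ValueError(f"negative base concentration for {m!r}")
        if self.dilution_sd < 0 or self.noise_sd < 0 or self.within_group_cv < 0 or self.state_sd < 0:
            raise ValueError("spread parameters must be non-negative")


def default_axis(start: float = 0.5, stop: float = 10.0, step: float = 0.00025) -> np.ndarray:
    """Uniform ppm grid covering the displayed spectral window."""
    n = int(round((stop - start) / step)) + 1
    return start + step * np.arange(n)


def default_library() -> list[MetaboliteSpec]:
    """Line library matching the shipped chemical-shift annotation fixture.

    Shift ranges are represented by up to three singlet-like lines with
    equal relative areas; J-coupling fine structure is not modelled.
    """
    def equal(name: str, centers: tuple[float, ...], linewidth: float = DEFAULT_LINEWIDTH) -> MetaboliteSpec:
        return MetaboliteSpec(name, tuple((c, 1.0 / len(centers)) for c in centers), linewidth)

    return [
        # lipid methyl/methylene resonances are genuinely broad
        equal("fatty_acids", (0.90, 1.28), linewidth=0.010),
        equal("leucine_isoleucine_valine", (1.00,)),
        equal("lactate", (1.33,)),
        equal("alanine", (1.48,)),
        equal("acetate", (1.92,)),
        equal("glutamine_glutamate", (2.03, 2.16, 2.34)),
        equal("succinate", (2.41,)),
        equal("beta_alanine", (2.56,)),
        equal("dimethylamine", (2.75,)),
        equal("lysine", (3.01,)),
        equal("choline", (3.22,)),
        # bulk-ring intensity concentrated in the 3.2-4.0 ppm carbohydrate
        # envelope, smaller anomeric lines outside it
        MetaboliteSpec("glucose", ((3.45, 0.4), (3.75, 0.4), (5.23, 0.2))),
        MetaboliteSpec("maltose", ((3.65, 0.4), (3.90, 0.4), (5.42, 0.2))),
        equal("glycerol", (4.10, 4.15)),
        equal("methyl_histidine", (7.12,)),
        equal("histidine", (7.94,)),
        equal("tyrosine", (6.89, 7.20)),
    ]


#: Metabolites whose survivor-group levels are planted below sham levels
#: (the ground truth the discriminant-selection stage must recover).
SURVIVOR_PLANTED = (
    "glucose",
    "maltose",
    "succinate",
    "beta_alanine",
    "acetate",
    "glutamine_glutamate",
    "tyrosine",
)


#: Log-scale sensitivity of each metabolite to the shared per-sample state
#: factor.  Metabolites without planted contrasts get large, sign-alternating
#: loadings (their within-group variation is dominated by the shared factor);
#: planted metabolites get small loadings so the fold-change dominates.
STATE_LOADINGS = {
    "fatty_acids": 0.9,
    "leucine_isoleucine_valine": -0.8,
    "lactate": 0.7,
    "alanine": -0.7,
    "dimethylamine": 0.8,
    "lysine": -0.9,
    "choline": 0.6,
    "glycerol": -0.6,
    "methyl_histidine": 1.0,
    "histidine": -1.0,
    "glucose": 0.15,
    "maltose": 0.10,
    "acetate": 0.20,
    "glutamine_glutamate": 0.15,
    "succinate": 0.20,
    "beta_alanine": 0.10,
    "tyrosine": 0.15,
}


def default_design(seed: int = 0, n_per_group: int = 10) -> CohortDesign:
    """Three-group design with effect directions mirroring the study groups.

    Survivor fold-changes are < 1 for the planted carbohydrate/amino-acid
    panel; sham shares the injury-only effects (maltose, alanine, glutamine
    down, choline up, dimethylamine down) so those do not separate sham from
    survivors.  Magnitudes are free design choices, not fitted values.
    """
    base = {
        "fatty_acids": 10.0,
        "leucine_isoleucine_valine": 3.0,
        "lactate": 3.0,
        "alanine": 3.0,
        "acetate": 1.5,
        "glutamine_glutamate": 2.4,
        "succinate": 1.2,
        "beta_alanine": 1.2,
        "dimethylamine": 2.0,
        "lysine": 3.0,
        "choline": 3.0,
        "glucose": 6.0,
        "maltose": 5.0,
        "glycerol": 4.0,
        "methyl_histidine": 2.0,
        "histidine": 2.0,
        "tyrosine": 1.2,
    }
    shared_injury = {
        "maltose": 0.80,
        "alanine": 0.75,
        "glutamine_glutamate": 0.85,
        "choline": 1.30,
        "dimethylamine": 0.70,
    }
    survivor_only = {
        "glucose": 0.55,
        "maltose": 0.45,
        "succinate": 0.50,
        "beta_alanine": 0.50,
        "acetate": 0.55,
        "glutamine_glutamate": 0.50,
        "tyrosine": 0.50,
    }
    effects: dict[tuple[str, str], float] = {}
    for m, f in shared_injury.items():
        effects[("sham", m)] = f
        effects[("sepsis_survivor", m)] = f
    for m, f in survivor_only.items():
        effects[("sepsis_survivor", m)] = f
    return CohortDesign(
        groups=[(g, n_per_group) for g in GROUPS],
        base_concentrations=base,
        group_effects=effects,
        dilution_sd=0.15,
        noise_sd=0.5,
        within_group_cv=0.005,
        state_sd=0.15,
        state_loadings=dict(STATE_LOADINGS),
        water_artifact=True,
        seed=seed,
    )


def null_design(seed: int = 0, n_per_group: int = 8) -> CohortDesign:
    """Two-group design with *no* group effects: same marginal structure as
    the default cohort, labels carry no information.  Used for calibration
    of the validation machinery."""
    d = default_design(seed=seed, n_per_group=n_per_group)
    d.groups = [("sham", n_per_group), ("sepsis_survivor", n_per_group)]
    d.group_effects = {}
    return d


def _lorentzian(axis: np.ndarray, center: float, gamma: float, area: float) -> np.ndarray:
    return (area / np.pi) * gamma / ((axis - center) ** 2 + gamma**2)


def render_spectrum(
    specs: Sequence[MetaboliteSpec],
    concentrations: Mapping[str, float],
    axis: np.ndarray,
    noise_sd: float = 0.0,
    dilution: float = 1.0,
    water_artifact: bool = True,
    rng: np.random.Generator | None = None,
    sample_id: str = "",
) -> Spectrum:
    """Render one spectrum: dilution x (metabolite Lorentzians + water) + noise."""
    axis = np.asarray(axis, dtype=float)
    if axis.ndim != 1 or axis.size < 2:
        raise ValueError("axis must be a 1-D grid with at least 2 points")
    steps = np.diff(axis)
    if np.any(steps <= 0):
        raise ValueError("axis must be strictly increasing")
    if not np.allclose(steps, steps[0], rtol=1e-6) or steps[0] > 0.0005 + 1e-12:
        raise ValueError("axis must be uniform with step <= 0.0005 ppm")
    by_name = {m.name: m for m in specs}
    signal = np.zeros_like(axis)
    for name, conc in concentrations.items():
        if name not in by_name:
            raise ValueError(f"unknown metabolite {name!r} in concentrations")
        if conc < 0:
            raise ValueError(f"negative concentration for {name!r}")
        if conc == 0:
            continue
        spec = by_name[name]
        for center, rel_area in spec.peaks:
            if not (axis[0] <= center <= axis[-1]):
                raise ValueError(f"{name}: peak at {center} ppm outside the axis range")
            signal += conc * _lorentzian(axis, center, spec.linewidth, rel_area)
    if water_artifact:
        signal += WATER_AMPLITUDE * np.exp(-0.5 * ((axis - WATER_CENTER) / WATER_SIGMA) ** 2)
    intensity = dilution * signal
    if noise_sd > 0:
        if rng is None:
            raise ValueError("rng required when noise_sd > 0")
        intensity = intensity + rng.normal(0.0, noise_sd, size=axis.size)
    return Spectrum(ppm=axis, intensity=intensity, sample_id=sample_id)


def generate_cohort(
    design: CohortDesign,
    library: Sequence[MetaboliteSpec] | None = None,
    axis: np.ndarray | None = None,
) -> tuple[list[Spectrum], pd.DataFrame]:
    """Draw a full cohort; a pure function of (design, library, seed)."""
    design.validate()
    if library is None:
        library = default_library()
    if axis is None:
        axis = default_axis()
    lib_names = {m.name for m in library}
    for m in design.base_concentrations:
        if m not in lib_names:
            raise ValueError(f"design refers to metabolite {m!r} absent from the library")
    rng = np.random.default_rng(design.seed)
    names = sorted(design.base_concentrations)
    spectra: list[Spectrum] = []
    meta_rows: list[dict[str, object]] = []
    for label, n in design.groups:
        for i in range(n):
            sid = f"{label}_{i:02d}"
            state = rng.normal(0.0, design.state_sd) if design.state_sd > 0 else 0.0
            conc: dict[str, float] = {}
            for m in names:
                fold = design.group_effects.get((label, m), 1.0)
                loading = design.state_loadings.get(m, 0.0)
                jitter = rng.normal(0.0, design.within_group_cv) if design.within_group_cv > 0 else 0.0
                conc[m] = design.base_concentrations[m] * fold * float(np.exp(loading * state + jitter))
            dilution = float(np.exp(rng.normal(0.0, design.dilution_sd))) if design.dilution_sd > 0 else 1.0
            spectra.append(
                render_spectrum(
                    library,
                    conc,
                    axis,
                    noise_sd=design.noise_sd,
                    dilution=dilution,
                    water_artifact=design.water_artifact,
                    rng=rng,
                    sample_id=sid,
                )
            )
            meta_rows.append({"sample_id": sid, "group": label, "dilution": dilution})
    return spectra, pd.DataFrame(meta_rows)


def write_cohort(spectra: Sequence[Spectrum], metadata: pd.DataFrame, out_dir: str | Path) -> None:
    """Write one two-column text file per spectrum plus a metadata CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for s in spectra:
        write_spectrum(s, out / f"{s.sample_id}.txt")
    metadata[["sample_id", "group"]].to_csv(out / "metadata.csv", index=False)
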