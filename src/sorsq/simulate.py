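"""Synthetic traditional/offset Raman pairs for hand-sanitizer formulations.

The generator emulates the physical structure of through-container Raman
measurements of alcohol-based hand sanitizers:

* each component (four alcohols, glycerin, water) is a sum of Lorentzian
  bands at literature positions, weighted by the spontaneous-scattering
  factor (nu0 - nu)^4 / (1 - exp(-h c nu / k T)) for 830 nm excitation;
* C-O and C-C stretching band centers shift with the total alcohol fraction x
  following the exponential-decay law delta_nu(x) = direction * A * exp(-x/t),
  emulating hydrogen-bonding effects in alcohol-water mixtures;
* a container contributes a surface spectrum (sharp polymer bands, or broad
  silica bands for glass) and a fluorescence baseline; traditional and offset
  acquisitions mix surface and content spectra with different weights, the
  offset being relatively enriched in content signal (the defining SORS
  property);
* noise is shot-noise-like additive Gaussian, seeded and reproducible.

Cohort designs mirror the study layout: a training design of 4 alcohols x 9
containers = 36 content-container combinations plus mixture/dilution
augmentation (78 combination-level spectra), and a 173-sample test cohort
with 65 fair, 24 subpotent and 84 contaminated products.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .spectra import (
    ALCOHOLS,
    APPROVED,
    CONTAMINANTS,
    Formulation,
    SampleRecord,
    SpectralDataset,
    Spectrum,
    SpectrumPair,
    WavenumberGrid,
    who_base,
)

# physical constants (SI)
PLANCK_H = 6.62607015e-34  # J s
BOLTZMANN_K = 1.380649e-23  # J / K
SPEED_OF_LIGHT_CM = 2.99792458e10  # cm / s


@dataclass(frozen=True)
class EmissionPhysics:
    """Spontaneous Raman intensity scaling for a band at Raman shift nu (cm^-1).

    The factor (nu0 - nu)^4 / (1 - exp(-h c nu / k T)) combines the
    scattered-frequency dependence with the Boltzmann thermal population of
    the vibrational ground state; nu0 is the excitation frequency in cm^-1.
    """

    excitation_nm: float = 830.0
    temperature_K: float = 298.15
    #: reference shift at which the factor is normalized to 1 (keeps synthetic
    #: intensities O(1); cancels in all ratios)
    reference_shift: float = 1000.0

    @property
    def excitation_wavenumber(self) -> float:
        return 1.0e7 / self.excitation_nm

    def factor(self, nu) -> np.ndarray:
        """Unnormalized scaling factor, strictly positive for nu > 0."""
        nu = np.asarray(nu, dtype=float)
        nu0 = self.excitation_wavenumber
        beta = PLANCK_H * SPEED_OF_LIGHT_CM / (BOLTZMANN_K * self.temperature_K)
        return (nu0 - nu) ** 4 / (1.0 - np.exp(-beta * nu))

    def weight(self, nu) -> np.ndarray:
        """Scaling factor normalized to 1 at :attr:`reference_shift`."""
        return self.factor(nu) / self.factor(self.reference_shift)


@dataclass(frozen=True)
class ShiftModel:
    """Concentration-dependent band-center shift delta_nu(x) = dir * A * exp(-x/t).

    ``x`` is the total alcohol fraction in % v/v.  A (cm^-1) is the shift
    amplitude at the dilute limit and t (% v/v) the decay constant; direction
    +1 moves the band to higher wavenumber on dilution (C-O stretches), -1 to
    lower (C-C stretches).
    """

    amplitude: float = 10.0  # A, cm^-1
    decay: float = 30.0  # t, % v/v
    direction: int = 1

    def __post_init__(self) -> None:
        if self.decay <= 0:
            raise ValueError("decay constant t must be positive")
        if self.direction not in (-1, 1):
            raise ValueError("direction must be +1 or -1")

    def offset_at(self, x: float) -> float:
        return self.direction * self.amplitude * math.exp(-x / self.decay)


@dataclass(frozen=True)
class RamanBand:
    """One vibrational band of a pure component.

    ``center_ref`` is the band position (cm^-1) observed at the reference
    formulation concentration ``x_ref``; the dilute-limit center0 used by the
    shift law is back-calculated so that the literature position is reproduced
    exactly at the reference concentration.
    """

    center_ref: float
    fwhm: float
    rel_intensity: float
    shape: str = "lorentzian"  # lorentzian | gaussian | pseudo_voigt
    eta: float = 0.5  # Lorentzian fraction for pseudo_voigt
    shift: Optional[ShiftModel] = None
    x_ref: float = 80.0

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError("fwhm must be positive")
        if self.rel_intensity < 0:
            raise ValueError("relative intensity must be non-negative")
        if self.shape not in ("lorentzian", "gaussian", "pseudo_voigt"):
            raise ValueError(f"unknown band shape {self.shape!r}")

    @property
    def center0(self) -> float:
        """Dilute-limit center: center_ref minus the shift already present at x_ref."""
        if self.shift is None:
            return self.center_ref
        return self.center_ref - self.shift.offset_at(self.x_ref)

    def center_at(self, x: float) -> float:
        if self.shift is None:
            return self.center_ref
        return self.center0 + self.shift.offset_at(x)

    def profile(self, nu: np.ndarray, x: float) -> np.ndarray:
        c = self.center_at(x)
        if self.shape == "lorentzian":
            g = self.fwhm / 2.0
            shape = g * g / ((nu - c) ** 2 + g * g)
        elif self.shape == "gaussian":
            shape = np.exp(-4.0 * math.log(2.0) * (nu - c) ** 2 / self.fwhm**2)
        else:  # pseudo_voigt
            g = self.fwhm / 2.0
            lor = g * g / ((nu - c) ** 2 + g * g)
            gau = np.exp(-4.0 * math.log(2.0) * (nu - c) ** 2 / self.fwhm**2)
            shape = self.eta * lor + (1.0 - self.eta) * gau
        return self.rel_intensity * shape


def _co(center: float, fwhm: float, rel: float, x_ref: float) -> RamanBand:
    """C-O stretching mode: shifts up on dilution."""
    return RamanBand(center, fwhm, rel, shift=ShiftModel(direction=+1), x_ref=x_ref)


def _cc(center: float, fwhm: float, rel: float, x_ref: float) -> RamanBand:
    """C-C stretching mode: shifts down on dilution."""
    return RamanBand(center, fwhm, rel, shift=ShiftModel(direction=-1), x_ref=x_ref)


#: Default band tables.  Centers are the literature positions used to identify
#: each alcohol (C-C / C-O stretches plus CH3 deformation modes); relative
#: intensities are synthetic-truth values chosen so the strongest-band ordering
#: matches scaled-subtracted hand-sanitizer spectra qualitatively.  x_ref is
#: 80% v/v for ethanol/methanol tables and 75% v/v for the propanols (the
#: reference formulation strengths).
DEFAULT_BANDS: Dict[str, Tuple[RamanBand, ...]] = {
    "ethanol": (
        _cc(882.0, 16.0, 1.00, 80.0),
        _co(1049.0, 18.0, 0.55, 80.0),
        RamanBand(1092.0, 18.0, 0.45),  # CH3 rocking, no shift
        RamanBand(1454.0, 20.0, 0.35),  # CH3 bending, no shift
    ),
    "methanol": (
        _co(1030.0, 17.0, 1.00, 80.0),
        RamanBand(1452.0, 22.0, 0.30),
    ),
    "propan2ol": (
        _cc(818.0, 15.0, 1.00, 75.0),
        _co(950.0, 16.0, 0.50, 75.0),
        RamanBand(1450.0, 20.0, 0.30),
    ),
    "propan1ol": (
        _cc(859.0, 15.0, 0.85, 75.0),
        _cc(888.0, 15.0, 0.75, 75.0),
        _co(968.0, 16.0, 0.70, 75.0),
        RamanBand(1456.0, 20.0, 0.30),
    ),
    "glycerin": (
        RamanBand(850.0, 20.0, 0.25),
        RamanBand(1060.0, 24.0, 0.20),
    ),
    # negligible at 0.145% v/v: no bands
    "h2o2": (),
    # weak broad in-range water features: intermolecular librations and the
    # H-O-H bending mode
    "water": (
        RamanBand(430.0, 180.0, 0.12),
        RamanBand(1640.0, 85.0, 0.08),
    ),
}


def pure_component_spectrum(
    component: str,
    grid: WavenumberGrid,
    total_alcohol: float,
    physics: Optional[EmissionPhysics] = None,
    bands: Optional[Mapping[str, Tuple[RamanBand, ...]]] = None,
) -> Spectrum:
    """Spectrum of one pure component at unit amount.

    Band centers are evaluated at the given total alcohol fraction (% v/v)
    through each band's shift law; intensities carry the emission-physics
    scaling factor.
    """
    table = DEFAULT_BANDS if bands is None else bands
    if component not in table:
        raise KeyError(
            f"unknown component {component!r}; known components: {sorted(table)}"
        )
    physics = physics or EmissionPhysics()
    nu = grid.values
    out = np.zeros(len(grid))
    for band in table[component]:
        out += band.profile(nu, total_alcohol)
    out *= physics.weight(nu)
    return Spectrum(grid=grid, intensities=out, acquisition="traditional", sample_id=component)


def content_spectrum(
    formulation: Formulation,
    grid: WavenumberGrid,
    physics: Optional[EmissionPhysics] = None,
    bands: Optional[Mapping[str, Tuple[RamanBand, ...]]] = None,
) -> np.ndarray:
    """Volume-fraction-weighted sum of component spectra, water included."""
    x = formulation.total_alcohol
    out = np.zeros(len(grid))
    for comp, frac in formulation.fractions.items():
        if frac > 0:
            out += (frac / 100.0) * pure_component_spectrum(comp, grid, x, physics, bands).intensities
    out += (formulation.water / 100.0) * pure_component_spectrum("water", grid, x, physics, bands).intensities
    return out


# ---------------------------------------------------------------------------
# containers

MATERIAL_BANDS: Dict[str, Tuple[Tuple[float, float], ...]] = {
    # (center cm^-1, relative intensity); the strongest entries are the marker
    # bands used to identify each material in mixture spectra
    "PE": ((1064.0, 0.55), (1130.0, 0.65), (1169.0, 0.25), (1296.0, 0.85), (1418.0, 0.50), (1440.0, 1.00)),
    "PET": ((1614.0, 1.00), (1728.0, 0.85)),
    "PP": ((809.0, 0.45), (841.0, 0.50), (1151.0, 0.30), (1168.0, 0.35), (1330.0, 0.40), (1459.0, 1.00)),
    "glass": (),  # no sharp bands; broad silica background only
}

#: broad glass pseudo-bands (center, fwhm, rel); removed by baseline filtering
GLASS_BROAD = ((560.0, 300.0, 0.40), (1090.0, 250.0, 0.30))

OPACITIES = ("transparent", "semitransparent", "opaque")


@dataclass(frozen=True)
class ContainerModel:
    """Mixing model of one container: surface/content weights per acquisition.

    The SORS property requires v_c / v_s > w_c / w_s: the offset acquisition
    is relatively enriched in content (subsurface) signal.  Content weights
    decrease with opacity.
    """

    container_id: str
    material: str
    opacity: str
    surface_weight_traditional: float  # w_s
    content_weight_traditional: float  # w_c
    surface_weight_offset: float  # v_s
    content_weight_offset: float  # v_c
    fluorescence_level: float = 0.5
    band_fwhm: float = 14.0

    def __post_init__(self) -> None:
        if self.material not in MATERIAL_BANDS:
            raise ValueError(f"unknown material {self.material!r}")
        if self.opacity not in OPACITIES:
            raise ValueError(f"opacity must be one of {OPACITIES}")
        for w in (self.surface_weight_traditional, self.content_weight_traditional,
                  self.surface_weight_offset, self.content_weight_offset):
            if not (0.0 <= w <= 1.0):
                raise ValueError("mixing weights must lie in [0, 1]")
        ws, wc = self.surface_weight_traditional, self.content_weight_traditional
        vs, vc = self.surface_weight_offset, self.content_weight_offset
        if ws > 0 and vs > 0 and wc > 0 and vc > 0:
            if not vc / vs > wc / ws:
                raise ValueError(
                    "offset acquisition must be relatively enriched in content "
                    "signal (v_c/v_s > w_c/w_s)"
                )

    @property
    def band_centers(self) -> Tuple[float, ...]:
        return tuple(c for c, _ in MATERIAL_BANDS[self.material])

    @property
    def subtraction_windows(self) -> Tuple[float, ...]:
        """Window centers for scale-factor estimation: the sharp marker bands
        for polymers, or the broad silica band centers for glass (regions
        dominated by surface signal)."""
        if self.band_centers:
            return self.band_centers
        return tuple(c for c, _, _ in GLASS_BROAD)

    def surface_spectrum(self, grid: WavenumberGrid, physics: Optional[EmissionPhysics] = None) -> np.ndarray:
        physics = physics or EmissionPhysics()
        nu = grid.values
        out = np.zeros(len(grid))
        for center, rel in MATERIAL_BANDS[self.material]:
            g = self.band_fwhm / 2.0
            out += rel * g * g / ((nu - center) ** 2 + g * g)
        if self.material == "glass":
            for center, fwhm, rel in GLASS_BROAD:
                out += rel * np.exp(-4.0 * math.log(2.0) * (nu - center) ** 2 / fwhm**2)
        return out * physics.weight(nu)


# weights per opacity class: (w_s, w_c, v_s, v_c)
_OPACITY_WEIGHTS = {
    "transparent": (0.50, 0.70, 0.20, 0.90),
    "semitransparent": (0.65, 0.40, 0.30, 0.65),
    "opaque": (0.85, 0.12, 0.45, 0.30),
}
_OPACITY_FLUOR = {"transparent": 0.3, "semitransparent": 0.6, "opaque": 1.0}


def _container(cid: str, material: str, opacity: str, fluor: Optional[float] = None) -> ContainerModel:
    ws, wc, vs, vc = _OPACITY_WEIGHTS[opacity]
    return ContainerModel(
        container_id=cid, material=material, opacity=opacity,
        surface_weight_traditional=ws, content_weight_traditional=wc,
        surface_weight_offset=vs, content_weight_offset=vc,
        fluorescence_level=_OPACITY_FLUOR[opacity] if fluor is None else fluor,
    )


def default_containers() -> List[ContainerModel]:
    """Nine synthetic containers: {PE, PET} x {T, ST, O} + PP(ST) + glass(T) +
    amber glass.  The real container set is not publicly specified; this set
    mirrors the purchased materials and opacity spread."""
    return [
        _container("PE_T", "PE", "transparent"),
        _container("PE_ST", "PE", "semitransparent"),  # the semitransparent HDPE reference
        _container("PE_O", "PE", "opaque"),
        _container("PET_T", "PET", "transparent"),
        _container("PET_ST", "PET", "semitransparent"),
        _container("PET_O", "PET", "opaque"),
        _container("PP_ST", "PP", "semitransparent"),
        _container("GLASS_T", "glass", "transparent"),
        _container("GLASS_AMBER", "glass", "semitransparent", fluor=2.0),
    ]


REFERENCE_CONTAINER_ID = "PE_ST"


# ---------------------------------------------------------------------------
# pair synthesis


def _fluorescence_baseline(grid: WavenumberGrid, level: float) -> np.ndarray:
    """Smooth positive baseline: broad Gaussian hump plus a gentle slope."""
    nu = grid.values
    span = grid.stop - grid.start
    hump = np.exp(-0.5 * ((nu - (grid.start + 0.35 * span)) / (0.45 * span)) ** 2)
    slope = 1.0 - 0.3 * (nu - grid.start) / span
    return 0.35 * level * (0.8 * hump + 0.4 * slope)


DEFAULT_NOISE_SD = 0.005  # relative to spectrum maximum


def _add_noise(clean: np.ndarray, noise_sd: float, rng: np.random.Generator) -> np.ndarray:
    if noise_sd <= 0:
        return clean.copy()
    peak = float(np.max(clean)) if clean.size else 0.0
    if peak <= 0:
        peak = 1.0
    # shot-noise-like: sd grows with sqrt(intensity), small constant dark floor
    sd = noise_sd * np.sqrt(np.clip(clean, 0.0, None) * peak) + 0.1 * noise_sd * peak
    return clean + rng.normal(0.0, 1.0, size=clean.size) * sd


def simulate_pair(
    formulation: Formulation,
    container: ContainerModel,
    physics: Optional[EmissionPhysics] = None,
    noise_seed: int | np.random.SeedSequence = 0,
    noise_sd: float = DEFAULT_NOISE_SD,
    grid: Optional[WavenumberGrid] = None,
    sample_id: str = "",
    bands: Optional[Mapping[str, Tuple[RamanBand, ...]]] = None,
) -> SpectrumPair:
    """One matched traditional/offset acquisition pair.

    traditional = w_s * S_surface + w_c * S_content + fluorescence + noise
    offset      = v_s * S_surface + v_c * S_content + attenuated fluorescence + noise
    """
    grid = grid or WavenumberGrid()
    physics = physics or EmissionPhysics()
    s_content = content_spectrum(formulation, grid, physics, bands)
    s_surface = container.surface_spectrum(grid, physics)
    baseline = _fluorescence_baseline(grid, container.fluorescence_level)

    trad_clean = (
        container.surface_weight_traditional * s_surface
        + container.content_weight_traditional * s_content
        + baseline
    )
    off_clean = (
        container.surface_weight_offset * s_surface
        + container.content_weight_offset * s_content
        + 0.5 * baseline
    )
    ss = noise_seed if isinstance(noise_seed, np.random.SeedSequence) else np.random.SeedSequence(noise_seed)
    child_t, child_o = ss.spawn(2)
    trad = _add_noise(trad_clean, noise_sd, np.random.default_rng(child_t))
    off = _add_noise(off_clean, noise_sd, np.random.default_rng(child_o))
    return SpectrumPair(
        traditional=Spectrum(grid=grid, intensities=trad, acquisition="traditional", sample_id=sample_id),
        offset=Spectrum(grid=grid, intensities=off, acquisition="offset", sample_id=sample_id),
    )


# ---------------------------------------------------------------------------
# cohort designs


@dataclass(frozen=True)
class CohortSpec:
    """Design of a simulated measurement cohort.

    ``training`` enumerates the 4 alcohols x 9 containers = 36 content-container
    combinations plus the binary-mixture / dilution augmentation in the fixed
    semitransparent HDPE container (78 combination-level spectra);
    ``study_test`` yields 173 test samples of which 65 are fair, 24 subpotent
    and 84 contaminated.
    """

    seed: int = 0
    design: str = "training"  # training | study_test
    noise_sd: float = DEFAULT_NOISE_SD
    n_replicates: int = 5

    def __post_init__(self) -> None:
        if self.design not in ("training", "study_test"):
            raise ValueError("design must be 'training' or 'study_test'")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


#: contaminant levels of the binary-mixture training series (% v/v), bracketing
#: the 2.5% detectability claim and the 2.5-30% contamination range
BINARY_LEVELS = (2.5, 5.0, 10.0, 15.0, 20.0, 30.0)
#: total-alcohol levels of the single-alcohol dilution training series (% v/v)
DILUTION_LEVELS = (20.0, 35.0, 50.0, 65.0)

STUDY_N_FAIR = 65
STUDY_N_SUBPOTENT = 24
STUDY_N_CONTAMINATED = 84
STUDY_N_HOUSE = 120
STUDY_N_COMMERCIAL = 53


def training_combinations() -> List[Tuple[str, Formulation, str]]:
    """(combination_id, formulation, container_id) for the 78 training spectra."""
    combos: List[Tuple[str, Formulation, str]] = []
    containers = default_containers()
    # 36 single-alcohol content-container combinations at reference strength
    for alcohol in ALCOHOLS:
        for c in containers:
            combos.append((f"train-{alcohol}-{c.container_id}", who_base(alcohol), c.container_id))
    # augmentation in the fixed semitransparent HDPE container:
    ref = REFERENCE_CONTAINER_ID
    # WHO base blanks (0% contaminant members of the binary series)
    combos.append(("mix-ethanol-blank", who_base("ethanol"), ref))
    combos.append(("mix-propan2ol-blank", who_base("propan2ol"), ref))
    # binary contaminant-in-approved mixtures at fixed total alcohol
    for base in APPROVED:
        total = 80.0 if base == "ethanol" else 75.0
        for cont in CONTAMINANTS:
            for level in BINARY_LEVELS:
                f = Formulation.make(**{
                    base: total - level, cont: level,
                    "glycerin": 1.45, "h2o2": 0.145,
                })
                combos.append((f"mix-{base}-{cont}-{level:g}", f, ref))
    # single-alcohol dilution series (varying water content -> band shifts)
    for alcohol in ALCOHOLS:
        for level in DILUTION_LEVELS:
            combos.append((f"dil-{alcohol}-{level:g}", who_base(alcohol, level), ref))
    return combos


def _study_formulations(rng: np.random.Generator) -> List[Tuple[Formulation, str]]:
    """(formulation, true_label) for the 173-sample study test cohort."""
    out: List[Tuple[Formulation, str]] = []
    for _ in range(STUDY_N_FAIR):
        base = "ethanol" if rng.random() < 0.6 else "propan2ol"
        out.append((who_base(base, float(rng.uniform(62.0, 88.0))), "fair"))
    for _ in range(STUDY_N_SUBPOTENT):
        base = "ethanol" if rng.random() < 0.6 else "propan2ol"
        out.append((who_base(base, float(rng.uniform(35.0, 58.0))), "subpotent"))
    for _ in range(STUDY_N_CONTAMINATED):
        base = "ethanol" if rng.random() < 0.5 else "propan2ol"
        total = 80.0 if base == "ethanol" else 75.0
        u = rng.random()
        if u < 0.45:
            cont = {"methanol": float(rng.uniform(2.5, 30.0))}
        elif u < 0.80:
            cont = {"propan1ol": float(rng.uniform(2.5, 30.0))}
        else:
            cont = {
                "methanol": float(rng.uniform(2.5, 15.0)),
                "propan1ol": float(rng.uniform(2.5, 15.0)),
            }
        fracs = {base: total - sum(cont.values()), "glycerin": 1.45, "h2o2": 0.145}
        fracs.update(cont)
        out.append((Formulation.make(**fracs), "contaminated"))
    perm = rng.permutation(len(out))
    return [out[i] for i in perm]


def generate_cohort(
    spec: CohortSpec,
    containers: Optional[Sequence[ContainerModel]] = None,
    grid: Optional[WavenumberGrid] = None,
    physics: Optional[EmissionPhysics] = None,
) -> SpectralDataset:
    """Deterministically generate a full cohort dataset for the given design."""
    containers = list(containers) if containers is not None else default_containers()
    if spec.design == "training" and len(containers) != 9:
        raise ValueError("the training design requires exactly 9 containers")
    grid = grid or WavenumberGrid()
    physics = physics or EmissionPhysics()
    by_id = {c.container_id: c for c in containers}

    records: List[SampleRecord] = []
    pairs: Dict[str, SpectrumPair] = {}
    root = np.random.SeedSequence(spec.seed)

    if spec.design == "training":
        combos = training_combinations()
        children = root.spawn(len(combos) * spec.n_replicates)
        k = 0
        for combo_id, formulation, cid in combos:
            for rep in range(1, spec.n_replicates + 1):
                sid = f"{combo_id}-r{rep}"
                pairs[sid] = simulate_pair(
                    formulation, by_id[cid], physics, children[k],
                    noise_sd=spec.noise_sd, grid=grid, sample_id=sid,
                )
                records.append(SampleRecord(sid, formulation, cid, origin="training"))
                k += 1
    else:  # study_test
        rng = np.random.default_rng(root.spawn(1)[0])
        formulations = _study_formulations(rng)
        container_idx = rng.integers(0, len(containers), size=len(formulations))
        origins = ["test_house"] * STUDY_N_HOUSE + ["test_commercial"] * STUDY_N_COMMERCIAL
        origin_perm = rng.permutation(len(origins))
        children = root.spawn(len(formulations))
        for i, ((formulation, label), child) in enumerate(zip(formulations, children)):
            c = containers[int(container_idx[i])]
            sid = f"test-{i + 1:03d}"
            pairs[sid] = simulate_pair(
                formulation, c, physics, child,
                noise_sd=spec.noise_sd, grid=grid, sample_id=sid,
            )
            records.append(SampleRecord(
                sid, formulation, c.container_id,
                origin=origins[origin_perm[i]], true_label=label,
            ))
    return SpectralDataset(grid=grid, records=records, pairs=pairs)


def contaminant_series(
    base: str,
    contaminant: str,
    levels: Sequence[float],
    n_replicates: int = 20,
    container: Optional[ContainerModel] = None,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
    grid: Optional[WavenumberGrid] = None,
) -> SpectralDataset:
    """Binary dilution series for limit-of-detection characterization.

    The contaminant replaces the approved alcohol at fixed total alcohol
    (80% ethanol-based / 75% 2-propanol-based); level 0 gives blank replicates.
    """
    if base not in APPROVED:
        raise ValueError(f"base must be an approved alcohol {APPROVED}")
    if contaminant not in CONTAMINANTS:
        raise ValueError(f"contaminant must be one of {CONTAMINANTS}")
    container = container or _container(REFERENCE_CONTAINER_ID, "PE", "semitransparent")
    grid = grid or WavenumberGrid()
    total = 80.0 if base == "ethanol" else 75.0
    records: List[SampleRecord] = []
    pairs: Dict[str, SpectrumPair] = {}
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(levels) * n_replicates)
    k = 0
    for level in levels:
        fracs = {base: total - level, "glycerin": 1.45, "h2o2": 0.145}
        if level > 0:
            fracs[contaminant] = level
        f = Formulation.make(**fracs)
        for rep in range(1, n_replicates + 1):
            sid = f"lod-{contaminant}-{level:g}-r{rep}"
            pairs[sid] = simulate_pair(
                f, container, noise_seed=children[k],
                noise_sd=noise_sd, grid=grid, sample_id=sid,
            )
            records.append(SampleRecord(sid, f, container.container_id, origin="training"))
            k += 1
    return SpectralDataset(grid=grid, records=records, pairs=pairs)
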