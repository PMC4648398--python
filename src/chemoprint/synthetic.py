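"""Seeded simulator of species-specific mass-spectral fingerprints.

The generator emulates the structure of ambient-ionization chemotype data:
each species carries a set of small-molecule compounds (think FAME series,
cuticular hydrocarbons, alkaloids or terpenes) observed as singly charged
adduct ions over m/z 60-1000.  Within a species, replicate spectra share
the compound set with reproducible log-normal abundances; between species,
profiles differ through private compounds and through abundance shifts of
a shared compound pool — the two axes real chemotype datasets vary along.

Noise covers the main instrumental artefacts at this level of abstraction:
Gaussian ppm mass error, random compound dropout, and spurious baseline
peaks.  Everything is reproducible from a single master seed; per-spectrum
random streams are derived from ``(master seed, species index, replicate
index)`` so adding or removing one replicate never perturbs the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ConfigError, DataError
from .spectra_io import Mode, Polarity, Spectrum, SpectrumCollection

# monoisotopic constants (u)
PROTON_MASS = 1.007276
O2_MASS = 31.989829
ELECTRON_MASS = 0.000549

ADDUCTS = {
    "M+H": lambda m: m + PROTON_MASS,
    "M-H": lambda m: m - PROTON_MASS,
    "M+O2_minus": lambda m: m + O2_MASS + ELECTRON_MASS,
}

#: Minimum spacing between any two compound masses in a generated pool (u).
#: Keeps default-tolerance feature windows disjoint and mirrors chemically
#: distinct compounds rather than isobars.
MIN_MASS_SPACING_U = 0.5


def adduct_mz(neutral_mass: float, adduct: str) -> float:
    """m/z of a singly charged adduct ion of the given neutral mass."""
    if adduct not in ADDUCTS:
        raise ConfigError(
            f"unknown adduct {adduct!r}; supported: {sorted(ADDUCTS)}"
        )
    if neutral_mass < 0:
        raise DataError("neutral_mass must be non-negative")
    return ADDUCTS[adduct](neutral_mass)


@dataclass(frozen=True)
class Compound:
    neutral_mass: float
    adduct: str
    mean_log10_abundance: float
    abundance_cv: float


@dataclass(frozen=True)
class SpeciesProfile:
    """A species' chemotype: compounds with expected log abundances."""

    name: str
    compounds: tuple[Compound, ...]
    polarity: Polarity = Polarity.POSITIVE

    def __post_init__(self):
        if len(self.compounds) < 1:
            raise DataError("a species profile needs at least one compound")
        for c in self.compounds:
            if not (50.0 < c.neutral_mass < 1000.0):
                raise DataError(
                    f"compound mass {c.neutral_mass} outside (50, 1000) u"
                )
            if c.abundance_cv < 0:
                raise DataError("abundance CV must be non-negative")


@dataclass(frozen=True)
class NoiseModel:
    """Instrumental noise parameters for spectrum simulation."""

    mass_error_ppm_sd: float = 5.0
    dropout_probability: float = 0.02
    baseline_peak_rate: float = 5.0
    baseline_rel_intensity_max: float = 2.0

    def __post_init__(self):
        if min(self.mass_error_ppm_sd, self.dropout_probability,
               self.baseline_peak_rate, self.baseline_rel_intensity_max) < 0:
            raise ConfigError("noise parameters must be non-negative")
        if self.dropout_probability >= 1:
            raise ConfigError("dropout_probability must be < 1")

    @classmethod
    def noiseless(cls) -> "NoiseModel":
        return cls(0.0, 0.0, 0.0, 0.0)


def _draw_spaced_masses(rng: np.random.Generator, count: int,
                        lo: float = 80.0, hi: float = 950.0) -> np.ndarray:
    """Uniform masses with pairwise spacing >= MIN_MASS_SPACING_U."""
    masses: list[float] = []
    for _ in range(100 * count):
        m = float(rng.uniform(lo, hi))
        if all(abs(m - x) >= MIN_MASS_SPACING_U for x in masses):
            masses.append(m)
            if len(masses) == count:
                return np.array(masses)
    raise ConfigError("could not place compound masses with required spacing")


def make_species_profiles(
    n_species: int,
    compounds_per_species: int = 25,
    shared_fraction: float = 0.5,
    separation: float = 1.0,
    seed: int = 0,
    abundance_cv: float = 0.1,
    adduct: str = "M+H",
) -> list[SpeciesProfile]:
    """Generate reproducible species chemotype profiles.

    A common pool of ``round(shared_fraction * compounds_per_species)``
    compounds is shared by all species, but each species' mean log10
    abundance for a shared compound is offset by ``+separation`` or
    ``-separation`` (random sign per species/compound).  The remaining
    compounds are private to each species.  ``separation=0`` with
    ``shared_fraction=1`` yields statistically identical species (the
    synonym scenario).
    """
    if n_species < 2:
        raise ConfigError("n_species must be >= 2")
    if not (0.0 <= shared_fraction <= 1.0):
        raise ConfigError("shared_fraction must be in [0, 1]")
    if compounds_per_species < 1:
        raise ConfigError("compounds_per_species must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5AFE]))
    n_shared = round(shared_fraction * compounds_per_species)
    n_private = compounds_per_species - n_shared
    total = n_shared + n_species * n_private
    pool = np.sort(_draw_spaced_masses(rng, total))
    shared_masses = pool[:n_shared]
    private_masses = pool[n_shared:].reshape(n_species, n_private) \
        if n_private else np.zeros((n_species, 0))
    shared_base = rng.uniform(4.0, 6.0, size=n_shared)
    profiles = []
    for si in range(n_species):
        compounds = []
        signs = rng.choice([-1.0, 1.0], size=n_shared)
        for mass, base, sign in zip(shared_masses, shared_base, signs):
            compounds.append(Compound(
                float(mass), adduct,
                float(base + sign * separation), abundance_cv,
            ))
        for mass in private_masses[si]:
            compounds.append(Compound(
                float(mass), adduct, float(rng.uniform(4.0, 6.0)), abundance_cv,
            ))
        compounds.sort(key=lambda c: c.neutral_mass)
        polarity = (Polarity.NEGATIVE if adduct in ("M-H", "M+O2_minus")
                    else Polarity.POSITIVE)
        profiles.append(SpeciesProfile(f"species_{si:02d}", tuple(compounds),
                                       polarity))
    return profiles


def simulate_spectrum(
    profile: SpeciesProfile,
    noise: NoiseModel | None = None,
    seed: int | np.random.SeedSequence = 0,
    meta: dict | None = None,
) -> Spectrum:
    """Simulate one centroided, base-peak-normalized replicate spectrum.

    Each compound that survives dropout emits one centroid at its adduct
    m/z perturbed by Gaussian ppm mass error, with intensity
    ``10**Normal(mean_log10, cv * mean_log10)``.  Poisson-distributed
    spurious baseline peaks are added uniformly over the acquisition
    range.  If all compounds drop out, the draw is repeated once before
    failing.
    """
    noise = noise or NoiseModel.noiseless()
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(int(seed)))
    rng = np.random.default_rng(ss)

    for attempt in range(2):
        mzs, ints = [], []
        for c in profile.compounds:
            if rng.random() < noise.dropout_probability:
                continue
            mz = adduct_mz(c.neutral_mass, c.adduct)
            if noise.mass_error_ppm_sd > 0:
                mz *= 1.0 + rng.normal(0.0, noise.mass_error_ppm_sd * 1e-6)
            # log-normal replicate scatter with linear-scale coefficient of
            # variation abundance_cv: sd(ln I) = CV to first order
            log10_i = rng.normal(c.mean_log10_abundance,
                                 c.abundance_cv / np.log(10.0))
            mzs.append(mz)
            ints.append(10.0 ** log10_i)
        if mzs:
            break
    else:
        raise DataError(
            f"all compounds of {profile.name} dropped out twice; "
            "lower dropout_probability"
        )

    n_baseline = rng.poisson(noise.baseline_peak_rate) \
        if noise.baseline_peak_rate > 0 else 0
    base = max(ints)
    for _ in range(n_baseline):
        mzs.append(float(rng.uniform(60.0, 1000.0)))
        ints.append(float(rng.uniform(0.0, noise.baseline_rel_intensity_max / 100.0)
                          * base))
    mz_arr = np.array(mzs)
    int_arr = np.array(ints)
    order = np.argsort(mz_arr)
    mz_arr, int_arr = mz_arr[order], int_arr[order]
    keep = np.r_[True, np.diff(mz_arr) > 0]
    mz_arr, int_arr = mz_arr[keep], int_arr[keep]
    int_arr = int_arr * (100.0 / int_arr.max())
    full_meta = {"species_label": profile.name,
                 "acquisition_range": (60.0, 1000.0)}
    if meta:
        full_meta.update(meta)
    return Spectrum(mz_arr, int_arr, Mode.CENTROID, profile.polarity, full_meta)


def simulate_dataset(
    profiles: Sequence[SpeciesProfile],
    replicates_per_species: int = 5,
    noise: NoiseModel | None = None,
    seed: int = 0,
) -> tuple[SpectrumCollection, list[str]]:
    """Simulate a labeled replicate dataset in species-block order.

    Per-spectrum seeds derive deterministically from ``(seed, species
    index, replicate index)``; the same master seed always reproduces the
    identical collection.
    """
    if replicates_per_species < 2:
        raise ConfigError("replicates_per_species must be >= 2")
    spectra, labels = [], []
    for si, profile in enumerate(profiles):
        for ri in range(replicates_per_species):
            ss = np.random.SeedSequence([int(seed), si, ri])
            s = simulate_spectrum(
                profile, noise, ss,
                meta={"sample_id": f"{profile.name}_rep{ri}",
                      "replicate_index": ri},
            )
            spectra.append(s)
            labels.append(profile.name)
    return SpectrumCollection(spectra, labels), labels


def profile_target_masses(profiles: Sequence[SpeciesProfile]) -> np.ndarray:
    """Union of all profiles' adduct m/z values, sorted — the natural
    feature-mass list for a simulated study."""
    targets = {
        round(adduct_mz(c.neutral_mass, c.adduct), 6)
        for p in profiles for c in p.compounds
    }
    return np.array(sorted(targets))
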