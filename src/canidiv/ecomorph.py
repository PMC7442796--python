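"""Trait estimation and ecomorphological classification of fossil canids.

Fragmentary fossils rarely preserve body mass or diet directly, so both are
estimated from dental and mandibular measurements through log10-log10
allometric regressions:

* body mass (kg) from lower first molar (m1) length (mm);
* dentary length (mm) from m1 length via within-subfamily regressions, used
  only when a measured dentary is unavailable;
* typical prey mass (kg) from jaw depth (mm) between m1 and m2, via the
  published extant-canid line ``log10(prey kg) = 5.583 log10(jaw mm) - 6.482``;
* carnivory as m1BS: carnassial blade length relative to dentary length.

Classification: a species is a *large hypercarnivore* when its m1BS is at
least 0.107 (the minimum seen in extant large hypercarnivorous canids) and
it is either >= 20 kg or estimated to take prey at least as large as itself.
The three-level carnivory coding (hypo/meso/hyper) uses the same 0.107 upper
cut; the hypocarnivory cut has no published value and ships as a clearly
marked placeholder (0.07) that should be overridden for real analyses.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .fossilrec import ConfigurationError, ValidationError

__all__ = [
    "RegressionSpec",
    "MorphMeasurement",
    "EcomorphProfile",
    "ClassificationThresholds",
    "DEFAULT_MASS_SPEC",
    "DEFAULT_PREY_SPEC",
    "DEFAULT_DENTARY_SPECS",
    "estimate_body_mass",
    "estimate_dentary_length",
    "compute_m1bs",
    "estimate_prey_mass",
    "classify_species",
    "profiles_from_measurements",
]


@dataclass(frozen=True)
class RegressionSpec:
    """A log10-log10 line ``response = slope * predictor + intercept``.

    Both predictor and response are understood on the log10 scale; `predict`
    and `invert` work on the raw (linear) scale.
    """

    slope: float
    intercept: float
    predictor: str = "log10 x"
    response: str = "log10 y"
    source: str = ""

    def __post_init__(self) -> None:
        if not math.isfinite(self.slope) or not math.isfinite(self.intercept):
            raise ValidationError("regression coefficients must be finite")

    def predict(self, x: float) -> float:
        if x <= 0:
            raise ValidationError(f"predictor {self.predictor!r} must be > 0, got {x}")
        return 10.0 ** (self.slope * math.log10(x) + self.intercept)

    def invert(self, y: float) -> float:
        """Raw-scale predictor value giving response ``y`` (needs slope != 0)."""
        if self.slope == 0:
            raise ValidationError("cannot invert a zero-slope regression")
        if y <= 0:
            raise ValidationError("response must be > 0 to invert")
        return 10.0 ** ((math.log10(y) - self.intercept) / self.slope)


#: Extant-canid body mass from m1 length (Van Valkenburgh 1990 allometry):
#: log10(mass kg) = 2.97 log10(m1 mm) - 2.27.  Config-overridable.
DEFAULT_MASS_SPEC = RegressionSpec(
    slope=2.97, intercept=-2.27,
    predictor="log10 m1 length (mm)", response="log10 body mass (kg)",
    source="Van Valkenburgh (1990) extant-canid m1 allometry",
)

#: Extant-canid typical prey mass from jaw depth between m1 and m2.
DEFAULT_PREY_SPEC = RegressionSpec(
    slope=5.583, intercept=-6.482,
    predictor="log10 jaw depth (mm)", response="log10 prey mass (kg)",
    source="published extant-canid jaw-depth/prey-mass regression",
)

#: Placeholder within-subfamily dentary-length regressions (synthetic values,
#: not fitted to published specimens; dentary ~ 10 x m1 length).  Real
#: analyses must supply fitted per-subfamily coefficients via config.
DEFAULT_DENTARY_SPECS: dict[str, RegressionSpec] = {
    "Hesperocyoninae": RegressionSpec(1.0, 1.0, "log10 m1 (mm)", "log10 dentary (mm)",
                                      source="synthetic placeholder"),
    "Borophaginae": RegressionSpec(1.0, 1.0, "log10 m1 (mm)", "log10 dentary (mm)",
                                   source="synthetic placeholder"),
    "Caninae": RegressionSpec(1.0, 1.0, "log10 m1 (mm)", "log10 dentary (mm)",
                              source="synthetic placeholder"),
}


@dataclass(frozen=True)
class MorphMeasurement:
    """Raw morphometrics (mm) for one species."""

    taxon: str
    m1_length: float
    blade_length: float
    jaw_depth: float | None = None
    dentary_length: float | None = None
    subfamily: str = ""

    def __post_init__(self) -> None:
        for name in ("m1_length", "blade_length", "jaw_depth", "dentary_length"):
            v = getattr(self, name)
            if v is not None and v <= 0 and not (name == "blade_length" and v == 0):
                raise ValidationError(f"{self.taxon!r}: {name} must be > 0, got {v}")


@dataclass(frozen=True)
class ClassificationThresholds:
    """Inclusive classification boundaries."""

    large_mass_kg: float = 20.0     # "large" predator
    hyper_m1bs: float = 0.107       # hypercarnivory cut (extant-canid minimum)
    hypo_m1bs: float = 0.07         # PLACEHOLDER: no published value


@dataclass(frozen=True)
class EcomorphProfile:
    """Derived ecomorphology of one species."""

    taxon: str
    mass: float                     # kg
    m1bs: float
    prey_mass: float | None = None  # kg
    large_hypercarnivore: bool = False
    carnivory_class: str = "meso"   # hypo | meso | hyper

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValidationError(f"{self.taxon!r}: mass must be > 0")
        if not (0 <= self.m1bs < 1):
            raise ValidationError(f"{self.taxon!r}: m1BS must lie in [0, 1)")
        if self.carnivory_class not in ("hypo", "meso", "hyper"):
            raise ValidationError(f"{self.taxon!r}: unknown carnivory class")


def estimate_body_mass(m1_length: float, spec: RegressionSpec | None = None) -> float:
    """Body mass (kg) from m1 length (mm) via a log10-log10 regression."""
    if spec is None:
        raise ConfigurationError(
            "a mass RegressionSpec is required (no universal coefficients exist); "
            "DEFAULT_MASS_SPEC ships a documented extant-canid default"
        )
    return spec.predict(m1_length)


def estimate_dentary_length(m1_length: float, subfamily: str,
                            specs: Mapping[str, RegressionSpec],
                            measured: float | None = None) -> float:
    """Dentary length (mm); a measured value takes precedence over regression."""
    if measured is not None:
        return measured
    if subfamily not in specs:
        raise ConfigurationError(
            f"no dentary regression for subfamily {subfamily!r}; "
            f"available: {sorted(specs)}"
        )
    return specs[subfamily].predict(m1_length)


def compute_m1bs(blade_length: float, dentary_length: float) -> float:
    """Carnivory index: carnassial blade length / dentary length."""
    if dentary_length <= 0:
        raise ValidationError(f"dentary_length must be > 0, got {dentary_length}")
    if blade_length < 0:
        raise ValidationError("blade_length must be >= 0")
    ratio = blade_length / dentary_length
    if ratio >= 1:
        warnings.warn(
            f"implausible m1BS = {ratio:.3f} (blade at least as long as dentary)",
            stacklevel=2,
        )
    return ratio


def estimate_prey_mass(jaw_depth: float, spec: RegressionSpec = DEFAULT_PREY_SPEC) -> float:
    """Typical prey mass (kg) from jaw depth (mm) between m1 and m2."""
    return spec.predict(jaw_depth)


def classify_species(mass: float, m1bs: float, prey_mass: float | None = None,
                     thresholds: ClassificationThresholds = ClassificationThresholds(),
                     ) -> tuple[bool, str]:
    """(large_hypercarnivore, carnivory_class) under inclusive thresholds.

    Large hypercarnivore: hypercarnivorous (m1BS >= hyper cut) AND either
    mass >= the large-size cut or estimated prey mass >= own mass -- the
    prey-size supplement rescues robust species whose mass regression lands
    just under the cut.
    """
    hyper = m1bs >= thresholds.hyper_m1bs
    big = mass >= thresholds.large_mass_kg
    prey_big = prey_mass is not None and prey_mass >= mass
    large_hyper = hyper and (big or prey_big)
    if hyper:
        carnivory = "hyper"
    elif m1bs <= thresholds.hypo_m1bs:
        carnivory = "hypo"
    else:
        carnivory = "meso"
    return large_hyper, carnivory


def profiles_from_measurements(
    measurements: list[MorphMeasurement],
    mass_spec: RegressionSpec = DEFAULT_MASS_SPEC,
    dentary_specs: Mapping[str, RegressionSpec] | None = None,
    prey_spec: RegressionSpec = DEFAULT_PREY_SPEC,
    thresholds: ClassificationThresholds = ClassificationThresholds(),
) -> list[EcomorphProfile]:
    """Full trait-estimation pipeline: measurements -> classified profiles."""
    dentary_specs = dict(DEFAULT_DENTARY_SPECS if dentary_specs is None else dentary_specs)
    profiles = []
    for m in measurements:
        mass = estimate_body_mass(m.m1_length, mass_spec)
        dentary = estimate_dentary_length(m.m1_length, m.subfamily, dentary_specs,
                                          measured=m.dentary_length)
        m1bs = compute_m1bs(m.blade_length, dentary)
        prey = estimate_prey_mass(m.jaw_depth, prey_spec) if m.jaw_depth else None
        large, carn = classify_species(mass, m1bs, prey, thresholds)
        profiles.append(EcomorphProfile(
            taxon=m.taxon, mass=mass, m1bs=m1bs, prey_mass=prey,
            large_hypercarnivore=large, carnivory_class=carn,
        ))
    return profiles


def profiles_to_frame(profiles: list[EcomorphProfile]) -> pd.DataFrame:
    return pd.DataFrame({
        "taxon": [p.taxon for p in profiles],
        "mass_kg": [p.mass for p in profiles],
        "log10_mass": [math.log10(p.mass) for p in profiles],
        "m1bs": [p.m1bs for p in profiles],
        "prey_mass_kg": [p.prey_mass for p in profiles],
        "large_hypercarnivore": [p.large_hypercarnivore for p in profiles],
        "carnivory_class": [p.carnivory_class for p in profiles],
    })
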