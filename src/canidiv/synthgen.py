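"""Ground-truth simulator for fossil birth-death clade histories.

Every inference stage in this package is exercised against data generated
here, so the generator mirrors the model being fitted, stage by stage:

* an exact event-driven (piecewise-exponential inversion) birth-death
  simulation from one lineage at ``root_age`` under piecewise-constant
  lambda(t) / mu(t), optionally with per-lineage rate multipliers driven by
  a continuous trait (the Covar model's generative counterpart);
* species traits fixed at origination: log10 body mass (normal) and m1BS
  (truncated normal in [0, 1)), each with an optional linear temporal trend
  in expectation (younger species larger / more carnivorous -- the
  escalation "ratchet");
* Poisson-process fossil sampling under a time-variable preservation rate
  q(t); species with zero occurrences are silently unobservable, mirroring
  the conditioning in the preservation likelihood;
* interval censoring of every point age to its timescale bin, emulating
  NALMA-interval dating;
* morphometrics obtained by inverting the ecomorph regressions, so a
  noiseless round trip through the trait-estimation pipeline is exact.

Default study conditions: lambda = 0.3, mu = 0.2 (events / lineage / My),
q = 1.5 (occurrences / lineage / My), root age 40 Ma, at least 120 sampled
species -- a clade of roughly the size and span of the North American canid
record.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
import numpy as np
import pandas as pd
from scipy import stats

from . import ecomorph
from .fossilrec import SpeciesRange, TimeScale, ValidationError
from .fbd_mcmc import (FossilDataset, PiecewiseRateFunction, PreservationModel,
                       _compile_pw, _pw_integral0, _pw_rate_at)

__all__ = [
    "SimConfig",
    "SyntheticDataset",
    "simulate_bd",
    "simulate_traits",
    "simulate_occurrences",
    "simulate_morphometrics",
    "make_covariate_curve",
    "couple_rates",
    "simulate_dataset",
    "simulate_selectivity_data",
]


@dataclass(frozen=True)
class SimConfig:
    """Ground-truth parameters of one synthetic clade."""

    root_age: float = 40.0
    lam: PiecewiseRateFunction = field(
        default_factory=lambda: PiecewiseRateFunction.constant(0.3, "origination"))
    mu: PiecewiseRateFunction = field(
        default_factory=lambda: PiecewiseRateFunction.constant(0.2, "extinction"))
    preservation: PreservationModel = field(
        default_factory=lambda: PreservationModel.constant(1.5, oldest=60.0))
    # trait model (per species, fixed at origination)
    mass_mean: float = 0.85        # log10 kg (~7 kg, canid-like)
    mass_sd: float = 0.45
    mass_trend: float = 0.0        # log10 kg per My since root (escalation)
    m1bs_mean: float = 0.09
    m1bs_sd: float = 0.03
    m1bs_trend: float = 0.0        # per My since root
    # trait-rate coupling (per standard deviation of log10 mass)
    alpha_lambda: float = 0.0
    alpha_mu: float = 0.0
    min_sampled_species: int = 120
    #: optional acceptance window upper bound on sampled species; keeps
    #: desk-scale inference runs bounded (None = unbounded)
    max_sampled_species: int | None = None
    max_species: int = 20_000
    max_retries: int = 1000
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.root_age <= 0:
            raise ValidationError("root_age must be > 0")
        if self.min_sampled_species < 2:
            raise ValidationError("min_sampled_species must be >= 2")
        if self.mass_sd <= 0 or self.m1bs_sd <= 0:
            raise ValidationError("trait standard deviations must be > 0")


@dataclass
class SyntheticDataset:
    """A fully ground-truthed synthetic fossil record."""

    ranges: list[SpeciesRange]          # true ts/te of every SAMPLED species
    all_ranges: list[SpeciesRange]      # including unsampled species
    traits: pd.DataFrame                # taxon, log10_mass, m1bs, classes
    occurrences: pd.DataFrame           # taxon, age, min_ma, max_ma
    timescale: TimeScale
    config: SimConfig
    truth: dict                         # serializable ground-truth record

    def to_fossil_dataset(self) -> FossilDataset:
        """Inference-ready container (observed occurrences + extant flags)."""
        extant = {r.taxon for r in self.ranges if r.extant}
        return FossilDataset.from_frame(self.occurrences, extant_taxa=extant)


# ---------------------------------------------------------------------------
# Birth-death histories
# ---------------------------------------------------------------------------

def _draw_event_age(birth_age: float, edges_asc, r_asc, rng) -> float:
    """Age of the next event for a lineage born at ``birth_age`` under a
    piecewise-constant total rate, by segment-wise exponential inversion.
    Returns a value <= 0 if the lineage survives past the present."""
    target = rng.exponential(1.0)
    t = birth_age
    while t > 0.0:
        # side='left' so an age exactly on an edge walks into the segment below
        idx = min(max(int(np.searchsorted(edges_asc, t, side="left")) - 1, 0),
                  len(r_asc) - 1)
        seg_lo = edges_asc[idx]
        rate = r_asc[idx]
        seg_span = t - seg_lo
        if rate > 0 and rate * seg_span >= target:
            return t - target / rate
        target -= rate * seg_span
        t = seg_lo
    return -1.0  # survives to the present


def simulate_bd(config: SimConfig, rng: np.random.Generator | None = None,
                return_traits: bool = False):
    """One unconditioned birth-death realization from a single root lineage.

    Returns the list of true :class:`SpeciesRange` (te = 0 for extant), or
    ``(ranges, trait_frame)`` when ``return_traits`` is set.  Traits are
    drawn at each lineage's origination; when ``alpha_lambda`` or
    ``alpha_mu`` is nonzero, the lineage's rates are multiplied by
    exp(alpha * x) with x the species' standardized log10 mass, so the
    trait-rate coupling of the Covar model is generated exactly.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    lam_e, lam_r, _ = _compile_pw(np.asarray(config.lam.shift_times),
                                  np.asarray(config.lam.rates))
    mu_e, mu_r, _ = _compile_pw(np.asarray(config.mu.shift_times),
                                np.asarray(config.mu.rates))
    coupled = config.alpha_lambda != 0.0 or config.alpha_mu != 0.0
    tot_e = np.union1d(lam_e, mu_e)
    # per-segment rates, evaluated at each segment's lower (younger) edge
    lam_seg = _pw_rate_at(lam_e, lam_r, tot_e)
    mu_seg = _pw_rate_at(mu_e, mu_r, tot_e)

    ranges: list[SpeciesRange] = []
    traits: list[tuple] = []
    # stack of (birth_age,); process depth-first
    stack = [config.root_age]
    while stack:
        birth = stack.pop()
        k = len(ranges)
        if k >= config.max_species:
            raise ValidationError(
                "clade exceeded max_species; lower the rates or root_age")
        x_std = rng.normal()  # standardized mass deviation, fixed per species
        ml = math.exp(config.alpha_lambda * x_std) if coupled else 1.0
        mm = math.exp(config.alpha_mu * x_std) if coupled else 1.0
        tot_r = ml * lam_seg + mm * mu_seg
        t = birth
        while True:
            ev = _draw_event_age(t, tot_e, tot_r, rng)
            if ev <= 0.0:
                te = 0.0
                break
            p_birth = (ml * _pw_rate_at(lam_e, lam_r, ev)) / \
                _pw_rate_at(tot_e, tot_r, ev)
            if rng.random() < p_birth:
                stack.append(ev)
                t = ev
            else:
                te = ev
                break
        ranges.append(SpeciesRange(taxon=f"sp{k:04d}", ts=birth, te=te))
        traits.append((f"sp{k:04d}", x_std))
    if return_traits:
        tf = pd.DataFrame(traits, columns=["taxon", "x_std"])
        return ranges, tf
    return ranges


# ---------------------------------------------------------------------------
# Traits and morphometrics
# ---------------------------------------------------------------------------

def simulate_traits(ranges: list[SpeciesRange], config: SimConfig,
                    rng: np.random.Generator | None = None,
                    x_std: pd.DataFrame | None = None) -> pd.DataFrame:
    """Species trait table (log10 mass, m1BS, carnivory classes).

    Trait expectations may drift linearly with origination age: a species
    originating at ``ts`` has mean log10 mass
    ``mass_mean + mass_trend * (root_age - ts)`` (and analogously for m1BS),
    so positive trends make younger species larger and more carnivorous.
    ``x_std`` (from :func:`simulate_bd` with coupling) fixes the mass
    deviations instead of redrawing them.
    """
    if not ranges:
        raise ValidationError("no species to assign traits to")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    ts = np.array([r.ts for r in ranges])
    age_since_root = config.root_age - ts
    if x_std is not None:
        z = x_std.set_index("taxon").loc[[r.taxon for r in ranges], "x_std"].to_numpy()
    else:
        z = rng.normal(size=len(ranges))
    log_mass = config.mass_mean + config.mass_trend * age_since_root \
        + config.mass_sd * z
    loc = config.m1bs_mean + config.m1bs_trend * age_since_root
    a = (0.0 - loc) / config.m1bs_sd
    b = (1.0 - 1e-9 - loc) / config.m1bs_sd
    m1bs = stats.truncnorm.rvs(a, b, loc=loc, scale=config.m1bs_sd,
                               random_state=rng)
    rows = []
    for r, lm, mb in zip(ranges, log_mass, m1bs):
        large, carn = ecomorph.classify_species(10.0 ** lm, float(mb))
        rows.append((r.taxon, lm, float(mb), large, carn))
    return pd.DataFrame(rows, columns=["taxon", "log10_mass", "m1bs",
                                       "large_hypercarnivore", "carnivory_class"])


def simulate_morphometrics(traits: pd.DataFrame,
                           mass_spec: ecomorph.RegressionSpec = ecomorph.DEFAULT_MASS_SPEC,
                           dentary_spec: ecomorph.RegressionSpec | None = None,
                           prey_spec: ecomorph.RegressionSpec = ecomorph.DEFAULT_PREY_SPEC,
                           noise_sd: float = 0.0,
                           rng: np.random.Generator | None = None,
                           subfamily: str = "Caninae") -> pd.DataFrame:
    """Morphometric measurements consistent with the ecomorph regressions.

    m1 length is the mass regression inverted at the true mass; dentary
    length follows the subfamily regression; blade length is m1BS times the
    dentary; jaw depth is the prey regression inverted at a target prey
    mass equal to the species' own mass (so the recovered prey/predator
    ratio is 1).  ``noise_sd`` adds independent log10-normal measurement
    noise to every measurement.  With ``noise_sd = 0`` the ecomorph pipeline
    recovers mass and m1BS exactly.
    """
    rng = np.random.default_rng() if rng is None else rng
    if dentary_spec is None:
        dentary_spec = ecomorph.DEFAULT_DENTARY_SPECS[subfamily]
    if mass_spec.slope == 0 or dentary_spec.slope == 0 or prey_spec.slope == 0:
        raise ValidationError("regressions must have nonzero slopes to invert")
    rows = []
    for r in traits.itertuples(index=False):
        mass = 10.0 ** r.log10_mass
        m1 = mass_spec.invert(mass)
        dentary = dentary_spec.predict(m1)
        blade = r.m1bs * dentary
        jaw = prey_spec.invert(mass)
        if noise_sd > 0:
            m1 *= 10.0 ** rng.normal(0, noise_sd)
            dentary *= 10.0 ** rng.normal(0, noise_sd)
            blade *= 10.0 ** rng.normal(0, noise_sd)
            jaw *= 10.0 ** rng.normal(0, noise_sd)
        rows.append((r.taxon, m1, blade, jaw, dentary, subfamily))
    return pd.DataFrame(rows, columns=["taxon", "m1_length_mm", "blade_length_mm",
                                       "jaw_depth_mm", "dentary_length_mm",
                                       "subfamily"])


# ---------------------------------------------------------------------------
# Fossil sampling and interval censoring
# ---------------------------------------------------------------------------

def simulate_occurrences(ranges: list[SpeciesRange],
                         preservation: PreservationModel,
                         scale: TimeScale,
                         rng: np.random.Generator | None = None,
                         ) -> pd.DataFrame:
    """Poisson fossil sampling with interval-censored ages.

    Per species the occurrence count is Poisson(integral of q over the
    lifespan); ages are drawn from the normalized q(t) density on [te, ts]
    (segment choice by integral weight, uniform within the segment).
    Species with zero occurrences are dropped.  Each point age is censored
    to the edges of its containing timescale bin (``min_ma`` / ``max_ma``),
    emulating interval dating of real occurrences.
    """
    rng = np.random.default_rng() if rng is None else rng
    pw = preservation._pw()
    edges_asc, r_asc, cum = _compile_pw(np.asarray(pw.shift_times),
                                        np.asarray(pw.rates))
    rows = []
    oldest, youngest = scale.span
    for r in ranges:
        Q = float(pw.integral(r.te, r.ts))
        n = rng.poisson(Q)
        if n == 0:
            continue
        # inverse-CDF sampling on the piecewise-constant density
        u = rng.random(n) * Q
        base = _pw_integral0(edges_asc, r_asc, cum, np.array([r.te]))[0]
        # invert I(t) - I(te) = u by walking segments
        ages = np.empty(n)
        for i, ui in enumerate(u):
            target = base + ui
            j = int(np.searchsorted(cum, target, side="right") - 1)
            j = min(max(j, 0), len(r_asc) - 1)
            ages[i] = edges_asc[j] + (target - cum[j]) / r_asc[j]
        ages = np.clip(ages, r.te, r.ts)
        for a in ages:
            a_clip = min(max(a, youngest), oldest)
            b = int(scale.bin_index(a_clip)[0])
            older, younger = scale.interval_bounds(b)
            rows.append((r.taxon, float(a), younger, older))
    return pd.DataFrame(rows, columns=["taxon", "age", "min_ma", "max_ma"])


# ---------------------------------------------------------------------------
# Covariate curves and rate coupling
# ---------------------------------------------------------------------------

def make_covariate_curve(span: tuple[float, float] = (45.0, 0.0),
                         shape: str = "sinusoid",
                         params: dict | None = None,
                         n_points: int = 200,
                         seed: int | None = None) -> pd.DataFrame:
    """A synthetic time-continuous covariate series (e.g. a d18O proxy).

    Shapes: 'constant', 'linear' (value drifts from ``start`` to ``end``),
    'step' (jumps by ``height`` at ``step_age``), 'sinusoid' (``amplitude``,
    ``period`` in My).  Optional ``noise`` adds iid normal jitter.  Returns
    (age_ma, value) with strictly decreasing ages, oldest first.
    """
    p = {"value": 0.0, "start": -0.5, "end": 0.5, "step_age": 20.0,
         "height": 1.0, "amplitude": 1.0, "period": 20.0, "noise": 0.0}
    if params:
        p.update(params)
    rng = np.random.default_rng(seed)
    old, young = span
    ages = np.linspace(old, young, n_points)
    frac = (old - ages) / max(old - young, 1e-12)
    if shape == "constant":
        vals = np.full(n_points, p["value"])
    elif shape == "linear":
        vals = p["start"] + (p["end"] - p["start"]) * frac
    elif shape == "step":
        vals = np.where(ages > p["step_age"], 0.0, p["height"])
    elif shape == "sinusoid":
        vals = p["amplitude"] * np.sin(2 * np.pi * (old - ages) / p["period"])
    else:
        raise ValidationError(f"unknown curve shape {shape!r}")
    if p["noise"] > 0:
        vals = vals + rng.normal(0, p["noise"], n_points)
    return pd.DataFrame({"age_ma": ages, "d18O": vals})


def couple_rates(base: PiecewiseRateFunction, curve: pd.DataFrame,
                 gamma: float, link: str = "exponential",
                 span: tuple[float, float] | None = None,
                 n_segments: int = 200) -> PiecewiseRateFunction:
    """True rate function rescaled by a covariate: a fine piecewise-constant
    approximation of base(t) * exp(gamma * z(t)) (or * (1 + gamma z) for the
    linear link), with z mean-centered over ``span``.

    A constant curve leaves the rates statistically indistinguishable from
    the uncoupled ones (gamma is then unidentifiable by design).
    """
    ages = curve["age_ma"].to_numpy()
    vals = curve["d18O"].to_numpy()
    old, young = span if span else (float(ages.max()), float(ages.min()))
    g = np.linspace(old, young, n_segments + 1)  # descending if old > young
    mid = (g[:-1] + g[1:]) / 2
    z = np.interp(mid[::-1], ages[::-1], vals[::-1])[::-1]
    zc = z - np.mean(z)
    if link == "exponential":
        f = np.exp(gamma * zc)
    elif link == "linear":
        f = 1.0 + gamma * zc
        if np.min(f) <= 0:
            raise ValidationError("linear link drives a rate <= 0")
    else:
        raise ValidationError("link must be 'exponential' or 'linear'")
    rates = base.rate_at(mid) * f
    return PiecewiseRateFunction(shift_times=tuple(g[1:-1]), rates=tuple(rates),
                                 role=base.role)


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def simulate_dataset(config: SimConfig = SimConfig(),
                     scale: TimeScale | None = None) -> SyntheticDataset:
    """Simulate until at least ``min_sampled_species`` survive preservation.

    The retry loop resimulates whole clades (never resampling preservation
    alone), so the accepted history is a genuine draw conditioned on the
    sampled-species count.  Raises after ``max_retries`` failures with a
    suggestion to change parameters.
    """
    if scale is None:
        base = TimeScale()
        if config.root_age > base.edges[0]:
            scale = TimeScale(edges=(config.root_age,) + base.edges[1:])
        else:
            scale = base
    rng = np.random.default_rng(config.seed)
    for attempt in range(config.max_retries):
        all_ranges, xstd = simulate_bd(config, rng=rng, return_traits=True)
        occ = simulate_occurrences(all_ranges, config.preservation, scale, rng=rng)
        sampled = set(occ["taxon"].unique()) if len(occ) else set()
        if len(sampled) >= config.min_sampled_species and (
                config.max_sampled_species is None
                or len(sampled) <= config.max_sampled_species):
            break
    else:
        raise ValidationError(
            f"no simulation reached {config.min_sampled_species} sampled species "
            f"in {config.max_retries} tries; raise the rates, preservation or "
            "root_age")
    ranges = [r for r in all_ranges if r.taxon in sampled]
    traits = simulate_traits(all_ranges, config, rng=rng, x_std=xstd)
    truth = {
        "lambda": {"shift_times": list(config.lam.shift_times),
                   "rates": list(config.lam.rates)},
        "mu": {"shift_times": list(config.mu.shift_times),
               "rates": list(config.mu.rates)},
        "q": {"bin_edges": list(config.preservation.bin_edges),
              "rates": list(config.preservation.q)},
        "alpha_lambda": config.alpha_lambda,
        "alpha_mu": config.alpha_mu,
        "root_age": config.root_age,
        "seed": config.seed,
        "n_species_true": len(all_ranges),
        "n_species_sampled": len(ranges),
        "attempts": attempt + 1,
    }
    return SyntheticDataset(ranges=ranges, all_ranges=all_ranges,
                            traits=traits, occurrences=occ, timescale=scale,
                            config=config, truth=truth)


def simulate_selectivity_data(n_species: int = 80,
                              frac_large_hyper: float = 0.25,
                              p_early_death: float = 0.5,
                              scale: TimeScale | None = None,
                              planted_final_slice: bool = True,
                              seed: int | None = None):
    """Presence matrix + trait profiles for survivor-victim testing.

    Every species draws its traits first (a ``frac_large_hyper`` share are
    large hypercarnivores), then a random start interval.

    With ``planted_final_slice`` the record reproduces the end-Pleistocene
    pattern: background extinction (probability ``p_early_death`` per
    species, at a random earlier interval) only ever removes the smaller
    non-hypercarnivores, the large hypercarnivores persist to the
    penultimate interval and all vanish at the final slice, and every other
    persistent species survives it -- so the final slice is the only one
    removing large high-m1BS species.

    Without it, *all* extinction (early deaths and the final-slice coin
    flip) is independent of traits, giving an exact selectivity null for
    false-discovery calibration.

    Returns ``(PresenceMatrix, profiles DataFrame)``.
    """
    from .fossilrec import PresenceMatrix

    rng = np.random.default_rng(seed)
    scale = scale or TimeScale()
    n_int = scale.n_intervals
    taxa, first, last, lmass, m1bs, lh = [], [], [], [], [], []
    for i in range(n_species):
        flag = rng.random() < frac_large_hyper
        mass = rng.normal(1.45 if flag else 0.7, 0.2)
        bs = float(np.clip(rng.normal(0.13 if flag else 0.08, 0.01), 0.0, 0.4))
        f = int(rng.integers(0, n_int - 2))
        if planted_final_slice:
            if flag:
                l = n_int - 2                          # dies at the final slice
            elif rng.random() < p_early_death:
                l = int(rng.integers(f, n_int - 2))    # background extinction
            else:
                l = n_int - 1                          # survives throughout
        else:
            if rng.random() < p_early_death:
                l = int(rng.integers(f, n_int - 2))    # trait-independent
            else:
                l = n_int - 2 if rng.random() < 0.5 else n_int - 1
        taxa.append(f"sp{i:03d}")
        first.append(f)
        last.append(l)
        lmass.append(mass)
        m1bs.append(bs)
        lh.append(flag)

    mat = np.zeros((len(taxa), n_int), dtype=bool)
    for k, (f, l) in enumerate(zip(first, last)):
        mat[k, f:l + 1] = True
    matrix = PresenceMatrix(taxa=taxa, scale=scale, matrix=mat)
    profiles = pd.DataFrame({
        "taxon": taxa, "log10_mass": lmass, "m1bs": m1bs,
        "large_hypercarnivore": lh,
    })
    return matrix, profiles
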