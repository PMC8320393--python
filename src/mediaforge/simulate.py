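"""Synthetic multi-donor response surfaces for pipeline development and testing.

Each donor carries a full second-order response surface per response
variable: intercept, main effects, pure-quadratic curvature and two-way
interactions in coded (−1 … +1) units.  Coefficients are drawn as shared
population values plus independent donor-specific deviations, which is the
structure the screening pipeline assumes: effects are real but their sizes
differ from donor to donor.

The default scenario emulates a T-cell media screen with two responses:

* ``viability_d3`` — percent viable cells at day 3, clamped to [0, 100].
  One designated component is toxic at its high level (a strong negative
  main effect), which splits the screening runs into a low (< 75 %) and a
  high (> 75 %) performance group.
* ``expansion_d6`` — day-6 expansion in abstract "expansion units",
  floored at 0, spanning roughly 15–32 units over a screening block with
  replicate noise of about 1 unit.  The reference medium performs near the
  top of that range.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .design import REFERENCE_RUN_ID, factor_columns

__all__ = [
    "ResponseParams",
    "Scenario",
    "default_scenario",
    "planted_optimum_scenario",
    "SurfaceCoefficients",
    "DonorEffectProfile",
    "sample_population",
    "sample_donor_profiles",
    "true_response",
    "simulate_block",
    "simulate_study",
]

VIABILITY = "viability_d3"
EXPANSION = "expansion_d6"


@dataclass(frozen=True)
class ResponseParams:
    """Population and noise structure of one response variable.

    Sparsity is the fraction of null coefficients in each class; the
    complementary number of active components is drawn without replacement.
    Active magnitudes are a floor plus a half-normal spread
    (``|coef| = floor + |N(0, scale)|``) so a screen always contains real,
    detectable effects: mains and interactions get random signs, pure
    quadratics are negative (each active component has an interior optimum,
    ``quad_mean`` is their negative floor).  ``main_donor_sd``,
    ``quad_donor_sd`` and ``int_donor_sd`` are *relative* between-donor
    standard deviations: each donor's coefficient is the population value
    times ``1 + N(0, sd)``, so effect sizes (and hence each donor's
    optimum) vary across donors while the sparse support is shared — null
    components stay null for every donor.  ``beta0_donor_sd`` and
    ``reference_donor_sd`` are absolute.
    """

    name: str
    beta0_mean: float
    beta0_donor_sd: float
    main_floor: float
    main_scale: float
    main_sparsity: float
    main_donor_sd: float
    quad_mean: float
    quad_scale: float
    quad_sparsity: float
    quad_donor_sd: float
    int_floor: float
    int_scale: float
    int_sparsity: float
    int_donor_sd: float
    replicate_sd: float
    lower: float
    upper: float
    reference_mean: float
    reference_donor_sd: float
    # index of a component forced to carry a strong negative main effect
    toxic_component: int | None = None
    toxic_effect: float = 0.0
    # quad-active components get an interior optimum drawn uniformly from
    # ±optimum_range (0 = pure curvature about the center); donors shift
    # that optimum location by a heavy-tailed jitter of sd optimum_donor_sd
    optimum_range: float = 0.0
    optimum_donor_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.replicate_sd <= 0:
            raise ValueError(f"{self.name}: replicate_sd must be positive")
        for nm in ("beta0_donor_sd", "main_donor_sd", "quad_donor_sd", "int_donor_sd"):
            if getattr(self, nm) < 0:
                raise ValueError(f"{self.name}: {nm} must be non-negative")
        for nm in ("main_sparsity", "quad_sparsity", "int_sparsity"):
            if not 0.0 <= getattr(self, nm) <= 1.0:
                raise ValueError(f"{self.name}: {nm} must lie in [0, 1]")


@dataclass(frozen=True)
class Scenario:
    """A complete data-generating configuration for one simulated study."""

    k: int
    responses: tuple[ResponseParams, ...]
    # optional planted optimum per response: coded vector where the
    # noiseless surface attains its unconstrained maximum
    planted_optimum: dict[str, tuple[float, ...]] = field(default_factory=dict)
    planted_quad_strength: float = 3.0

    def response(self, name: str) -> ResponseParams:
        for r in self.responses:
            if r.name == name:
                return r
        raise KeyError(name)

    @property
    def response_names(self) -> list[str]:
        return [r.name for r in self.responses]


def default_scenario(k: int = 12) -> Scenario:
    """The standard four-donor T-cell screening scenario."""
    viability = ResponseParams(
        name=VIABILITY,
        beta0_mean=80.0, beta0_donor_sd=3.0,
        main_floor=1.5, main_scale=0.5, main_sparsity=0.75, main_donor_sd=0.4,
        quad_mean=-0.9, quad_scale=0.3, quad_sparsity=0.917, quad_donor_sd=0.3,
        int_floor=0.8, int_scale=0.2, int_sparsity=0.985, int_donor_sd=0.3,
        replicate_sd=0.8, lower=0.0, upper=100.0,
        reference_mean=88.0, reference_donor_sd=2.0,
        toxic_component=min(6, k - 1), toxic_effect=-8.0,
    )
    expansion = ResponseParams(
        name=EXPANSION,
        beta0_mean=23.0, beta0_donor_sd=0.75,
        main_floor=3.0, main_scale=0.5, main_sparsity=0.83, main_donor_sd=0.3,
        quad_mean=-1.5, quad_scale=0.3, quad_sparsity=0.75, quad_donor_sd=0.25,
        int_floor=0.8, int_scale=0.2, int_sparsity=0.985, int_donor_sd=0.3,
        replicate_sd=0.8, lower=0.0, upper=np.inf,
        reference_mean=30.0, reference_donor_sd=1.0,
        optimum_range=0.6, optimum_donor_sd=0.45,
    )
    return Scenario(k=k, responses=(viability, expansion))


def planted_optimum_scenario(
    optimum: np.ndarray,
    k: int = 12,
    quad_strength: float = 3.0,
    donor_sd_scale: float = 1.0,
) -> Scenario:
    """Scenario whose every response surface peaks at one shared optimum.

    The surface is a concave diagonal quadratic: ``beta_quad = −q`` and
    ``beta_main = 2·q·x*`` so the unconstrained argmax sits exactly at
    ``x*``.  Donor deviations rescale the curvature (and hence effect
    sizes) per component — a vertex is invariant under rescaling, so every
    donor's optimum stays exactly at ``x*``; the optimum location itself
    is not jittered.
    """
    optimum = np.asarray(optimum, dtype=float)
    if optimum.shape != (k,):
        raise ValueError(f"optimum must have shape ({k},)")
    base = default_scenario(k)
    resp = []
    for r in base.responses:
        resp.append(
            replace(
                r,
                toxic_component=None,
                toxic_effect=0.0,
                main_donor_sd=r.main_donor_sd * donor_sd_scale,
                quad_donor_sd=r.quad_donor_sd * donor_sd_scale,
                int_donor_sd=r.int_donor_sd * donor_sd_scale,
                optimum_donor_sd=0.0,
            )
        )
    return Scenario(
        k=k,
        responses=tuple(resp),
        planted_optimum={r.name: tuple(optimum) for r in resp},
        planted_quad_strength=quad_strength,
    )


@dataclass(frozen=True)
class SurfaceCoefficients:
    """Second-order surface in coded units for a single response."""

    beta0: float
    main: np.ndarray          # (k,)
    quad: np.ndarray          # (k,)
    inter: np.ndarray         # (k, k) strictly upper triangular
    reference_value: float
    # population-only decomposition (used to structure donor deviations):
    # main = main_pure - 2 * quad * x_opt
    x_opt: np.ndarray | None = None
    main_pure: np.ndarray | None = None

    def __post_init__(self) -> None:
        k = self.main.shape[0]
        if self.quad.shape != (k,) or self.inter.shape != (k, k):
            raise ValueError("coefficient shapes inconsistent")
        if np.any(np.tril(self.inter) != 0):
            raise ValueError("interaction matrix must be strictly upper triangular")
        for arr in (self.main, self.quad, self.inter):
            if not np.all(np.isfinite(arr)):
                raise ValueError("coefficients must be finite")


@dataclass(frozen=True)
class DonorEffectProfile:
    donor_id: str
    surfaces: dict[str, SurfaceCoefficients]


def _population_surface(params: ResponseParams, k: int, rng: np.random.Generator,
                        optimum: np.ndarray | None, quad_strength: float) -> SurfaceCoefficients:
    if optimum is not None:
        # curvature only where the optimum is off-center: a dozen mutually
        # correlated quadratic columns cannot be resolved from 2k + 1 runs,
        # and a screen's surface is sparse anyway
        quad = np.where(optimum != 0.0, -quad_strength, 0.0)
        main = -2.0 * quad * optimum
        inter = np.zeros((k, k))
        return SurfaceCoefficients(
            beta0=params.beta0_mean, main=main, quad=quad, inter=inter,
            reference_value=params.reference_mean,
            x_opt=optimum.copy(), main_pure=np.zeros(k),
        )
    n_main = int(round((1.0 - params.main_sparsity) * k))
    main_pure = np.zeros(k)
    active = rng.choice(k, n_main, replace=False)
    main_pure[active] = (
        params.main_floor + np.abs(rng.normal(0.0, params.main_scale, n_main))
    ) * rng.choice([-1.0, 1.0], n_main)
    if params.toxic_component is not None:
        main_pure[params.toxic_component] = params.toxic_effect
    n_quad = int(round((1.0 - params.quad_sparsity) * k))
    quad = np.zeros(k)
    quad_active = rng.choice(k, n_quad, replace=False)
    quad[quad_active] = params.quad_mean - np.abs(
        rng.normal(0.0, params.quad_scale, n_quad)
    )
    x_opt = np.zeros(k)
    if params.optimum_range > 0:
        x_opt[quad_active] = rng.uniform(
            -params.optimum_range, params.optimum_range, n_quad
        )
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    n_int = int(round((1.0 - params.int_sparsity) * len(pairs)))
    inter = np.zeros((k, k))
    for idx in rng.choice(len(pairs), n_int, replace=False):
        i, j = pairs[idx]
        inter[i, j] = (
            params.int_floor + abs(rng.normal(0.0, params.int_scale))
        ) * rng.choice([-1.0, 1.0])
    return SurfaceCoefficients(
        beta0=params.beta0_mean,
        main=main_pure - 2.0 * quad * x_opt,
        quad=quad,
        inter=inter,
        reference_value=params.reference_mean,
        x_opt=x_opt,
        main_pure=main_pure,
    )


def sample_population(scenario: Scenario, seed: int | None) -> dict[str, SurfaceCoefficients]:
    """Draw the shared population surface for every response."""
    rng = np.random.default_rng(seed)
    pop = {}
    for params in scenario.responses:
        opt = scenario.planted_optimum.get(params.name)
        opt_arr = np.asarray(opt, dtype=float) if opt is not None else None
        pop[params.name] = _population_surface(
            params, scenario.k, rng, opt_arr, scenario.planted_quad_strength
        )
    return pop


def _donor_dev(rng: np.random.Generator, sd: float, shape) -> np.ndarray:
    """Relative donor deviations with heavy tails (scaled Student-t, df=3).

    Most donors sit near the population effect size, but occasionally a
    donor responds idiosyncratically to a component — the heavy tail that
    makes pooled (mean-based) modeling fragile while median-based
    consensus stays stable.
    """
    return rng.standard_t(3, size=shape) * (sd / np.sqrt(3.0))


def sample_donor_profiles(
    n_donors: int,
    scenario: Scenario,
    seed: int | None,
    population: dict[str, SurfaceCoefficients] | None = None,
    donor_ids: list[str] | None = None,
) -> list[DonorEffectProfile]:
    """Draw donor profiles as population surface + per-donor deviations.

    With every between-donor SD equal to zero, all profiles coincide with
    the population surface.  Pass a precomputed ``population`` to draw
    training and test donors from the same underlying surface.
    """
    ss = np.random.SeedSequence(seed)
    pop_seed, donor_seed = (int(s) for s in ss.generate_state(2) % (2**31))
    if population is None:
        population = sample_population(scenario, pop_seed)
    rng = np.random.default_rng(donor_seed)
    if donor_ids is None:
        donor_ids = [f"d{i + 1:02d}" for i in range(n_donors)]
    if len(donor_ids) != n_donors:
        raise ValueError("donor_ids length must equal n_donors")
    k = scenario.k
    profiles = []
    for donor_id in donor_ids:
        surfaces = {}
        for params in scenario.responses:
            pop = population[params.name]
            quad = pop.quad * (1.0 + _donor_dev(rng, params.quad_donor_sd, k))
            if pop.x_opt is not None:
                # deviations act on the donor's optimum location and peak
                # curvature; the main coefficient follows from the vertex
                x_opt = pop.x_opt + np.where(
                    pop.quad != 0, _donor_dev(rng, params.optimum_donor_sd, k), 0.0
                )
                main_pure = pop.main_pure * (
                    1.0 + _donor_dev(rng, params.main_donor_sd, k)
                )
                main = main_pure - 2.0 * quad * x_opt
            else:
                main = pop.main * (1.0 + _donor_dev(rng, params.main_donor_sd, k))
            inter = pop.inter * (1.0 + np.triu(_donor_dev(rng, params.int_donor_sd, (k, k)), 1))
            surfaces[params.name] = SurfaceCoefficients(
                beta0=pop.beta0 + rng.normal(0.0, params.beta0_donor_sd),
                main=main,
                quad=quad,
                inter=np.triu(inter, 1),
                reference_value=pop.reference_value
                + rng.normal(0.0, params.reference_donor_sd),
            )
        profiles.append(DonorEffectProfile(donor_id=donor_id, surfaces=surfaces))
    return profiles


def _clip(values: np.ndarray, params: ResponseParams) -> np.ndarray:
    return np.clip(values, params.lower, params.upper)


def true_response(
    profile: DonorEffectProfile,
    formulation: np.ndarray,
    response: str,
    params: ResponseParams | None = None,
) -> float | np.ndarray:
    """Noiseless surface value(s) at coded formulation(s).

    Accepts a single coded vector of length k or an (n, k) matrix.  Values
    are clipped to the response bounds when ``params`` is given.
    """
    surf = profile.surfaces[response]
    X = np.atleast_2d(np.asarray(formulation, dtype=float))
    k = surf.main.shape[0]
    if X.shape[1] != k:
        raise ValueError(f"formulation length {X.shape[1]} != k={k}")
    vals = (
        surf.beta0
        + X @ surf.main
        + (X**2) @ surf.quad
        + np.einsum("ni,ij,nj->n", X, surf.inter, X)
    )
    if params is not None:
        vals = _clip(vals, params)
    if np.ndim(formulation) == 1:
        return float(vals[0])
    return vals


def simulate_block(
    profile: DonorEffectProfile,
    design: pd.DataFrame,
    scenario: Scenario,
    replicates: int = 3,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate noisy replicate measurements for one donor block.

    Reference runs draw around the donor's reference performance; coded
    runs draw around the donor's surface value.  All values respect the
    response bounds.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    cols = factor_columns(design)
    records = []
    for _, row in design.iterrows():
        is_ref = row.get("run_role", "dsd_formulation") == "reference"
        x = None if is_ref else row[cols].to_numpy(dtype=float)
        for params in scenario.responses:
            if is_ref:
                mean = profile.surfaces[params.name].reference_value
            else:
                mean = true_response(profile, x, params.name, params)
            noisy = _clip(mean + rng.normal(0.0, params.replicate_sd, replicates), params)
            for rep in range(1, replicates + 1):
                records.append(
                    {
                        "donor_id": profile.donor_id,
                        "run_id": row["run_id"],
                        "replicate": rep,
                        "response": params.name,
                        "value": float(noisy[rep - 1]),
                    }
                )
    return pd.DataFrame.from_records(records)


def simulate_study(
    profiles: list[DonorEffectProfile],
    design: pd.DataFrame,
    scenario: Scenario,
    replicates: int = 3,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate all donor blocks of a study into one long-form table."""
    seeds = np.random.SeedSequence(seed).generate_state(len(profiles)) % (2**31)
    blocks = []
    for profile, s in zip(profiles, seeds):
        sub = design
        if "block_id" in design.columns:
            sub = design[design["block_id"] == profile.donor_id]
            if sub.empty:
                sub = design
        blocks.append(simulate_block(profile, sub, scenario, replicates, int(s)))
    return pd.concat(blocks, ignore_index=True)
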