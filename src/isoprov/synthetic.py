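"""Synthetic world with known ground truth for end-to-end testing.

The generator emulates the structure of the real problem on an abstract
equal-area grid: a parametric coastline drives a sea-salt deposition field
(exponential decay with distance to coast), a dust field forms a smooth
north-south gradient, a gravity-anomaly field is a smooth random surface,
and a set of pure-noise decoy covariates exercises variable selection. The
true δ³⁴S surface is a coastal plateau that declines smoothly inland
(softplus response in the distance implied by sea salt) plus additive dust
and gravity terms, spanning roughly -5 to 21 permil. Site compilations add
between-site and within-site scatter; individuals are drawn from known
origin cells with measurement noise matching each isoscape's SD.

One seed governs a splittable stream (world / sites / individuals), so each
component regenerates independently and deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import assignment as asg
from . import model as mdl
from .compilation import CollagenRecord, site_average
from .grids import (CovariateStack, GridSpec, Isoscape, RasterGrid,
                    distance_to_coast, extract_at_points)


@dataclass
class ResponseSpec:
    """Monotone plateau response of true δ³⁴S to coastal distance."""

    plateau: float = 15.5          # permil: coastal ceiling
    breakpoint_km: float = 150.0   # decline onset (coastal plateau width)
    slope: float = 0.021           # permil lost per km beyond the breakpoint
    softness_km: float = 60.0      # softplus width of the transition
    dust_amplitude: float = 2.5    # permil, bounded additive dust term
    bouguer_amplitude: float = 2.5  # permil, bounded additive gravity term


@dataclass
class WorldSpec:
    """Study conditions of the synthetic world."""

    grid: GridSpec = field(default_factory=lambda: GridSpec(
        crs="local", cell_size=10_000.0, xmin=0.0, ymax=1_200_000.0,
        nrows=120, ncols=120))
    seed: int = 0
    coast_fraction: float = 0.25      # western sea band, fraction of width
    coast_wiggle_cells: float = 6.0   # coastline sinuosity amplitude
    response: ResponseSpec = field(default_factory=ResponseSpec)
    ssa_scale_km: float = 100.0       # e-folding of sea-salt deposition
    ssa_max: float = 20.0             # kg/ha/yr at the coast
    n_decoys: int = 5
    within_site_sd: float = 1.77      # permil, replicate scatter inside a site
    site_effect_sd: float = 1.8       # permil, used when signal_fraction is None
    signal_fraction: float | None = 0.65  # target share of site-mean variance
    sd_O: float = 0.8                 # permil, water-equivalent O isoscape SD
    sd_Sr: float = 0.0008             # ratio units, Sr isoscape SD
    sd_S_true: float = 2.0            # permil, SD attached to the true S surface

    def streams(self) -> dict[str, np.random.Generator]:
        root = np.random.SeedSequence(self.seed)
        world_ss, sites_ss, indiv_ss = root.spawn(3)
        return {"world": np.random.default_rng(world_ss),
                "sites": np.random.default_rng(sites_ss),
                "individuals": np.random.default_rng(indiv_ss)}


@dataclass
class SyntheticIndividual:
    individual_id: str
    true_cell: tuple[int, int]
    measurements: dict[str, float]


@dataclass
class SyntheticWorld:
    """Covariates, truth surfaces and masks bundled with their WorldSpec."""

    ws: WorldSpec
    land: RasterGrid
    stack: CovariateStack
    distance_km: RasterGrid
    true_isoscapes: dict[str, Isoscape]

    @property
    def truth(self) -> Isoscape:
        return self.true_isoscapes["S"]


def _smooth_field(rng: np.random.Generator, shape, sigma_cells: float) -> np.ndarray:
    """Standardized low-frequency Gaussian random field."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma_cells,
                                mode="reflect")
    return (f - f.mean()) / f.std()


def make_land_mask(ws: WorldSpec) -> RasterGrid:
    """Sea band along the western edge with a sinuous coastline."""
    g = ws.grid
    rows = np.arange(g.nrows)
    base = ws.coast_fraction * g.ncols
    coast_col = base + ws.coast_wiggle_cells * np.sin(
        2 * np.pi * rows / g.nrows * 3.0)
    cols = np.arange(g.ncols)
    land = cols[None, :] >= coast_col[:, None]
    return RasterGrid(g, land.astype(float), np.zeros(g.shape, bool), "land")


def make_covariates(ws: WorldSpec) -> SyntheticWorld:
    """Build the covariate stack and the true isoscapes for a WorldSpec.

    Layers: ``r.ssa`` (sea-salt deposition, exponential decay of distance to
    coast), ``r.dust`` (north-south gradient plus low-frequency noise),
    ``r.bouguer`` (smooth random field), and ``n_decoys`` pure-noise decoys
    checked at generation to share <0.2 absolute correlation with the true
    surface. Deterministic given the seed.
    """
    rng = ws.streams()["world"]
    g = ws.grid
    land = make_land_mask(ws)
    dist = distance_to_coast(land, g)

    ssa = ws.ssa_max * np.exp(-dist.values / ws.ssa_scale_km)
    lat_grad = np.linspace(1.0, -1.0, g.nrows)[:, None] * np.ones((1, g.ncols))
    dust = 3.0 * lat_grad + 1.0 * _smooth_field(rng, g.shape, g.nrows / 8)
    dust = 5.0 + 2.0 * (dust - dust.mean()) / dust.std()   # g/m2/yr, positive
    # gravity anomaly: finer correlation scale than the aerosol fields, and
    # decorrelated from dust by construction so the two responses on the
    # true surface are separately identifiable
    raw = _smooth_field(rng, g.shape, g.nrows / 12)
    dstd = (dust - dust.mean()) / dust.std()
    raw = raw - (np.mean(raw * dstd) / np.mean(dstd * dstd)) * dstd
    bouguer = 120.0 * (raw - raw.mean()) / raw.std()  # mGal

    sea = ~land.values.astype(bool)
    stack = CovariateStack(g)
    for name, vals in (("r.ssa", ssa), ("r.dust", dust), ("r.bouguer", bouguer)):
        stack.add(RasterGrid(g, np.where(sea, np.nan, vals), sea, name))
    stack.add(RasterGrid(g, np.where(sea, np.nan, dist.values), sea,
                         "r.distance"))

    world = SyntheticWorld(ws=ws, land=land, stack=stack, distance_km=dist,
                           true_isoscapes={})
    world.true_isoscapes.update(_make_true_isoscapes(world, rng))

    # decoys: near-white noise, independent of the truth by construction;
    # verified empirically over land at generation time
    truth = world.truth.mean.values
    land_mask = land.values.astype(bool)
    for i in range(ws.n_decoys):
        for attempt in range(10):
            vals = ndimage.gaussian_filter(rng.standard_normal(g.shape), 1.0)
            r = np.corrcoef(vals[land_mask], truth[land_mask])[0, 1]
            if abs(r) < 0.2:
                break
        else:  # pragma: no cover - white noise on >10^3 cells never gets here
            raise RuntimeError("decoy generation failed the independence check")
        stack.add(RasterGrid(g, np.where(sea, np.nan, vals), sea,
                             f"decoy{i + 1}"))
    return world


def distance_response(d_km, response: ResponseSpec):
    """Closed-form coastal response: plateau minus a softplus decline.

    Flat (near the plateau) within the breakpoint distance, then declining
    at ``slope`` permil/km, with a transition of width ``softness_km``.
    """
    w = response.softness_km
    with np.errstate(invalid="ignore"):
        drop = response.slope * w * np.logaddexp(
            0.0, (np.asarray(d_km, float) - response.breakpoint_km) / w)
    return response.plateau - drop


def true_s_surface(stack: CovariateStack, ws: WorldSpec) -> np.ndarray:
    """True δ³⁴S mean from the covariates (closed-form response).

    The coastal-distance response is re-expressed through the sea-salt
    covariate (d = -L log(ssa/max)), so the informative signal is entirely
    carried by stack layers the regression can see.
    """
    r = ws.response
    ssa = stack["r.ssa"].values
    with np.errstate(divide="ignore", invalid="ignore"):
        d = -ws.ssa_scale_km * np.log(np.clip(ssa / ws.ssa_max, 1e-12, None))
    base = distance_response(d, r)
    dust = stack["r.dust"].values
    boug = stack["r.bouguer"].values
    land = stack["r.ssa"].valid_mask
    dust_std = (dust - np.nanmean(dust[land])) / np.nanstd(dust[land])
    boug_std = (boug - np.nanmean(boug[land])) / np.nanstd(boug[land])
    # tanh bounds each additive term to +-amplitude, keeping the surface span
    # inside the observed compilation range regardless of field extremes
    return (base
            + r.dust_amplitude * np.tanh(dust_std)
            + r.bouguer_amplitude * np.tanh(boug_std))


def _make_true_isoscapes(world: SyntheticWorld,
                         rng: np.random.Generator) -> dict[str, Isoscape]:
    ws = world.ws
    g = ws.grid
    sea = ~world.land.values.astype(bool)

    mu_s = np.where(sea, np.nan, true_s_surface(world.stack, ws))
    iso_s = Isoscape("S", RasterGrid(g, mu_s, sea, "S_true"), ws.sd_S_true,
                     note="synthetic truth")

    # O: drinking-water-equivalent precipitation surface; smooth gradient in
    # continentality (distance) and latitude, typical European magnitudes
    lat_grad = np.linspace(0.0, -4.0, g.nrows)[:, None] * np.ones((1, g.ncols))
    mu_o = -4.0 - 0.006 * world.distance_km.values + lat_grad \
        + 0.5 * _smooth_field(rng, g.shape, g.nrows / 10)
    iso_o = Isoscape("O", RasterGrid(g, np.where(sea, np.nan, mu_o), sea,
                                     "O_true"), ws.sd_O,
                     note="synthetic truth")

    # Sr: bedrock-driven smooth random field in a realistic ratio range
    f = _smooth_field(rng, g.shape, g.nrows / 15)
    mu_sr = 0.7095 + 0.0025 * f
    iso_sr = Isoscape("Sr", RasterGrid(g, np.where(sea, np.nan, mu_sr), sea,
                                       "Sr_true"), ws.sd_Sr,
                      note="synthetic truth")
    return {"S": iso_s, "O": iso_o, "Sr": iso_sr}


def make_true_isoscape(world: SyntheticWorld, system: str = "S") -> Isoscape:
    return world.true_isoscapes[system]


def _site_effect_sd(world: SyntheticWorld, per_site_n: int) -> float:
    """Between-site noise SD implied by the configured signal fraction.

    With signal fraction f, total noise variance on a site mean is
    Var(mu) (1 - f) / f; the within-site term contributes sd^2 / n of it and
    the site effect supplies the rest (floored at 0).
    """
    ws = world.ws
    if ws.signal_fraction is None:
        return ws.site_effect_sd
    land = world.land.values.astype(bool)
    var_mu = float(np.var(world.truth.mean.values[land]))
    noise_var = var_mu * (1.0 - ws.signal_fraction) / ws.signal_fraction
    site_var = noise_var - ws.within_site_sd ** 2 / per_site_n
    return float(np.sqrt(max(site_var, 0.0)))


def sample_sites(world: SyntheticWorld, n_sites: int = 200,
                 per_site_n: int = 5, flagged_fraction: float = 0.0,
                 rng: np.random.Generator | None = None) -> list[CollagenRecord]:
    """Draw a site compilation from the true surface.

    Each record is mu_true(cell) + site effect + within-site noise. A
    ``flagged_fraction`` of records receives screening-violating ratios and
    a non-local flag to exercise the compilation screens.
    """
    ws = world.ws
    rng = rng or world.ws.streams()["sites"]
    land_idx = np.argwhere(world.land.values.astype(bool))
    pick = rng.choice(len(land_idx), size=n_sites, replace=False)
    cells = land_idx[pick]
    site_sd = _site_effect_sd(world, per_site_n)
    records: list[CollagenRecord] = []
    cx, cy = world.ws.grid.cell_centers()
    for i, (r, c) in enumerate(cells):
        mu = world.truth.mean.values[r, c]
        effect = rng.normal(0.0, site_sd)
        # "local" CRS: projected metres double as the lat/lon slots, scaled
        # into valid degree ranges for record validation
        lat = cy[r, c] / 1e5
        lon = cx[r, c] / 1e5
        for k in range(per_site_n):
            val = mu + effect + rng.normal(0.0, ws.within_site_sd)
            flagged = rng.random() < flagged_fraction
            records.append(CollagenRecord(
                record_id=f"s{i}_{k}", site_id=f"site{i:04d}",
                latitude=lat, longitude=lon, d34S=float(val),
                CS_ratio=120.0, NS_ratio=40.0,
                flags={"nonlocal_reported"} if flagged else set()))
    return records


def sample_individuals(world: SyntheticWorld, n: int,
                       isoscapes: dict[str, Isoscape] | None = None,
                       noise_multiplier: float = 1.0,
                       rng: np.random.Generator | None = None
                       ) -> list[SyntheticIndividual]:
    """Draw individuals from known land cells.

    Measurements are isoscape mean at the true cell plus Normal noise with
    the isoscape's own SD (the well-specified case) times
    ``noise_multiplier`` (misspecification experiments).
    """
    isoscapes = isoscapes or world.true_isoscapes
    rng = rng or world.ws.streams()["individuals"]
    valid = np.logical_and.reduce(
        [iso.mean.valid_mask for iso in isoscapes.values()])
    land_idx = np.argwhere(valid & world.land.values.astype(bool))
    picks = rng.integers(0, len(land_idx), size=n)
    out = []
    for i, p in enumerate(picks):
        r, c = land_idx[p]
        meas = {}
        for sysname, iso in isoscapes.items():
            sd = iso.sd_values()[r, c] * noise_multiplier
            meas[sysname] = float(iso.mean.values[r, c] + rng.normal(0.0, sd))
        out.append(SyntheticIndividual(f"ind{i:04d}", (int(r), int(c)), meas))
    return out


@dataclass
class ExperimentReport:
    cv_r2: float
    cv_rmse: float
    selected_variables: list[str]
    selection_recall: float
    selection_false_positives: int
    coverage_at_q: float
    mean_pct_area_removed: dict[str, float]
    isoscape_rmse_vs_truth: float


INFORMATIVE = ("r.ssa", "r.dust", "r.bouguer")


def end_to_end_experiment(ws: WorldSpec,
                          n_sites: int = 200, per_site_n: int = 5,
                          n_individuals: int = 200,
                          q: float = 1.0 / 3.0,
                          folds: int = 10, repeats: int = 5,
                          selector_params: dict | None = None,
                          model_params: dict | None = None,
                          run_selection: bool = True) -> ExperimentReport:
    """Run compilation -> covariates -> model -> isoscape -> assignment.

    Deterministic given ``ws.seed``. Candidate covariates exclude
    ``r.distance`` (its signal is already carried by sea salt, mirroring how
    deposition fields subsume raw distance).
    """
    world = make_covariates(ws)
    streams = ws.streams()
    records = sample_sites(world, n_sites, per_site_n, rng=streams["sites"])
    sites = site_average(records)
    pts = [(s.site_id, s.latitude * 1e5, s.longitude * 1e5) for s in sites]
    # local CRS: x from lon slot, y from lat slot
    cov = extract_at_points(world.stack, [(sid, y, x) for sid, y, x in pts])
    candidates = [n for n in world.stack.names if n != "r.distance"]
    ds = mdl.build_regression_dataset(sites, cov, candidates)

    seed_sel, seed_cv, seed_fit = (
        int(s) for s in np.random.SeedSequence(ws.seed).generate_state(3) % (2 ** 31))
    if run_selection:
        sel = mdl.select_variables(ds, seed=seed_sel,
                                   **(selector_params or {}))
        selected = sel.selected_variables_
    else:
        selected = list(INFORMATIVE)
    recall = sum(v in selected for v in INFORMATIVE) / len(INFORMATIVE)
    false_pos = sum(v not in INFORMATIVE for v in selected)
    use_vars = selected if selected else list(INFORMATIVE)

    cv = mdl.cross_validate(ds, use_vars, folds=folds, repeats=repeats,
                            seed=seed_cv, model_params=model_params)
    forest = mdl.fit_forest(ds, use_vars, seed=seed_fit,
                            **{k: v for k, v in (model_params or {}).items()})
    fitted_iso = forest.predict_isoscape(world.stack, constant_rmse=cv.rmse)

    land = world.land.values.astype(bool) & fitted_iso.mean.valid_mask
    iso_rmse = float(np.sqrt(np.mean(
        (fitted_iso.mean.values[land] - world.truth.mean.values[land]) ** 2)))

    # assignment ensemble in the well-specified case: the S surface used for
    # assignment is the fitted isoscape, and individuals are drawn from it
    assign_isoscapes = {"S": fitted_iso,
                        "O": world.true_isoscapes["O"],
                        "Sr": world.true_isoscapes["Sr"]}
    individuals = sample_individuals(world, n_individuals, assign_isoscapes,
                                     rng=streams["individuals"])
    subset_sums: dict[str, float] = {}
    covered = 0
    for ind in individuals:
        ms = [asg.TissueMeasurement(ind.individual_id, s, v)
              for s, v in ind.measurements.items()]
        res = asg.assign(ms, assign_isoscapes, q=q, subsets="all")
        for key, pct in res.pct_area_removed.items():
            subset_sums[key] = subset_sums.get(key, 0.0) + pct
        joint_key = "+".join(sorted(ind.measurements))
        if res.regions[joint_key].included[ind.true_cell]:
            covered += 1
    mean_pct = {k: v / len(individuals) for k, v in subset_sums.items()}

    return ExperimentReport(
        cv_r2=cv.r2, cv_rmse=cv.rmse,
        selected_variables=list(selected),
        selection_recall=recall, selection_false_positives=false_pos,
        coverage_at_q=covered / len(individuals),
        mean_pct_area_removed=mean_pct,
        isoscape_rmse_vs_truth=iso_rmse)
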