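"""Continuous-surface probabilistic geographic assignment.

Given an isoscape (per-cell predicted mean and SD) and a tissue measurement
x*, every grid cell c is scored with the standard-normal density of
z = (x* - mu_c) / sigma_c and the densities are normalized over the valid
cells into a probability-of-origin surface. Under independence between
isotopic systems, surfaces from several systems multiply cell-wise (then
renormalize). High-probability origin regions are the smallest sets of
cells, by descending probability, whose cumulative mass reaches a quantile
q (default 1/3), and assignment precision is summarized as the percentage
of the study area excluded from that region.

Densities are handled in log space with max-subtraction so that extreme
mismatches (|z| well beyond 30) survive numerically.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .grids import GridSpec, Isoscape

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


@dataclass(frozen=True)
class TissueMeasurement:
    """One measured isotope value for one individual.

    ``system`` must match the isoscape it is assigned against; oxygen
    measurements are drinking-water-equivalent values (post conversion
    chain). ``measurement_sd`` is folded into the isoscape SD in
    quadrature.
    """

    individual_id: str
    system: str
    x_star: float
    measurement_sd: float = 0.0


@dataclass
class ProbabilitySurface:
    """Normalized per-cell probability of origin over the valid mask."""

    spec: GridSpec
    probs: np.ndarray
    mask: np.ndarray  # True on valid cells

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, float)
        self.mask = np.asarray(self.mask, bool)
        if self.probs.shape != self.spec.shape or self.mask.shape != self.spec.shape:
            raise ValueError("probs/mask shape mismatch with grid spec")
        if (self.probs[~self.mask] != 0).any():
            raise ValueError("probabilities must be 0 on invalid cells")
        total = self.probs[self.mask].sum()
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"probabilities sum to {total}, not 1")

    def mode_cell(self) -> tuple[int, int]:
        masked = np.where(self.mask, self.probs, -np.inf)
        return tuple(np.unravel_index(int(np.argmax(masked)), self.probs.shape))


@dataclass
class BinaryRegion:
    """Thresholded high-probability origin region."""

    spec: GridSpec
    included: np.ndarray
    threshold_q: float
    mass_captured: float


@dataclass
class AssignmentResult:
    individual_id: str
    surfaces: dict[str, ProbabilitySurface] = field(default_factory=dict)
    regions: dict[str, BinaryRegion] = field(default_factory=dict)
    pct_area_removed: dict[str, float] = field(default_factory=dict)
    modes: dict[str, tuple[int, int]] = field(default_factory=dict)

    @property
    def joint(self) -> ProbabilitySurface | None:
        keys = [k for k in self.surfaces if "+" in k]
        if not keys:
            return None
        return self.surfaces[max(keys, key=lambda k: k.count("+"))]


def z_surface(m: TissueMeasurement, iso: Isoscape) -> np.ndarray:
    """Per-cell standardized deviation z = (x* - mu_c) / sigma_c.

    ``measurement_sd`` inflates sigma in quadrature. NaN on nodata cells.
    """
    if m.system != iso.system:
        raise ValueError(
            f"measurement system {m.system!r} does not match isoscape "
            f"{iso.system!r}")
    sd = iso.sd_values()
    if m.measurement_sd:
        sd = np.sqrt(sd ** 2 + m.measurement_sd ** 2)
    z = np.where(iso.mean.valid_mask,
                 (m.x_star - iso.mean.values) / sd, np.nan)
    return z


def likelihood_surface(z: np.ndarray) -> np.ndarray:
    """Standard-normal density of each z value: exp(-z^2/2)/sqrt(2*pi)."""
    return np.exp(log_likelihood_surface(z))


def log_likelihood_surface(z: np.ndarray) -> np.ndarray:
    return -0.5 * np.asarray(z, float) ** 2 - _LOG_SQRT_2PI


def normalize(likelihood: np.ndarray, mask: np.ndarray,
              spec: GridSpec) -> ProbabilitySurface:
    """Turn a (linear-space) density grid into a probability surface."""
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("no valid cells to normalize over")
    dens = np.where(mask, np.asarray(likelihood, float), 0.0)
    total = dens.sum()
    if total <= 0 or not np.isfinite(total):
        raise ValueError(
            "density underflowed to zero everywhere; use the log-space path "
            "(normalize_log) for extreme standardized deviations")
    return ProbabilitySurface(spec, dens / total, mask)


def normalize_log(log_likelihood: np.ndarray, mask: np.ndarray,
                  spec: GridSpec) -> ProbabilitySurface:
    """Normalize from log densities via max-subtraction (underflow-safe)."""
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("no valid cells to normalize over")
    ll = np.asarray(log_likelihood, float)
    peak = ll[mask].max()
    dens = np.where(mask, np.exp(ll - peak), 0.0)
    return ProbabilitySurface(spec, dens / dens.sum(), mask)


def single_system_surface(m: TissueMeasurement, iso: Isoscape) -> ProbabilitySurface:
    """z -> log density -> normalized probability, for one system."""
    z = z_surface(m, iso)
    ll = np.where(iso.mean.valid_mask, log_likelihood_surface(z), -np.inf)
    return normalize_log(ll, iso.mean.valid_mask, iso.spec)


def combine(surfaces: list[ProbabilitySurface]) -> ProbabilitySurface:
    """Cell-wise product of probability surfaces, renormalized.

    Masks intersect; assumes independence between the isotopic systems.
    Computed in log space.
    """
    if len(surfaces) < 2:
        raise ValueError("need at least two surfaces to combine")
    spec = surfaces[0].spec
    for s in surfaces[1:]:
        if s.spec != spec:
            raise ValueError("surfaces are on different grid specs")
    mask = np.logical_and.reduce([s.mask for s in surfaces])
    if not mask.any():
        raise ValueError("intersected valid mask is empty")
    with np.errstate(divide="ignore"):
        log_prod = sum(np.log(s.probs) for s in surfaces)
    return normalize_log(np.where(mask, log_prod, -np.inf), mask, spec)


def top_mass_region(P: ProbabilitySurface, q: float = 1.0 / 3.0,
                    mode: str = "mass") -> BinaryRegion:
    """Highest-probability region at quantile q.

    With ``mode="mass"`` (the probability-quantile convention of
    continuous-surface assignment): cells are ranked by probability
    descending and the shortest prefix whose cumulative mass reaches q is
    included. With ``mode="area_fraction"``: the top q fraction of valid
    cells by probability value. In both modes, cells tied with the
    probability at the cut are all included, making the region independent
    of cell ordering.
    """
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    flat = P.probs[P.mask]
    order = np.argsort(-flat, kind="stable")
    sorted_p = flat[order]
    if mode == "mass":
        cum = np.cumsum(sorted_p)
        k = int(np.searchsorted(cum, q - 1e-12) + 1)
    elif mode == "area_fraction":
        k = max(1, int(np.ceil(q * sorted_p.size)))
    else:
        raise ValueError(f"unknown threshold mode {mode!r}")
    k = min(k, sorted_p.size)
    cut_value = sorted_p[k - 1]
    include_flat = flat >= cut_value
    included = np.zeros(P.probs.shape, bool)
    included[P.mask] = include_flat
    return BinaryRegion(P.spec, included, q,
                        float(flat[include_flat].sum()))


def pct_area_removed(region: BinaryRegion, total_valid_cells: int) -> float:
    """Percent of the (equal-area) study area excluded from the region."""
    return 100.0 * (1.0 - int(region.included.sum()) / total_valid_cells)


def assign(measurements: list[TissueMeasurement],
           isoscapes: dict[str, Isoscape],
           q: float = 1.0 / 3.0,
           subsets: str = "all",
           threshold_mode: str = "mass") -> AssignmentResult:
    """Full assignment of one individual.

    Builds the single-system surfaces, combines every requested subset
    (``"all"``: all singles, duals, ..., up to the full combination;
    ``"joint"``: singles plus the full combination only), and computes the
    q-threshold region and % area removed for each. Deterministic.
    """
    if not measurements:
        raise ValueError("no measurements supplied")
    ids = {m.individual_id for m in measurements}
    if len(ids) != 1:
        raise ValueError(f"measurements span multiple individuals: {ids}")
    singles: dict[str, ProbabilitySurface] = {}
    for m in measurements:
        if m.system not in isoscapes:
            raise ValueError(f"no isoscape provided for system {m.system!r}")
        singles[m.system] = single_system_surface(m, isoscapes[m.system])

    systems = sorted(singles)
    result = AssignmentResult(individual_id=next(iter(ids)))
    combos: list[tuple[str, ...]] = [(s,) for s in systems]
    if subsets == "all":
        for r in range(2, len(systems) + 1):
            combos += list(itertools.combinations(systems, r))
    elif subsets == "joint":
        if len(systems) > 1:
            combos.append(tuple(systems))
    else:
        raise ValueError(f"unknown subsets mode {subsets!r}")

    for combo in combos:
        key = "+".join(combo)
        surf = (singles[combo[0]] if len(combo) == 1
                else combine([singles[s] for s in combo]))
        region = top_mass_region(surf, q, mode=threshold_mode)
        result.surfaces[key] = surf
        result.regions[key] = region
        result.pct_area_removed[key] = pct_area_removed(
            region, int(surf.mask.sum()))
        result.modes[key] = surf.mode_cell()
    return result
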