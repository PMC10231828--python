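"""Continuous geographic assignment on otolith-oxygen isoscapes.

Given a fish's measured otolith δ¹⁸O value ``y`` and the isoscape of its
contingent and year-class, the probability that it originated at grid cell
``i`` follows from Bayes' rule with a spatially uniform prior inside the
shelf-constrained domain. The likelihood at each cell is a normal density
with mean μ_i (the isoscape prediction) and a combined standard deviation
pooling analytical error with within-population variability:

    σ_combined = sqrt(σ_analytical² + σ_within_pop²)

Defaults are 0.1 ‰ (repeated carbonate-standard measurements) and 0.29 ‰
(spread of otolith δ¹⁸O among age-0 fish at one site), giving
σ_combined ≈ 0.307 ‰. Posteriors are normalized to sum to one over
defined cells, plus a max-scaled copy for cross-individual comparison.
Likelihoods are computed in log space with max-subtraction so a fish far
outside the isoscape range still yields a proper posterior.

Surfaces are summarized by a rank-based binary transformation: at quantile
q the top ceil((1−q)·m) cells of the posterior (ties broken by ascending
lat, lon index) are marked "likely". Year-class summary maps average the
binary surfaces, giving the fraction of fish assigned to each cell. A
validation protocol checks known-origin fish (a fish is correct when its
likely set intersects its collection subregion) and sweeps q over
[0.05, 0.95] to expose the accuracy–precision trade-off.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from .isoscape import Isoscape, IsoscapeError

SIGMA_ANALYTICAL_DEFAULT = 0.1   # ‰, IRMS carbonate-standard repeatability
SIGMA_WITHIN_POP_DEFAULT = 0.29  # ‰, same-site age-0 otolith spread
BINARY_QUANTILE_DEFAULT = 0.75


class AssignmentError(ValueError):
    """Raised on invalid assignment inputs."""


@dataclass
class VarianceModel:
    """Independent-normal error components of observed otolith δ¹⁸O."""

    sigma_analytical: float = SIGMA_ANALYTICAL_DEFAULT
    sigma_within_pop: float = SIGMA_WITHIN_POP_DEFAULT

    def __post_init__(self):
        if self.sigma_analytical < 0 or self.sigma_within_pop < 0:
            raise AssignmentError("sigma components must be >= 0")

    @property
    def sigma_combined(self) -> float:
        return combined_sigma(self)


def combined_sigma(vm: VarianceModel) -> float:
    """Quadrature combination sqrt(σ_a² + σ_w²) of independent errors."""
    return math.hypot(vm.sigma_analytical, vm.sigma_within_pop)


@dataclass
class ProbabilitySurface:
    """Per-fish posterior probability-of-origin grid and its scaled copy."""

    fish_id: object
    posterior: xr.DataArray   # sums to 1 over defined cells; NaN outside
    scaled: xr.DataArray      # posterior / max(posterior)
    observed: float           # measured otolith δ¹⁸O, ‰ VPDB
    isoscape: Isoscape


@dataclass
class BinarySurface:
    """Likely/unlikely origin cells at one binarization quantile."""

    fish_id: object
    likely: xr.DataArray      # boolean grid, subset of defined cells
    threshold_quantile: float


@dataclass
class SummaryMap:
    """Fraction of a year-class's fish assigned "likely" per cell."""

    year_class: int
    contingent: str
    values: xr.DataArray      # in [0, 1]; NaN outside domain
    n_fish: int


@dataclass
class ValidationCurve:
    """Assignment accuracy across binarization quantiles."""

    thresholds: np.ndarray
    accuracy: np.ndarray
    chosen: float | None
    floor: float = 0.7

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"threshold": self.thresholds,
                             "accuracy": self.accuracy})


def posterior_surface(y: float, iso: Isoscape, vm: VarianceModel,
                      prior: xr.DataArray | None = None,
                      fish_id: object = None) -> ProbabilitySurface:
    """Posterior probability of origin at every defined isoscape cell.

    Normal likelihood of the observation at each cell mean, times the
    prior (uniform inside the domain by default), normalized over defined
    cells. Computed in log space; cells outside the domain mask (or with
    zero prior) never enter.
    """
    if not np.isfinite(y):
        raise AssignmentError("observed d18o must be finite")
    sigma = combined_sigma(vm)
    if sigma <= 0:
        raise AssignmentError("combined sigma must be > 0")
    mask = iso.domain_mask.values.astype(bool)
    if prior is not None:
        pv = prior.values.astype(float)
        if np.any(pv[mask] < 0):
            raise AssignmentError("prior must be nonnegative")
        mask = mask & (pv > 0)
    if not mask.any():
        raise IsoscapeError("no defined cells with positive prior")
    mu = iso.values.values
    loglik = np.full(mu.shape, -np.inf)
    loglik[mask] = -0.5 * ((y - mu[mask]) / sigma) ** 2
    if prior is not None:
        loglik[mask] += np.log(prior.values[mask])
    loglik[mask] -= loglik[mask].max()           # underflow guard
    dens = np.zeros_like(loglik)
    dens[mask] = np.exp(loglik[mask])
    post = np.full(mu.shape, np.nan)
    post[mask] = dens[mask] / dens[mask].sum()
    scaled = np.full(mu.shape, np.nan)
    scaled[mask] = post[mask] / post[mask].max()
    coords = iso.values.coords
    return ProbabilitySurface(
        fish_id=fish_id,
        posterior=xr.DataArray(post, coords=coords, name="posterior"),
        scaled=xr.DataArray(scaled, coords=coords, name="scaled"),
        observed=float(y),
        isoscape=iso,
    )


def _ranked_cells(posterior: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Defined cells ordered by posterior desc, ties by (lat, lon) asc."""
    mask = np.isfinite(posterior)
    ii, jj = np.nonzero(mask)
    vals = posterior[mask]
    order = np.lexsort((jj, ii, -vals))
    return ii[order], jj[order]


def binarize(ps: ProbabilitySurface,
             q: float = BINARY_QUANTILE_DEFAULT) -> BinarySurface:
    """Mark the top ceil((1−q)·m) posterior cells "likely".

    Rank-based over defined cells only, with a deterministic tie-break by
    ascending (lat index, lon index) so the likely count is exact and the
    likely sets are nested across q.
    """
    if not (0.0 < q < 1.0):
        raise AssignmentError("quantile must lie in (0, 1)")
    post = ps.posterior.values
    m = int(np.isfinite(post).sum())
    if m < 4:
        raise AssignmentError("need at least 4 defined cells to binarize")
    n_likely = math.ceil((1.0 - q) * m)
    ii, jj = _ranked_cells(post)
    likely = np.zeros(post.shape, dtype=bool)
    likely[ii[:n_likely], jj[:n_likely]] = True
    return BinarySurface(
        fish_id=ps.fish_id,
        likely=xr.DataArray(likely, coords=ps.posterior.coords, name="likely"),
        threshold_quantile=q,
    )


def summarize(binaries: list[BinarySurface], year_class: int,
              contingent: str = "") -> SummaryMap:
    """Average binary surfaces of one year-class into a nursery heat map.

    Cell value = fraction of fish whose likely set contains the cell,
    which equals the summed binary maps scaled by sample size.
    """
    if not binaries:
        raise AssignmentError("no binary surfaces to summarize")
    ref = binaries[0].likely
    total = np.zeros(ref.shape, dtype=float)
    for b in binaries:
        if b.likely.shape != ref.shape:
            raise AssignmentError("binary surfaces are on different grids")
        total += b.likely.values
    vals = total / len(binaries)
    return SummaryMap(
        year_class=year_class,
        contingent=contingent,
        values=xr.DataArray(vals, coords=ref.coords, name="fraction_assigned"),
        n_fish=len(binaries),
    )


def validate(fish: pd.DataFrame, isoscapes: dict[int, Isoscape],
             vm: VarianceModel, subregion_masks: dict[str, xr.DataArray],
             q: float = BINARY_QUANTILE_DEFAULT) -> float:
    """Known-origin validation accuracy at one binarization quantile.

    ``fish`` needs columns fish_id, d18o, year_class, subregion. A fish is
    correctly assigned when its likely set intersects its collection
    subregion mask. Accuracy is the fraction correct.
    """
    if len(fish) == 0:
        raise AssignmentError("no validation fish")
    correct = 0
    for row in fish.itertuples():
        iso = isoscapes[int(row.year_class)]
        sub = subregion_masks[row.subregion]
        dom = iso.domain_mask.values.astype(bool)
        if not (sub.values.astype(bool) & dom).any():
            raise AssignmentError(
                f"subregion {row.subregion!r} is disjoint from the "
                f"isoscape domain (year {iso.year})"
            )
        ps = posterior_surface(row.d18o, iso, vm, fish_id=row.fish_id)
        bs = binarize(ps, q)
        if (bs.likely.values & sub.values.astype(bool)).any():
            correct += 1
    return correct / len(fish)


def threshold_sweep(fish: pd.DataFrame, isoscapes: dict[int, Isoscape],
                    vm: VarianceModel,
                    subregion_masks: dict[str, xr.DataArray],
                    q_grid: np.ndarray | None = None,
                    floor: float = 0.7) -> ValidationCurve:
    """Accuracy across binarization quantiles (the accuracy–precision sweep).

    The chosen threshold is the largest (most precise) quantile whose
    accuracy still meets the floor; None, with a warning from the caller,
    when no quantile qualifies.
    """
    if q_grid is None:
        q_grid = np.linspace(0.05, 0.95, 19)
    q_grid = np.asarray(q_grid, dtype=float)
    if q_grid.size < 2 or np.any(np.diff(q_grid) <= 0):
        raise AssignmentError("q_grid must be >= 2 strictly increasing values")
    acc = np.array([
        validate(fish, isoscapes, vm, subregion_masks, q=q) for q in q_grid
    ])
    meets = acc >= floor
    chosen = float(q_grid[meets][-1]) if meets.any() else None
    return ValidationCurve(thresholds=q_grid, accuracy=acc, chosen=chosen,
                           floor=floor)


def assign_fish(adults: pd.DataFrame, isoscapes: dict[tuple[str, int], Isoscape],
                vm: VarianceModel, q: float = BINARY_QUANTILE_DEFAULT,
                ) -> tuple[list[ProbabilitySurface], list[BinarySurface],
                           list[SummaryMap]]:
    """End-to-end continuous assignment of contingent-classified adults.

    ``adults`` needs columns fish_id, d18o, year_class, decision; fish
    whose decision is "unassigned" are skipped. Isoscapes are keyed by
    (contingent, year_class). Returns per-fish posterior and binary
    surfaces plus per-(contingent, year-class) summary maps.
    """
    surfaces: list[ProbabilitySurface] = []
    binaries: list[BinarySurface] = []
    groups: dict[tuple[str, int], list[BinarySurface]] = {}
    for row in adults.itertuples():
        if row.decision not in ("northern", "southern"):
            continue
        key = (row.decision, int(row.year_class))
        if key not in isoscapes:
            raise AssignmentError(f"no isoscape for contingent/year {key}")
        ps = posterior_surface(row.d18o, isoscapes[key], vm,
                               fish_id=row.fish_id)
        bs = binarize(ps, q)
        surfaces.append(ps)
        binaries.append(bs)
        groups.setdefault(key, []).append(bs)
    summaries = [
        summarize(blist, year_class=yc, contingent=cont)
        for (cont, yc), blist in sorted(groups.items())
    ]
    return surfaces, binaries, summaries
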