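"""Forecasting species abundance distributions to larger sample sizes.

The forecast combines the two preceding modules: power-law fits of the raw
moments, richness and maximum abundance against sample size (``scaling``)
and density reconstruction from moments with scaled discrete Tchebichef
polynomials (``tchebichef``).  The full procedure for one ordering is:

1. tabulate raw moments ``M_1..M_m`` of the pooled log2 abundances at every
   accumulation step, together with ``S(t)`` and ``N_max(t)``;
2. fit a power law to each series over the scaling region;
3. choose the reconstruction order ``k*`` as the number of moments whose
   Tchebichef reconstruction best matches (least squares) the empirical
   histogram at the largest observed size;
4. extrapolate ``M_1..M_k*``, ``S`` and ``N_max`` to the target size;
5. the forecast support is ``NB* = floor(log2 N_max*) + 1`` octave classes;
   convert the extrapolated moments (with ``M_0 = 1``) to Tchebichef
   moments on that support, reconstruct the density, clip negatives, and
   scale by the forecast richness ``S*``.

Extrapolated high-order moments can be mutually inconsistent, producing
explosive Tchebichef moments or reconstructions with substantial negative
mass; in that case the order is lowered until the reconstruction is tame,
and the event is recorded as a warning.  Running the procedure once per
start transect gives an ensemble of forecasts whose per-class mean and
standard deviation (+/-2 SD error bars) quantify the ordering uncertainty.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .accumulation import (
    TransectTable,
    accumulate_sads,
    order_concentric,
    order_sequential,
)
from .sad import BinnedSAD, bin_abundances
from .scaling import (
    MomentScalingFits,
    MomentSeries,
    extrapolate,
    fit_moment_scaling,
    moment_series,
    power_mean_violation,
)
from .tchebichef import (
    build_basis,
    clipped_mass,
    reconstruct,
    select_order,
    tcheb_moments_from_raw,
)

__all__ = [
    "ForecastResult",
    "SADForecaster",
    "forecast_sad",
    "forecast_across_orderings",
    "half_data_validation",
]

logger = logging.getLogger(__name__)

_ORDER_FNS = {"concentric": order_concentric, "sequential": order_sequential}


@dataclass
class ForecastResult:
    """A forecasted SAD: expected species count per octave class.

    ``class_counts`` sums to ``predicted_richness`` (the reconstruction is a
    density scaled by the forecast richness).  For ensemble forecasts
    (across transect orderings) ``class_sd`` holds the per-class standard
    deviation and ``moment_orders_used`` the order chosen per ordering.
    """

    target_factor: float
    target_size: float
    predicted_richness: float
    predicted_max_abundance: float
    predicted_num_classes: int
    class_counts: np.ndarray
    moment_order_used: int
    clipped_fraction: float = 0.0
    class_sd: np.ndarray | None = None
    moment_orders_used: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    def to_text(self, path, delimiter: str = ",") -> None:
        """Write per-class mean (and SD when available) as delimited text."""
        idx = np.arange(self.predicted_num_classes)
        sd = (
            self.class_sd
            if self.class_sd is not None
            else np.zeros(self.predicted_num_classes)
        )
        np.savetxt(
            path,
            np.column_stack([idx, self.class_counts, sd]),
            fmt=["%d", "%.10g", "%.10g"],
            delimiter=delimiter,
            header=f"class_index{delimiter}mean_species{delimiter}sd_species",
            comments="",
        )


class SADForecaster(BaseEstimator):
    """Fit moment scaling laws and forecast the SAD at a larger sample size.

    Parameters
    ----------
    n_moments
        Number of raw-moment orders fitted (1..n_moments).
    k_max
        Largest reconstruction order offered to the order selection; by
        default ``min(6, NB - 1)`` where NB is the observed number of
        octave classes (published applications used orders 3-5).
    fit_range
        Scaling region ``(lo, hi)`` in sample-size units; default is all
        sizes >= 2.
    max_tcheb_magnitude
        Any converted Tchebichef moment exceeding this magnitude flags a
        numerical instability (for a true density ``|T_n| <= 1``) and
        triggers a fallback to a lower order.
    max_clipped_fraction
        Maximum tolerated negative mass in the reconstruction before the
        order is lowered.

    Attributes
    ----------
    fits_ : MomentScalingFits
        Power-law fits for every moment order, richness and N_max.
    k_star_ : int
        Selected reconstruction order.
    """

    def __init__(
        self,
        n_moments: int = 10,
        k_max: int | None = None,
        fit_range=None,
        max_tcheb_magnitude: float = 2.0,
        max_clipped_fraction: float = 0.5,
    ):
        self.n_moments = n_moments
        self.k_max = k_max
        self.fit_range = fit_range
        self.max_tcheb_magnitude = max_tcheb_magnitude
        self.max_clipped_fraction = max_clipped_fraction

    def fit(self, series: MomentSeries, empirical: BinnedSAD):
        """Fit scaling laws and select the reconstruction order.

        Parameters
        ----------
        series
            Moment series over accumulated sample sizes.
        empirical
            Octave histogram of the pooled sample at the largest size in
            ``series`` (used only to select the reconstruction order).
        """
        self.fits_ = fit_moment_scaling(series, self.fit_range)
        self.t_max_ = float(np.max(series.sizes))
        nb_obs = empirical.num_classes
        if nb_obs < 2:
            raise ValueError("empirical histogram must span at least 2 classes")
        k_cap = self.k_max if self.k_max is not None else min(6, nb_obs - 1)
        k_cap = min(k_cap, nb_obs - 1, self.n_moments)
        basis = build_basis(nb_obs, k_cap)
        raw_at_max = np.concatenate(
            [
                [1.0],
                [
                    self.fits_.moments[n].predict(self.t_max_)[()]
                    for n in range(1, k_cap + 1)
                ],
            ]
        )
        self.k_star_ = select_order(empirical, raw_at_max, basis, k_cap)
        self.n_classes_obs_ = nb_obs
        self.empirical_ = empirical
        return self

    def predict(self, factor: float = 2.0) -> ForecastResult:
        """Forecast the SAD at ``factor`` times the largest observed size."""
        if not hasattr(self, "fits_"):
            raise RuntimeError("SADForecaster is not fitted")
        if factor < 1:
            raise ValueError("forecast factor must be >= 1")
        target = factor * self.t_max_
        warn_msgs: list = []
        s_star = extrapolate(self.fits_.richness, target)
        nmax_star = extrapolate(self.fits_.max_abundance, target)
        nb_star = int(np.floor(np.log2(nmax_star))) + 1
        if nb_star < self.n_classes_obs_:
            raise ValueError(
                f"forecast support ({nb_star} classes) smaller than the "
                f"observed histogram ({self.n_classes_obs_} classes)"
            )
        k = self.k_star_
        raw_full = np.concatenate(
            [
                [1.0],
                [
                    extrapolate(self.fits_.moments[n], target)
                    for n in range(1, k + 1)
                ],
            ]
        )
        pm_violation = power_mean_violation(raw_full)
        if pm_violation > 1e-9:
            msg = (
                f"extrapolated moments violate the power-mean ordering by "
                f"{pm_violation:.3g}; they are not the moments of any "
                "distribution and the reconstruction may be unstable"
            )
            logger.warning(msg)
            warn_msgs.append(msg)
        while True:
            basis = build_basis(nb_star, k)
            T = tcheb_moments_from_raw(raw_full[: k + 1], basis)
            clip = clipped_mass(T, basis)
            unstable = (
                np.max(np.abs(T)) > self.max_tcheb_magnitude
                or clip > self.max_clipped_fraction
            )
            if not unstable or k == 1:
                break
            msg = (
                f"numerical instability at order {k} "
                f"(max |T_n| = {np.max(np.abs(T)):.3g}, clipped mass = "
                f"{clip:.3g}); falling back to order {k - 1}"
            )
            logger.warning(msg)
            warn_msgs.append(msg)
            k -= 1
        p_hat = reconstruct(T, basis)
        return ForecastResult(
            target_factor=float(factor),
            target_size=float(target),
            predicted_richness=float(s_star),
            predicted_max_abundance=float(nmax_star),
            predicted_num_classes=nb_star,
            class_counts=s_star * p_hat,
            moment_order_used=int(k),
            clipped_fraction=float(clip),
            warnings=warn_msgs,
        )


def forecast_sad(
    series: MomentSeries,
    factor: float,
    empirical: BinnedSAD,
    **forecaster_kwargs,
) -> ForecastResult:
    """One-shot forecast for a single ordering (functional wrapper)."""
    return SADForecaster(**forecaster_kwargs).fit(series, empirical).predict(factor)


def _pad(arr: np.ndarray, n: int) -> np.ndarray:
    out = np.zeros(n)
    out[: arr.size] = arr
    return out


def forecast_across_orderings(
    table: TransectTable,
    group: str,
    factor: float,
    method: str = "concentric",
    n_moments: int = 10,
    k_max: int | None = None,
    fit_range=None,
) -> ForecastResult:
    """Ensemble forecast over all transect orderings of one dispersal group.

    The procedure is run once per start transect (T orderings for T
    transects); per-class mean and standard deviation across the ensemble
    are returned, the latter feeding +/-2 SD error bars.
    """
    try:
        order_fn = _ORDER_FNS[method]
    except KeyError:
        raise ValueError(f"unknown ordering method {method!r}") from None
    empirical = bin_abundances(table.pooled_abundances(group))
    results = []
    for start in table.transect_ids:
        ordering = order_fn(table, start)
        traj = accumulate_sads(table, ordering, groups=(group,))
        series = moment_series(traj.vectors[group], n_max=n_moments)
        res = forecast_sad(
            series,
            factor,
            empirical,
            n_moments=n_moments,
            k_max=k_max,
            fit_range=fit_range,
        )
        results.append(res)
    nb = max(r.predicted_num_classes for r in results)
    stacked = np.vstack([_pad(r.class_counts, nb) for r in results])
    mean = stacked.mean(axis=0)
    sd = stacked.std(axis=0, ddof=1) if len(results) > 1 else np.zeros(nb)
    return ForecastResult(
        target_factor=float(factor),
        target_size=float(np.mean([r.target_size for r in results])),
        predicted_richness=float(np.mean([r.predicted_richness for r in results])),
        predicted_max_abundance=float(
            np.mean([r.predicted_max_abundance for r in results])
        ),
        predicted_num_classes=nb,
        class_counts=mean,
        class_sd=sd,
        moment_order_used=int(np.median([r.moment_order_used for r in results])),
        clipped_fraction=float(np.mean([r.clipped_fraction for r in results])),
        moment_orders_used=[r.moment_order_used for r in results],
        warnings=[w for r in results for w in r.warnings],
    )


def half_data_validation(
    table: TransectTable,
    group: str,
    method: str = "concentric",
    n_moments: int = 10,
    k_max: int | None = None,
    min_size: int = 2,
) -> dict:
    """Fit on the first half of each ordering, forecast the full sample.

    For every start transect the scaling laws are estimated from the first
    ``T // 2`` accumulation steps only and the SAD forecast at the full
    T transects; the ensemble mean and SD per class are then compared with
    the empirical histogram of all T transects pooled.  Returns a dict with
    the ensemble forecast, the empirical histogram, and ``coverage`` — the
    fraction of classes whose empirical count lies inside the forecast's
    +/-2 SD band.
    """
    order_fn = _ORDER_FNS[method]
    t_total = table.n_transects
    half = t_total // 2
    if half < 3:
        raise ValueError("need at least 6 transects for the half-data protocol")
    factor = t_total / half
    results = []
    for start in table.transect_ids:
        ordering = order_fn(table, start)
        traj = accumulate_sads(table, ordering, groups=(group,))
        vecs = traj.vectors[group][:half]
        series = moment_series(vecs, n_max=n_moments)
        empirical_half = bin_abundances(vecs[-1])
        res = forecast_sad(
            series,
            factor,
            empirical_half,
            n_moments=n_moments,
            k_max=k_max,
            fit_range=(min_size, half),
        )
        results.append(res)
    nb = max(r.predicted_num_classes for r in results)
    stacked = np.vstack([_pad(r.class_counts, nb) for r in results])
    mean = stacked.mean(axis=0)
    sd = stacked.std(axis=0, ddof=1) if len(results) > 1 else np.zeros(nb)
    empirical_full = bin_abundances(table.pooled_abundances(group))
    nb_all = max(nb, empirical_full.num_classes)
    emp = _pad(empirical_full.class_counts, nb_all)
    mean_p, sd_p = _pad(mean, nb_all), _pad(sd, nb_all)
    inside = np.abs(emp - mean_p) <= 2 * sd_p
    return {
        "forecast_mean": mean,
        "forecast_sd": sd,
        "empirical": empirical_full.class_counts,
        "coverage": float(inside.mean()),
        "orders_used": [r.moment_order_used for r in results],
        "factor": factor,
    }
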