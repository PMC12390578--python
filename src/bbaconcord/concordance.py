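"""Bioassay/field concordance: RMSE to field mortality and a bootstrap CI
on the RMSE difference between two bioassay arms.

The concordance statistic asks how well a bottle-bioassay time-mortality
curve predicts the mean 12 h sentinel-cage mortality m_f: over the schedule
times t_1..t_T,

    RMSE = sqrt( (1/T) * sum_t (curve(t_i) - m_f)^2 )

in percentage points. To compare a technical-grade arm (a) against a
formulated-product arm (b), a non-parametric cluster bootstrap resamples the
independent experimental units — replicate bottles within each arm and
sentinel cages — with replacement, recomputes both mean curves, the field
mean, and the RMSE difference (a - b) each iteration, and reports the mean
resampled difference with a 95% interval. A difference is called significant
when the interval excludes zero. The field mean is recomputed from the
resampled cages each iteration rather than held fixed, because it is itself
an estimate.

Resampling time points instead of replicates is available (``resample_unit=
"time_points"``) as a sensitivity analysis, as is excluding the 0-min
observation from the RMSE grid and a BCa interval in place of the percentile
interval.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .errors import ValidationError
from .mortality import MortalityCurve, mean_curve, pct_matrix
from .types import BottleAssay, FieldCageRecord


@dataclass(frozen=True)
class ConcordanceResult:
    """Paired RMSEs, bootstrap difference CI, and closest-match times."""

    strain: str
    field_mean_pct: float
    label_a: str
    label_b: str
    rmse_a: float
    rmse_b: float
    diff_label: str
    boot_mean_diff: float
    ci_low: float
    ci_high: float
    significant: bool
    closest_time_a: int
    closest_time_b: int
    closest_mortality_a: float
    closest_mortality_b: float
    n_boot: int
    seed: int
    ci_method: str = "percentile"
    resample_unit: str = "replicates"
    boot_diffs: tuple[float, ...] | None = field(default=None, repr=False, compare=False)

    def to_dict(self) -> dict:
        return {
            "strain": self.strain,
            "field_mean_pct": self.field_mean_pct,
            "arm_a": self.label_a,
            "arm_b": self.label_b,
            "rmse_a": self.rmse_a,
            "rmse_b": self.rmse_b,
            "diff_label": self.diff_label,
            "boot_mean_diff": self.boot_mean_diff,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "significant": self.significant,
            "closest_time_a_min": self.closest_time_a,
            "closest_time_b_min": self.closest_time_b,
            "closest_mortality_a_pct": self.closest_mortality_a,
            "closest_mortality_b_pct": self.closest_mortality_b,
            "n_boot": self.n_boot,
            "seed": self.seed,
            "ci_method": self.ci_method,
            "resample_unit": self.resample_unit,
        }


def rmse_vs_field(curve: MortalityCurve, field_mean_pct: float, include_t0: bool = True) -> float:
    """Root mean squared deviation of a mortality curve from the field mean."""
    if not 0 <= field_mean_pct <= 100:
        raise ValidationError(f"field mortality {field_mean_pct} outside [0, 100]")
    values = np.asarray(curve.mean_pct, dtype=float)
    if not include_t0:
        values = values[np.asarray(curve.times) != 0]
    if values.size == 0:
        raise ValidationError("empty curve: RMSE undefined")
    return float(np.sqrt(np.mean((values - field_mean_pct) ** 2)))


def closest_time(curve: MortalityCurve, field_mean_pct: float) -> tuple[int, float]:
    """Schedule time whose curve value best matches the field mean.

    Ties are broken toward the earliest time. Returns (time, curve value).
    """
    if not 0 <= field_mean_pct <= 100:
        raise ValidationError(f"field mortality {field_mean_pct} outside [0, 100]")
    deviations = np.abs(np.asarray(curve.mean_pct) - field_mean_pct)
    i = int(np.argmin(deviations))  # argmin returns the first minimum: earliest time
    return curve.times[i], curve.mean_pct[i]


def _rmse_rows(curves: np.ndarray, field_means: np.ndarray) -> np.ndarray:
    """Row-wise RMSE of (n, T) curves against length-n field means."""
    return np.sqrt(np.mean((curves - field_means[:, None]) ** 2, axis=1))


def bootstrap_rmse_diff(
    bottles_a: list[BottleAssay],
    bottles_b: list[BottleAssay],
    cages: list[FieldCageRecord],
    n_boot: int = 1000,
    seed: int = 0,
    ci_method: str = "percentile",
    resample_unit: str = "replicates",
    include_t0: bool = True,
    keep_diffs: bool = False,
) -> ConcordanceResult:
    """Bootstrap the RMSE difference (arm a - arm b) against field mortality.

    Arms are replicate bottle collections for the same strain under two
    treatments (conventionally a = technical, b = formulated); ``cages`` are
    the treated sentinel cages whose 12 h mortality defines field performance.
    Deterministic given ``seed``.
    """
    if ci_method not in ("percentile", "bca"):
        raise ValidationError(f"unknown ci_method {ci_method!r}")
    if resample_unit not in ("replicates", "time_points"):
        raise ValidationError(f"unknown resample_unit {resample_unit!r}")
    cages = [c for c in cages if not c.is_control]
    if not cages:
        raise ValidationError("no treated cages supplied")
    curve_a, curve_b = mean_curve(bottles_a), mean_curve(bottles_b)
    if curve_a.strain != curve_b.strain:
        raise ValidationError(
            f"arms compare different strains: {curve_a.strain} vs {curve_b.strain}"
        )
    if curve_a.times != curve_b.times:
        raise ValidationError("arms must share one observation schedule")
    for name, units in (("arm a", bottles_a), ("arm b", bottles_b), ("cages", cages)):
        if len(units) < 2:
            warnings.warn(
                f"{name} has a single replicate: the bootstrap collapses to a point "
                "and its interval is meaningless",
                stacklevel=2,
            )

    mat_a, mat_b = pct_matrix(bottles_a), pct_matrix(bottles_b)
    cage_pct = np.array([c.mortality_12h_pct for c in cages])
    times = np.asarray(curve_a.times)
    t_mask = np.ones(times.size, bool) if include_t0 else times != 0

    field_mean = float(cage_pct.mean())
    rmse_a = rmse_vs_field(curve_a, field_mean, include_t0)
    rmse_b = rmse_vs_field(curve_b, field_mean, include_t0)

    rng = np.random.default_rng(seed)
    if resample_unit == "replicates":
        diffs = _replicate_boot(mat_a, mat_b, cage_pct, t_mask, n_boot, rng)
    else:
        diffs = _timepoint_boot(
            mat_a.mean(axis=0)[t_mask], mat_b.mean(axis=0)[t_mask], field_mean, n_boot, rng
        )

    lo, hi = _interval(
        diffs, rmse_a - rmse_b, ci_method, mat_a, mat_b, cage_pct, t_mask
    )
    ta, ma = closest_time(curve_a, field_mean)
    tb, mb = closest_time(curve_b, field_mean)
    return ConcordanceResult(
        strain=curve_a.strain,
        field_mean_pct=field_mean,
        label_a=curve_a.treatment.name,
        label_b=curve_b.treatment.name,
        rmse_a=rmse_a,
        rmse_b=rmse_b,
        diff_label=f"{curve_a.treatment.name}-{curve_b.treatment.name}",
        boot_mean_diff=float(diffs.mean()),
        ci_low=lo,
        ci_high=hi,
        significant=not (lo <= 0.0 <= hi),
        closest_time_a=ta,
        closest_time_b=tb,
        closest_mortality_a=ma,
        closest_mortality_b=mb,
        n_boot=n_boot,
        seed=seed,
        ci_method=ci_method,
        resample_unit=resample_unit,
        boot_diffs=tuple(float(d) for d in diffs) if keep_diffs else None,
    )


def _replicate_boot(
    mat_a: np.ndarray,
    mat_b: np.ndarray,
    cage_pct: np.ndarray,
    t_mask: np.ndarray,
    n_boot: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Cluster bootstrap over bottles (within arm) and cages, jointly."""
    na, nb, nc = mat_a.shape[0], mat_b.shape[0], cage_pct.size
    idx_a = rng.integers(0, na, size=(n_boot, na))
    idx_b = rng.integers(0, nb, size=(n_boot, nb))
    idx_c = rng.integers(0, nc, size=(n_boot, nc))
    curves_a = mat_a[idx_a].mean(axis=1)[:, t_mask]
    curves_b = mat_b[idx_b].mean(axis=1)[:, t_mask]
    field = cage_pct[idx_c].mean(axis=1)
    return _rmse_rows(curves_a, field) - _rmse_rows(curves_b, field)


def _timepoint_boot(
    curve_a: np.ndarray,
    curve_b: np.ndarray,
    field_mean: float,
    n_boot: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Bootstrap over schedule time points (same draw applied to both arms)."""
    nt = curve_a.size
    idx_t = rng.integers(0, nt, size=(n_boot, nt))
    sq_a = (curve_a - field_mean) ** 2
    sq_b = (curve_b - field_mean) ** 2
    return np.sqrt(sq_a[idx_t].mean(axis=1)) - np.sqrt(sq_b[idx_t].mean(axis=1))


def _plugin_diff(
    mat_a: np.ndarray, mat_b: np.ndarray, cage_pct: np.ndarray, t_mask: np.ndarray
) -> float:
    field = cage_pct.mean()
    ra = math.sqrt(float(np.mean((mat_a.mean(axis=0)[t_mask] - field) ** 2)))
    rb = math.sqrt(float(np.mean((mat_b.mean(axis=0)[t_mask] - field) ** 2)))
    return ra - rb


def _interval(
    diffs: np.ndarray,
    plugin: float,
    ci_method: str,
    mat_a: np.ndarray,
    mat_b: np.ndarray,
    cage_pct: np.ndarray,
    t_mask: np.ndarray,
    alpha: float = 0.05,
) -> tuple[float, float]:
    if ci_method == "percentile" or np.allclose(diffs, diffs[0]):
        lo, hi = np.percentile(diffs, [100 * alpha / 2, 100 * (1 - alpha / 2)])
        return float(lo), float(hi)

    # BCa: bias correction from the bootstrap distribution, acceleration from a
    # grouped jackknife deleting one experimental unit (bottle or cage) at a time.
    z0 = norm.ppf((np.sum(diffs < plugin) + 0.5 * np.sum(diffs == plugin)) / diffs.size)
    jack = []
    for i in range(mat_a.shape[0]):
        jack.append(_plugin_diff(np.delete(mat_a, i, axis=0), mat_b, cage_pct, t_mask))
    for i in range(mat_b.shape[0]):
        jack.append(_plugin_diff(mat_a, np.delete(mat_b, i, axis=0), cage_pct, t_mask))
    for i in range(cage_pct.size):
        jack.append(_plugin_diff(mat_a, mat_b, np.delete(cage_pct, i), t_mask))
    jack = np.asarray(jack)
    d = jack.mean() - jack
    denom = 6.0 * (d**2).sum() ** 1.5
    a = (d**3).sum() / denom if denom > 0 else 0.0
    z_lo, z_hi = norm.ppf(alpha / 2), norm.ppf(1 - alpha / 2)
    p_lo = norm.cdf(z0 + (z0 + z_lo) / (1 - a * (z0 + z_lo)))
    p_hi = norm.cdf(z0 + (z0 + z_hi) / (1 - a * (z0 + z_hi)))
    lo, hi = np.percentile(diffs, [100 * p_lo, 100 * p_hi])
    return float(lo), float(hi)
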