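"""Error profiles, calibrated error bars and power tables.

An *error profile* summarizes, per diversity measure, the worst-case
proportional estimation error as a function of coverage (sample cells
per overall clone), built from an ensemble of gold-standard fits.  The
band is symmetric: the same fraction above and below the truth.

Error bars for an estimate invert the profile: the upper bar is the
largest true diversity whose lower band still reaches the estimate; the
lower bar is the smallest true diversity whose upper band reaches it.
Because coverage itself depends on the candidate true diversity, the
inversion is solved self-consistently.  Monte-Carlo 70-30
cross-validation calibrates the bars to a target bracketing rate
(default 95%) by inflating the upper bar.

Power tables give the minimum number of sampled cells needed for the
calibrated intervals around two diversities differing by a given fold to
separate, subject to a floor below which too few non-singleton clones
are expected for the reconstruction to run.
"""
from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import as_rng

__all__ = [
    "ErrorProfile",
    "PowerTable",
    "CalibrationResult",
    "build_error_profile",
    "error_bars",
    "calibrate_profile",
    "power_table",
    "ensemble_from_sweep",
]

# ensemble rows with |proportional error| above this are excluded as outliers
_OUTLIER_ERROR = 10.0
# log-floor used so zero-error bins interpolate cleanly
_ERR_FLOOR = 1e-12


@dataclass
class ErrorProfile:
    """Worst-case proportional error versus coverage for one Hill measure."""

    measure: float
    coverages: np.ndarray
    errors: np.ndarray
    upper_adjustment: float = 0.0
    provenance: str = ""

    def __post_init__(self):
        self.coverages = np.asarray(self.coverages, dtype=float)
        self.errors = np.asarray(self.errors, dtype=float)
        if self.coverages.size == 0:
            raise ValueError("empty error profile")
        if np.any(self.coverages <= 0) or np.any(self.errors < 0):
            raise ValueError("coverages must be > 0 and errors >= 0")
        order = np.argsort(self.coverages)
        self.coverages = self.coverages[order]
        self.errors = self.errors[order]

    def band(self, coverage):
        """Interpolated worst-case proportional error at ``coverage``.

        Linear in (log coverage, log error); flat beyond the grid.
        Returns (error, extrapolated flag); vectorized over coverage.
        """
        cov = np.asarray(coverage, dtype=float)
        loge = np.interp(
            np.log(np.maximum(cov, 1e-300)),
            np.log(self.coverages),
            np.log(np.maximum(self.errors, _ERR_FLOOR)),
        )
        err = np.exp(loge)
        err = np.where(err <= _ERR_FLOOR * 1.01, 0.0, err)
        extrapolated = (cov < self.coverages[0]) | (cov > self.coverages[-1])
        if np.isscalar(coverage):
            return float(err), bool(extrapolated)
        return err, extrapolated

    def to_dict(self) -> dict:
        return {
            "measure": "inf" if math.isinf(self.measure) else self.measure,
            "coverages": self.coverages.tolist(),
            "errors": self.errors.tolist(),
            "upper_adjustment": self.upper_adjustment,
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ErrorProfile":
        measure = d["measure"]
        measure = math.inf if measure == "inf" else float(measure)
        return cls(
            measure=measure,
            coverages=np.asarray(d["coverages"]),
            errors=np.asarray(d["errors"]),
            upper_adjustment=float(d.get("upper_adjustment", 0.0)),
            provenance=d.get("provenance", ""),
        )

    def save(self, path):
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "ErrorProfile":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def ensemble_from_sweep(sweep: pd.DataFrame, measure: float = 0.0) -> np.ndarray:
    """Extract (true, coverage, estimate) triplets for one measure from a sweep table."""
    key = "inf" if math.isinf(measure) else f"{measure:g}"
    df = sweep[sweep["error"] == ""] if "error" in sweep else sweep
    cols = [f"true_q{key}", "coverage", f"est_q{key}"]
    return df[cols].to_numpy(dtype=float)


def build_error_profile(
    ensemble_results, measure: float = 0.0, provenance: str = ""
) -> ErrorProfile:
    """Build a symmetric worst-case error profile from calibration results.

    ``ensemble_results``: iterable of (true_diversity, coverage,
    estimate).  At each coverage bin the band is the maximum absolute
    proportional error; gross outliers (|error| > 10x) are excluded with
    a warning.  Bands are regularized to be non-increasing in coverage.
    """
    arr = np.asarray(list(map(tuple, ensemble_results)), dtype=float)
    if arr.size == 0:
        raise ValueError("empty ensemble")
    true, cov, est = arr[:, 0], arr[:, 1], arr[:, 2]
    prop_err = np.abs(est - true) / true
    keep = prop_err <= _OUTLIER_ERROR
    if not keep.all():
        warnings.warn(
            f"excluded {int((~keep).sum())} outlier fits (|error| > {_OUTLIER_ERROR}x)",
            stacklevel=2,
        )
        cov, prop_err = cov[keep], prop_err[keep]
    if cov.size == 0:
        raise ValueError("all ensemble results were outliers")
    # bin by coverage value (grid values; rounded to 6 significant digits)
    binned: dict[float, float] = {}
    for c, e in zip(cov, prop_err):
        key = float(f"{c:.6g}")
        binned[key] = max(binned.get(key, 0.0), float(e))
    if len(binned) < 2:
        raise ValueError("need results at >= 2 coverage levels")
    cs = np.array(sorted(binned))
    es = np.array([binned[c] for c in cs])
    # worst-case error may not increase with coverage: running max from the top
    es = np.maximum.accumulate(es[::-1])[::-1]
    return ErrorProfile(measure=measure, coverages=cs, errors=es, provenance=provenance)


def _bar_grid(estimate: float) -> np.ndarray:
    g = estimate * np.geomspace(1e-2, 1e2, 3001)
    return np.unique(np.append(g, estimate))


def _raw_bars(estimate: float, sample_cells: float, profile: ErrorProfile):
    """Raw (lower, upper) true-diversity bounds consistent with the estimate.

    Solved on a log grid of candidate true diversities d, looking the
    band up at the coverage sample_cells/d implied by each candidate.
    """
    d = _bar_grid(estimate)
    band, extrap = profile.band(sample_cells / d)
    lower_ok = d * (1.0 + band) >= estimate  # candidate's upper band reaches estimate
    upper_ok = d * (1.0 - band) <= estimate  # candidate's lower band reaches estimate
    d_minus = float(d[lower_ok][0]) if lower_ok.any() else float(d[0])
    d_plus = float(d[upper_ok][-1]) if upper_ok.any() else float(d[-1])
    flagged = bool(extrap[np.argmin(np.abs(d - estimate))])
    at_edge = (upper_ok.any() and d_plus == d[-1]) or (lower_ok.any() and d_minus == d[0])
    return d_minus, d_plus, flagged or bool(at_edge)


def error_bars(
    estimate: float,
    coverage: float,
    profile: ErrorProfile,
    return_flags: bool = False,
):
    """Calibrated (lower, upper) error bars for a diversity estimate.

    ``coverage`` is the sample-based coverage ``S / estimate``; the
    implied cell count ``S`` is held fixed while candidate true
    diversities (and hence their coverages) vary during inversion.  The
    upper bar is inflated by the profile's calibration adjustment.
    """
    if estimate <= 0 or coverage <= 0:
        raise ValueError("estimate and coverage must be positive")
    sample_cells = estimate * coverage
    d_minus, d_plus, flagged = _raw_bars(estimate, sample_cells, profile)
    upper = d_plus * (1.0 + profile.upper_adjustment)
    if flagged:
        warnings.warn("error bars extrapolated beyond the profile's coverage range",
                      stacklevel=2)
    if return_flags:
        return d_minus, upper, flagged
    return d_minus, upper


@dataclass
class CalibrationResult:
    raw_rate: float
    raw_rate_sd: float
    adjusted_rate: float
    adjusted_rate_sd: float
    upper_adjustment: float
    target: float
    reached_target: bool


def calibrate_profile(
    samples,
    n_splits: int = 100,
    train_fraction: float = 0.7,
    target: float = 0.95,
    measure: float = 0.0,
    seed: int = 0,
    adjustment_step: float = 0.001,
    max_adjustment: float = 0.5,
) -> tuple[ErrorProfile, CalibrationResult]:
    """Calibrate error bars to a target bracketing rate by cross-validation.

    ``samples``: (true, coverage, estimate) triplets.  Each split builds
    a profile from a random ``train_fraction`` of the ensemble and
    checks, on the held-out rest, how often the bars bracket the truth.
    The smallest upper-bar inflation (searched in ``adjustment_step``
    increments) achieving the target mean rate is applied to a profile
    built from the full ensemble.
    """
    arr = np.asarray(list(map(tuple, samples)), dtype=float)
    if len(arr) < 20:
        raise ValueError("need an ensemble of >= 20 results to calibrate")
    rng = as_rng(seed)
    n = len(arr)
    n_train = max(2, int(round(train_fraction * n)))
    per_split_low_ok: list[np.ndarray] = []
    per_split_req_adj: list[np.ndarray] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(n_splits):
            idx = rng.permutation(n)
            train, val = arr[idx[:n_train]], arr[idx[n_train:]]
            try:
                prof = build_error_profile(train, measure=measure)
            except ValueError:
                continue
            low_ok = np.empty(len(val), dtype=bool)
            req = np.empty(len(val))
            for i, (true, cov, est) in enumerate(val):
                if est <= 0:
                    low_ok[i], req[i] = False, np.inf
                    continue
                s_cells = cov * true  # ensemble coverage is cells per true clone
                d_minus, d_plus, _ = _raw_bars(est, s_cells, prof)
                low_ok[i] = d_minus <= true
                req[i] = 0.0 if d_plus >= true else (
                    true / d_plus - 1.0 if d_plus > 0 else np.inf
                )
            per_split_low_ok.append(low_ok)
            per_split_req_adj.append(req)
    if not per_split_low_ok:
        raise ValueError("calibration failed on every split")

    def rates(adj: float) -> np.ndarray:
        return np.array(
            [
                float(np.mean(lo & (rq <= adj)))
                for lo, rq in zip(per_split_low_ok, per_split_req_adj)
            ]
        )

    raw = rates(0.0)
    adj = 0.0
    reached = raw.mean() >= target
    while not reached and adj < max_adjustment:
        adj = round(adj + adjustment_step, 10)
        reached = rates(adj).mean() >= target
    adjusted = rates(adj)
    if not reached:
        warnings.warn(
            f"target bracketing rate {target:.0%} unreachable; best "
            f"{adjusted.mean():.1%} at +{adj:.1%} upper adjustment",
            stacklevel=2,
        )
    profile = build_error_profile(
        arr, measure=measure, provenance=f"calibrated on {n} fits, {n_splits} splits"
    )
    profile.upper_adjustment = adj
    result = CalibrationResult(
        raw_rate=float(raw.mean()),
        raw_rate_sd=float(raw.std(ddof=1)) if len(raw) > 1 else 0.0,
        adjusted_rate=float(adjusted.mean()),
        adjusted_rate_sd=float(adjusted.std(ddof=1)) if len(adjusted) > 1 else 0.0,
        upper_adjustment=adj,
        target=target,
        reached_target=bool(reached),
    )
    return profile, result


@dataclass
class PowerTable:
    """Minimum cells to analyse, by fold-difference (rows) x richness (columns)."""

    table: pd.DataFrame
    alpha: float = 0.05
    floor_doublets: float = 10.0
    notes: str = field(default="cells in clones above the large-clone threshold excluded")

    def to_tsv(self, path):
        self.table.to_csv(path, sep="\t", index_label="fold_difference")


def _runnability_floor(diversity: float, floor_doublets: float) -> float:
    """Smallest sample with >= floor_doublets expected doubleton clones.

    Uses a uniform parent of the stated richness: expected doubletons are
    D * (lam^2 / 2) e^{-lam} with lam = S / D.
    """
    lam = np.geomspace(1e-6, 10.0, 4000)
    expected = diversity * 0.5 * lam**2 * np.exp(-lam)
    ok = expected >= floor_doublets
    if not ok.any():
        return math.inf
    return float(np.ceil(lam[ok][0] * diversity))


def power_table(
    diversities,
    fold_thresholds,
    profile: ErrorProfile,
    alpha: float = 0.05,
    floor_doublets: float = 10.0,
    max_cells: float = 1e9,
) -> PowerTable:
    """Minimum sample size to distinguish diversities differing by given folds.

    For richness ``D`` and fold ``f``, finds the smallest ``S`` such that
    the calibrated interval around an estimate of ``D`` (coverage S/D)
    does not overlap the interval around ``f*D`` (coverage S/(f*D)) --
    a conservative surrogate for a two-sample test at ``alpha`` -- and
    enforces the runnability floor of the reference richness ``D``.
    Unattainable cells are NaN.
    """
    diversities = [float(d) for d in diversities]
    folds = [float(f) for f in fold_thresholds]
    if any(d <= 0 for d in diversities) or any(f <= 1 for f in folds):
        raise ValueError("diversities must be > 0 and folds > 1")

    def separated(d: float, f: float, s: float) -> bool:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, upper_lo = error_bars(d, s / d, profile)
            lower_hi, _ = error_bars(f * d, s / (f * d), profile)
        return upper_lo < lower_hi

    cells: dict[float, dict[float, float]] = {}
    for d in diversities:
        floor = _runnability_floor(d, floor_doublets)
        col = {}
        for f in folds:
            lo, hi = max(floor, 1.0), max_cells
            if not separated(d, f, hi):
                col[f] = math.nan
                continue
            if separated(d, f, lo):
                col[f] = float(np.ceil(lo))
            else:
                while hi / lo > 1.0 + 1e-4:
                    mid = math.sqrt(lo * hi)
                    if separated(d, f, mid):
                        hi = mid
                    else:
                        lo = mid
                col[f] = float(np.ceil(max(hi, floor)))
        cells[d] = col
    df = pd.DataFrame(cells, index=folds)
    df.index.name = "fold_difference"
    return PowerTable(table=df, alpha=alpha, floor_doublets=floor_doublets)
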