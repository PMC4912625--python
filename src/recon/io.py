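"""Readers and writers for spectra and fit reports.

The canonical interchange format for clone-size spectra is a two-column
tab-separated table ``clone_size<TAB>clone_count`` with sizes ascending
(header optional).  A bare per-clone abundance list (one or more
whitespace-separated sizes per line, not two columns) is also accepted
and tallied into a spectrum.  Fit reports are JSON.
"""
from __future__ import annotations

import json
import math
from dataclasses import asdict

import numpy as np

from .core import AlgoConfig, FitReport, ParentMixture
from .distributions import CloneSizeDistribution
from .sampling import RepertoireScale

__all__ = ["read_spectrum", "write_spectrum", "write_report", "read_report"]

_VERSION = "0.1.0"


def _tokenize(path):
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            toks = line.split()
            if not toks or line.lstrip().startswith("#"):
                continue
            rows.append((lineno, toks))
    return rows


def read_spectrum(path) -> CloneSizeDistribution:
    """Read a clone-size spectrum, or tally a per-clone abundance list.

    Two numeric columns on every line are read as (clone_size,
    clone_count); anything else is read as a flat list of per-clone
    sizes.  A single non-numeric header line is tolerated.
    """
    rows = _tokenize(path)
    if rows:
        try:
            [float(t) for t in rows[0][1]]
        except ValueError:
            rows = rows[1:]  # header
    if not rows:
        raise ValueError(f"{path}: no observed clones")

    def parse(lineno, tok):
        try:
            v = float(tok)
        except ValueError:
            raise ValueError(f"{path}:{lineno}: non-numeric entry {tok!r}") from None
        if v < 0:
            raise ValueError(f"{path}:{lineno}: negative entry {tok!r}")
        return v

    if all(len(toks) == 2 for _, toks in rows):
        spectrum: dict[int, float] = {}
        for lineno, toks in rows:
            size, count = (parse(lineno, t) for t in toks)
            if size != int(size):
                raise ValueError(f"{path}:{lineno}: clone size must be an integer")
            if int(size) in spectrum:
                raise ValueError(f"{path}:{lineno}: duplicate clone size {int(size)}")
            spectrum[int(size)] = count
        dist = CloneSizeDistribution(spectrum)
    else:
        sizes = []
        for lineno, toks in rows:
            for t in toks:
                v = parse(lineno, t)
                if v != int(v):
                    raise ValueError(f"{path}:{lineno}: clone size must be an integer")
                sizes.append(int(v))
        dist = CloneSizeDistribution.from_clone_sizes(sizes)
    if dist.n_clones <= 0:
        raise ValueError(f"{path}: no observed clones")
    return dist


def write_spectrum(dist: CloneSizeDistribution, path, header: bool = True):
    """Write a spectrum as TSV; a size-0 row records predicted missing clones."""
    with open(path, "w") as fh:
        if header:
            fh.write("clone_size\tclone_count\n")
        for size, count in sorted(dist.as_dict().items()):
            c = int(count) if float(count).is_integer() else count
            fh.write(f"{size}\t{c}\n")


def _qkey(q) -> str:
    return "inf" if math.isinf(q) else f"{q:g}"


def _divmap(d: dict) -> dict:
    return {_qkey(q): v for q, v in d.items()}


def _parse_qkey(k: str) -> float:
    return math.inf if k == "inf" else float(k)


def write_report(report: FitReport, path, error_bars: dict | None = None):
    """Serialize a fit report to JSON (lossless round trip via read_report).

    ``error_bars`` optionally maps Hill order to (lower, upper) bounds on
    the overall diversity, as produced by the uncertainty module.
    """
    mix = report.mixture
    scale = mix.scale
    payload = {
        "version": _VERSION,
        "seed": report.seed,
        "config": asdict(report.config),
        "scale": None if scale is None else {"N": scale.N, "S": scale.S},
        "mixture": {
            "weights": mix.weights.tolist(),
            "means": mix.means.tolist(),
            "D_total": mix.D_total,
            "missing": mix.missing,
            "n_observed_small": mix.n_observed_small,
            "large_clone_sizes": mix.large_clone_sizes.tolist(),
            "loglik": mix.loglik,
            "adjusted_loglik": mix.adjusted_loglik,
            "converged": mix.converged,
        },
        "diversity_overall": _divmap(report.diversity_overall),
        "diversity_sample": _divmap(report.diversity_sample),
        "diversity_error_bars": None if error_bars is None else _divmap(error_bars),
        "missing": report.missing,
        "min_detected_clone_size": report.min_detected_clone_size,
        "upper_bound_U": report.upper_bound_U,
        "upper_bound_U_plus_richness": report.upper_bound_U_plus_richness,
        "log_likelihood": report.log_likelihood,
        "aicc": report.aicc,
        "trajectory": report.trajectory,
        "resampled_spectrum": {str(k): v for k, v in report.resampled_spectrum.as_dict().items()},
        "flags": report.flags,
    }
    if report.min_detected_clone_size is None and scale is not None and not scale.N:
        payload["warning"] = "overall cell count N unknown: min detected clone size and U omitted"

    def _clean(o):
        if isinstance(o, float) and math.isnan(o):
            return None
        if isinstance(o, dict):
            return {k: _clean(v) for k, v in o.items()}
        if isinstance(o, list):
            return [_clean(v) for v in o]
        return o

    with open(path, "w") as fh:
        json.dump(_clean(payload), fh, indent=1)


def read_report(path) -> FitReport:
    """Load a fit report written by :func:`write_report`."""
    with open(path) as fh:
        d = json.load(fh)
    scale = None
    if d.get("scale") is not None:
        scale = RepertoireScale(N=d["scale"]["N"], S=d["scale"]["S"])
    m = d["mixture"]
    mix = ParentMixture(
        weights=np.asarray(m["weights"]),
        means=np.asarray(m["means"]),
        D_total=m["D_total"],
        missing=m["missing"],
        n_observed_small=m["n_observed_small"],
        large_clone_sizes=np.asarray(m["large_clone_sizes"], dtype=np.int64),
        scale=scale,
        loglik=m["loglik"] if m["loglik"] is not None else math.nan,
        adjusted_loglik=m["adjusted_loglik"] if m["adjusted_loglik"] is not None else math.nan,
        converged=m["converged"],
    )
    cfg = AlgoConfig(**d["config"])
    return FitReport(
        mixture=mix,
        diversity_overall={_parse_qkey(k): v for k, v in d["diversity_overall"].items()},
        diversity_sample={_parse_qkey(k): v for k, v in d["diversity_sample"].items()},
        missing=d["missing"],
        min_detected_clone_size=d["min_detected_clone_size"],
        upper_bound_U=d["upper_bound_U"],
        upper_bound_U_plus_richness=d["upper_bound_U_plus_richness"],
        log_likelihood=d["log_likelihood"] if d["log_likelihood"] is not None else math.nan,
        aicc=d["aicc"] if d["aicc"] is not None else math.nan,
        trajectory=d["trajectory"],
        resampled_spectrum=CloneSizeDistribution(
            {int(k): v for k, v in d["resampled_spectrum"].items()}
        ),
        config=cfg,
        seed=d["seed"],
        flags=d.get("flags", []),
    )
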