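"""Spike-in calibration: from observed mutant families back to molecule numbers.

The spike-in experiment measures, at each known input amount of mutant
template molecules, the number of unique mutant UMI families the caller
recovers.  The resulting monotone curve (piecewise linear in log-log space,
isotonically adjusted) is inverted to back-calculate an expected molecule
number from an observed deduplicated mutant count.  The UMI capacity bound
``4**umi_length`` and the birthday-collision correction
``U * (1 - (1 - 1/U)**n)`` describe the theoretical saturation ceiling; the
observed plateau sits well below it because wild-type molecules, which the
analysis ignores, consume most templates and depth.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression

from .types import LocusCallReport, TruthRecord


def umi_capacity(umi_length: int) -> int:
    """Number of distinct UMIs, ``4**umi_length`` (the molecule-count ceiling)."""
    if umi_length < 0:
        raise ValueError("umi_length must be >= 0")
    return 4**umi_length


def expected_distinct(n_molecules: float, capacity: int) -> float:
    """Expected distinct UMIs among ``n_molecules`` uniform draws.

    Closed form ``U * (1 - (1 - 1/U)**n)``; approaches ``capacity`` as n
    grows, equals 1 at n = 1.
    """
    if n_molecules < 0:
        raise ValueError("n_molecules must be >= 0")
    if capacity < 1:
        raise ValueError("capacity must be >= 1")
    return capacity * (1.0 - (1.0 - 1.0 / capacity) ** n_molecules)


@dataclass
class SpikeInCurve:
    """Monotone log-log mapping between input molecules and mutant families.

    ``x`` holds log10 input molecules at each usable spike level, ``y`` the
    isotonically-adjusted per-level mean of log10 observed mutant families.
    ``saturation_level`` is the observed plateau in family units.
    """

    x: np.ndarray
    y: np.ndarray
    saturation_level: float
    replicate_sd: dict[float, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if len(self.x) != len(self.y) or len(self.x) < 2:
            raise ValueError("curve needs >= 2 support points")
        if not np.all(np.diff(self.x) > 0):
            raise ValueError("support must be strictly increasing in x")
        if np.any(np.diff(self.y) < -1e-12):
            raise ValueError("fitted curve must be non-decreasing")

    def __call__(self, molecules) -> np.ndarray | float:
        """Predicted mutant families at the given input molecule number(s)."""
        m = np.asarray(molecules, dtype=float)
        out = 10.0 ** np.interp(np.log10(np.maximum(m, 1e-12)), self.x, self.y)
        out = np.where(m <= 0, 0.0, out)
        return float(out) if np.isscalar(molecules) else out

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "log10_molecules": self.x.tolist(),
                    "log10_families": self.y.tolist(),
                    "saturation_level": self.saturation_level,
                    "replicate_sd": {str(k): v for k, v in self.replicate_sd.items()},
                },
                indent=2,
            )
            + "\n"
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "SpikeInCurve":
        d = json.loads(Path(path).read_text())
        return cls(
            np.array(d["log10_molecules"]),
            np.array(d["log10_families"]),
            d["saturation_level"],
            {float(k): v for k, v in d.get("replicate_sd", {}).items()},
        )


def fit_spikein_curve(observations: pd.DataFrame | Sequence[tuple[float, float]]) -> SpikeInCurve:
    """Fit the spike-in curve from (input molecules, observed mutant families).

    ``observations`` is a DataFrame with columns ``molecules`` and
    ``mutant_families`` (one row per replicate library, pooled across loci)
    or an equivalent sequence of pairs.  Per level, the support value is the
    mean of log10(observed) over replicates with at least one family; levels
    where every replicate observed zero families are excluded with a
    warning.  Fewer than three usable levels is an error.  Monotonicity is
    enforced by isotonic regression.
    """
    if not isinstance(observations, pd.DataFrame):
        observations = pd.DataFrame(observations, columns=["molecules", "mutant_families"])
    df = observations[["molecules", "mutant_families"]].astype(float)
    if (df["molecules"] <= 0).any():
        raise ValueError("spike levels must be positive molecule counts")

    xs, ys, sds = [], [], {}
    for level, grp in df.groupby("molecules"):
        usable = grp.loc[grp["mutant_families"] >= 1, "mutant_families"]
        if usable.empty:
            warnings.warn(
                f"spike level {level:g}: zero observed families in all replicates; excluded",
                stacklevel=2,
            )
            continue
        logs = np.log10(usable.to_numpy())
        xs.append(np.log10(level))
        ys.append(float(logs.mean()))
        sds[float(np.log10(level))] = float(logs.std(ddof=0))
    if len(xs) < 3:
        raise ValueError(f"need >= 3 usable spike levels, got {len(xs)}")

    x = np.array(xs)
    y = np.array(ys)
    order = np.argsort(x)
    x, y = x[order], y[order]
    iso = IsotonicRegression(increasing=True)
    y_fit = iso.fit_transform(x, y)
    return SpikeInCurve(x, y_fit, saturation_level=float(10.0 ** y_fit[-1]), replicate_sd=sds)


def curve_from_benchmark(
    reports_by_library: dict[str, dict[str, LocusCallReport]],
    truth: Optional[Sequence[TruthRecord]] = None,
    library_levels: Optional[dict[str, float]] = None,
) -> SpikeInCurve:
    """Fit a pooled spike-in curve from per-library caller reports.

    ``reports_by_library`` maps library id to its per-locus reports; the
    input amount per library comes from ``library_levels`` or is summed from
    truth records.  Mutant families are pooled (summed) across loci within
    each library; negative-control libraries (zero input) are skipped.
    """
    if library_levels is None:
        if truth is None:
            raise ValueError("need truth records or library_levels")
        library_levels = {}
        for t in truth:
            library_levels[t.library_id] = (
                library_levels.get(t.library_id, 0) + t.true_template_molecules
            )
    rows = []
    for lib_id, rep in reports_by_library.items():
        level = library_levels.get(lib_id, 0)
        if level <= 0:
            continue
        rows.append((level, sum(r.mutant_families for r in rep.values())))
    return fit_spikein_curve(rows)


def interpolate_molecules(
    observed_families: float, curve: SpikeInCurve
) -> tuple[float, bool]:
    """Back-calculate an expected molecule number from observed mutant families.

    Piecewise-linear inversion of the monotone curve in log-log space.
    Returns ``(estimate, at_or_above_saturation)``.  Zero observed families
    estimate zero molecules; observations at or above the plateau are
    clamped to the largest calibrated input and flagged; observations below
    the lowest support extrapolate proportionally toward (0, 0).
    """
    if observed_families < 0:
        raise ValueError("observed_families must be >= 0")
    if observed_families == 0:
        return 0.0, False
    obs_log = float(np.log10(observed_families))
    x, y = curve.x, curve.y
    if obs_log >= y[-1]:
        return float(10.0 ** x[-1]), True
    if obs_log <= y[0]:
        # proportional (slope-1 in log space) extrapolation toward the origin
        return float(10.0 ** (x[0] - (y[0] - obs_log))), False
    # drop flat stretches so the inverse interpolation is well defined
    keep = np.concatenate(([True], np.diff(y) > 1e-12))
    y_inv, x_inv = y[keep], x[keep]
    return float(10.0 ** np.interp(obs_log, y_inv, x_inv)), False


def quantify_reports(
    reports: dict[str, LocusCallReport], curve: SpikeInCurve
) -> dict[str, LocusCallReport]:
    """Annotate call reports in place with interpolated molecule estimates."""
    for rep in reports.values():
        est, sat = interpolate_molecules(rep.mutant_families, curve)
        rep.interpolated_molecules = est
        rep.at_or_above_saturation = sat
    return reports
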