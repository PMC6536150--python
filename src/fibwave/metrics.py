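"""Cycle-length metrics, two-way ANOVA and the experiment matrix.

Cycle length (CL) — the interval between successive local activations
during an arrhythmia — is computed from voltage traces at a 4x4 lattice of
16 recording sites (10% margin), the convention used in optical-mapping
and simulation work. Activations are upward threshold crossings (-40 mV, rising
edge) with a 30 ms refractory lockout; the windowed mean averages all
inter-activation intervals pooled across sites.

The whole-heart experiment matrix crosses cell model {P1..P4} x fibers
{A, I} x fine structure {wS, nS} into 16 labelled configurations
("P2_I_nS" = model P2, isotropic, no structure); two-way ANOVA on windowed
CL samples tests the structure and fiber factors.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .solver import FieldMovie

__all__ = ["CycleLengthSeries", "activation_times", "site_lattice",
           "mean_cycle_length", "anova_two_way", "experiment_matrix"]


@dataclass
class CycleLengthSeries:
    """Per-site activation times and pooled cycle lengths for one run."""

    sites: list  # (i, j) voxel indices
    site_positions: np.ndarray  # (n, 2) cm
    activation_times: list  # per site, ms
    intervals: np.ndarray  # pooled inter-activation intervals in window, ms
    window: tuple
    label: str = ""

    @property
    def mean(self) -> float:
        return float(np.mean(self.intervals)) if self.intervals.size else float("nan")

    @property
    def variance(self) -> float:
        return float(np.var(self.intervals, ddof=1)) if self.intervals.size > 1 else float("nan")

    def per_site_means(self) -> np.ndarray:
        """Windowed mean CL per site (NaN for sites with < 2 activations)."""
        out = []
        t0, t1 = self.window
        for at in self.activation_times:
            at = np.asarray(at)
            at = at[(at >= t0) & (at <= t1)]
            out.append(np.diff(at).mean() if at.size >= 2 else np.nan)
        return np.asarray(out)


def activation_times(trace: np.ndarray, times: np.ndarray,
                     threshold: float = -40.0, lockout: float = 30.0,
                     direction: str = "up") -> np.ndarray:
    """Threshold-crossing activation times with refractory lockout.

    Crossing times are linearly interpolated between samples; ``lockout``
    suppresses double counting on fragmented upstrokes. ``direction`` is
    'up' (default) or 'down'.
    """
    v = np.asarray(trace, dtype=float)
    if direction == "down":
        v = -v
        threshold = -threshold
    above = v >= threshold
    idx = np.nonzero(~above[:-1] & above[1:])[0]
    out = []
    last = -np.inf
    for i in idx:
        frac = (threshold - v[i]) / (v[i + 1] - v[i])
        t = times[i] + frac * (times[i + 1] - times[i])
        if t - last >= lockout:
            out.append(t)
            last = t
    return np.asarray(out)


def site_lattice(shape: tuple, n_per_side: int = 4, margin: float = 0.1):
    """Uniform n x n lattice of recording sites with a fractional margin."""
    nx, ny = shape
    mi, mj = int(margin * nx), int(margin * ny)
    return [(mi + i * (nx - 1 - 2 * mi) // (n_per_side - 1),
             mj + j * (ny - 1 - 2 * mj) // (n_per_side - 1))
            for i, j in product(range(n_per_side), repeat=2)]


def mean_cycle_length(movie: FieldMovie, window: tuple,
                      sites: Optional[list] = None, threshold: float = -40.0,
                      lockout: float = 30.0, label: str = "",
                      min_activations: int = 2) -> CycleLengthSeries:
    """Windowed mean cycle length from a 16-site lattice on a 2-D movie.

    Sites with fewer than ``min_activations`` crossings inside the window
    are excluded (logged via the returned object's NaN per-site means).
    """
    if movie.frames.ndim != 3:
        raise ValueError("mean_cycle_length expects a 2-D movie")
    if sites is None:
        sites = site_lattice(movie.frames.shape[1:])
    acts, pooled = [], []
    t0, t1 = window
    for (i, j) in sites:
        at = activation_times(movie.frames[:, i, j], movie.times,
                              threshold=threshold, lockout=lockout)
        acts.append(at)
        atw = at[(at >= t0) & (at <= t1)]
        if atw.size >= min_activations:
            pooled.extend(np.diff(atw))
    return CycleLengthSeries(
        sites=sites,
        site_positions=np.asarray(sites, dtype=float) * movie.spacing,
        activation_times=acts,
        intervals=np.asarray(pooled, dtype=float),
        window=window, label=label)


def anova_two_way(samples: pd.DataFrame, value: str = "cl",
                  factor_a: str = "structure", factor_b: str = "fibers",
                  alpha: float = 0.05) -> pd.DataFrame:
    """Fixed-effects two-way ANOVA with interaction.

    ``samples`` has one row per CL sample with categorical factor columns
    (e.g. structure in {wS, nS}, fibers in {A, I}). Returns a DataFrame
    indexed by effect with columns F, p, significant. Raises on empty cells.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    df = samples.rename(columns={value: "_y", factor_a: "_a", factor_b: "_b"})
    counts = df.groupby(["_a", "_b"], observed=True).size()
    n_a, n_b = df["_a"].nunique(), df["_b"].nunique()
    if len(counts) < n_a * n_b or (counts < 2).any():
        raise ValueError("two-way ANOVA needs >= 2 samples in every cell")
    if df["_y"].var(ddof=1) == 0:
        # degenerate all-identical data: F = 0 by convention
        idx = [factor_a, factor_b, f"{factor_a}:{factor_b}"]
        return pd.DataFrame({"F": 0.0, "p": 1.0, "significant": False}, index=idx)
    model = ols("_y ~ C(_a) * C(_b)", data=df).fit()
    tab = sm.stats.anova_lm(model, typ=2)
    rename = {"C(_a)": factor_a, "C(_b)": factor_b,
              "C(_a):C(_b)": f"{factor_a}:{factor_b}"}
    out = tab.loc[list(rename), ["F", "PR(>F)"]].rename(
        index=rename, columns={"PR(>F)": "p"})
    out["significant"] = out["p"] < alpha
    return out


def experiment_matrix(models: Sequence[str] = ("P1", "P2", "P3", "P4"),
                      fibers: Sequence[str] = ("A", "I"),
                      structure: Sequence[str] = ("wS", "nS")) -> pd.DataFrame:
    """The full factorial of whole-heart run configurations with canonical
    labels ``P{n}_{A|I}_{wS|nS}``. 2-D sheet runs are a separate track and
    are deliberately not part of this matrix."""
    rows = [{"label": f"{m}_{f}_{s}", "model": m, "fibers": f, "structure": s}
            for m, f, s in product(models, fibers, structure)]
    df = pd.DataFrame(rows).set_index("label")
    if df.index.duplicated().any():  # pragma: no cover - defensive
        raise ValueError("duplicate experiment labels")
    return df


def parse_label(label: str) -> dict:
    """Inverse of the matrix labels: 'P2_I_nS' -> factors."""
    m, f, s = label.split("_")
    if f not in {"A", "I"} or s not in {"wS", "nS"}:
        raise ValueError(f"malformed experiment label {label!r}")
    return {"model": m, "fibers": f, "structure": s}
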