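"""Dose-response surface analysis: 4PL rays, isoboles and Loewe CI.

A factorial growth-inhibition grid (two drugs, doses including zero) is
analyzed the classical way: four-parameter logistic (4PL) curves are fitted
along each ray (one drug varying at each fixed dose of the other, and vice
versa), the fitted curves are inverted at the requested effect level (30%
or 50% inhibition) to obtain iso-effective dose pairs, and each pair (a, b)
is scored with the Loewe Combination Index

    CI = a / ICx_A + b / ICx_B

where ICx_A, ICx_B are the single-agent iso-effective doses.  CI < 1
indicates synergy, CI around 1 additivity, CI > 1 antagonism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import lmfit
import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "DoseResponseGrid",
    "RayFit",
    "IsoboleResult",
    "fit_ray",
    "combination_index",
    "analyze_grid",
    "hill_inhibition",
    "loewe_additive_surface",
    "bootstrap_ci",
]


def hill_inhibition(dose, ec50: float, hill: float = 1.0, top: float = 1.0):
    """Hill (2PL) growth-inhibition curve through 0 with ceiling ``top``."""
    dose = np.asarray(dose, dtype=float)
    with np.errstate(divide="ignore"):
        ratio = np.where(dose > 0, (ec50 / dose) ** hill, np.inf)
    return top / (1.0 + ratio)


def four_pl(dose, bottom, top, ec50, hill):
    dose = np.asarray(dose, dtype=float)
    with np.errstate(divide="ignore"):
        ratio = np.where(dose > 0, (ec50 / dose) ** hill, np.inf)
    return bottom + (top - bottom) / (1.0 + ratio)


@dataclass
class DoseResponseGrid:
    """Rectangular factorial inhibition grid with replicate structure."""

    doses_A: np.ndarray
    doses_B: np.ndarray
    inhibition: np.ndarray  # (nA, nB) replicate means
    sd: np.ndarray  # (nA, nB)
    n_replicates: int

    @classmethod
    def from_tidy(cls, df: pd.DataFrame) -> "DoseResponseGrid":
        doses_A = np.sort(df["dose_A"].unique())
        doses_B = np.sort(df["dose_B"].unique())
        g = df.groupby(["dose_A", "dose_B"])["inhibition"]
        mean = g.mean().unstack()
        sd = g.std().fillna(0.0).unstack()
        nrep = int(g.count().min())
        missing = mean.isna().any(axis=None)
        if missing:
            raise ValueError("grid is not rectangular: missing dose pairs")
        return cls(
            doses_A=doses_A,
            doses_B=doses_B,
            inhibition=mean.loc[doses_A, doses_B].to_numpy(),
            sd=sd.loc[doses_A, doses_B].to_numpy(),
            n_replicates=nrep,
        )

    def __post_init__(self):
        if self.inhibition.shape != (len(self.doses_A), len(self.doses_B)):
            raise ValueError("inhibition grid shape mismatch")
        if 0.0 not in self.doses_A or 0.0 not in self.doses_B:
            raise ValueError("dose vectors must include 0")


@dataclass
class RayFit:
    """Constrained 4PL fit of one ray and its inversion."""

    bottom: float
    top: float
    ec50: float
    hill: float
    flags: list[str] = field(default_factory=list)
    dose_range: tuple[float, float] = (0.0, np.inf)

    def predict(self, dose):
        return four_pl(dose, self.bottom, self.top, self.ec50, self.hill)

    def ic(self, level: float) -> float:
        """Dose producing the given inhibition level; NaN if unreachable."""
        if not self.bottom < level < self.top:
            return np.nan
        d = self.ec50 * ((level - self.bottom) / (self.top - level)) ** (1.0 / self.hill)
        lo, hi = self.dose_range
        if not lo <= d <= hi:
            self.flags.append(f"IC{100 * level:.0f} extrapolated beyond tested range")
        return float(d)


def fit_ray(doses, inhibitions, sds=None) -> RayFit:
    """Constrained 4PL fit (bottom >= 0, top <= 1, slope > 0) of one ray."""
    doses = np.asarray(doses, dtype=float)
    y = np.asarray(inhibitions, dtype=float)
    if len(doses) < 4:
        raise ValueError("need at least 4 dose levels on a ray")
    order = np.argsort(doses)
    doses, y = doses[order], y[order]
    weights = None
    if sds is not None:
        sds = np.asarray(sds, dtype=float)[order]
        floor = max(np.median(sds[sds > 0]) if (sds > 0).any() else 1.0, 1e-3)
        weights = 1.0 / np.maximum(sds, 0.5 * floor)

    flags = []
    diffs = np.diff(y)
    noise = float(np.std(y)) if np.std(y) > 0 else 1.0
    if (diffs < -3.0 * noise / np.sqrt(len(y))).any():
        flags.append("non-monotone ray beyond noise")

    model = lmfit.Model(four_pl)
    pos = doses[doses > 0]
    half = 0.5 * (y.min() + y.max())
    above = doses[y >= half]
    ec0 = float(above[0]) if (len(above) and above[0] > 0) else float(np.median(pos))
    params = model.make_params(
        bottom=dict(value=max(y.min(), 0.0), min=0.0, max=1.0),
        top=dict(value=min(max(y.max(), 0.05), 1.0), min=0.0, max=1.0),
        ec50=dict(value=ec0, min=pos.min() * 1e-4, max=pos.max() * 1e4),
        hill=dict(value=1.0, min=0.05, max=20.0),
    )
    best = None
    for h0 in (1.0, 2.0, 0.5):
        params["hill"].value = h0
        res = model.fit(y, params, dose=doses, weights=weights)
        if best is None or res.chisqr < best.chisqr:
            best = res
    p = best.params
    return RayFit(
        bottom=float(p["bottom"].value),
        top=float(p["top"].value),
        ec50=float(p["ec50"].value),
        hill=float(p["hill"].value),
        flags=flags,
        dose_range=(0.0, float(doses.max())),
    )


def combination_index(pair, icx_A: float, icx_B: float) -> float:
    """Loewe CI of an iso-effective pair given single-agent iso-doses."""
    a, b = pair
    if a < 0 or b < 0:
        raise ValueError("doses must be >= 0")
    if not (np.isfinite(icx_A) and np.isfinite(icx_B)) or icx_A <= 0 or icx_B <= 0:
        raise ValueError("single-agent iso-effective doses must be finite and > 0")
    return float(a / icx_A + b / icx_B)


@dataclass
class IsoboleResult:
    level: float
    icx_A: float
    icx_B: float
    pairs: pd.DataFrame  # dose_A, dose_B, ci, direction, flags

    def median_ci(self) -> float:
        return float(self.pairs["ci"].median())


def analyze_grid(grid: DoseResponseGrid | pd.DataFrame, level: float) -> IsoboleResult:
    """Iso-effective pairs and Loewe CI at one effect level.

    Dose-response curves are fitted for drug A at each dose of drug B and
    vice versa; each fitted ray is inverted at ``level`` to give the
    combined dose completing the iso-effect, excluding rays whose fixed
    dose alone already exceeds the level.
    """
    if isinstance(grid, pd.DataFrame):
        grid = DoseResponseGrid.from_tidy(grid)
    if not 0.0 < level < 1.0:
        raise ValueError("effect level must be in (0, 1)")
    iB0 = int(np.where(grid.doses_B == 0.0)[0][0])
    iA0 = int(np.where(grid.doses_A == 0.0)[0][0])
    ray_A = fit_ray(grid.doses_A, grid.inhibition[:, iB0], grid.sd[:, iB0])
    ray_B = fit_ray(grid.doses_B, grid.inhibition[iA0, :], grid.sd[iA0, :])
    icx_A, icx_B = ray_A.ic(level), ray_B.ic(level)
    if not (np.isfinite(icx_A) and np.isfinite(icx_B)):
        raise ValueError(f"effect level {level} unreachable by a single agent")

    rows = []
    for j, b in enumerate(grid.doses_B):
        if b == 0.0:
            continue
        rf = fit_ray(grid.doses_A, grid.inhibition[:, j], grid.sd[:, j])
        a_iso = rf.ic(level)
        if np.isfinite(a_iso):
            rows.append((a_iso, b, combination_index((a_iso, b), icx_A, icx_B),
                         "A_at_fixed_B", ";".join(rf.flags)))
    for i, a in enumerate(grid.doses_A):
        if a == 0.0:
            continue
        rf = fit_ray(grid.doses_B, grid.inhibition[i, :], grid.sd[i, :])
        b_iso = rf.ic(level)
        if np.isfinite(b_iso):
            rows.append((a, b_iso, combination_index((a, b_iso), icx_A, icx_B),
                         "B_at_fixed_A", ";".join(rf.flags)))
    pairs = pd.DataFrame(rows, columns=["dose_A", "dose_B", "ci", "direction", "flags"])
    return IsoboleResult(level=level, icx_A=icx_A, icx_B=icx_B, pairs=pairs)


def loewe_additive_surface(curve_A: dict, curve_B: dict):
    """Inhibition surface of two non-interacting drugs under Loewe additivity.

    ``curve_A``/``curve_B`` are Hill curves ``{'ec50': ..., 'hill': ...}``
    with bottom 0 and top 1.  For each (a, b) the additive effect E solves
    a/IC_E^A + b/IC_E^B = 1, with IC_E = ec50 (E/(1-E))^(1/hill).
    """

    def ic(curve, e):
        return curve["ec50"] * (e / (1.0 - e)) ** (1.0 / curve["hill"])

    def surface(a: float, b: float) -> float:
        if a <= 0 and b <= 0:
            return 0.0
        if b <= 0:
            return float(hill_inhibition(a, **curve_A))
        if a <= 0:
            return float(hill_inhibition(b, **curve_B))

        def g(e):
            return a / ic(curve_A, e) + b / ic(curve_B, e) - 1.0

        return float(optimize.brentq(g, 1e-9, 1.0 - 1e-9, xtol=1e-12))

    return surface


def bootstrap_ci(
    tidy_grid: pd.DataFrame, level: float, n_boot: int = 100, seed: int = 0
) -> pd.DataFrame:
    """Bootstrap over replicate plates: percentile intervals of the median CI."""
    rng = np.random.default_rng(seed)
    reps = tidy_grid["replicate"].unique()
    medians = []
    for _ in range(n_boot):
        take = rng.choice(reps, size=len(reps), replace=True)
        parts = [tidy_grid[tidy_grid["replicate"] == r] for r in take]
        boot = pd.concat(parts, ignore_index=True)
        try:
            medians.append(analyze_grid(boot, level).median_ci())
        except ValueError:
            continue
    med = np.array(medians)
    return pd.DataFrame(
        {
            "level": [level],
            "median_ci": [float(np.median(med))],
            "lo": [float(np.percentile(med, 2.5))],
            "hi": [float(np.percentile(med, 97.5))],
            "n_boot_ok": [len(med)],
        }
    )
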