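"""Stochastic layout generators used to validate the heterogeneity index.

Three kinds of transplanting layouts are simulated on a rows x cols grid
with plant spacing PD (within a row, x direction) and row spacing RD
(between rows, y direction); the canonical study plot is a 15 x 15 grid
with RD:PD = 2:3.

* perturbed lattice:  x(i,j) = PD*i + N(0, sigma1^2),
                      y(i,j) = RD*j + N(0, sigma2^2),
  with sigma grids expressed as fractions of PD / RD
  (sigma = 0 is the exact lattice, whose CV is 0);
* omission: the boundary ring of the lattice is always retained and each
  interior cluster is dropped independently with probability P (transplanter
  skips);
* fully random: n i.i.d. uniform points in the lattice extent (its CV
  concentrates around 0.5).

``run_cv_experiment`` sweeps a parameter grid with common random numbers:
each replicate reuses one seed across all levels, so level-to-level CV
differences are paired and Monte-Carlo noise largely cancels — the natural
design for testing monotone trends.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .metrics import heterogeneity_cv
from .tessellation import PointSet, tessellate

__all__ = [
    "LatticeSpec",
    "PerturbationSpec",
    "OmissionSpec",
    "RandomFieldSpec",
    "ExperimentResult",
    "lattice_points",
    "perturb_lattice",
    "omit_clusters",
    "random_field",
    "run_cv_experiment",
]


@dataclass(frozen=True)
class LatticeSpec:
    """A rows x cols planting grid; PD = plant spacing (x), RD = row spacing (y)."""

    rows: int = 15
    cols: int = 15
    PD: float = 3.0
    RD: float = 2.0

    def __post_init__(self):
        if self.rows < 3 or self.cols < 3:
            raise InvalidParameterError("lattice needs rows, cols >= 3")
        if self.PD <= 0 or self.RD <= 0:
            raise InvalidParameterError("spacings must be positive")

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) bounding box of the lattice points."""
        return (self.PD, self.PD * self.cols, self.RD, self.RD * self.rows)


@dataclass(frozen=True)
class PerturbationSpec:
    """Gaussian positional noise; sigmas are fractions of PD/RD by default."""

    sigma1: float = 0.0
    sigma2: float = 0.0
    fractional: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.sigma1 < 0 or self.sigma2 < 0:
            raise InvalidParameterError("sigmas must be non-negative")


@dataclass(frozen=True)
class OmissionSpec:
    """Independent interior-cluster omission with probability p; boundary kept."""

    p: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.p <= 1.0):
            raise InvalidParameterError("omission probability must lie in [0, 1]")


@dataclass(frozen=True)
class RandomFieldSpec:
    """n i.i.d. uniform points in a rectangle [xmin, xmax] x [ymin, ymax]."""

    n: int = 225
    xmin: float = 3.0
    xmax: float = 45.0
    ymin: float = 2.0
    ymax: float = 30.0
    seed: int = 0

    def __post_init__(self):
        if self.n < 4:
            raise InvalidParameterError("need at least 4 points")
        if self.xmax <= self.xmin or self.ymax <= self.ymin:
            raise InvalidParameterError("extent must be positive")

    @classmethod
    def from_lattice(cls, lattice: LatticeSpec, n: int | None = None, seed: int = 0):
        xmin, xmax, ymin, ymax = lattice.extent
        return cls(
            n=n if n is not None else lattice.rows * lattice.cols,
            xmin=xmin, xmax=xmax, ymin=ymin, ymax=ymax, seed=seed,
        )


def lattice_points(spec: LatticeSpec) -> PointSet:
    """Exact grid: x = PD*i (i = 1..cols), y = RD*j (j = 1..rows)."""
    i = np.arange(1, spec.cols + 1, dtype=float)
    j = np.arange(1, spec.rows + 1, dtype=float)
    xx, yy = np.meshgrid(spec.PD * i, spec.RD * j)
    return PointSet(np.column_stack([xx.ravel(), yy.ravel()]))


def _interior_mask(spec: LatticeSpec) -> np.ndarray:
    """Boolean mask over lattice_points order; True for non-boundary clusters."""
    jj, ii = np.meshgrid(np.arange(spec.rows), np.arange(spec.cols), indexing="ij")
    return (
        (ii > 0) & (ii < spec.cols - 1) & (jj > 0) & (jj < spec.rows - 1)
    ).ravel()


def perturb_lattice(spec: LatticeSpec, pert: PerturbationSpec) -> PointSet:
    """Lattice plus independent per-point Gaussian offsets on each axis.

    Offsets are sigma * z with z standard normal, so sigma = 0 reproduces the
    exact lattice bit-for-bit and a shared seed yields coupled layouts across
    sigma levels.
    """
    base = lattice_points(spec).points
    s1 = pert.sigma1 * spec.PD if pert.fractional else pert.sigma1
    s2 = pert.sigma2 * spec.RD if pert.fractional else pert.sigma2
    rng = np.random.default_rng(pert.seed)
    z = rng.standard_normal(base.shape)
    out = base + z * np.array([s1, s2])
    return PointSet(out)


def omit_clusters(spec: LatticeSpec, om: OmissionSpec) -> PointSet:
    """Drop interior clusters i.i.d. with probability p, keeping the boundary ring.

    Omission is realised as u < p on per-cluster uniforms, so with a shared
    seed the omitted sets are nested across increasing p.
    """
    pts = lattice_points(spec).points
    interior = _interior_mask(spec)
    rng = np.random.default_rng(om.seed)
    u = rng.random(int(interior.sum()))
    drop = np.zeros(len(pts), dtype=bool)
    drop[interior] = u < om.p
    return PointSet(pts[~drop])


def random_field(spec: RandomFieldSpec) -> PointSet:
    """Completely random layout: n i.i.d. uniform points in the rectangle."""
    rng = np.random.default_rng(spec.seed)
    x = rng.uniform(spec.xmin, spec.xmax, spec.n)
    y = rng.uniform(spec.ymin, spec.ymax, spec.n)
    return PointSet(np.column_stack([x, y]))


@dataclass(frozen=True)
class ExperimentResult:
    """Per-level CV summaries of a parameter sweep, plus the raw records."""

    mode: str
    levels: tuple[float, ...]
    replicates: int
    base_seed: int
    replicate_seeds: tuple[int, ...]
    records: tuple[dict, ...]  # keys: level, replicate, cv, n_interior, flagged
    cv_mean: tuple[float, ...] = field(default=())
    cv_sd: tuple[float, ...] = field(default=())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(list(self.records))

    def cv_matrix(self) -> np.ndarray:
        """(levels, replicates) array of CV values; NaN where flagged."""
        m = np.full((len(self.levels), self.replicates), np.nan)
        idx = {lv: i for i, lv in enumerate(self.levels)}
        for r in self.records:
            if not r["flagged"]:
                m[idx[r["level"]], r["replicate"]] = r["cv"]
        return m


def _layout_for(mode: str, level: float, seed: int, lattice: LatticeSpec,
                random_spec: RandomFieldSpec | None) -> PointSet:
    if mode == "perturb":
        return perturb_lattice(
            lattice, PerturbationSpec(sigma1=level, sigma2=level, seed=seed)
        )
    if mode == "omit":
        return omit_clusters(lattice, OmissionSpec(p=level, seed=seed))
    if mode == "random":
        base = random_spec or RandomFieldSpec.from_lattice(lattice)
        return random_field(
            RandomFieldSpec(n=base.n, xmin=base.xmin, xmax=base.xmax,
                            ymin=base.ymin, ymax=base.ymax, seed=seed)
        )
    raise InvalidParameterError(f"unknown simulation mode {mode!r}")


def run_cv_experiment(
    mode: str,
    levels,
    replicates: int = 100,
    base_seed: int = 0,
    lattice: LatticeSpec | None = None,
    random_spec: RandomFieldSpec | None = None,
) -> ExperimentResult:
    """Sweep a parameter grid, tessellating each layout and recording its CV.

    ``mode`` is "perturb" (levels = sigma as a fraction of PD/RD, applied to
    both axes), "omit" (levels = omission probability) or "random" (levels
    ignored; pass [0]).  Replicate r uses one derived seed at every level
    (common random numbers).  Levels whose layout has fewer than 4 points or
    no interior site are flagged, not silently dropped.
    """
    if replicates < 1:
        raise InvalidParameterError("replicates must be >= 1")
    lattice = lattice or LatticeSpec()
    levels = tuple(float(v) for v in levels)
    # one sub-seed per replicate, shared across levels; < 2^31 for portability
    rep_seeds = tuple(
        int(s) % (2**31) for s in np.random.SeedSequence(base_seed).generate_state(replicates)
    )

    records: list[dict] = []
    cv_mean: list[float] = []
    cv_sd: list[float] = []
    for level in levels:
        vals = []
        for r, seed in enumerate(rep_seeds):
            pts = _layout_for(mode, level, seed, lattice, random_spec)
            flagged = len(pts) < 4
            cv = np.nan
            n_interior = 0
            if not flagged:
                tess = tessellate(pts)
                n_interior = tess.n_interior
                if n_interior == 0:
                    flagged = True
                else:
                    cv = heterogeneity_cv(tess.interior_areas()).cv
            records.append(
                {"level": level, "replicate": r, "cv": cv,
                 "n_interior": n_interior, "flagged": flagged}
            )
            if not flagged:
                vals.append(cv)
        cv_mean.append(float(np.mean(vals)) if vals else np.nan)
        cv_sd.append(float(np.std(vals, ddof=1)) if len(vals) > 1 else np.nan)

    return ExperimentResult(
        mode=mode,
        levels=levels,
        replicates=replicates,
        base_seed=base_seed,
        replicate_seeds=rep_seeds,
        records=tuple(records),
        cv_mean=tuple(cv_mean),
        cv_sd=tuple(cv_sd),
    )
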