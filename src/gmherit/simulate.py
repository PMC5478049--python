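"""Synthetic landmark datasets: mean shape + allometric, noise and heritable
deformations.

Each simulated individual is built in shape space as

    shape_i = template + AD(size_i) + ND_i + HD(patriline_i)

and then scaled by its drawn centroid size to give raw digitized-style
coordinates.  AD is a per-coordinate linear response to centroid size (static
allometry); ND is isotropic per-landmark Gaussian noise (measurement error);
HD displaces two target landmarks by a patriline-specific amount — the
heritable signal the likelihood method is meant to detect.

The default parameterization emulates a polymorphic ant-worker head study:
a 14-landmark head-like template, log-normal centroid sizes spanning roughly
a threefold range, an allometric gradient strong enough to dominate PC1, and
a standard heritable effect of 0.01 shape units at landmarks 9 and 10.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .gm import _canonical_orientation
from .io import LandmarkConfiguration, Pedigree

__all__ = [
    "DeformationSpec",
    "Treatment",
    "SimulatedDataset",
    "default_mean_shape",
    "default_allometry_slopes",
    "hd_offset",
    "simulate_dataset",
    "STANDARD_HD_MAGNITUDE",
    "DEFAULT_ND_SD",
]

# standard heritable effect: 0.01 shape units at two landmarks
STANDARD_HD_MAGNITUDE = 0.01
# per-landmark isotropic noise SD (shape units) of the standard noise ND1
DEFAULT_ND_SD = 0.004
# default heritable target landmarks (1-based homology indices)
DEFAULT_TARGETS = (9, 10)
# smallest mating frequency in the multi-patriline design; HD6's effect
# inflation is anchored here
MF_MIN = 3
HD6_INFLATION_PER_MATE = 0.05

_HD_TYPES = {"HD1", "HD2", "HD3", "HD5", "HD6"}


def default_mean_shape() -> np.ndarray:
    """A 14-landmark, head-capsule-like template (bilaterally symmetric),
    centered, normalized to unit centroid size, and expressed in the same
    canonical principal-axes frame that Procrustes alignment returns, so the
    generating and aligned coordinate frames coincide."""
    pts = np.array([
        [-0.55, 0.90],   # 1  posterolateral corner, left
        [0.55, 0.90],    # 2  posterolateral corner, right
        [0.00, 1.00],    # 3  occipital midpoint
        [-0.70, 0.35],   # 4  lateral margin, left
        [0.70, 0.35],    # 5  lateral margin, right
        [-0.45, 0.45],   # 6  eye, left
        [0.45, 0.45],    # 7  eye, right
        [0.00, 0.15],    # 8  frons midpoint
        [-0.30, -0.55],  # 9  clypeal corner, left   (heritable target)
        [0.30, -0.55],   # 10 clypeal corner, right  (heritable target)
        [-0.60, -0.30],  # 11 mandible insertion, left
        [0.60, -0.30],   # 12 mandible insertion, right
        [0.00, -0.70],   # 13 clypeal midpoint
        [0.00, 0.60],    # 14 vertex midpoint
    ])
    pts = pts - pts.mean(axis=0)
    pts = pts / np.sqrt(np.sum(pts**2))
    return _canonical_orientation(pts[None])[0]


def default_allometry_slopes(norm: float = 0.04,
                             targets: Tuple[int, ...] = DEFAULT_TARGETS,
                             mean_shape: Optional[np.ndarray] = None) -> np.ndarray:
    """Fixture allometric gradient: flattened (2k,) per-coordinate slopes.

    A smooth relative-broadening field is projected so that it (a) carries no
    translation, scaling or rotation of the template (those are removed by
    Procrustes alignment anyway, and keeping them out makes the generating
    model live in the tangent space), and (b) is zero at the heritable target
    landmarks, so the allometric and heritable axes are geometrically
    distinct — the design the simulation emulates, where PC1 carries the
    allometric signal only.
    """
    mean = default_mean_shape() if mean_shape is None else mean_shape
    k = mean.shape[0]
    x, y = mean[:, 0], mean[:, 1]
    # larger heads relatively broader and shorter-faced: a smooth field
    seed = np.column_stack([x * (0.8 - 0.6 * y), -0.5 * y * np.abs(x) - 0.2 * y**2])
    v = seed.astype(float)
    tmask = np.zeros(k, dtype=bool)
    tmask[[t - 1 for t in targets]] = True
    v[tmask] = 0.0
    # similarity-transform directions (flattened), restricted off the targets
    def flat(m):
        return m.reshape(-1)
    tx = np.column_stack([np.ones(k), np.zeros(k)])
    ty = np.column_stack([np.zeros(k), np.ones(k)])
    scale_dir = mean.copy()
    rot_dir = np.column_stack([-mean[:, 1], mean[:, 0]])
    basis = []
    for u in (tx, ty, scale_dir, rot_dir):
        u = u.copy()
        u[tmask] = 0.0
        u = flat(u)
        for b in basis:
            u = u - (u @ b) * b
        nrm = np.linalg.norm(u)
        if nrm > 1e-12:
            basis.append(u / nrm)
    vf = flat(v)
    for b in basis:
        vf = vf - (vf @ b) * b
    vf = vf / np.linalg.norm(vf) * norm
    return vf


@dataclass
class DeformationSpec:
    """Full parameterization of the three deformation components.

    nd_sd : per-landmark noise SD in shape units (scalar or length-k array).
    nd_multiplier : 1 for standard noise (ND1), 2 for double (ND2).
    hd_type : HD1/HD2/HD3 (two-patriline standard/double/half) or HD5/HD6
        (multi-patriline, maximum effect independent of / inflated with
        mating frequency).
    hd_magnitude : maximum landmark displacement in shape units.
    orientation : 'parallel' (same displacement direction at both targets)
        or 'orthogonal' (perpendicular directions).
    """

    mean_shape: np.ndarray = field(default_factory=default_mean_shape)
    ad_slopes: Optional[np.ndarray] = None  # (2k,) flattened; None = fixture default
    size_log_mu: float = 0.0
    size_log_sigma: float = 0.43
    nd_sd: float | np.ndarray = DEFAULT_ND_SD
    nd_multiplier: float = 1.0
    hd_type: str = "HD1"
    hd_magnitude: float = STANDARD_HD_MAGNITUDE
    hd_targets: Tuple[int, int] = DEFAULT_TARGETS
    orientation: str = "parallel"

    def __post_init__(self):
        self.mean_shape = np.asarray(self.mean_shape, dtype=float)
        if self.hd_type not in _HD_TYPES:
            raise ValueError(f"unknown HD type {self.hd_type!r}")
        if self.hd_magnitude < 0:
            raise ValueError("HD magnitude must be >= 0")
        if self.orientation not in ("parallel", "orthogonal"):
            raise ValueError("orientation must be 'parallel' or 'orthogonal'")
        k = self.mean_shape.shape[0]
        t = tuple(int(i) for i in self.hd_targets)
        if len(set(t)) != len(t) or any(not (1 <= i <= k) for i in t):
            raise ValueError(f"target landmark indices must be distinct and in 1..{k}")
        self.hd_targets = t
        if self.ad_slopes is None:
            self.ad_slopes = default_allometry_slopes(
                targets=self.hd_targets, mean_shape=self.mean_shape)
        self.ad_slopes = np.asarray(self.ad_slopes, dtype=float)

    @property
    def k(self) -> int:
        return self.mean_shape.shape[0]

    def noise_sd_vector(self) -> np.ndarray:
        sd = np.broadcast_to(np.atleast_1d(np.asarray(self.nd_sd, float)),
                             (self.k,)).copy()
        return sd * self.nd_multiplier


@dataclass(frozen=True)
class Treatment:
    """A named simulation treatment resolving to a DeformationSpec."""

    name: str
    spec: DeformationSpec

    _TABLE = {
        # two-patriline effect-size series
        "T1": dict(hd_type="HD1", hd_scale=1.0, nd_multiplier=1.0),
        "T2": dict(hd_type="HD2", hd_scale=2.0, nd_multiplier=1.0),
        "T3": dict(hd_type="HD1", hd_scale=1.0, nd_multiplier=2.0),
        "T4": dict(hd_type="HD3", hd_scale=0.5, nd_multiplier=1.0),
        # multi-patriline robustness series
        "T5o": dict(hd_type="HD5", hd_scale=1.0, nd_multiplier=1.0, orientation="orthogonal"),
        "T5p": dict(hd_type="HD5", hd_scale=1.0, nd_multiplier=1.0, orientation="parallel"),
        "T6o": dict(hd_type="HD6", hd_scale=1.0, nd_multiplier=1.0, orientation="orthogonal"),
        "T6p": dict(hd_type="HD6", hd_scale=1.0, nd_multiplier=1.0, orientation="parallel"),
    }

    @classmethod
    def names(cls) -> List[str]:
        return list(cls._TABLE)

    @classmethod
    def from_name(cls, name: str, base_magnitude: float = STANDARD_HD_MAGNITUDE,
                  noise_sd: float | np.ndarray = DEFAULT_ND_SD,
                  **spec_overrides) -> "Treatment":
        """Resolve a named treatment (T1-T4, T5o/p, T6o/p).

        ``base_magnitude`` is the standard effect; T2 doubles it and T4
        halves it by construction. ``spec_overrides`` are passed through to
        DeformationSpec (e.g. hd_targets, size law parameters).
        """
        if name not in cls._TABLE:
            raise ValueError(f"unknown treatment {name!r}; one of {cls.names()}")
        row = cls._TABLE[name]
        spec = DeformationSpec(
            nd_sd=noise_sd,
            nd_multiplier=row["nd_multiplier"],
            hd_type=row["hd_type"],
            hd_magnitude=base_magnitude * row["hd_scale"],
            orientation=row.get("orientation", "parallel"),
            **spec_overrides,
        )
        return cls(name=name, spec=spec)

    def with_magnitude(self, magnitude: float) -> "Treatment":
        return Treatment(self.name, replace(self.spec, hd_magnitude=magnitude))


def _hd_directions(spec: DeformationSpec) -> np.ndarray:
    """Unit displacement direction at each target landmark (2 x 2).

    The reference axis is a convention: 'parallel' displaces both targets
    along +y; 'orthogonal' uses +y at the first target and +x at the second
    (dot product zero).
    """
    if spec.orientation == "parallel":
        return np.array([[0.0, 1.0], [0.0, 1.0]])
    return np.array([[0.0, 1.0], [1.0, 0.0]])


def hd_offset(spec: DeformationSpec, patriline_index: int,
              mating_frequency: int) -> np.ndarray:
    """Heritable deformation of one patriline: a (k, 2) landmark offset.

    Patriline 1 is the undeformed reference form; patriline magnitudes rise
    on a linear gradient to the maximum at ``patriline_index ==
    mating_frequency``: magnitude * (p - 1) / (mf - 1). For HD6 the maximum
    is additionally inflated by 5% per mating above the smallest simulated
    mating frequency (3), making the effect 'nonindependent' of polyandry.
    """
    if mating_frequency < 2:
        raise ValueError("mating_frequency must be >= 2")
    if not (1 <= patriline_index <= mating_frequency):
        raise ValueError("patriline_index must be in 1..mating_frequency")
    mag = spec.hd_magnitude * (patriline_index - 1) / (mating_frequency - 1)
    if spec.hd_type == "HD6":
        mag *= 1.0 + HD6_INFLATION_PER_MATE * max(mating_frequency - MF_MIN, 0)
    offset = np.zeros_like(spec.mean_shape)
    dirs = _hd_directions(spec)
    for row, t in enumerate(spec.hd_targets):
        offset[t - 1] = mag * dirs[row]
    return offset


@dataclass
class SimulatedDataset:
    """One simulated colony sample plus the truth that generated it."""

    configs: List[LandmarkConfiguration]
    pedigree: Pedigree
    sizes: np.ndarray
    shapes: np.ndarray  # (n, k, 2) shape-space configurations before size scaling
    patriline_indices: np.ndarray  # 1-based patriline per individual
    treatment_name: str
    spec: DeformationSpec
    mating_frequency: int
    seed: int

    @property
    def n(self) -> int:
        return len(self.configs)

    def truth(self) -> dict:
        return {
            "treatment": self.treatment_name,
            "hd_type": self.spec.hd_type,
            "hd_magnitude": self.spec.hd_magnitude,
            "hd_targets": list(self.spec.hd_targets),
            "orientation": self.spec.orientation,
            "nd_multiplier": self.spec.nd_multiplier,
            "mating_frequency": self.mating_frequency,
            "n": self.n,
            "seed": self.seed,
        }


def _patriline_blocks(n: int, mating_frequency: int) -> np.ndarray:
    """Near-equal contiguous blocks; the remainder goes to the earliest
    patrilines. Returns 1-based indices, length n."""
    base, rem = divmod(n, mating_frequency)
    counts = [base + (1 if i < rem else 0) for i in range(mating_frequency)]
    return np.repeat(np.arange(1, mating_frequency + 1), counts)


def simulate_dataset(treatment: Treatment, n: int = 100,
                     mating_frequency: int = 2, seed: int = 0,
                     colony_id: str = "C1") -> SimulatedDataset:
    """Generate one replicate dataset under a treatment.

    Individuals are assigned to patrilines in near-equal blocks; centroid
    sizes are drawn from the log-normal size law; each raw configuration is
    size_i * (template + AD(size_i) + ND_i + HD(patriline_i)). The random
    streams for sizes and noise are split from the seed independently, so
    switching a deformation on or off does not shift the other's draws.
    Bit-for-bit reproducible from (treatment, n, mating_frequency, seed).
    """
    if n < mating_frequency:
        raise ValueError("need n >= mating_frequency")
    spec = treatment.spec
    k = spec.k
    ss = np.random.SeedSequence([int(seed)])
    sizes_rng, noise_rng, _assign_rng = [np.random.default_rng(c)
                                         for c in ss.spawn(3)]
    patrilines = _patriline_blocks(n, mating_frequency)
    sizes = sizes_rng.lognormal(spec.size_log_mu, spec.size_log_sigma, size=n)
    noise = noise_rng.normal(0.0, 1.0, size=(n, k, 2)) * \
        spec.noise_sd_vector()[None, :, None]

    offsets = np.stack([hd_offset(spec, p, mating_frequency)
                        for p in range(1, mating_frequency + 1)])
    slopes = spec.ad_slopes.reshape(k, 2)
    shapes = (spec.mean_shape[None, :, :]
              + slopes[None, :, :] * (sizes - 1.0)[:, None, None]
              + noise
              + offsets[patrilines - 1])
    raw = shapes * sizes[:, None, None]

    width = len(str(n))
    ids = [f"S{i + 1:0{width}d}" for i in range(n)]
    configs = [LandmarkConfiguration(sid, xy) for sid, xy in zip(ids, raw)]
    ped = Pedigree(pd.DataFrame({
        "specimen_id": ids,
        "colony_id": colony_id,
        "patriline_id": [f"P{p}" for p in patrilines],
    }))
    return SimulatedDataset(
        configs=configs, pedigree=ped, sizes=sizes, shapes=shapes,
        patriline_indices=patrilines, treatment_name=treatment.name,
        spec=spec, mating_frequency=mating_frequency, seed=int(seed),
    )
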