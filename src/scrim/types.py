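"""Domain containers shared by the simulator, the likelihood kernel and the sampler.

All coordinates are kilometres in a local planar frame; densities are
individuals per square kilometre.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "StateSpace",
    "TrapArray",
    "SCRData",
    "OccData",
    "TelemetryData",
    "AugmentedState",
    "DataBundle",
]


@dataclass(frozen=True)
class StateSpace:
    """Planar rectangular state space over which activity centers live.

    Parameters
    ----------
    xmin, xmax, ymin, ymax : float
        Rectangle bounds in km.
    """

    xmin: float
    xmax: float
    ymin: float
    ymax: float

    def __post_init__(self) -> None:
        if not (self.xmax > self.xmin and self.ymax > self.ymin):
            raise ValueError("state space must have positive extent")

    @property
    def area(self) -> float:
        """Area in km^2."""
        return (self.xmax - self.xmin) * (self.ymax - self.ymin)

    @property
    def bounds(self) -> np.ndarray:
        return np.array([self.xmin, self.xmax, self.ymin, self.ymax])

    def contains(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        return (
            (pts[:, 0] >= self.xmin)
            & (pts[:, 0] <= self.xmax)
            & (pts[:, 1] >= self.ymin)
            & (pts[:, 1] <= self.ymax)
        )

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` uniform points on the rectangle."""
        x = rng.uniform(self.xmin, self.xmax, n)
        y = rng.uniform(self.ymin, self.ymax, n)
        return np.column_stack([x, y])

    @classmethod
    def from_traps(cls, traps: Sequence["TrapArray"], buffer: float = 2.0) -> "StateSpace":
        """Union of trap envelopes buffered by ``buffer`` km on every side."""
        coords = np.vstack([t.coords for t in traps])
        return cls(
            coords[:, 0].min() - buffer,
            coords[:, 0].max() + buffer,
            coords[:, 1].min() - buffer,
            coords[:, 1].max() + buffer,
        )


LIVE_TRAP = "live"
CAMERA = "camera"


@dataclass
class TrapArray:
    """Detector array of one class (live traps or cameras).

    Attributes
    ----------
    coords : (J, 2) float array, km
    kind : "live" or "camera"
    effort : (J,) int array
        Sampling occasions K_j per detector.
    bait : optional (J,) int array in {0, 1}
        Binary bait covariate; only meaningful for live traps.
    ids : optional sequence of detector identifiers.
    """

    coords: np.ndarray
    kind: str
    effort: np.ndarray
    bait: Optional[np.ndarray] = None
    ids: Optional[list] = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 2)
        self.effort = np.asarray(self.effort, dtype=np.int64)
        if self.kind not in (LIVE_TRAP, CAMERA):
            raise ValueError(f"kind must be '{LIVE_TRAP}' or '{CAMERA}', got {self.kind!r}")
        if self.effort.shape != (self.coords.shape[0],):
            raise ValueError("effort must have one entry per detector")
        if np.any(self.effort < 0):
            raise ValueError("effort K_j must be nonnegative")
        if self.bait is not None:
            if self.kind != LIVE_TRAP:
                raise ValueError("bait covariate is defined only for live traps")
            self.bait = np.asarray(self.bait, dtype=np.int64)
            if self.bait.shape != (self.coords.shape[0],):
                raise ValueError("bait must have one entry per trap")
            if not np.isin(self.bait, (0, 1)).all():
                raise ValueError("bait entries must be 0 or 1")
        if self.ids is None:
            prefix = "T" if self.kind == LIVE_TRAP else "C"
            self.ids = [f"{prefix}{j + 1}" for j in range(self.coords.shape[0])]

    @property
    def n_traps(self) -> int:
        return self.coords.shape[0]

    def envelope_area(self) -> float:
        """Area (km^2) of the bounding rectangle of the detectors."""
        ext = self.coords.max(axis=0) - self.coords.min(axis=0)
        return float(ext[0] * ext[1])


@dataclass
class SCRData:
    """Occasion-aggregated encounter counts for individually identified animals.

    ``y`` is an (n, J) nonnegative integer matrix; row i holds individual i's
    counts over the live traps, 0 <= y[i, j] <= K_j, and every row has at
    least one capture.
    """

    y: np.ndarray
    individual_ids: Optional[list] = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.int64)
        if self.y.ndim != 2:
            raise ValueError("y must be a 2-D individuals x traps matrix")
        if np.any(self.y < 0):
            raise ValueError("encounter counts must be nonnegative")
        if self.y.shape[0] and np.any(self.y.sum(axis=1) == 0):
            raise ValueError("every SCR individual must have at least one capture")
        if self.individual_ids is None:
            self.individual_ids = [f"ind{i + 1}" for i in range(self.y.shape[0])]

    def validate_against(self, traps: TrapArray) -> None:
        if self.y.shape[1] != traps.n_traps:
            raise ValueError("capture matrix does not match trap count")
        if np.any(self.y > traps.effort[None, :]):
            raise ValueError("encounter count exceeds trap effort K_j")

    @property
    def n_individuals(self) -> int:
        return self.y.shape[0]

    @property
    def n_captures(self) -> int:
        return int(self.y.sum())


@dataclass
class OccData:
    """Per-camera counts of occasions with at least one (unidentified) detection."""

    y: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.int64)
        if self.y.ndim != 1:
            raise ValueError("occupancy counts must be a 1-D per-camera vector")
        if np.any(self.y < 0):
            raise ValueError("detection counts must be nonnegative")

    def validate_against(self, cameras: TrapArray) -> None:
        if self.y.shape[0] != cameras.n_traps:
            raise ValueError("occupancy vector does not match camera count")
        if np.any(self.y > cameras.effort):
            raise ValueError("detections exceed camera effort K_j")

    @property
    def n_detections(self) -> int:
        return int(self.y.sum())


@dataclass
class TelemetryData:
    """Thinned telemetry fixes for m tagged individuals.

    ``fixes`` is a list of (R_i, 2) arrays (km); ``links`` maps each tagged
    individual to its row index in the SCRData matrix (tagged animals come
    from the capture cohort).
    """

    fixes: list
    links: np.ndarray

    def __post_init__(self) -> None:
        self.fixes = [np.asarray(f, dtype=float).reshape(-1, 2) for f in self.fixes]
        self.links = np.asarray(self.links, dtype=np.int64)
        if len(self.fixes) != self.links.shape[0]:
            raise ValueError("one link per tagged individual required")
        if any(f.shape[0] < 1 for f in self.fixes):
            raise ValueError("each tagged individual needs at least one fix")
        if len(set(self.links.tolist())) != len(self.links):
            raise ValueError("duplicate telemetry link")

    @property
    def n_tagged(self) -> int:
        return len(self.fixes)

    @property
    def n_fixes(self) -> np.ndarray:
        return np.array([f.shape[0] for f in self.fixes], dtype=np.int64)

    def centroids(self) -> np.ndarray:
        return np.vstack([f.mean(axis=0) for f in self.fixes])

    def sum_sq_dev(self) -> np.ndarray:
        """Per-individual sum of squared deviations from the fix centroid (both axes)."""
        return np.array([((f - f.mean(axis=0)) ** 2).sum() for f in self.fixes])


@dataclass
class AugmentedState:
    """Full parameter + latent state of one MCMC iteration."""

    z: np.ndarray  # (M,) 0/1 inclusion indicators
    s: np.ndarray  # (M, 2) activity centers, km
    psi: float
    lam0_trap: float
    lam0_cam: float
    sigma: float
    beta0: float = 0.0
    beta1: float = 0.0
    w: int = 0  # covariate-inclusion indicator
    n_obs: int = 0  # first n_obs slots are observed (z pinned to 1)

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=np.int64)
        self.s = np.asarray(self.s, dtype=float).reshape(-1, 2)
        if self.s.shape[0] != self.z.shape[0]:
            raise ValueError("z and s must have the same augmentation size M")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.lam0_trap < 0 or self.lam0_cam < 0:
            raise ValueError("baseline rates must be nonnegative")
        if not 0.0 <= self.psi <= 1.0:
            raise ValueError("psi must be a probability")
        if np.any(self.z[: self.n_obs] != 1):
            raise ValueError("observed individuals must have z = 1")

    @property
    def M(self) -> int:
        return self.z.shape[0]

    @property
    def N(self) -> int:
        return int(self.z.sum())

    def copy(self) -> "AugmentedState":
        return AugmentedState(
            z=self.z.copy(),
            s=self.s.copy(),
            psi=self.psi,
            lam0_trap=self.lam0_trap,
            lam0_cam=self.lam0_cam,
            sigma=self.sigma,
            beta0=self.beta0,
            beta1=self.beta1,
            w=self.w,
            n_obs=self.n_obs,
        )


@dataclass
class DataBundle:
    """Everything one fit consumes, on a single spatial frame."""

    traps: TrapArray
    scr: SCRData
    space: StateSpace
    cameras: Optional[TrapArray] = None
    occ: Optional[OccData] = None
    telemetry: Optional[TelemetryData] = None

    def __post_init__(self) -> None:
        self.scr.validate_against(self.traps)
        if (self.occ is None) != (self.cameras is None):
            raise ValueError("occupancy data and camera array must be supplied together")
        if self.occ is not None:
            self.occ.validate_against(self.cameras)
        if self.telemetry is not None:
            if np.any(self.telemetry.links >= self.scr.n_individuals) or np.any(
                self.telemetry.links < 0
            ):
                raise ValueError("telemetry link outside the capture cohort")
        if not self.space.contains(self.traps.coords).all():
            raise ValueError("live traps outside the state space")
        if self.cameras is not None and not self.space.contains(self.cameras.coords).all():
            raise ValueError("cameras outside the state space")
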