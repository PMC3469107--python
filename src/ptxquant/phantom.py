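"""Synthetic thorax CT phantoms with voxel-exact ground truth.

Every pipeline stage is testable without patient data against a phantom
that emulates the anatomy the method has to cope with: an elliptical
body on every slice, two ellipsoidal lungs of parenchymal density, a
spine-like bone insert, a tracheal air column reaching the top of the
scanned range, an optional sub-diaphragmatic bowel-gas pocket reaching
the bottom face, and a pleural pneumothorax crescent carved out of one
lung so that the analytic air fraction V_ptx = n_air/(n_air + n_lung)
matches a requested target exactly.

Voxel values are class means plus additive white Gaussian noise (no
streak/beam-hardening model); geometry is deterministic and independent
of the seed, so distinct seeds give distinct noise on identical anatomy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core_io import HU_MAX, HU_MIN, CTVolume, LabelMap

logger = logging.getLogger(__name__)

# ground-truth classes
GT_BODY = 1
GT_LUNG = 2
GT_PTX = 3
GT_AIRWAY = 4
GT_BOWEL = 5
GT_BONE = 6

DEFAULT_HU_MEANS: dict[str, float] = {
    "exterior": -1000.0,
    "body": 40.0,
    "parenchyma": -850.0,
    "air": -1000.0,  # pneumothorax, airway lumen, bowel gas
    "bone": 700.0,
}

#: Pneumothorax fractions mirroring the manually measured spread of an
#: 8-case cohort spanning normal to large.
TABLE1_FRACTIONS: tuple[float, ...] = (
    0.079, 0.0, 0.201, 0.184, 0.065, 0.353, 0.040, 0.195,
)


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic thorax."""

    shape: tuple[int, int, int] = (40, 384, 384)
    spacing: tuple[float, float, float] = (2.5, 0.7, 0.7)
    ptx_fraction: float = 0.0
    ptx_side: str = "right"
    include_trachea: bool = True
    include_bowel_gas: bool = True
    noise_sd: float = 20.0
    hu_means: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_HU_MEANS))
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.ptx_fraction <= 0.6):
            raise ValueError(f"ptx_fraction must be in [0, 0.6], got {self.ptx_fraction}")
        if self.ptx_side not in ("left", "right"):
            raise ValueError("ptx_side must be 'left' or 'right'")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if min(self.shape) < 16 or self.shape[0] < 8:
            raise ValueError(f"phantom shape too small: {self.shape}")


@dataclass
class PhantomCase:
    """Generated phantom: volume, voxel-exact labels, achieved fraction."""

    volume: CTVolume
    truth: LabelMap
    achieved_ptx_fraction: float
    spec: PhantomSpec


def _ellipse_mask(nr, nc, center, semi) -> np.ndarray:
    rr, cc = np.ogrid[:nr, :nc]
    return ((rr - center[0]) / semi[0]) ** 2 + ((cc - center[1]) / semi[1]) ** 2 <= 1.0


def _render_truth(spec: PhantomSpec) -> np.ndarray:
    """Noiseless class map; geometry scales with the grid shape."""
    ns, nr, nc = spec.shape
    truth = np.zeros(spec.shape, dtype=np.int32)

    body2d = _ellipse_mask(nr, nc, (0.5 * nr, 0.5 * nc), (0.35 * nr, 0.45 * nc))
    bone2d = _ellipse_mask(nr, nc, (0.78 * nr, 0.5 * nc), (0.055 * nr, 0.055 * nr))
    truth[:, body2d] = GT_BODY
    truth[:, bone2d & body2d] = GT_BONE

    # lungs: ellipsoids spanning slices [0.1, 0.8) of the stack
    lung_top, lung_bot = int(0.1 * ns), int(0.8 * ns)
    s_mid = (lung_top + lung_bot - 1) / 2.0
    s_half = (lung_bot - lung_top) / 2.0
    lung_r = 0.48 * nr
    for side, sign in (("left", -1.0), ("right", +1.0)):
        lung_c = 0.5 * nc + sign * 0.235 * nc
        for s in range(lung_top, lung_bot):
            w = np.sqrt(max(1.0 - 0.8 * ((s - s_mid) / s_half) ** 2, 0.05))
            ell = _ellipse_mask(nr, nc, (lung_r, lung_c), (0.22 * nr * w, 0.16 * nc * w))
            truth[s][ell & (truth[s] == GT_BODY)] = GT_LUNG

    if spec.include_trachea:
        tr = _ellipse_mask(nr, nc, (0.44 * nr, 0.5 * nc), (0.047 * nc, 0.047 * nc))
        tr &= body2d
        for s in range(0, int(0.5 * ns)):  # reaches the top slice face
            truth[s][tr & (truth[s] != GT_LUNG)] = GT_AIRWAY

    if spec.include_bowel_gas:
        bw = _ellipse_mask(nr, nc, (0.55 * nr, 0.39 * nc), (0.0625 * nc, 0.0625 * nc))
        bw &= body2d
        for s in range(int(0.85 * ns), ns):  # reaches the bottom slice face
            truth[s][bw] = GT_BOWEL
    return truth


def _carve_crescent(truth: np.ndarray, spec: PhantomSpec) -> float:
    """Convert lateral lung voxels of one side to PTX until the analytic
    fraction n_ptx/(n_ptx + n_lung) equals the target; returns it."""
    n_total = int(np.count_nonzero(truth == GT_LUNG))
    if n_total == 0:
        raise ValueError("phantom has no lung voxels to carve from")
    k = int(round(spec.ptx_fraction * n_total))
    if k == 0:
        return 0.0

    ns, nr, nc = spec.shape
    sign = -1.0 if spec.ptx_side == "left" else 1.0
    lung_r = 0.48 * nr
    lung_c = 0.5 * nc + sign * 0.235 * nc
    ss, rr, cc = np.nonzero(truth == GT_LUNG)
    on_side = sign * (cc - 0.5 * nc) > 0
    n_side = int(on_side.sum())
    if k > n_side:
        raise ValueError(
            f"ptx_fraction {spec.ptx_fraction} infeasible: carving one lung "
            f"gives at most {n_side / n_total:.3f}"
        )
    ss, rr, cc = ss[on_side], rr[on_side], cc[on_side]
    # crescent = top-k voxels of a score favouring the outer shell
    # (elliptical radius) and the lateral, chest-wall side of the lung
    rho = np.sqrt(((rr - lung_r) / (0.22 * nr)) ** 2 + ((cc - lung_c) / (0.16 * nc)) ** 2)
    lateral = sign * (cc - lung_c) / (0.16 * nc)
    score = rho + 0.6 * lateral
    pick = np.argsort(score, kind="stable")[-k:]
    truth[ss[pick], rr[pick], cc[pick]] = GT_PTX
    return k / n_total


_CLASS_TO_HU_KEY = {
    0: "exterior",
    GT_BODY: "body",
    GT_LUNG: "parenchyma",
    GT_PTX: "air",
    GT_AIRWAY: "air",
    GT_BOWEL: "air",
    GT_BONE: "bone",
}


def render_hu(truth: np.ndarray, hu_means: dict[str, float] | None = None) -> np.ndarray:
    """Noiseless HU image of a ground-truth class map."""
    hu_means = hu_means or DEFAULT_HU_MEANS
    out = np.empty(truth.shape, dtype=np.float64)
    for cls, key in _CLASS_TO_HU_KEY.items():
        out[truth == cls] = hu_means[key]
    return out


def generate(spec: PhantomSpec) -> PhantomCase:
    """Generate one phantom case (deterministic for a fixed seed)."""
    truth = _render_truth(spec)
    achieved = _carve_crescent(truth, spec)
    hu = render_hu(truth, spec.hu_means)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        hu = hu + rng.normal(0.0, spec.noise_sd, size=hu.shape)
    np.clip(hu, HU_MIN, HU_MAX, out=hu)
    vol = CTVolume(hu.astype(np.float32), spacing=spec.spacing)
    return PhantomCase(
        volume=vol,
        truth=LabelMap(truth),
        achieved_ptx_fraction=achieved,
        spec=spec,
    )


def generate_cohort(
    n: int,
    fractions: list[float] | None = None,
    seed: int = 0,
    **spec_kwargs,
) -> list[PhantomCase]:
    """Generate ``n`` cases with the given pneumothorax fractions.

    With ``fractions=None`` the Table-like preset spread (normal through
    large) is used, cycled to length ``n``.  Each case gets a distinct
    sub-seed derived from ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if fractions is None:
        fractions = [TABLE1_FRACTIONS[i % len(TABLE1_FRACTIONS)] for i in range(n)]
    if len(fractions) != n:
        raise ValueError(f"expected {n} fractions, got {len(fractions)}")
    cases = []
    for i, f in enumerate(fractions):
        spec = PhantomSpec(ptx_fraction=f, seed=(seed * 1009 + i) % (2**31), **spec_kwargs)
        cases.append(generate(spec))
    return cases
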