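"""Synthetic inputs: voxel phantoms and simulated two-group FD cohorts.

No real MRI ships with this package, so every downstream stage is exercised
on synthetic data of two kinds:

* **Phantoms** — binary voxel objects whose dimension is known in closed
  form (solid cube: 3, one-voxel slab: 2, Menger sponge: log 20 / log 3),
  the only desk-scale ground truth for the box-counting estimator.

* **Simulated cohorts** — subjects x 68-region fractal-dimension matrices
  drawn from a multivariate normal with a block-constant correlation matrix
  (``rho_within`` inside planted modules, ``rho_between`` across them) and
  per-region means/SDs on the scale of real cortical FD values (~2.0-2.45,
  SD ~0.01-0.08).  A "patient" group is derived from the same spec by
  lowering designated region means by ``effect_d`` standard deviations.

Defaults encode the emulated study: 30 subjects per group, five planted
modules with sizes 19/17/17/8/7, rho 0.6 within / 0.1 between, and a 27-region
effect set with a standardized shift of 0.3.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .atlas import N_REGIONS, CohortFDMatrix, RegionTable, load_region_table
from .volume import VoxelVolume

__all__ = [
    "SimulationSpec",
    "make_solid_cube",
    "make_slab",
    "make_menger_sponge",
    "simulate_cohort",
    "simulate_two_groups",
    "write_phantom",
    "make_block_parcellation",
    "DEFAULT_BLOCK_SIZES",
    "DEFAULT_EFFECT_REGIONS",
]

MENGER_LEVEL_GUARD = 4

# Five planted covariance modules, sizes matching a healthy-cohort modular
# decomposition (largest first), assigned to contiguous region ids.
DEFAULT_BLOCK_SIZES = (19, 17, 17, 8, 7)

# Region ids with a planted group-B mean reduction: the 27 cortical
# subregions reported with significantly decreased FD in patients.
DEFAULT_EFFECT_REGIONS = (
    9, 21,                       # left frontal
    2, 4, 8, 10, 24,             # right frontal
    31, 33, 35, 37, 43, 45,      # left temporal
    30, 34, 40, 42, 46,          # right temporal
    51, 59,                      # left parietal
    48, 52, 54, 58, 60,          # right parietal
    64, 66,                      # right occipital
)

# Per-lobe, per-hemisphere control-group FD means used as region defaults.
_LOBE_MEANS = {
    ("frontal", "L"): 2.2324,
    ("frontal", "R"): 2.2393,
    ("temporal", "L"): 2.2108,
    ("temporal", "R"): 2.1985,
    ("parietal", "L"): 2.2902,
    ("parietal", "R"): 2.2990,
    ("occipital", "L"): 2.2146,
    ("occipital", "R"): 2.2247,
}
_DEFAULT_REGION_SD = 0.03


def _default_region_means(table: RegionTable) -> np.ndarray:
    return np.array(
        [_LOBE_MEANS[(l, h)] for l, h in zip(table.lobes, table.hemispheres)]
    )


def _default_planted_modules() -> dict[int, int]:
    blocks: dict[int, int] = {}
    rid = 1
    for b, size in enumerate(DEFAULT_BLOCK_SIZES, start=1):
        for _ in range(size):
            blocks[rid] = b
            rid += 1
    return blocks


# ---------------------------------------------------------------------------
# Phantoms


def make_solid_cube(side: int) -> VoxelVolume:
    """A fully filled side^3 cube (topological dimension 3)."""
    if side < 1:
        raise ValueError(f"side must be >= 1, got {side}")
    return VoxelVolume(np.ones((side, side, side), dtype=bool))


def make_slab(side: int, thickness: int = 1) -> VoxelVolume:
    """A side x side x thickness filled block inside a side^3 grid.

    With thickness 1 this is a planar phantom of dimension 2.
    """
    if side < 1:
        raise ValueError(f"side must be >= 1, got {side}")
    if not 1 <= thickness <= side:
        raise ValueError(f"thickness must be in 1..side, got {thickness}")
    grid = np.zeros((side, side, side), dtype=bool)
    grid[:, :, :thickness] = True
    return VoxelVolume(grid)


def make_menger_sponge(level: int) -> VoxelVolume:
    """Menger sponge of the given construction level on a 3^level grid.

    Each level keeps 20 of 27 subcubes (face centers and the body center are
    removed), so the filled-voxel count is exactly 20^level and the Hausdorff
    dimension is log 20 / log 3 ~ 2.727.  Guarded at level 4 (an 81^3 grid).
    """
    if level < 0:
        raise ValueError("level must be non-negative")
    if level > MENGER_LEVEL_GUARD:
        raise ValueError(f"level {level} exceeds guard {MENGER_LEVEL_GUARD}")
    grid = np.ones((1, 1, 1), dtype=bool)
    # removal pattern on a 3x3x3 cell: keep unless >=2 coordinates are central
    i = np.arange(3)
    central = (i == 1).astype(int)
    keep3 = (
        central[:, None, None] + central[None, :, None] + central[None, None, :]
    ) < 2
    for _ in range(level):
        grid = np.kron(grid, keep3)
    return VoxelVolume(grid)


def write_phantom(volume: VoxelVolume, path: str | Path) -> None:
    """Write a phantom as a NIfTI label volume (0/1)."""
    import nibabel as nib

    affine = np.diag(list(volume.voxel_size_mm) + [1.0])
    nib.save(nib.Nifti1Image(volume.grid.astype(np.int16), affine), str(path))


def make_block_parcellation(
    block_side: int = 12, gap: int = 2, region_table: RegionTable | None = None
):
    """A synthetic 68-region label volume: one solid cube per region.

    Regions are laid out on a 4 x 5 x 4 lattice of ``block_side``-sized solid
    cubes separated by ``gap`` background voxels.  Every region is a solid
    block, so each region's fractal dimension is ~3 — useful for exercising
    parcellation-driven code paths, not for emulating cortical shape.
    """
    from .atlas import LabeledParcellation

    if block_side < 1 or gap < 0:
        raise ValueError("block_side must be >= 1 and gap >= 0")
    nx, ny, nz = 4, 5, 4  # 80 slots >= 68
    pitch = block_side + gap
    labels = np.zeros((nx * pitch, ny * pitch, nz * pitch), dtype=np.int32)
    rid = 1
    for ix in range(nx):
        for iy in range(ny):
            for iz in range(nz):
                if rid > N_REGIONS:
                    break
                x0, y0, z0 = ix * pitch, iy * pitch, iz * pitch
                labels[
                    x0 : x0 + block_side,
                    y0 : y0 + block_side,
                    z0 : z0 + block_side,
                ] = rid
                rid += 1
    return LabeledParcellation(
        labels=labels, region_table=region_table or load_region_table()
    )


# ---------------------------------------------------------------------------
# Cohort simulation


@dataclass
class SimulationSpec:
    """Generative model for one simulated cohort.

    The implied 68x68 correlation matrix (rho_within inside planted modules,
    rho_between across, unit diagonal) must be positive definite; this is
    checked at construction.
    """

    n_subjects: int = 30
    region_means: np.ndarray | None = None
    region_sds: np.ndarray | None = None
    planted_modules: dict[int, int] = field(default_factory=_default_planted_modules)
    rho_within: float = 0.6
    rho_between: float = 0.1
    effect_regions: tuple[int, ...] = DEFAULT_EFFECT_REGIONS
    effect_d: float = 0.3
    seed: int = 0
    region_table: RegionTable = field(default_factory=load_region_table)

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        if self.region_means is None:
            self.region_means = _default_region_means(self.region_table)
        self.region_means = np.asarray(self.region_means, dtype=float)
        if self.region_sds is None:
            self.region_sds = np.full(N_REGIONS, _DEFAULT_REGION_SD)
        self.region_sds = np.asarray(self.region_sds, dtype=float)
        if self.region_means.shape != (N_REGIONS,):
            raise ValueError(f"region_means must have {N_REGIONS} entries")
        if self.region_sds.shape != (N_REGIONS,) or np.any(self.region_sds <= 0):
            raise ValueError(f"region_sds must be {N_REGIONS} positive values")
        if not 0 <= self.rho_within < 1:
            raise ValueError("rho_within must lie in [0, 1)")
        if not 0 <= self.rho_between <= self.rho_within:
            raise ValueError("rho_between must lie in [0, rho_within]")
        if set(self.planted_modules) != set(range(1, N_REGIONS + 1)):
            raise ValueError("planted_modules must assign every region id 1..68")
        bad = [r for r in self.effect_regions if not 1 <= r <= N_REGIONS]
        if bad:
            raise ValueError(f"effect_regions outside 1..{N_REGIONS}: {bad}")
        eig_min = float(np.linalg.eigvalsh(self.correlation()).min())
        if eig_min <= 1e-10:
            raise ValueError(
                f"implied correlation matrix is not positive definite "
                f"(min eigenvalue {eig_min:.3g})"
            )

    def block_labels(self) -> np.ndarray:
        """Planted module label per region, in region-id order."""
        return np.array([self.planted_modules[r] for r in range(1, N_REGIONS + 1)])

    def correlation(self) -> np.ndarray:
        """The implied 68x68 block-constant correlation matrix."""
        labels = self.block_labels()
        same = labels[:, None] == labels[None, :]
        corr = np.where(same, self.rho_within, self.rho_between)
        np.fill_diagonal(corr, 1.0)
        return corr

    def replace(self, **changes) -> "SimulationSpec":
        return replace(self, **changes)


def _draw(
    spec: SimulationSpec,
    rng: np.random.Generator,
    means: np.ndarray,
    group_label: str,
) -> CohortFDMatrix:
    chol = np.linalg.cholesky(spec.correlation())
    z = rng.standard_normal((spec.n_subjects, N_REGIONS))
    values = means + (z @ chol.T) * spec.region_sds
    return CohortFDMatrix(
        values=values, group_label=group_label, region_table=spec.region_table
    )


def simulate_cohort(spec: SimulationSpec, group_label: str = "control") -> CohortFDMatrix:
    """One cohort draw: n_subjects from N(means, D C D); deterministic given seed."""
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    return _draw(spec, rng, spec.region_means, group_label)


def simulate_two_groups(
    spec: SimulationSpec,
    labels: tuple[str, str] = ("control", "patient"),
) -> tuple[CohortFDMatrix, CohortFDMatrix]:
    """Independent control/patient draws with distinct sub-seeds.

    Group A follows the spec unchanged; group B has the means of
    ``effect_regions`` lowered by ``effect_d`` x region SD.
    """
    ss_a, ss_b = np.random.SeedSequence(spec.seed).spawn(2)
    means_b = spec.region_means.copy()
    if spec.effect_regions:
        idx = np.array(spec.effect_regions, dtype=int) - 1
        means_b[idx] -= spec.effect_d * spec.region_sds[idx]
    group_a = _draw(spec, np.random.default_rng(ss_a), spec.region_means, labels[0])
    group_b = _draw(spec, np.random.default_rng(ss_b), means_b, labels[1])
    return group_a, group_b
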