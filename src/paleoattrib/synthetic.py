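"""Synthetic data generators for every pipeline stage.

The comparative datasets this kind of attribution study rests on
(landmark configurations of comparative molars, segmented tooth scans,
museum lithic attribute tables) are typically not redistributable, so
each generator here emulates the statistical structure the corresponding
analysis assumes:

* grouped semilandmark samples — a five-curve closed 3D rim with five
  peaks (mimicking an EDJ marginal outline with dentine horns) perturbed
  by group-specific deformations, optional allometric size–shape
  covariation, and isotropic Gaussian landmark noise, then hit with
  random similarity motions;
* voxelized tooth phantoms with enamel / dentine / pulp compartments, a
  root stem and bifurcated branch cylinders, all with closed-form
  compartment volumes (ground truth is never measured from the voxel
  grid);
* lithic attribute tables with lognormal metric noise around class means;
* normal comparative samples summarised as (mean, sample SD, n).

Every generator is a pure function of its spec plus a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_core import BACKGROUND, DENTINE, ENAMEL, PULP, ComparativeStats, LabeledVolume, LandmarkSet

__all__ = [
    "edj_template",
    "ShapeSimSpec",
    "GroupedShapeSample",
    "simulate_shape_groups",
    "PhantomSpec",
    "simulate_tooth_phantom",
    "cylindrical_shell_phantom",
    "simulate_lithic_assemblages",
    "simulate_comparative_sample",
]

DEFAULT_SEED = 20210215

#: per-curve semilandmark counts; five marginal-outline curves totalling 116
DEFAULT_CURVE_COUNTS = (24, 23, 23, 23, 23)


def edj_template(
    curve_counts=DEFAULT_CURVE_COUNTS,
    radius: float = 5.0,
    radial_amplitude: float = 0.6,
    horn_height: float = 1.5,
) -> LandmarkSet:
    """Closed five-peaked 3D rim used as the mean shape for shape simulations.

    Points sit on a circle of the given radius (mm) with five-fold radial
    and vertical modulation, split into five named curves running between
    consecutive peaks.
    """
    k = int(sum(curve_counts))
    phi = 2 * np.pi * np.arange(k) / k
    r = radius + radial_amplitude * np.cos(5 * phi)
    z = horn_height * np.cos(5 * phi)
    coords = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    curves, start = {}, 0
    for i, c in enumerate(curve_counts):
        curves[f"curve_{i + 1}"] = list(range(start, start + int(c)))
        start += int(c)
    return LandmarkSet("template", coords, curves=curves)


def _similarity_tangent_basis(coords: np.ndarray) -> np.ndarray:
    """Orthonormal basis (rows) of the translation/rotation/scale tangent
    directions at a configuration, in flattened (3K,) form."""
    x = coords - coords.mean(axis=0)
    k = len(x)
    basis = []
    for d in range(3):  # translations
        t = np.zeros((k, 3))
        t[:, d] = 1.0
        basis.append(t.ravel())
    for d in range(3):  # infinitesimal rotations
        omega = np.zeros(3)
        omega[d] = 1.0
        basis.append(np.cross(omega, x).ravel())
    basis.append(x.ravel())  # scaling
    q, _ = np.linalg.qr(np.stack(basis).T)
    return q.T  # (7, 3K)


def _orthogonalized_direction(vec: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Project a deformation vector out of the similarity tangent space and
    normalise it, so group effects are pure shape changes."""
    basis = _similarity_tangent_basis(coords)
    v = vec - basis.T @ (basis @ vec)
    nrm = np.linalg.norm(v)
    if nrm == 0:
        raise ValueError("deformation vector lies entirely in the similarity directions")
    return v / nrm


@dataclass
class ShapeSimSpec:
    """Parameters of the grouped-shape simulation.

    group_effects maps group name to either a magnitude (mm; a direction
    is drawn from the seed) or a (vector, magnitude) pair. The deformation
    directions are orthogonalized against translation/rotation/scale, so
    the injected effects survive Procrustes superimposition.
    """

    template: LandmarkSet = field(default_factory=edj_template)
    group_effects: dict = field(default_factory=lambda: {"A": 0.5, "B": 0.5})
    noise_sd: float = 0.05  # mm, per coordinate
    allometry_slope: float = 0.0  # shape displacement (mm) per unit log centroid size
    size_log_sd: float = 0.05  # lognormal spread of specimen scale factors
    n_per_group: int = 20
    seed: int = DEFAULT_SEED

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be at least 1")


@dataclass
class GroupedShapeSample:
    """Simulated specimens with group labels and true generating directions."""

    configs: np.ndarray  # (n, K, 3)
    labels: np.ndarray  # (n,)
    centroid_sizes: np.ndarray  # (n,) true sizes before random motion... nominal
    effect_directions: dict  # group -> unit (3K,) shape direction
    template: LandmarkSet

    def landmark_sets(self) -> list[LandmarkSet]:
        return [
            LandmarkSet(f"{lab}_{i}", c, curves=dict(self.template.curves))
            for i, (c, lab) in enumerate(zip(self.configs, self.labels))
        ]


def simulate_shape_groups(spec: ShapeSimSpec) -> GroupedShapeSample:
    """Draw grouped landmark samples: template + group effect + allometry +
    Gaussian noise, then a random rigid motion and scaling per specimen."""
    rng = np.random.default_rng(spec.seed)
    x0 = spec.template.coords - spec.template.coords.mean(axis=0)
    k = len(x0)
    directions, magnitudes = {}, {}
    for g, eff in spec.group_effects.items():
        if isinstance(eff, (tuple, list)) and len(eff) == 2:
            vec, mag = np.asarray(eff[0], float).ravel(), float(eff[1])
        else:
            vec, mag = rng.standard_normal(3 * k), float(eff)
        directions[g] = _orthogonalized_direction(vec, x0)
        magnitudes[g] = mag
    allo_dir = _orthogonalized_direction(rng.standard_normal(3 * k), x0)

    configs, labels, sizes = [], [], []
    for g in spec.group_effects:
        for _ in range(spec.n_per_group):
            logc = rng.normal(0.0, spec.size_log_sd)
            shape = (
                x0.ravel()
                + magnitudes[g] * directions[g]
                + spec.allometry_slope * logc * allo_dir
                + rng.normal(0.0, spec.noise_sd, 3 * k)
            ).reshape(k, 3)
            # random similarity motion: rotation, translation, scale
            q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
            if np.linalg.det(q) < 0:
                q[:, 0] = -q[:, 0]
            scale = np.exp(logc)
            moved = scale * shape @ q.T + rng.uniform(-10, 10, 3)
            c = moved - moved.mean(axis=0)
            sizes.append(float(np.sqrt((c**2).sum())))
            configs.append(moved)
            labels.append(g)
    return GroupedShapeSample(
        np.stack(configs), np.asarray(labels), np.asarray(sizes), directions, spec.template
    )


# ---------------------------------------------------------------------------
# tooth phantoms


@dataclass
class PhantomSpec:
    """Constructive-solid-geometry tooth phantom, z axis pointing occlusally.

    Branch cylinders sit at the bottom (z in [0, branch_height)), the stem
    above them, and an optional hemispherical crown (dentine core capped
    by enamel) on top of the stem. The pulp is an inner cylinder running
    the height of the stem. All compartment volumes have closed forms.
    """

    stem_radius: float = 4.0
    stem_height: float = 6.0
    n_branches: int = 2
    branch_radius: float = 1.5
    branch_height: float = 6.0
    crown_radius: float | None = 4.5  # dentine core radius; None = no crown
    enamel_thickness: float = 1.0
    pulp_radius: float = 1.2
    voxel_size: float = 0.1

    def branch_centers(self) -> np.ndarray:
        if self.n_branches == 1:
            return np.zeros((1, 2))
        ang = 2 * np.pi * np.arange(self.n_branches) / self.n_branches
        off = self.stem_radius - self.branch_radius
        return off * np.column_stack([np.cos(ang), np.sin(ang)])

    def analytic_volumes(self) -> dict:
        v = {
            "stem_total": np.pi * self.stem_radius**2 * self.stem_height,
            "pulp": np.pi * self.pulp_radius**2 * self.stem_height,
            "branch_total": self.n_branches
            * np.pi
            * self.branch_radius**2
            * self.branch_height,
        }
        v["stem_dentine"] = v["stem_total"] - v["pulp"]
        if self.crown_radius is not None:
            rd, t = self.crown_radius, self.enamel_thickness
            v["crown_dentine"] = 2.0 / 3.0 * np.pi * rd**3
            v["enamel"] = 2.0 / 3.0 * np.pi * ((rd + t) ** 3 - rd**3)
        v["vbi_true"] = 100.0 * v["stem_total"] / (v["stem_total"] + v["branch_total"])
        return v


def simulate_tooth_phantom(spec: PhantomSpec) -> tuple[LabeledVolume, dict]:
    """Voxelize a tooth phantom; returns the volume and its analytic ground truth.

    Raises if any feature (enamel thickness, branch/pulp radius, branch
    separation) spans fewer than 3 voxels.
    """
    vs = spec.voxel_size
    features = {
        "branch_radius": spec.branch_radius,
        "pulp_radius": spec.pulp_radius,
        "stem_radius": spec.stem_radius,
    }
    if spec.crown_radius is not None:
        features["enamel_thickness"] = spec.enamel_thickness
    centers2d = spec.branch_centers()
    if spec.n_branches > 1:
        gaps = [
            np.linalg.norm(centers2d[i] - centers2d[j]) - 2 * spec.branch_radius
            for i in range(spec.n_branches)
            for j in range(i + 1, spec.n_branches)
        ]
        features["branch_separation"] = min(gaps)
    thin = min(features.values())
    if thin < 3 * vs:
        worst = min(features, key=features.get)
        raise ValueError(
            f"feature {worst!r} ({features[worst]:.3f} mm) spans fewer than 3 voxels; "
            f"need voxel_size <= {features[worst] / 3:.4f} mm"
        )

    r_outer = (spec.crown_radius or 0) + (spec.enamel_thickness if spec.crown_radius else 0)
    half_xy = max(spec.stem_radius, r_outer, np.abs(centers2d).max() + spec.branch_radius)
    margin = 2 * vs
    z_top = spec.branch_height + spec.stem_height + (r_outer if spec.crown_radius else 0)
    nx = int(np.ceil(2 * (half_xy + margin) / vs))
    nz = int(np.ceil((z_top + 2 * margin) / vs))
    x = (np.arange(nx) + 0.5) * vs - (half_xy + margin)
    z = (np.arange(nz) + 0.5) * vs - margin
    xx, yy = np.meshgrid(x, x, indexing="ij")
    rho2 = xx**2 + yy**2
    labels = np.zeros((nx, nx, nz), dtype=np.int16)

    zb0, zb1 = 0.0, spec.branch_height
    zs1 = zb1 + spec.stem_height
    in_branch_z = (z > zb0) & (z <= zb1)
    in_stem_z = (z > zb1) & (z <= zs1)
    branch_mask2d = np.zeros_like(rho2, dtype=bool)
    for cx, cy in centers2d:
        branch_mask2d |= (xx - cx) ** 2 + (yy - cy) ** 2 <= spec.branch_radius**2
    stem_mask2d = rho2 <= spec.stem_radius**2
    pulp_mask2d = rho2 <= spec.pulp_radius**2
    labels[:, :, in_branch_z] = np.where(branch_mask2d[:, :, None], DENTINE, BACKGROUND)
    stem_layer = np.where(
        pulp_mask2d, PULP, np.where(stem_mask2d, DENTINE, BACKGROUND)
    ).astype(np.int16)
    labels[:, :, in_stem_z] = stem_layer[:, :, None]

    if spec.crown_radius is not None:
        rd, t = spec.crown_radius, spec.enamel_thickness
        zc = zs1  # crown hemisphere base
        crown_z = (z > zc) & (z <= zc + rd + t)
        zz = z[crown_z] - zc
        d2 = rho2[:, :, None] + zz[None, None, :] ** 2
        crown = np.where(
            d2 <= rd**2, DENTINE, np.where(d2 <= (rd + t) ** 2, ENAMEL, BACKGROUND)
        ).astype(np.int16)
        labels[:, :, crown_z] = crown

    truth = spec.analytic_volumes()
    # plane positions in the volume's own frame (voxel centre = (i+0.5)*vs):
    # geometry z=0 sits `margin` above the grid origin
    truth["z_branch_base"] = margin
    truth["z_bifurcation"] = margin + spec.branch_height
    truth["z_cervix"] = margin + spec.branch_height + spec.stem_height
    truth["xy_center"] = half_xy + margin
    return LabeledVolume(labels, vs), truth


def cylindrical_shell_phantom(
    outer_radius: float,
    inner_radius: float,
    height: float,
    voxel_size: float,
    pulp_radius: float = 0.0,
) -> tuple[LabeledVolume, dict]:
    """Concentric cylinder phantom: enamel shell around a dentine core.

    Ground truth (closed form): shell volume ``pi (R² - r²) h``, inner
    (EDJ) lateral area ``2 pi r h``, so the analytic average enamel
    thickness is their ratio.
    """
    if not 0 <= pulp_radius < inner_radius < outer_radius:
        raise ValueError("need pulp_radius < inner_radius < outer_radius")
    vs = voxel_size
    margin = 2 * vs
    half = outer_radius + margin
    nx = int(np.ceil(2 * half / vs))
    nz = int(np.ceil((height + 2 * margin) / vs))
    x = (np.arange(nx) + 0.5) * vs - half
    z = (np.arange(nz) + 0.5) * vs - margin
    xx, yy = np.meshgrid(x, x, indexing="ij")
    rho2 = xx**2 + yy**2
    layer = np.where(
        rho2 <= pulp_radius**2,
        PULP,
        np.where(
            rho2 <= inner_radius**2,
            DENTINE,
            np.where(rho2 <= outer_radius**2, ENAMEL, BACKGROUND),
        ),
    ).astype(np.int16)
    labels = np.zeros((nx, nx, nz), dtype=np.int16)
    inz = (z > 0) & (z <= height)
    labels[:, :, inz] = layer[:, :, None]
    truth = {
        "v_enamel": np.pi * (outer_radius**2 - inner_radius**2) * height,
        "v_dentine_pulp": np.pi * inner_radius**2 * height,
        "s_edj": 2 * np.pi * inner_radius * height,
    }
    truth["laet"] = truth["v_enamel"] / truth["s_edj"]
    truth["lret"] = 100.0 * truth["laet"] / truth["v_dentine_pulp"] ** (1.0 / 3.0)
    truth["z_base"] = margin  # grid-frame z of the cylinder base plane
    truth["z_top"] = margin + height
    truth["xy_center"] = half
    return LabeledVolume(labels, vs), truth


# ---------------------------------------------------------------------------
# lithics and comparative statistics

DEFAULT_LITHIC_MEANS = {
    # plausible Levallois point / core calliper means (mm)
    "Levallois point": {
        "length": 55.0, "width": 32.0, "proximal_width": 28.0, "medial_width": 32.0,
        "distal_width": 18.0, "medial_thickness": 8.0, "distal_thickness": 5.0,
        "platform_width": 20.0, "platform_thickness": 9.0, "platform_angle": 75.0,
    },
    "Nubian point": {
        "length": 58.0, "width": 30.0, "proximal_width": 27.0, "medial_width": 30.0,
        "distal_width": 15.0, "medial_thickness": 9.0, "distal_thickness": 5.5,
        "platform_width": 21.0, "platform_thickness": 10.0, "platform_angle": 78.0,
    },
}


def simulate_lithic_assemblages(
    n_per_class: int,
    class_means: dict | None = None,
    noise_cv: float = 0.15,
    seed: int = DEFAULT_SEED,
    assemblage: str = "SIM",
) -> pd.DataFrame:
    """Lognormal metric draws around per-class means, CV ``noise_cv``.

    The lognormal is mean-parameterized (``mu = ln m - s²/2``) so the
    expected value of every column equals the requested class mean;
    ``noise_cv = 0`` returns the means exactly.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be nonnegative")
    if n_per_class < 1:
        raise ValueError("n_per_class must be at least 1")
    class_means = class_means or DEFAULT_LITHIC_MEANS
    for cls, means in class_means.items():
        if any(m <= 0 for m in means.values()):
            raise ValueError(f"class {cls!r} has non-positive means")
    rng = np.random.default_rng(seed)
    sigma2 = np.log1p(noise_cv**2)
    rows = []
    for cls, means in class_means.items():
        for _ in range(n_per_class):
            row = {"assemblage": assemblage, "class": cls}
            for var, m in means.items():
                mu = np.log(m) - sigma2 / 2
                row[var] = float(np.exp(rng.normal(mu, np.sqrt(sigma2))))
            rows.append(row)
    return pd.DataFrame(rows)


def simulate_comparative_sample(
    mean: float, sd: float, n: int, seed: int = DEFAULT_SEED,
    group: str = "SIM", variable: str = "var",
) -> tuple[np.ndarray, ComparativeStats]:
    """Normal draws plus their (mean, sample SD, n) summary.

    The returned statistics are recomputed from the draws (sample SD,
    n−1 denominator), not echoed from the inputs.
    """
    if sd < 0:
        raise ValueError("sd must be nonnegative")
    if n < 2:
        raise ValueError("n must be at least 2")
    rng = np.random.default_rng(seed)
    draws = rng.normal(mean, sd, n)
    return draws, ComparativeStats(
        group, variable, float(draws.mean()), float(draws.std(ddof=1)), int(n)
    )
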