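"""Digital tissue phantoms: seeded 2-D axial slices of a tumor-bearing
mouse abdomen.

Each phantom is a labeled tissue map plus per-pixel maps of the
refractive-index decrement delta and the linear attenuation coefficient mu
at the scene energy, the two quantities a phase-contrast CT scan measures.
A third map carries a per-tissue small-angle-scattering strength that the
forward model turns into visibility loss (bone scatters strongly, which is
what seeds streaks in the phase reconstruction).

Scenes
------
``mouse_abdomen``
    Elliptical soft-tissue body containing one solid-tumor blob, one large
    cystic lesion (fluid core wrapped in a two-sector wall of fibrotic and
    cell-rich stroma), one vertebral bone disc and a few air bubbles, all
    placements jittered by the seed.
``cylinder``
    A single centered disc of one tissue -- the analytic oracle scene
    (chord lengths through a disc are closed-form).
``bone_streak``
    Body ellipse plus the bone disc only, for streak-suppression studies.

The default delta values keep the realistic ordering and relative
contrasts of soft tissue at these energies (order 1e-7, bone severalfold
higher, solid tumor a ~10% delta step against soft tissue versus ~2% in
mu) but are globally scaled so that the differential-phase signal of the
default interferometer stays inside (-pi, pi): they are plausible-magnitude
configuration, not physics claims, and are fully overridable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import IntEnum

import numpy as np


class Tissue(IntEnum):
    AIR = 0
    SOFT_TISSUE = 1
    SOLID_TUMOR = 2
    CYST_FLUID = 3
    STROMA_FIBROTIC = 4
    STROMA_CELLRICH = 5
    BONE = 6
    AIR_BUBBLE = 7


@dataclass(frozen=True)
class TissueSpec:
    """Optical properties of one tissue class at the scene energy.

    delta: refractive-index decrement (dimensionless); mu: linear
    attenuation (1/cm); vis_loss: small-angle scattering strength (1/cm)
    that attenuates fringe visibility as exp(-vis_loss * path).
    """

    label: Tissue
    delta: float
    mu: float
    vis_loss: float = 0.0

    def __post_init__(self):
        if self.delta < 0 or self.mu < 0 or self.vis_loss < 0:
            raise ValueError("tissue coefficients must be non-negative")


_TABLE_23KEV = {
    Tissue.AIR: (0.0, 0.0, 0.0),
    Tissue.SOFT_TISSUE: (1.40e-7, 0.62, 0.0),
    Tissue.SOLID_TUMOR: (1.55e-7, 0.63, 0.0),
    Tissue.CYST_FLUID: (1.30e-7, 0.60, 0.0),
    Tissue.STROMA_FIBROTIC: (1.60e-7, 0.64, 0.0),
    Tissue.STROMA_CELLRICH: (1.48e-7, 0.625, 0.0),
    Tissue.BONE: (4.50e-7, 2.80, 30.0),
    Tissue.AIR_BUBBLE: (0.0, 0.0, 0.0),
}

# delta scales ~1/E^2, mu of soft tissue roughly halves from 23 to 35 keV,
# bone drops faster (photoelectric-dominated).  Placeholder magnitudes.
_TABLE_35KEV = {
    t: (d * (23.0 / 35.0) ** 2, m * (0.40 if t is Tissue.BONE else 0.55), v)
    for t, (d, m, v) in _TABLE_23KEV.items()
}


def tissue_table(
    energy_kev: float, overrides: dict | None = None
) -> dict[Tissue, TissueSpec]:
    """Default tissue table at 23 or 35 keV, with optional per-tissue patches.

    ``overrides`` maps a :class:`Tissue` (or its name) to a dict of field
    patches, e.g. ``{"bone": {"delta": 5e-7}}``; untouched tissues keep
    their defaults.  Unknown energies require a full override table.
    """
    if energy_kev == 23.0:
        base = _TABLE_23KEV
    elif energy_kev == 35.0:
        base = _TABLE_35KEV
    else:
        if overrides is None or set(_as_tissue(k) for k in overrides) != set(Tissue):
            raise ValueError(
                f"no default tissue table at {energy_kev} keV; supply a "
                "complete override table"
            )
        base = {t: (0.0, 0.0, 0.0) for t in Tissue}
    table = {
        t: TissueSpec(label=t, delta=d, mu=m, vis_loss=v)
        for t, (d, m, v) in base.items()
    }
    if overrides:
        for key, patch in overrides.items():
            t = _as_tissue(key)
            table[t] = replace(table[t], **patch)
    _check_table(table)
    return table


def _as_tissue(key) -> Tissue:
    if isinstance(key, Tissue):
        return key
    return Tissue[str(key).upper()]


def _check_table(table: dict[Tissue, TissueSpec]) -> None:
    non_air = [t for t in Tissue if t not in (Tissue.AIR, Tissue.AIR_BUBBLE)]
    if not all(
        table[Tissue.BONE].delta >= table[t].delta
        and table[Tissue.BONE].mu >= table[t].mu
        for t in non_air
    ):
        raise ValueError("bone must have the largest delta and mu")
    if not (
        table[Tissue.STROMA_FIBROTIC].delta != table[Tissue.STROMA_CELLRICH].delta
    ):
        raise ValueError("the two stroma classes need a nonzero delta contrast")


class LayoutError(ValueError):
    """A structure would cross the air border or leave the body."""


@dataclass
class PhantomSlice:
    """A phantom: label grid plus delta/mu/scatter maps and provenance."""

    labels: np.ndarray
    delta_map: np.ndarray
    mu_map: np.ndarray
    scatter_map: np.ndarray
    pixel_size_um: float
    energy_kev: float
    seed: int
    scene: str
    features: dict = field(default_factory=dict)

    @property
    def size(self) -> int:
        return self.labels.shape[0]


def _coverage_disc(n, ss, cx, cy, r):
    """Supersampled area coverage of a disc, in [0, 1] per pixel."""
    u = (np.arange(n * ss) + 0.5) / ss - 0.5
    X, Y = np.meshgrid(u, u, indexing="xy")
    mask = (X - cx) ** 2 + (Y - cy) ** 2 <= r * r
    return mask.reshape(n, ss, n, ss).mean(axis=(1, 3))


def _coverage_ellipse(n, ss, cx, cy, a, b):
    u = (np.arange(n * ss) + 0.5) / ss - 0.5
    X, Y = np.meshgrid(u, u, indexing="xy")
    mask = ((X - cx) / a) ** 2 + ((Y - cy) / b) ** 2 <= 1.0
    return mask.reshape(n, ss, n, ss).mean(axis=(1, 3))


def _coverage_annulus_sector(n, ss, cx, cy, r_in, r_out, phi0, phi1):
    """Annulus between r_in and r_out restricted to angles [phi0, phi1)."""
    u = (np.arange(n * ss) + 0.5) / ss - 0.5
    X, Y = np.meshgrid(u, u, indexing="xy")
    rr = (X - cx) ** 2 + (Y - cy) ** 2
    ang = np.mod(np.arctan2(Y - cy, X - cx) - phi0, 2 * np.pi)
    width = np.mod(phi1 - phi0, 2 * np.pi) or 2 * np.pi
    mask = (rr >= r_in**2) & (rr <= r_out**2) & (ang < width)
    return mask.reshape(n, ss, n, ss).mean(axis=(1, 3))


_SUPERSAMPLE = 4


class _Painter:
    """Paints tissues back-to-front with area-weighted (anti-aliased) edges.

    The value maps blend by coverage inside a one-pixel edge band; the
    label grid stores the majority (coverage > 0.5) tissue.
    """

    def __init__(self, n: int, table: dict[Tissue, TissueSpec]):
        self.n = n
        self.table = table
        self.labels = np.zeros((n, n), dtype=np.uint8)
        self.delta = np.zeros((n, n), dtype=np.float64)
        self.mu = np.zeros((n, n), dtype=np.float64)
        self.scatter = np.zeros((n, n), dtype=np.float64)

    def paint(self, tissue: Tissue, cov: np.ndarray) -> None:
        spec = self.table[tissue]
        self.delta = self.delta * (1 - cov) + spec.delta * cov
        self.mu = self.mu * (1 - cov) + spec.mu * cov
        self.scatter = self.scatter * (1 - cov) + spec.vis_loss * cov
        self.labels[cov > 0.5] = int(tissue)


def build_phantom(
    size: int,
    pixel_size_um: float = 30.0,
    energy_kev: float = 23.0,
    scene: str = "mouse_abdomen",
    seed: int = 0,
    tissues: dict[Tissue, TissueSpec] | None = None,
    scene_params: dict | None = None,
) -> PhantomSlice:
    """Build a seeded 2-D phantom slice.

    Structure placement is expressed in fractions of the grid size, so the
    anatomy scales with ``size``; the same seed and configuration always
    yields bit-identical grids.  An air border of at least 5% of the width
    is enforced on all sides.
    """
    if size < 64:
        raise ValueError("size must be at least 64 pixels")
    if pixel_size_um <= 0:
        raise ValueError("pixel size must be positive")
    table = tissues or tissue_table(energy_kev)
    params = dict(scene_params or {})
    rng = np.random.default_rng(seed)
    painter = _Painter(size, table)
    n, ss = size, _SUPERSAMPLE
    features: dict = {}

    border = 0.05 * n

    def check_inside_border(cx, cy, extent, what):
        # cx, cy are offsets from grid center
        if max(abs(cx), abs(cy)) + extent > n / 2.0 - border:
            raise LayoutError(f"{what} crosses the 5% air border")

    # coordinates below are offsets from grid center, in pixels
    c0 = (n - 1) / 2.0

    def cov_disc(cx, cy, r):
        return _coverage_disc(n, ss, cx + c0, cy + c0, r)

    def cov_ellipse(cx, cy, a, b):
        return _coverage_ellipse(n, ss, cx + c0, cy + c0, a, b)

    if scene == "cylinder":
        tissue = _as_tissue(params.pop("tissue", Tissue.SOFT_TISSUE))
        r = float(params.pop("radius_frac", 0.30)) * n / 2.0
        check_inside_border(0, 0, r, "cylinder")
        painter.paint(tissue, cov_disc(0.0, 0.0, r))
        features["cylinder"] = {"center_px": (0.0, 0.0), "radius_px": r, "tissue": tissue.name}
    elif scene in ("mouse_abdomen", "bone_streak"):
        jc = rng.uniform(-0.02, 0.02, size=2) * n
        ja = 1.0 + rng.uniform(-0.005, 0.005, size=2)
        body_a = params.pop("body_a_frac", 0.275) * n * ja[0]
        body_b = params.pop("body_b_frac", 0.21) * n * ja[1]
        bx, by = jc
        check_inside_border(bx, by, max(body_a, body_b), "body")
        painter.paint(Tissue.SOFT_TISSUE, cov_ellipse(bx, by, body_a, body_b))
        features["body"] = {"center_px": (bx, by), "axes_px": (body_a, body_b)}

        def inside_body(cx, cy, r, what):
            # structure plus one pixel of margin must stay inside the body
            f = ((cx - bx) / (body_a - r - 1)) ** 2 + ((cy - by) / (body_b - r - 1)) ** 2
            if body_a - r - 1 <= 0 or body_b - r - 1 <= 0 or f > 1.0:
                raise LayoutError(f"{what} does not fit inside the body")

        bone_r = params.pop("bone_radius_frac", 0.020) * n
        bcx = bx + 0.01 * n + rng.uniform(-0.01, 0.01) * n
        bcy = by + 0.145 * n + rng.uniform(-0.005, 0.005) * n
        inside_body(bcx, bcy, bone_r, "bone")
        painter.paint(Tissue.BONE, cov_disc(bcx, bcy, bone_r))
        features["bone"] = {"center_px": (bcx, bcy), "radius_px": bone_r}

        if scene == "mouse_abdomen":
            tum_r = params.pop("tumor_radius_frac", 0.055) * n
            tx = bx - 0.12 * n + rng.uniform(-0.01, 0.01) * n
            ty = by - 0.06 * n + rng.uniform(-0.01, 0.01) * n
            inside_body(tx, ty, tum_r, "solid tumor")
            painter.paint(Tissue.SOLID_TUMOR, cov_disc(tx, ty, tum_r))
            features["solid_tumor"] = {"center_px": (tx, ty), "radius_px": tum_r}

            core_r = params.pop("cyst_core_radius_frac", 0.062) * n
            wall_r = params.pop("cyst_wall_radius_frac", 0.085) * n
            cx = bx + 0.10 * n + rng.uniform(-0.01, 0.01) * n
            cy = by + 0.05 * n + rng.uniform(-0.01, 0.01) * n
            inside_body(cx, cy, wall_r, "cystic lesion")
            phi0 = rng.uniform(0, 2 * np.pi)
            painter.paint(
                Tissue.STROMA_FIBROTIC,
                _coverage_annulus_sector(
                    n, ss, cx + c0, cy + c0, core_r, wall_r, phi0, phi0 + np.pi
                ),
            )
            painter.paint(
                Tissue.STROMA_CELLRICH,
                _coverage_annulus_sector(
                    n, ss, cx + c0, cy + c0, core_r, wall_r, phi0 + np.pi, phi0
                ),
            )
            painter.paint(Tissue.CYST_FLUID, cov_disc(cx, cy, core_r))
            features["cystic_lesion"] = {
                "center_px": (cx, cy),
                "core_radius_px": core_r,
                "wall_radius_px": wall_r,
                "sector_start_rad": phi0,
            }

            n_bubbles = int(rng.integers(2, 6))
            spots = [(-0.17, 0.08), (0.0, -0.13), (-0.02, 0.10), (0.19, -0.05), (-0.20, -0.03)]
            bubbles = []
            for ux, uy in spots[:n_bubbles]:
                r = rng.uniform(0.012, 0.018) * n
                px = bx + ux * n + rng.uniform(-0.008, 0.008) * n
                py = by + uy * n + rng.uniform(-0.008, 0.008) * n
                inside_body(px, py, r, "air bubble")
                painter.paint(Tissue.AIR_BUBBLE, cov_disc(px, py, r))
                bubbles.append({"center_px": (px, py), "radius_px": r})
            features["air_bubbles"] = bubbles
            # homogeneous soft-tissue spot, kept clear of all structures
            features["soft_tissue_ref"] = {"center_px": (bx + 0.10 * n, by - 0.12 * n)}
            features["noise_roi"] = {"center_px": (bx - 0.05 * n, by + 0.10 * n)}
        else:
            features["soft_tissue_ref"] = {"center_px": (bx - 0.12 * n, by - 0.06 * n)}
            features["noise_roi"] = {"center_px": (bx - 0.05 * n, by - 0.10 * n)}
    else:
        raise ValueError(f"unknown scene {scene!r}")
    if params:
        raise ValueError(f"unused scene parameters: {sorted(params)}")

    return PhantomSlice(
        labels=painter.labels,
        delta_map=painter.delta,
        mu_map=painter.mu,
        scatter_map=painter.scatter,
        pixel_size_um=float(pixel_size_um),
        energy_kev=float(energy_kev),
        seed=int(seed),
        scene=scene,
        features=features,
    )
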