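"""Forward model: parallel-beam projection and phase-stepping acquisition.

The measurement chain of a grating interferometer is simulated in three
steps that mirror the bench:

1. :func:`project` -- parallel-beam line integrals of the phantom's mu and
   delta maps (rotate-and-sum Radon transform), giving the attenuation
   sinogram A = integral of mu ds and the wavefront phase sinogram
   Phi = (2 pi / lambda) integral of delta ds.  A small-angle-scattering
   sinogram yields the per-ray relative fringe visibility.
2. :func:`stepping_phase` -- the interferometer converts the transverse
   wavefront gradient into a stepping-curve phase: phi = (lambda d / p2)
   dPhi/dx, with the derivative taken as a central difference over the
   detector pitch.
3. :func:`simulate_stepping` -- K equispaced grating positions over one
   period produce intensities I_k = I0 T [1 + V v cos(2 pi k / K + phi)]
   for the sample scan and I0 [1 + V cos(2 pi k / K)] for the flat scan,
   with optional Poisson noise.

Parallel-beam geometry is used for both the synchrotron and the tube
virtual settings: the sample is small against the source distance and both
are reconstructed with standard FBP.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.transform import radon

from .optics import InterferometerDesign, tube_design
from .phantom import PhantomSlice


class TruncationError(ValueError):
    """Requested detector does not span the phantom diagonal."""


@dataclass(frozen=True)
class AcquisitionConfig:
    """Scan protocol: angles over [0, pi), K phase steps, flux per step."""

    n_projections: int = 301
    n_steps: int = 10
    flux: float = 1e4
    design: InterferometerDesign = field(default_factory=tube_design)
    seed: int = 0
    noiseless: bool = False

    def __post_init__(self):
        if self.n_steps < 3:
            raise ValueError("need at least 3 phase steps")
        if self.n_projections < 1:
            raise ValueError("need at least one projection")
        if not self.flux > 0:
            raise ValueError("flux must be positive")


@dataclass
class Projections:
    """Noise-free sinograms on the (angle, detector pixel) grid."""

    att_sino: np.ndarray  # line integrals of mu, dimensionless
    phase_sino: np.ndarray  # wavefront phase Phi, radians
    vis_sino: np.ndarray  # relative visibility per ray, in (0, 1]
    angles_deg: np.ndarray
    detector_pitch_um: float

    def __iter__(self):  # unpack as (att, phase)
        return iter((self.att_sino, self.phase_sino))


@dataclass
class SteppingScan:
    """Raw phase-stepping intensities for a sample scan and a flat scan."""

    sample_intensities: np.ndarray  # (step, angle, pixel)
    flat_intensities: np.ndarray  # (step, pixel)
    config: AcquisitionConfig
    angles_deg: np.ndarray
    detector_pitch_um: float


def project(
    phantom: PhantomSlice,
    n_projections: int,
    n_detector_pixels: int | None = None,
    energy_kev: float | None = None,
) -> Projections:
    """Parallel-beam line integrals of the phantom at angles j*pi/N.

    The detector pixel equals the phantom pixel and the detector spans the
    padded grid diagonal; asking for fewer pixels raises
    :class:`TruncationError`.  Attenuation line integrals are in cm, the
    wavefront phase uses the scene energy unless overridden.
    """
    angles_deg = np.arange(n_projections) * (180.0 / n_projections)
    px_cm = phantom.pixel_size_um * 1e-4
    att = radon(phantom.mu_map, theta=angles_deg, circle=False).T * px_cm
    energy = phantom.energy_kev if energy_kev is None else energy_kev
    lam_um = 12.39842 / energy * 1e-4
    delta_int = radon(phantom.delta_map, theta=angles_deg, circle=False).T
    phase = (2.0 * np.pi / lam_um) * delta_int * phantom.pixel_size_um
    scat = radon(phantom.scatter_map, theta=angles_deg, circle=False).T * px_cm
    vis = np.exp(-scat)
    n_natural = att.shape[1]
    if n_detector_pixels is not None:
        if n_detector_pixels < n_natural:
            raise TruncationError(
                f"detector of {n_detector_pixels} px does not span the "
                f"phantom diagonal ({n_natural} px)"
            )
        extra = n_detector_pixels - n_natural
        pad = (extra // 2, extra - extra // 2)
        att = np.pad(att, ((0, 0), pad))
        phase = np.pad(phase, ((0, 0), pad))
        vis = np.pad(vis, ((0, 0), pad), constant_values=1.0)
    return Projections(
        att_sino=att,
        phase_sino=phase,
        vis_sino=vis,
        angles_deg=angles_deg,
        detector_pitch_um=phantom.pixel_size_um,
    )


def stepping_phase(
    phase_sino: np.ndarray,
    design: InterferometerDesign,
    detector_pitch_um: float,
) -> np.ndarray:
    """Stepping-curve phase phi = (lambda d / p2) * dPhi/dx, radians.

    Central differences over the detector pitch in the interior, one-sided
    at the edges.  Emits a warning when |phi| exceeds pi anywhere: the
    retrieval cannot distinguish wrapped phases and no unwrapping is
    applied downstream.
    """
    if design.d_mm is None or design.p2_um is None:
        raise ValueError("design must have d and p2 populated")
    grad = np.gradient(np.asarray(phase_sino, dtype=float), detector_pitch_um, axis=-1)
    phi = design.phase_sensitivity_um() * grad
    if np.any(np.abs(phi) > np.pi):
        warnings.warn(
            f"differential phase wraps: max |phi| = {np.abs(phi).max():.2f} rad "
            "> pi; reconstruction will be biased",
            RuntimeWarning,
            stacklevel=2,
        )
    return phi


def simulate_stepping(
    att_sino: np.ndarray,
    phi_sino: np.ndarray,
    config: AcquisitionConfig,
    vis_sino: np.ndarray | None = None,
    detector_pitch_um: float = 1.0,
    angles_deg: np.ndarray | None = None,
) -> SteppingScan:
    """Simulate the K-step scan of sample and flat field.

    Steps sample exactly one grating period endpoint-exclusive (k/K), so
    the first discrete Fourier component of a noiseless stepping curve is
    exact.  Poisson noise is applied unless ``config.noiseless``; the flat
    field uses an independent sub-seed derived from the scan seed.
    """
    att = np.asarray(att_sino, dtype=float)
    phi = np.asarray(phi_sino, dtype=float)
    if att.shape != phi.shape:
        raise ValueError("attenuation and phase sinograms must share shape")
    v = np.ones_like(att) if vis_sino is None else np.asarray(vis_sino, dtype=float)
    K = config.n_steps
    V = config.design.design_visibility
    T = np.exp(-att)
    k = np.arange(K).reshape(-1, 1, 1)
    sample = config.flux * T * (1.0 + V * v * np.cos(2 * np.pi * k / K + phi))
    flat = config.flux * (1.0 + V * np.cos(2 * np.pi * np.arange(K).reshape(-1, 1) / K))
    flat = np.broadcast_to(flat, (K, att.shape[1])).copy()
    if not config.noiseless:
        ss_sample, ss_flat = np.random.SeedSequence(config.seed).spawn(2)
        sample = np.random.default_rng(ss_sample).poisson(sample).astype(float)
        flat = np.random.default_rng(ss_flat).poisson(flat).astype(float)
    if angles_deg is None:
        angles_deg = np.arange(att.shape[0]) * (180.0 / att.shape[0])
    return SteppingScan(
        sample_intensities=sample,
        flat_intensities=flat,
        config=config,
        angles_deg=np.asarray(angles_deg, dtype=float),
        detector_pitch_um=float(detector_pitch_um),
    )


def acquire(phantom: PhantomSlice, config: AcquisitionConfig) -> SteppingScan:
    """Project a phantom and simulate the full phase-stepping scan."""
    proj = project(phantom, config.n_projections)
    phi = stepping_phase(proj.phase_sino, config.design, proj.detector_pitch_um)
    return simulate_stepping(
        proj.att_sino,
        phi,
        config,
        vis_sino=proj.vis_sino,
        detector_pitch_um=proj.detector_pitch_um,
        angles_deg=proj.angles_deg,
    )
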