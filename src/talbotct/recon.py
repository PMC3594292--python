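"""Phase-stepping retrieval and filtered backprojection.

Retrieval reduces each pixel's K-step intensity curve to its zeroth and
first discrete Fourier components, giving three sinograms per scan:
transmission T (attenuation contrast), differential phase phi, and the
relative visibility v (the dark-field channel, used here only to weight
the phase sinogram).

Reconstruction is standard parallel-beam FBP.  Attenuation uses the ramp
(Ram-Lak) filter on -ln T.  The differential phase sinogram is first
rescaled to the transverse derivative of the delta line integral,
g = phi * p2 / (2 pi d), and then filtered with the Hilbert-type kernel
whose frequency response is sgn(f) / (2 pi i) -- the ramp divided by the
2 pi i f that differentiation contributes -- so the same backprojector
returns the refractive-index decrement delta directly.

Streak suppression: strongly scattering structures (bone) depress the
visibility, so multiplying the phase sinogram by the squared relative
visibility down-weights exactly the noisy rays that cause streaks.  The
weighted sinogram is deliberately not renormalized: the step reduces
streak magnitude at the price of a local bias, so quantitative analyses
use the unweighted reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .forward import SteppingScan
from .optics import InterferometerDesign


class RetrievalError(RuntimeError):
    pass


@dataclass
class SinogramSet:
    """Retrieved sinograms on the common (angle, pixel) grid."""

    transmission: np.ndarray
    dphase: np.ndarray
    rel_visibility: np.ndarray
    angles_deg: np.ndarray
    detector_pitch_um: float
    design: InterferometerDesign | None = None
    meta: dict = field(default_factory=dict)


@dataclass
class ReconSlice:
    """Reconstructed, intrinsically co-registered mu and delta maps."""

    mu_map: np.ndarray  # 1/cm
    delta_map: np.ndarray  # dimensionless
    pixel_size_um: float
    provenance: dict = field(default_factory=dict)


_T_CLIP_MAX = 1.5


def stepping_visibility(intensities: np.ndarray) -> np.ndarray:
    """Fringe visibility of stepping curves: 2 |c1| / a0 along axis 0.

    For a noiseless curve a (1 + V cos(2 pi k / K + phi)) sampled at K >= 3
    equispaced steps over one period this returns V exactly.
    """
    arr = np.asarray(intensities, dtype=float)
    K = arr.shape[0]
    basis = np.exp(-2j * np.pi * np.arange(K) / K)
    a0 = arr.mean(axis=0)
    c1 = np.tensordot(basis, arr, axes=(0, 0)) / K
    return 2.0 * np.abs(c1) / a0


def retrieve(scan: SteppingScan) -> SinogramSet:
    """Fourier analysis of the stepping curves of sample and flat scans.

    Per pixel and angle: a0 is the mean over steps, c1 the first discrete
    Fourier coefficient.  T = a0_sample / a0_flat, phi is the wrapped
    argument difference of c1, and v the sample-to-flat ratio of |c1|/a0.
    Transmission is clipped to (0, 1.5]; noisy flats can push T slightly
    above one, and the clip count is reported in the metadata.
    """
    sample = np.asarray(scan.sample_intensities, dtype=float)
    flat = np.asarray(scan.flat_intensities, dtype=float)
    K = sample.shape[0]
    if K < 3:
        raise RetrievalError("need at least 3 phase steps")
    basis = np.exp(-2j * np.pi * np.arange(K) / K)
    a0_s = sample.mean(axis=0)
    c1_s = np.tensordot(basis, sample, axes=(0, 0)) / K
    a0_f = flat.mean(axis=0)
    c1_f = np.tensordot(basis, flat, axes=(0, 0)) / K
    if np.any(a0_f <= 0):
        raise RetrievalError("flat field contains zero-intensity pixels")
    a0_s = np.maximum(a0_s, np.finfo(float).tiny)
    T = a0_s / a0_f[None, :]
    n_clipped = int(np.count_nonzero(T > _T_CLIP_MAX))
    T = np.clip(T, np.finfo(float).tiny, _T_CLIP_MAX)
    phi = np.angle(c1_s * np.conj(c1_f)[None, :])
    vis_flat = np.abs(c1_f) / a0_f
    if np.any(vis_flat <= 0):
        raise RetrievalError("flat field has zero visibility")
    v = (np.abs(c1_s) / a0_s) / vis_flat[None, :]
    return SinogramSet(
        transmission=T,
        dphase=phi,
        rel_visibility=v,
        angles_deg=scan.angles_deg.copy(),
        detector_pitch_um=scan.detector_pitch_um,
        design=scan.config.design,
        meta={
            "n_transmission_clipped": n_clipped,
            "seed": scan.config.seed,
            "n_steps": K,
        },
    )


def _apply_filter(
    sino: np.ndarray, pitch: float, kind: str, window: str | None = None
) -> np.ndarray:
    """Frequency-domain filtering of each projection row.

    Rows are zero-padded to the next power of two at least twice the
    detector width.  ``kind='ramp'`` multiplies by |f| (units 1/length,
    with f from the physical pitch); ``kind='hilbert'`` by the
    dimensionless sgn(f) / (2 pi i).  An optional Hann window apodizes the
    response; the default is the bare filter.
    """
    n = sino.shape[-1]
    npad = 1 << int(np.ceil(np.log2(2 * n)))
    f = np.fft.rfftfreq(npad, d=pitch)
    if kind == "ramp":
        H = np.abs(f).astype(complex)
    elif kind == "hilbert":
        H = np.sign(f) / (2j * np.pi)
    else:
        raise ValueError(f"unknown filter kind {kind!r}")
    if window == "hann":
        H = H * (0.5 + 0.5 * np.cos(np.pi * f / max(f.max(), 1e-300)))
    elif window is not None:
        raise ValueError(f"unknown window {window!r}")
    spec = np.fft.rfft(sino, n=npad, axis=-1)
    out = np.fft.irfft(spec * H, n=npad, axis=-1)[..., :n]
    return np.ascontiguousarray(out)


def _backproject(
    filtered: np.ndarray, angles_deg: np.ndarray, output_size: int
) -> np.ndarray:
    """Linear-interpolation backprojection with Delta-theta = pi/N weight.

    Geometry matches the rotate-and-sum forward projector: detector
    coordinate s = X cos(theta) - Y sin(theta), with X, Y pixel offsets
    from the grid center (n // 2 convention) and s centered on the
    detector midpoint.
    """
    n_angles, n_det = filtered.shape
    c_out = output_size // 2
    c_det = n_det // 2
    ax = np.arange(output_size) - c_out
    X, Y = np.meshgrid(ax, ax, indexing="xy")
    recon = np.zeros((output_size, output_size), dtype=float)
    for j, ang in enumerate(np.deg2rad(angles_deg)):
        s = X * np.cos(ang) - Y * np.sin(ang) + c_det
        i0 = np.floor(s).astype(np.int64)
        frac = s - i0
        i0 = np.clip(i0, 0, n_det - 2)
        q = filtered[j]
        recon += q[i0] * (1.0 - frac) + q[i0 + 1] * frac
    return recon * (np.pi / n_angles)


def fbp_attenuation(
    sinos: SinogramSet,
    output_size: int | None = None,
    window: str | None = None,
) -> np.ndarray:
    """Ram-Lak FBP of -ln T; returns mu in 1/cm."""
    T = sinos.transmission
    if np.any(T <= 0):
        raise ValueError("transmission must be positive")
    p = -np.log(T)  # line integrals in cm (pitch handled in the filter)
    pitch_cm = sinos.detector_pitch_um * 1e-4
    q = _apply_filter(p, pitch_cm, "ramp", window)
    n_out = output_size or T.shape[1]
    return _backproject(q, sinos.angles_deg, n_out)


def fbp_phase(
    sinos: SinogramSet,
    design: InterferometerDesign | None = None,
    output_size: int | None = None,
    window: str | None = None,
    weight_visibility: bool = False,
) -> np.ndarray:
    """Hilbert-filter FBP of the differential phase; returns delta.

    The phase sinogram is converted to the transverse derivative of the
    delta line integral, g = phi p2 / (2 pi d) (dimensionless), filtered
    with sgn(f)/(2 pi i) and backprojected.  ``weight_visibility`` applies
    the squared-visibility streak suppression first.
    """
    design = design or sinos.design
    if design is None or design.d_mm is None or design.p2_um is None:
        raise ValueError("interferometer design with d and p2 required")
    phi = sinos.dphase
    if weight_visibility:
        phi = visibility_weighting(phi, sinos.rel_visibility)
    g = phi * design.p2_um / (2.0 * np.pi * design.d_mm * 1e3)
    q = _apply_filter(g, sinos.detector_pitch_um, "hilbert", window)
    n_out = output_size or phi.shape[1]
    return _backproject(q, sinos.angles_deg, n_out)


def visibility_weighting(phi_sino: np.ndarray, vis_sino: np.ndarray) -> np.ndarray:
    """Weight the phase sinogram by the squared relative visibility.

    Rays through strong small-angle scatterers (bone) lose fringe
    visibility, so their noisy phase samples get weight v^2 <= 1.  Not
    renormalized; see module docstring.
    """
    phi = np.asarray(phi_sino, dtype=float)
    v = np.asarray(vis_sino, dtype=float)
    if phi.shape != v.shape:
        raise ValueError("phase and visibility sinograms must share shape")
    return phi * np.clip(v, 0.0, 1.0) ** 2


def sharpen(image: np.ndarray, amount: float = 1.0, radius: float = 1.0) -> np.ndarray:
    """Unsharp mask: out = in + amount * (in - Gaussian_radius(in))."""
    if amount < 0:
        raise ValueError("amount must be non-negative")
    if not radius > 0:
        raise ValueError("radius must be positive")
    img = np.asarray(image, dtype=float)
    return img + amount * (img - gaussian_filter(img, sigma=radius))


def reconstruct(
    sinos: SinogramSet,
    output_size: int | None = None,
    weight_visibility: bool = False,
    sharpen_amount: float = 0.0,
    sharpen_radius: float = 1.0,
    window: str | None = None,
) -> ReconSlice:
    """Reconstruct both contrasts from one retrieved scan.

    The two maps come from the same sinogram grid and are therefore
    pixel-registered by construction; the provenance records the settings.
    """
    mu = fbp_attenuation(sinos, output_size, window)
    delta = fbp_phase(sinos, None, output_size, window, weight_visibility)
    if sharpen_amount > 0:
        mu = sharpen(mu, sharpen_amount, sharpen_radius)
        delta = sharpen(delta, sharpen_amount, sharpen_radius)
    return ReconSlice(
        mu_map=mu,
        delta_map=delta,
        pixel_size_um=sinos.detector_pitch_um,
        provenance={
            "weight_visibility": weight_visibility,
            "sharpen_amount": sharpen_amount,
            "sharpen_radius": sharpen_radius,
            "window": window,
            "registered": True,
            **sinos.meta,
        },
    )
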