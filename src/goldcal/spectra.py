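"""Micrograph I/O, power spectra, radial profiles, whitening and peak finding.

The calibration signal is the polycrystalline Bragg ring in the power
spectrum of a micrograph of the gold (or carbon) foil.  The chain here is:
load the motion-corrected micrograph, take the squared modulus of its
Fourier transform, flatten the radially decaying background by noise
whitening, and locate the ring radius to sub-pixel precision.  Whitening
matters because the background (detector MTF plus low-angle scattering)
falls with spatial frequency, which drags the apparent maximum of a weak
peak toward the centre of the transform and would bias the pixel size low.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import FitError, NoPeakError
from .mrcio import read_mrc

__all__ = [
    "Micrograph",
    "PowerSpectrum2D",
    "RadialProfile",
    "RingPeak",
    "load_micrograph",
    "power_spectrum",
    "accumulate",
    "radial_profile",
    "whiten",
    "find_ring_peak",
    "expected_radius",
]


@dataclass
class Micrograph:
    """A single real-valued micrograph with its nominal pixel size (Å)."""

    pixels: np.ndarray
    nominal_pixel_size: float
    source_path: str = "<memory>"

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("micrograph must be 2D")
        if min(self.pixels.shape) < 64:
            raise ValueError(f"micrograph too small: {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("micrograph contains non-finite values")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class PowerSpectrum2D:
    """DC-centred accumulated 2D power spectrum.

    For even L the DC component sits at index (L/2, L/2); radii are measured
    from the centre of that bin.
    """

    values: np.ndarray
    L: int
    n_accumulated: int = 1
    pixel_size: float = 0.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (self.L, self.L):
            raise ValueError("power spectrum must be L x L")

    @property
    def center(self) -> tuple[float, float]:
        return (self.L // 2, self.L // 2)


@dataclass
class RadialProfile:
    """Mean power per unit-width annulus; only populated bins are kept."""

    radii: np.ndarray
    intensity: np.ndarray
    counts: np.ndarray

    def __post_init__(self):
        if not np.all(np.diff(self.radii) > 0):
            raise ValueError("radii must be strictly increasing")


@dataclass
class RingPeak:
    """Sub-pixel ring radius with its prominence over the whitened floor."""

    radius: float
    height: float
    window: tuple[float, float] = field(default=(0.0, 0.0))


def _center_crop_square(arr: np.ndarray) -> np.ndarray:
    h, w = arr.shape[-2:]
    n = min(h, w)
    if h == w:
        return arr
    top = (h - n) // 2
    left = (w - n) // 2
    return arr[..., top : top + n, left : left + n]


def load_micrograph(
    path: str | Path,
    override_pixel_size: float | None = None,
    stack: str = "mean",
) -> Micrograph | list[Micrograph]:
    """Load an MRC2014 micrograph (or stack) as Micrograph(s).

    Non-square images are centre-cropped to square with a warning.  For a
    stack, ``stack="mean"`` averages the frames into one micrograph and
    ``stack="frames"`` returns one Micrograph per frame.  The pixel size
    comes from the header unless overridden.
    """
    data, header_px = read_mrc(path)
    px = override_pixel_size if override_pixel_size is not None else header_px
    if data.ndim == 3 and data.shape[-2] != data.shape[-1] or (
        data.ndim == 2 and data.shape[0] != data.shape[1]
    ):
        warnings.warn(
            f"{path}: non-square image {data.shape[-2]}x{data.shape[-1]}, centre-cropping",
            stacklevel=2,
        )
        data = _center_crop_square(data)
    if data.ndim == 2:
        return Micrograph(data, px, str(path))
    if stack == "mean":
        return Micrograph(data.mean(axis=0), px, str(path))
    if stack == "frames":
        return [
            Micrograph(frame, px, f"{path}@{i}") for i, frame in enumerate(data)
        ]
    raise ValueError(f"unknown stack mode {stack!r}")


def power_spectrum(
    m: Micrograph, pad_to: int | None = None, apodize: bool = False
) -> PowerSpectrum2D:
    """|FFT|² of the mean-subtracted micrograph, DC-centred.

    ``pad_to`` zero-pads the image to a larger square before transforming
    (finer ring-radius sampling).  ``apodize`` applies a Hann window; off by
    default because windowing broadens Bragg peaks.
    """
    img = m.pixels - m.pixels.mean()
    if apodize:
        n = img.shape[0]
        w = np.hanning(n)
        img = img * np.outer(w, w)
    L = img.shape[0]
    if pad_to is not None:
        if pad_to < L:
            raise ValueError("pad_to smaller than image")
        padded = np.zeros((pad_to, pad_to))
        padded[:L, :L] = img
        img = padded
        L = pad_to
    ft = np.fft.fft2(img)
    ps = np.fft.fftshift((ft * ft.conj()).real)
    return PowerSpectrum2D(ps, L=L, n_accumulated=1, pixel_size=m.nominal_pixel_size)


def accumulate(spectra: list[PowerSpectrum2D]) -> PowerSpectrum2D:
    """Element-wise mean of same-size power spectra (weighted by n_accumulated)."""
    if not spectra:
        raise ValueError("no spectra to accumulate")
    L = spectra[0].L
    if any(s.L != L for s in spectra):
        raise ValueError("cannot accumulate spectra of different sizes")
    n = sum(s.n_accumulated for s in spectra)
    total = np.zeros((L, L))
    for s in spectra:
        total += s.values * s.n_accumulated
    return PowerSpectrum2D(
        total / n, L=L, n_accumulated=n, pixel_size=spectra[0].pixel_size
    )


def _radius_grid(L: int, center: tuple[float, float] | None = None) -> np.ndarray:
    cy, cx = (L // 2, L // 2) if center is None else center
    y = np.arange(L) - cy
    x = np.arange(L) - cx
    return np.hypot(y[:, None], x[None, :])


def radial_profile(
    ps: PowerSpectrum2D, center: tuple[float, float] | None = None
) -> RadialProfile:
    """Mean intensity in unit-width annuli about the (sub-pixel) centre."""
    L = ps.L
    if center is not None:
        cy, cx = center
        if not (0 <= cy < L and 0 <= cx < L):
            raise ValueError("center outside image")
    r = _radius_grid(L, center)
    bins = np.rint(r).astype(np.intp)
    nmax = bins.max() + 1
    counts = np.bincount(bins.ravel(), minlength=nmax)
    sums = np.bincount(bins.ravel(), weights=ps.values.ravel(), minlength=nmax)
    keep = counts > 0
    radii = np.arange(nmax)[keep].astype(np.float64)
    return RadialProfile(radii, sums[keep] / counts[keep], counts[keep])


def whiten(
    ps: PowerSpectrum2D,
    exclusion_windows: list[tuple[float, float]] | None = None,
    degree: int = 5,
    r_min_fraction: float = 0.02,
) -> PowerSpectrum2D:
    """Divide a power spectrum by a smooth radial background model.

    The background is a degree-``degree`` polynomial fitted to the log of
    the radial profile, with the given radius intervals (known Bragg rings)
    excluded from the fit, then exponentiated.  After whitening the noise
    floor fluctuates about 1, so Bragg peaks can be located without the
    low-frequency bias introduced by the decaying background.
    """
    exclusion_windows = exclusion_windows or []
    prof = radial_profile(ps)
    r, inten = prof.radii, prof.intensity
    r_max = ps.L / 2.0
    usable = (r >= max(1.0, r_min_fraction * ps.L)) & (r <= r_max)
    mask = usable.copy()
    for lo, hi in exclusion_windows:
        mask &= ~((r >= lo) & (r <= hi))
    if usable.sum() == 0 or mask.sum() < 0.2 * usable.sum():
        raise FitError("exclusion windows cover more than 80% of usable radii")
    if mask.sum() <= degree + 1:
        raise FitError("too few radial bins to fit the background")
    log_i = np.log(np.clip(inten[mask], 1e-300, None))
    # Polynomial.fit maps radii to [-1, 1] internally for conditioning
    poly = np.polynomial.Polynomial.fit(r[mask], log_i, degree)
    rgrid = _radius_grid(ps.L)
    background = np.exp(poly(np.clip(rgrid, r[mask].min(), r[mask].max())))
    return PowerSpectrum2D(
        ps.values / background,
        L=ps.L,
        n_accumulated=ps.n_accumulated,
        pixel_size=ps.pixel_size,
    )


def expected_radius(d: float, pixel_size: float, L: int) -> float:
    """Ring radius in pixels for a plane spacing d (Å): r = L·P/d."""
    return L * pixel_size / d


def _parabolic_vertex(y_m1: float, y0: float, y_p1: float) -> float:
    denom = y_m1 - 2.0 * y0 + y_p1
    if denom == 0:
        return 0.0
    return float(np.clip(0.5 * (y_m1 - y_p1) / denom, -0.5, 0.5))


def _peak_in_window(
    radii: np.ndarray,
    intensity: np.ndarray,
    r_lo: float,
    r_hi: float,
    prominence: float,
    refine: str = "parabola",
) -> RingPeak:
    sel = np.nonzero((radii >= r_lo) & (radii <= r_hi))[0]
    if sel.size < 3:
        raise NoPeakError(f"search annulus [{r_lo:.1f}, {r_hi:.1f}] has too few bins")
    v = intensity[sel]
    # tie-break on equal maxima: prefer the larger radius (outer ring)
    local = v.size - 1 - int(np.argmax(v[::-1]))
    idx = sel[local]
    # Baseline/noise come from sidebands flanking the window: a broad Bragg
    # peak can fill most of the search annulus and would otherwise inflate
    # its own noise estimate.  The two sidebands are assessed separately and
    # the quieter one wins, so a neighbouring ring spilling into one side
    # (e.g. hcp 2.48 Å next to fcc 2.35 Å) does not mask the peak.  Fall
    # back to the lower half of the in-window values if no sideband exists.
    half = 0.5 * (r_hi - r_lo)
    inner = np.nonzero((radii >= r_lo - half) & (radii < r_lo))[0]
    outer = np.nonzero((radii > r_hi) & (radii <= r_hi + half))[0]

    def _mad_stats(ref):
        b = float(np.median(ref))
        return b, 1.4826 * float(np.median(np.abs(ref - b)))

    sides_ok = inner.size >= 5 and outer.size >= 5
    medians_agree = True
    if sides_ok:
        b_in, n_in = _mad_stats(intensity[inner])
        b_out, n_out = _mad_stats(intensity[outer])
        medians_agree = abs(b_in - b_out) <= 3.0 * max(min(n_in, n_out), 1e-12)
        if medians_agree:
            side = np.concatenate([inner, outer])
        else:
            # one sideband is contaminated (e.g. a neighbouring ring);
            # the cleaner side is the one with the lower floor
            side = inner if b_in <= b_out else outer
    else:
        side = inner if inner.size >= 5 else outer
    if side.size >= 5:
        baseline, noise = _mad_stats(intensity[side])
    else:
        baseline, noise = _mad_stats(np.sort(v)[: max(3, v.size // 2)])
    height = float(v[local] - baseline)
    if noise <= 0 or height < prominence * noise:
        raise NoPeakError(
            f"no peak above {prominence:.1f}x background scatter in "
            f"[{r_lo:.1f}, {r_hi:.1f}] (height {height:.3g}, noise {noise:.3g})"
        )
    if refine == "centroid":
        # intensity-weighted centre of the baseline-subtracted window:
        # robust against speckle when the ring in a wedge is a handful of
        # discrete crystallite spots rather than a smooth annulus.  A
        # linear baseline through the two sidebands removes the residual
        # background slope under the ring (a constant baseline would let
        # the decaying background pull the centroid inward), and the
        # window is re-centred on the running estimate so tail truncation
        # stays symmetric.
        if sides_ok and medians_agree and np.ptp(radii[side]) > 0:
            b_coef = np.polynomial.polynomial.polyfit(radii[side], intensity[side], 1)
        else:
            b_coef = np.array([baseline, 0.0])
        radius = float(radii[idx])
        for _ in range(3):
            w_lo, w_hi = radius - half, radius + half
            cin = (radii >= w_lo) & (radii <= w_hi)
            local_base = np.polynomial.polynomial.polyval(radii[cin], b_coef)
            # the annular mean of a symmetric 2D peak at radius R falls off
            # as G(|r-R|)/r; weighting by r undoes the 1/r dilution that
            # would otherwise bias the centroid inward by ~2 sigma^2/R
            excess = np.clip(intensity[cin] - local_base, 0.0, None) * radii[cin]
            total = excess.sum()
            if total <= 0:
                break
            radius = float(np.sum(radii[cin] * excess) / total)
    elif 0 < idx < len(radii) - 1:
        shift = _parabolic_vertex(
            intensity[idx - 1], intensity[idx], intensity[idx + 1]
        )
        step = radii[idx + 1] - radii[idx] if shift >= 0 else radii[idx] - radii[idx - 1]
        radius = float(radii[idx] + shift * step)
    else:
        radius = float(radii[idx])
    return RingPeak(radius=radius, height=height, window=(r_lo, r_hi))


def find_ring_peak(
    profile: RadialProfile,
    expected_d: float,
    nominal_pixel_size: float,
    L: int,
    tolerance_fraction: float = 0.05,
    prominence: float = 4.0,
) -> RingPeak:
    """Locate the Bragg ring near its expected radius, to sub-pixel precision.

    The expected radius is r = L·Pnom/d; the search annulus is
    r·(1 ± tolerance_fraction).  The discrete maximum of the (whitened)
    radial profile inside the annulus is refined by a 3-point parabolic
    interpolation; a peak must exceed ``prominence`` times the background
    scatter (robust MAD estimate) over the annulus median, otherwise a
    NoPeakError is raised so the micrograph is rejected rather than
    silently mis-measured.
    """
    r_exp = expected_radius(expected_d, nominal_pixel_size, L)
    r_lo = r_exp * (1.0 - tolerance_fraction)
    r_hi = r_exp * (1.0 + tolerance_fraction)
    if r_lo <= 0 or r_hi >= L / 2:
        raise NoPeakError(
            f"expected ring radius {r_exp:.1f} px (d={expected_d} Å) outside "
            f"the usable spectrum (L={L})"
        )
    return _peak_in_window(
        profile.radii, profile.intensity, r_lo, r_hi, prominence
    )
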