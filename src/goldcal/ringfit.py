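"""Azimuthal ring fitting, anisotropy estimation and pixel-size calibration.

Anisotropic magnification turns the polycrystalline Bragg ring into an
ellipse, so a single reflection cannot calibrate the pixel size: it is not
known where on the ellipse it sits.  The ring is therefore measured in
azimuthal wedges, a centred ellipse r(θ) is fitted, and the scalar
magnified pixel size is taken from the geometric mean of the two semi-axes
(which preserves area scaling under anisotropy).  A larger ring radius
means a larger pixel size for a fixed plane spacing, via P = r·d/L, so the
ellipse's major axis corresponds to the direction of larger magnified
pixel size.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import spectra as sp
from .crystallography import reflection_for
from .errors import (
    CalibrationError,
    FitError,
    IncompleteRingError,
    NoPeakError,
)
from .spectra import Micrograph, PowerSpectrum2D, RingPeak

__all__ = [
    "EllipseFit",
    "PixelSizeEstimate",
    "CalibrationConfig",
    "azimuthal_peaks",
    "fit_ellipse",
    "pixel_size_from_radius",
    "calibrate",
    "write_report",
]


@dataclass
class EllipseFit:
    """Centred ellipse fitted to wedge ring radii r(θ)."""

    center: tuple[float, float]
    semi_major: float
    semi_minor: float
    angle: float  # major-axis orientation, radians in (-pi/2, pi/2]
    n_wedges_used: int
    residual_rms: float

    @property
    def anisotropy_percent(self) -> float:
        mean = 0.5 * (self.semi_major + self.semi_minor)
        return 100.0 * (self.semi_major - self.semi_minor) / mean

    @property
    def geometric_mean_radius(self) -> float:
        return math.sqrt(self.semi_major * self.semi_minor)


@dataclass
class PixelSizeEstimate:
    """Aggregated magnified pixel size over a set of micrographs.

    ``value`` is the mean over micrographs of the per-image geometric-mean
    pixel size; ``sigma`` the standard deviation and ``sem`` = sigma/sqrt(n)
    the standard error of that mean.  ``value_major``/``value_minor`` are
    the pixel sizes along the ellipse axes (major axis = larger radius =
    larger pixel size).
    """

    value: float
    value_major: float
    value_minor: float
    anisotropy_percent: float
    per_micrograph: list[dict] = field(default_factory=list)
    sigma: float = 0.0
    sem: float = 0.0
    n: int = 0
    warnings: list[str] = field(default_factory=list)


@dataclass
class CalibrationConfig:
    """Tunable parameters of the ring-fitting pipeline."""

    n_wedges: int = 36
    tolerance_fraction: float = 0.05
    whiten_degree: int = 5
    prominence: float = 4.0
    min_wedge_fraction: float = 2.0 / 3.0
    exclusion_halfwidth: float = 0.10
    pad_to: int | None = None
    apodize: bool = False
    mode: str = "per_micrograph"  # or "accumulated"
    weighted: bool = False  # prominence-weighted aggregation


def azimuthal_peaks(
    ps: PowerSpectrum2D,
    r0: float,
    n_wedges: int = 36,
    tolerance_fraction: float = 0.05,
    prominence: float = 4.0,
    min_wedge_fraction: float = 2.0 / 3.0,
) -> list[tuple[float, float]]:
    """Sub-pixel ring radius per azimuthal wedge of a whitened spectrum.

    Each wedge gets its own radial profile restricted to the annulus
    r0·(1 ± tolerance_fraction); wedges without a significant peak are
    dropped.  Returns (wedge centre angle, radius) pairs; raises
    IncompleteRingError when fewer than ``min_wedge_fraction`` of the
    wedges yield a peak (an incomplete ring cannot constrain the ellipse).
    """
    if n_wedges < 8:
        raise ValueError("need at least 8 wedges")
    L = ps.L
    if not (0 < r0 < L / 2):
        raise ValueError(f"r0={r0} outside spectrum of size {L}")
    r_lo = r0 * (1.0 - tolerance_fraction)
    r_hi = r0 * (1.0 + tolerance_fraction)
    cy, cx = ps.center
    y = np.arange(L) - cy
    x = np.arange(L) - cx
    rgrid = np.hypot(y[:, None], x[None, :])
    # pad the annulus so edge bins keep interpolation neighbours and the
    # peak finder has sideband bins for its baseline/noise estimate
    pad = 0.5 * (r_hi - r_lo) + 2
    annulus = (rgrid >= r_lo - pad) & (rgrid <= r_hi + pad)
    ry, rx = np.nonzero(annulus)
    rads = rgrid[ry, rx]
    theta = np.arctan2(ry - cy, rx - cx)  # (-pi, pi]
    wedge = np.floor((theta + np.pi) / (2 * np.pi) * n_wedges).astype(np.intp)
    wedge = np.clip(wedge, 0, n_wedges - 1)
    rbin = np.rint(rads).astype(np.intp)
    rb_min, rb_max = rbin.min(), rbin.max()
    nr = rb_max - rb_min + 1
    flat = wedge * nr + (rbin - rb_min)
    vals = ps.values[ry, rx]
    sums = np.bincount(flat, weights=vals, minlength=n_wedges * nr)
    counts = np.bincount(flat, minlength=n_wedges * nr)
    peaks: list[tuple[float, float]] = []
    radii_axis = np.arange(rb_min, rb_max + 1, dtype=np.float64)
    for w in range(n_wedges):
        c = counts[w * nr : (w + 1) * nr]
        s = sums[w * nr : (w + 1) * nr]
        good = c > 0
        if good.sum() < 3:
            continue
        prof_r = radii_axis[good]
        prof_i = s[good] / c[good]
        try:
            pk = sp._peak_in_window(
                prof_r, prof_i, r_lo, r_hi, prominence, refine="centroid"
            )
        except NoPeakError:
            continue
        angle = -np.pi + (w + 0.5) * 2 * np.pi / n_wedges
        peaks.append((float(angle), pk.radius))
    if len(peaks) < min_wedge_fraction * n_wedges:
        raise IncompleteRingError(
            f"only {len(peaks)}/{n_wedges} wedges produced a ring peak"
        )
    return peaks


def fit_ellipse(peaks: list[tuple[float, float]]) -> EllipseFit:
    """Least-squares centred ellipse through wedge (angle, radius) samples.

    A centred ellipse satisfies 1/r² = p + q·cos2θ + s·sin2θ, which is
    linear in (p, q, s); the semi-axes follow from p ± sqrt(q² + s²) and
    the major-axis orientation from atan2(s, q).  The centre is fixed at
    the DC bin: Friedel symmetry makes the Bragg ring centro-symmetric, so
    a free centre would only add variance.
    """
    if len(peaks) < 8:
        raise FitError(f"need at least 8 ring points, got {len(peaks)}")
    theta = np.array([p[0] for p in peaks], dtype=np.float64)
    r = np.array([p[1] for p in peaks], dtype=np.float64)
    if np.any(r <= 0):
        raise FitError("non-positive ring radius")
    # azimuthal coverage: longest gap in sorted angles must leave >= 240 deg
    ang = np.sort(np.mod(theta, 2 * np.pi))
    gaps = np.diff(np.concatenate([ang, [ang[0] + 2 * np.pi]]))
    span = 2 * np.pi - gaps.max()
    if span < np.deg2rad(240.0) - 1e-9:
        raise FitError(
            f"ring points span only {np.rad2deg(span):.0f} deg of azimuth"
        )
    u = 1.0 / r**2
    A = np.column_stack([np.ones_like(theta), np.cos(2 * theta), np.sin(2 * theta)])
    coef, *_ = np.linalg.lstsq(A, u, rcond=None)
    p, q, s = coef
    m = math.hypot(q, s)
    if p - m <= 0:
        raise FitError("degenerate ellipse fit (non-positive axis)")
    semi_major = 1.0 / math.sqrt(p - m)
    semi_minor = 1.0 / math.sqrt(p + m)
    # 1/r^2 is minimal (r maximal) where cos(2θ - ψ) = -1, ψ = atan2(s, q)
    psi = math.atan2(s, q)
    angle = 0.5 * (psi + math.pi)
    angle = math.remainder(angle, math.pi)
    if angle <= -math.pi / 2:
        angle += math.pi
    elif angle > math.pi / 2:
        angle -= math.pi
    pred = A @ coef
    r_pred = 1.0 / np.sqrt(pred)
    residual_rms = float(np.sqrt(np.mean((r - r_pred) ** 2)))
    return EllipseFit(
        center=(0.0, 0.0),
        semi_major=semi_major,
        semi_minor=semi_minor,
        angle=angle,
        n_wedges_used=len(peaks),
        residual_rms=residual_rms,
    )


def pixel_size_from_radius(r: float, L: int, d: float) -> float:
    """Magnified pixel size P = r·d/L from a ring radius (px), transform
    width (px) and plane spacing (Å)."""
    if r <= 0 or L <= 0 or d <= 0:
        raise ValueError("r, L and d must all be positive")
    return r * d / L


_HCP_002_D = 2.48  # hcp gold (002) spacing, Å — the mis-assignment hazard


def _process_spectrum(
    wps: PowerSpectrum2D,
    d_primary: float,
    d_others: list[tuple[tuple[int, int, int], float]],
    pnom: float,
    check_hcp: bool,
    cfg: CalibrationConfig,
) -> dict:
    """Measure one whitened spectrum; returns a per-micrograph record."""
    L = wps.L
    prof = sp.radial_profile(wps)
    peak = sp.find_ring_peak(
        prof, d_primary, pnom, L, cfg.tolerance_fraction, cfg.prominence
    )
    flags: list[str] = []
    if check_hcp:
        r_hcp = sp.expected_radius(_HCP_002_D, pnom, L)
        r_fcc = sp.expected_radius(d_primary, pnom, L)
        try:
            hcp_peak = sp._peak_in_window(
                prof.radii,
                prof.intensity,
                r_hcp * (1 - cfg.tolerance_fraction),
                r_hcp * (1 + cfg.tolerance_fraction),
                cfg.prominence,
            )
        except NoPeakError:
            hcp_peak = None
        # the fcc and hcp rings are only ~5.5% apart, so the search window
        # can catch the fcc ring's flank; assign the candidate to whichever
        # expected ring is nearer in relative radius before comparing
        if hcp_peak is not None:
            rel_hcp = abs(hcp_peak.radius - r_hcp) / r_hcp
            rel_fcc = abs(hcp_peak.radius - r_fcc) / r_fcc
            if rel_hcp < rel_fcc and hcp_peak.height > peak.height:
                flags.append("mixed_lattice")
    wedges = azimuthal_peaks(
        wps,
        peak.radius,
        cfg.n_wedges,
        cfg.tolerance_fraction,
        cfg.prominence,
        cfg.min_wedge_fraction,
    )
    ell = fit_ellipse(wedges)
    p_gm = pixel_size_from_radius(ell.geometric_mean_radius, L, d_primary)
    record = {
        "radius": peak.radius,
        "peak_height": peak.height,
        "pixel_size": p_gm,
        "pixel_size_major": pixel_size_from_radius(ell.semi_major, L, d_primary),
        "pixel_size_minor": pixel_size_from_radius(ell.semi_minor, L, d_primary),
        "anisotropy_percent": ell.anisotropy_percent,
        "ellipse_angle_deg": math.degrees(ell.angle),
        "n_wedges_used": ell.n_wedges_used,
        "residual_rms": ell.residual_rms,
        "flags": flags,
    }
    # secondary reflections cross-check the lattice assignment
    for hkl, d_sec in d_others:
        try:
            sec = sp.find_ring_peak(
                prof, d_sec, pnom, L, cfg.tolerance_fraction, cfg.prominence
            )
        except NoPeakError:
            continue
        p_sec = pixel_size_from_radius(sec.radius, L, d_sec)
        record[f"pixel_size_{''.join(map(str, hkl))}"] = p_sec
        if abs(p_sec / p_gm - 1.0) > 0.01:
            flags.append(f"reflection_mismatch_{''.join(map(str, hkl))}")
    return record


def calibrate(
    micrographs: list[Micrograph],
    material_id: str = "gold_fcc",
    hkl_list: list[tuple[int, int, int]] | None = None,
    temperature_k: float = 81.0,
    nominal_pixel_size: float | None = None,
    config: CalibrationConfig | None = None,
    catalogue: dict | None = None,
) -> PixelSizeEstimate:
    """Calibrate the magnified pixel size from foil micrographs.

    For each micrograph: power spectrum, noise whitening (with the expected
    Bragg rings excluded from the background fit), 1D ring search near the
    expected radius of the primary reflection, azimuthal wedge peaks,
    centred-ellipse fit, and conversion of the geometric-mean radius to a
    pixel size.  Across micrographs the unweighted mean, standard deviation
    and standard error are reported.  For fcc gold the profile is also
    checked for a stronger peak at the hcp (002) position (2.48 Å); picking
    that ring instead of the fcc (111) would bias the result by >5%, so
    such micrographs are flagged ``mixed_lattice``.
    """
    cfg = config or CalibrationConfig()
    hkl_list = hkl_list or [(1, 1, 1)]
    if not micrographs:
        raise CalibrationError("no micrographs supplied")
    refls = [
        reflection_for(material_id, hkl, temperature_k, catalogue) for hkl in hkl_list
    ]
    d_primary = refls[0].d
    d_others = [(r.hkl, r.d) for r in refls[1:]]
    check_hcp = material_id == "gold_fcc"

    def _whitened(m: Micrograph, pnom: float) -> PowerSpectrum2D:
        ps = sp.power_spectrum(m, pad_to=cfg.pad_to, apodize=cfg.apodize)
        windows = []
        d_all = [d_primary] + [d for _, d in d_others]
        if check_hcp:
            d_all.append(_HCP_002_D)
        for d in d_all:
            r_exp = sp.expected_radius(d, pnom, ps.L)
            windows.append(
                (r_exp * (1 - cfg.exclusion_halfwidth), r_exp * (1 + cfg.exclusion_halfwidth))
            )
        return sp.whiten(ps, windows, degree=cfg.whiten_degree)

    records: list[dict] = []
    reasons: dict[str, str] = {}
    if cfg.mode == "accumulated":
        pnom = nominal_pixel_size or micrographs[0].nominal_pixel_size
        acc = sp.accumulate(
            [sp.power_spectrum(m, pad_to=cfg.pad_to, apodize=cfg.apodize) for m in micrographs]
        )
        windows = [
            (
                sp.expected_radius(d, pnom, acc.L) * (1 - cfg.exclusion_halfwidth),
                sp.expected_radius(d, pnom, acc.L) * (1 + cfg.exclusion_halfwidth),
            )
            for d in [d_primary]
            + [d for _, d in d_others]
            + ([_HCP_002_D] if check_hcp else [])
        ]
        wps = sp.whiten(acc, windows, degree=cfg.whiten_degree)
        rec = _process_spectrum(wps, d_primary, d_others, pnom, check_hcp, cfg)
        rec["source"] = f"<accumulated:{len(micrographs)}>"
        records.append(rec)
    else:
        for m in micrographs:
            pnom = nominal_pixel_size or m.nominal_pixel_size
            if pnom <= 0:
                reasons[m.source_path] = "no nominal pixel size available"
                continue
            try:
                wps = _whitened(m, pnom)
                rec = _process_spectrum(wps, d_primary, d_others, pnom, check_hcp, cfg)
            except (NoPeakError, IncompleteRingError, FitError) as exc:
                reasons[m.source_path] = f"{type(exc).__name__}: {exc}"
                continue
            rec["source"] = m.source_path
            records.append(rec)

    if not records:
        raise CalibrationError(
            "all micrographs rejected during calibration", reasons=reasons
        )
    values = np.array([r["pixel_size"] for r in records])
    if cfg.weighted:
        w = np.array([r["peak_height"] for r in records])
        value = float(np.average(values, weights=w))
    else:
        value = float(values.mean())
    n = len(values)
    sigma = float(values.std(ddof=1)) if n > 1 else 0.0
    sem = sigma / math.sqrt(n) if n > 1 else 0.0
    warnings_list = sorted(
        {f for r in records for f in r["flags"]}
    ) + [f"rejected:{k}" for k in reasons]
    return PixelSizeEstimate(
        value=value,
        value_major=float(np.mean([r["pixel_size_major"] for r in records])),
        value_minor=float(np.mean([r["pixel_size_minor"] for r in records])),
        anisotropy_percent=float(np.mean([r["anisotropy_percent"] for r in records])),
        per_micrograph=records,
        sigma=sigma,
        sem=sem,
        n=n,
        warnings=warnings_list,
    )


def write_report(
    estimate: PixelSizeEstimate, out_prefix: str | Path, extra: dict | None = None
) -> tuple[Path, Path]:
    """Write the calibration report as <prefix>.json and <prefix>.csv."""
    out_prefix = Path(out_prefix)
    payload = asdict(estimate)
    if extra:
        payload = {**extra, **payload}
    json_path = out_prefix.with_suffix(".json")
    json_path.parent.mkdir(parents=True, exist_ok=True)
    json_path.write_text(json.dumps(payload, indent=2) + "\n")
    csv_path = out_prefix.with_suffix(".csv")
    rows = estimate.per_micrograph
    cols = [
        "source",
        "radius",
        "pixel_size",
        "pixel_size_major",
        "pixel_size_minor",
        "anisotropy_percent",
        "ellipse_angle_deg",
        "n_wedges_used",
        "residual_rms",
        "peak_height",
        "flags",
    ]
    with open(csv_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(cols)
        for r in rows:
            writer.writerow(
                [";".join(r[c]) if c == "flags" else r.get(c, "") for c in cols]
            )
        writer.writerow([])
        writer.writerow(["mean", estimate.value])
        writer.writerow(["sigma", estimate.sigma])
        writer.writerow(["sem", estimate.sem])
        writer.writerow(["n", estimate.n])
    return json_path, csv_path
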