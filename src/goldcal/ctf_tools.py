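"""CTF evaluation and the Cs-refinement pixel-size estimator.

A wrong magnified pixel size maps every measured spatial frequency to the
wrong physical frequency, so the fitted contrast transfer function is
wrong too.  Because the defocus term of the phase shift goes as q² and the
spherical-aberration term as q⁴, refitting the defocus can compensate the
error only at low spatial frequency; the residual CTF error grows toward
Nyquist.  Aberration refinement (e.g. RELION's) absorbs the resulting q⁴
phase error into an even Zernike coefficient (Z40), which can be converted
back into an apparent Cs and hence into the true pixel size:

    Cs_apparent = Cs_true + dCs(Z40),   P_true = P_nom (Cs_true/Cs_apparent)^(1/4)

User-facing units follow microscopy convention — kV, mm, µm, Å — and all
internal computation is in Å and radians.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
from scipy import constants as const
from scipy.optimize import minimize_scalar

from .errors import GoldcalError, StarParseError

__all__ = [
    "OpticsParams",
    "ZernikeSet",
    "electron_wavelength",
    "chi",
    "ctf",
    "ctf_error_curve",
    "cs_apparent_from_z40",
    "z40_from_delta_cs",
    "pixel_size_from_cs",
    "read_zernike_star",
    "pixel_sizes_from_star",
]

MM_TO_A = 1e7
UM_TO_A = 1e4


def electron_wavelength(voltage_kv: float) -> float:
    """Relativistic electron de Broglie wavelength in Å for a voltage in kV.

    λ = h / sqrt(2 m₀ e V (1 + eV / (2 m₀ c²)));  300 kV → 0.0197 Å.
    """
    if voltage_kv <= 0:
        raise ValueError("voltage must be positive")
    V = voltage_kv * 1e3
    ev = const.e * V
    p = np.sqrt(2 * const.m_e * ev * (1 + ev / (2 * const.m_e * const.c**2)))
    return const.h / p * 1e10


@dataclass(frozen=True)
class OpticsParams:
    """Microscope optics for CTF computation.

    voltage in kV, Cs in mm, defocus in µm with underfocus negative,
    amplitude contrast W dimensionless (≈0.04 at 300 kV without energy
    filtering).
    """

    voltage_kv: float = 300.0
    cs_mm: float = 2.7
    defocus_um: float = -1.5
    amplitude_contrast: float = 0.04

    def __post_init__(self):
        if not (0 < self.amplitude_contrast < 1):
            raise ValueError("amplitude contrast must be in (0, 1)")

    @property
    def wavelength(self) -> float:
        """Electron wavelength in Å."""
        return electron_wavelength(self.voltage_kv)

    @property
    def cs_angstrom(self) -> float:
        return self.cs_mm * MM_TO_A

    @property
    def defocus_angstrom(self) -> float:
        return self.defocus_um * UM_TO_A

    def nyquist(self, pixel_size: float) -> float:
        return 1.0 / (2.0 * pixel_size)


def chi(q, optics: OpticsParams, defocus_um: float | None = None):
    """Aberration phase shift χ(q) in radians; q in 1/Å.

    χ(q) = π λ Δz q² + (π/2) λ³ Cs q⁴ with Δz and Cs in Å.
    """
    q = np.asarray(q, dtype=np.float64)
    lam = optics.wavelength
    dz = (optics.defocus_um if defocus_um is None else defocus_um) * UM_TO_A
    cs = optics.cs_angstrom
    return np.pi * lam * dz * q**2 + 0.5 * np.pi * lam**3 * cs * q**4


def ctf(q, optics: OpticsParams, defocus_um: float | None = None):
    """Contrast transfer function √(1−W²)·sin χ − W·cos χ; |CTF| ≤ 1."""
    w = optics.amplitude_contrast
    x = chi(q, optics, defocus_um)
    return np.sqrt(1.0 - w * w) * np.sin(x) - w * np.cos(x)


def ctf_error_curve(
    pixel_error_fraction: float,
    optics: OpticsParams,
    refit_defocus: bool = False,
    q_grid: np.ndarray | None = None,
    pixel_size: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, float]:
    """CTF error vs spatial frequency for a fractional pixel-size error.

    A pixel size wrong by a fraction ε places the signal measured at true
    frequency q at the assumed frequency q·(1+ε), so the error is

        error(q) = CTF_true(q) − CTF_assumed(q·(1+ε)).

    With ``refit_defocus`` the assumed defocus is first adjusted (bounded
    scalar minimization of the RMS CTF difference over the grid) to mimic
    CTF fitting on mis-scaled data; the compensation works only at low q
    because defocus and Cs scale as q² and q⁴.  Returns (q_grid, error,
    assumed_defocus_um).
    """
    if abs(pixel_error_fraction) >= 0.1:
        raise ValueError("pixel_error_fraction must satisfy |eps| < 0.1")
    if q_grid is None:
        q_grid = np.linspace(1e-3, 0.9 * optics.nyquist(pixel_size), 512)
    q_grid = np.asarray(q_grid, dtype=np.float64)
    q_assumed = q_grid * (1.0 + pixel_error_fraction)
    true_vals = ctf(q_grid, optics)
    dz = optics.defocus_um
    if refit_defocus and pixel_error_fraction != 0.0:
        def objective(dz_trial: float) -> float:
            return float(
                np.sqrt(np.mean((true_vals - ctf(q_assumed, optics, dz_trial)) ** 2))
            )

        lo, hi = sorted((dz * 2.0, dz * 0.5)) if dz != 0 else (-5.0, 5.0)
        # the objective oscillates in defocus (CTF fringes beat against each
        # other), so bracket the global minimum on a coarse grid before the
        # local bounded minimization
        grid = np.linspace(lo, hi, 401)
        best = int(np.argmin([objective(g) for g in grid]))
        blo = grid[max(best - 1, 0)]
        bhi = grid[min(best + 1, grid.size - 1)]
        res = minimize_scalar(objective, bounds=(blo, bhi), method="bounded")
        if not res.success:
            raise GoldcalError(
                f"defocus refit failed to converge: {res.message} "
                f"(bounds {blo}..{bhi} um)"
            )
        dz = float(res.x)
        if objective(dz) > objective(grid[best]):
            dz = float(grid[best])
    error = true_vals - ctf(q_assumed, optics, dz)
    return q_grid, error, dz


@dataclass
class ZernikeSet:
    """Even Zernike coefficients from aberration refinement.

    z40 is the 7th entry of the coefficient list; q_max (1/Å) is the
    normalization radius of the polynomial argument ρ = q/q_max, by default
    the Nyquist frequency of the nominal pixel size.
    """

    even_coefficients: list[float]
    q_max: float
    optics_group: int = 1
    pixel_size: float | None = None

    def __post_init__(self):
        if self.q_max <= 0:
            raise ValueError("q_max must be positive")
        if len(self.even_coefficients) < 7:
            raise StarParseError(
                f"need >= 7 even Zernike coefficients to read Z40, "
                f"got {len(self.even_coefficients)}"
            )

    @property
    def z40(self) -> float:
        return float(self.even_coefficients[6])


def cs_apparent_from_z40(
    z: ZernikeSet, cs_true_mm: float, wavelength: float
) -> float:
    """Apparent Cs (mm) implied by a Z40 coefficient.

    The Z40 polynomial 6ρ⁴ − 6ρ² + 1 (ρ = q/q_max) adds Z40·6·q⁴/q_max⁴ to
    the q⁴ phase; matching against the Cs phase term (π/2)λ³ΔCs·q⁴ gives
    ΔCs = 12·Z40 / (π λ³ q_max⁴) (Å); the lower-order terms are absorbed by
    lower-order Zernike/defocus coefficients.  ``wavelength`` in Å.
    """
    delta_cs_a = 12.0 * z.z40 / (np.pi * wavelength**3 * z.q_max**4)
    return cs_true_mm + delta_cs_a / MM_TO_A


def z40_from_delta_cs(delta_cs_mm: float, wavelength: float, q_max: float) -> float:
    """Inverse of the Z40 → ΔCs conversion (for simulation and round trips)."""
    return delta_cs_mm * MM_TO_A * np.pi * wavelength**3 * q_max**4 / 12.0


def pixel_size_from_cs(
    nominal_pixel_size: float, cs_true_mm: float, cs_apparent_mm: float
) -> float:
    """True pixel size from the apparent Cs: P = Pnom·(Cs_true/Cs_app)^¼."""
    if cs_true_mm <= 0 or cs_apparent_mm <= 0:
        raise ValueError("spherical aberration coefficients must be positive")
    return nominal_pixel_size * (cs_true_mm / cs_apparent_mm) ** 0.25


_LIST_SPLIT = re.compile(r"[,\s]+")


def _parse_coeff_list(raw: str) -> list[float]:
    txt = raw.strip().strip("'\"").strip()
    if txt.startswith("["):
        txt = txt[1:]
    if txt.endswith("]"):
        txt = txt[:-1]
    return [float(tok) for tok in _LIST_SPLIT.split(txt.strip()) if tok]


def read_zernike_star(
    path: str | Path,
    q_max: float | None = None,
    default_pixel_size: float | None = None,
) -> list[ZernikeSet]:
    """Read rlnEvenZernike coefficient sets from a RELION-style STAR file.

    Returns one ZernikeSet per optics group (row of the table holding the
    field).  q_max defaults to the Nyquist frequency of the pixel size
    found in the same table (rlnImagePixelSize / rlnMicrographPixelSize /
    rlnMicrographOriginalPixelSize), or of ``default_pixel_size``.
    """
    try:
        doc = gemmi.cif.read_file(str(path))
    except (RuntimeError, ValueError, OSError) as exc:
        raise StarParseError(f"cannot parse STAR file {path}: {exc}") from exc
    px_tags = [
        "_rlnImagePixelSize",
        "_rlnMicrographPixelSize",
        "_rlnMicrographOriginalPixelSize",
    ]
    blocks_seen = []
    for block in doc:
        blocks_seen.append(block.name)
        col = block.find_loop("_rlnEvenZernike")
        if not col:
            item = block.find_value("_rlnEvenZernike")
            col = [item] if item is not None else None
        if not col:
            continue
        coeff_lists = [_parse_coeff_list(v) for v in col]
        groups: list[int] = []
        gcol = block.find_loop("_rlnOpticsGroup")
        if gcol:
            groups = [int(float(v)) for v in gcol]
        px_values: list[float | None] = [None] * len(coeff_lists)
        for tag in px_tags:
            pcol = block.find_loop(tag)
            if pcol:
                px_values = [float(v) for v in pcol]
                break
            item = block.find_value(tag)
            if item is not None:
                px_values = [float(item)] * len(coeff_lists)
                break
        out = []
        for i, coeffs in enumerate(coeff_lists):
            px = px_values[i] if i < len(px_values) else None
            if px is None:
                px = default_pixel_size
            if q_max is not None:
                qm = q_max
            elif px is not None:
                qm = 1.0 / (2.0 * px)
            else:
                raise StarParseError(
                    f"{path}: no pixel size in table {block.name!r} and no "
                    "q_max or default_pixel_size given"
                )
            out.append(
                ZernikeSet(
                    even_coefficients=coeffs,
                    q_max=qm,
                    optics_group=groups[i] if i < len(groups) else i + 1,
                    pixel_size=px,
                )
            )
        return out
    raise StarParseError(
        f"{path}: no rlnEvenZernike field found; tables present: {blocks_seen}"
    )


def pixel_sizes_from_star(
    path: str | Path,
    cs_true_mm: float,
    voltage_kv: float,
    nominal_pixel_size: float | None = None,
    q_max: float | None = None,
) -> list[dict]:
    """Corrected pixel size per optics group from an aberration-refined STAR.

    Combines the Z40 → apparent-Cs conversion with the quarter-power pixel
    size correction; returns one record per optics group.
    """
    lam = electron_wavelength(voltage_kv)
    records = []
    for z in read_zernike_star(path, q_max=q_max, default_pixel_size=nominal_pixel_size):
        pnom = nominal_pixel_size if nominal_pixel_size is not None else z.pixel_size
        if pnom is None:
            raise StarParseError(
                "nominal pixel size unavailable (not in STAR, not given)"
            )
        cs_app = cs_apparent_from_z40(z, cs_true_mm, lam)
        records.append(
            {
                "optics_group": z.optics_group,
                "z40": z.z40,
                "q_max": z.q_max,
                "cs_apparent_mm": cs_app,
                "nominal_pixel_size": pnom,
                "corrected_pixel_size": pixel_size_from_cs(pnom, cs_true_mm, cs_app),
            }
        )
    return records
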