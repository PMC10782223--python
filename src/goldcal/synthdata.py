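"""Synthetic polycrystalline-foil micrographs with known ground truth.

The generator emulates what the calibration pipeline actually consumes
from an image of a gold (or carbon) foil: many small randomly oriented
crystallites, each contributing a cosine lattice fringe at a known plane
spacing, on top of a radially decaying spectral background (standing in
for detector MTF and low-angle scattering) and counting noise.  An
optional anisotropic affine stretch emulates anisotropic magnification —
the affine image of the circular Bragg ring is an ellipse with exactly the
stretch ratio as its axis ratio, so anisotropy recovery can be tested
against an exact truth.

Fringes are additive cosines, not dynamical diffraction: the estimators
consume only Bragg-peak positions, and those a cosine reproduces exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .errors import ConfigurationError
from .mrcio import write_mrc
from .spectra import Micrograph

__all__ = ["SyntheticSceneConfig", "generate_micrograph", "generate_dataset"]


@dataclass(frozen=True)
class SyntheticSceneConfig:
    """Parameters of one synthetic foil micrograph.

    Defaults describe a 1024² K3-like counting exposure of HexAuFoil-scale
    gold: pixel size 0.6484 Å, fcc (111) fringes at 2.35 Å, 200
    crystallites of a few nm (≈48 px), ≈25 counts/pixel (60 e⁻/Å² on a
    0.65 Å pixel) with Poisson statistics, and a decaying spectral
    background.  ``seed`` fully determines the output.
    """

    image_size: int = 1024
    true_pixel_size: float = 0.6484
    spacings: tuple[tuple[float, float], ...] = ((2.35, 1.0),)
    n_crystallites: int = 200
    crystallite_scale: float = 48.0
    fringe_contrast: float = 0.5
    background: tuple[float, float] = (150.0, 0.1)  # (decay length px, rms amplitude)
    noise_model: str = "poisson"  # none | gaussian | poisson
    noise_sigma: float = 0.1  # gaussian sigma relative to mean level
    mean_counts: float = 25.0
    anisotropy: tuple[float, float] = (1.0, 0.0)  # (stretch ratio >= 1, axis angle rad)
    seed: int = 0
    decoy_nominal_pixel_size: float | None = None
    aliasing: bool = False

    def __post_init__(self):
        if self.image_size < 64:
            raise ConfigurationError("image_size must be >= 64")
        if self.true_pixel_size <= 0:
            raise ConfigurationError("true_pixel_size must be positive")
        if self.anisotropy[0] < 1.0:
            raise ConfigurationError("stretch ratio must be >= 1")
        if self.noise_model not in ("none", "gaussian", "poisson"):
            raise ConfigurationError(f"unknown noise model {self.noise_model!r}")
        if not self.spacings:
            raise ConfigurationError("at least one lattice spacing required")
        for d, amp in self.spacings:
            if d <= 0 or amp < 0:
                raise ConfigurationError("spacings must have d > 0, amplitude >= 0")
            if not self.aliasing and d / self.true_pixel_size < 2.0:
                raise ConfigurationError(
                    f"fringe period {d / self.true_pixel_size:.2f} px is "
                    "super-Nyquist; enable the aliasing flag to simulate "
                    "aliased detection"
                )


def _stretch_inverse(cfg: SyntheticSceneConfig):
    """Inverse of the anisotropic stretch, as a 2x2 matrix (identity if none).

    The stretch is area-preserving — sqrt(s) expansion along the axis,
    1/sqrt(s) compression across it — so the Bragg ring becomes an ellipse
    of axis ratio s while the geometric-mean magnified pixel size stays
    equal to ``true_pixel_size`` (anisotropic magnification redistributes
    magnification between axes rather than changing the mean).
    """
    s, alpha = cfg.anisotropy
    if s == 1.0:
        return None
    c, si = np.cos(alpha), np.sin(alpha)
    rot = np.array([[c, -si], [si, c]])
    rs = np.sqrt(s)
    inv = rot @ np.diag([1.0 / rs, rs]) @ rot.T
    return inv


def _render_noiseless(cfg: SyntheticSceneConfig, rng: np.random.Generator) -> np.ndarray:
    """Unit-mean crystallite fringe pattern plus background field."""
    L = cfg.image_size
    n = cfg.n_crystallites
    seeds = rng.uniform(0, L, size=(n, 2))  # (y, x)
    orientations = rng.uniform(0, np.pi, size=n)
    phases = rng.uniform(0, 2 * np.pi, size=n)
    weights = np.array([amp for _, amp in cfg.spacings], dtype=np.float64)
    d_values = np.array([d for d, _ in cfg.spacings], dtype=np.float64)
    which = rng.choice(len(d_values), size=n, p=weights / weights.sum())
    periods = d_values[which] / cfg.true_pixel_size

    c0 = L / 2.0
    yy, xx = np.meshgrid(np.arange(L, dtype=np.float64), np.arange(L, dtype=np.float64), indexing="ij")
    inv = _stretch_inverse(cfg)
    if inv is None:
        uy, ux = yy, xx
    else:
        dy, dx = yy - c0, xx - c0
        uy = inv[0, 0] * dy + inv[0, 1] * dx + c0
        ux = inv[1, 0] * dy + inv[1, 1] * dx + c0

    tree = cKDTree(seeds)
    pts = np.column_stack([uy.ravel(), ux.ravel()])
    dist, label = tree.query(pts, k=1)
    dist = dist.reshape(L, L)
    label = label.reshape(L, L)
    inside = dist <= cfg.crystallite_scale

    k = 2.0 * np.pi / periods
    ky = (k * np.sin(orientations))[label]
    kx = (k * np.cos(orientations))[label]
    ph = phases[label]
    fringe = np.where(inside, cfg.fringe_contrast * np.cos(ky * uy + kx * ux + ph), 0.0)

    decay, rms = cfg.background
    img = 1.0 + fringe
    if rms > 0:
        fy = np.fft.fftfreq(L) * L
        fr = np.hypot(fy[:, None], fy[None, :])
        envelope = np.exp(-fr / (2.0 * decay))  # amplitude; power decays exp(-r/decay)
        noise_field = rng.standard_normal((L, L))
        bg = np.fft.ifft2(np.fft.fft2(noise_field) * envelope).real
        bg -= bg.mean()
        std = bg.std()
        if std > 0:
            img += bg * (rms / std)
    return img


def generate_micrograph(cfg: SyntheticSceneConfig) -> Micrograph:
    """Render one synthetic foil micrograph from its config.

    In aliasing mode the scene is rendered at twice the sampling and
    decimated without a low-pass filter, folding super-Nyquist fringes back
    into the spectrum the way a high-efficiency detector does.
    """
    rng = np.random.default_rng(cfg.seed)
    if cfg.aliasing:
        fine = replace(
            cfg,
            image_size=cfg.image_size * 2,
            true_pixel_size=cfg.true_pixel_size / 2.0,
            crystallite_scale=cfg.crystallite_scale * 2.0,
            background=(cfg.background[0] * 2.0, cfg.background[1]),
            aliasing=False,
        )
        img = _render_noiseless(fine, rng)[::2, ::2]
    else:
        img = _render_noiseless(cfg, rng)
    scale = cfg.mean_counts
    if cfg.noise_model == "poisson":
        out = rng.poisson(np.clip(img, 0.01, None) * scale).astype(np.float64)
    elif cfg.noise_model == "gaussian":
        out = img * scale + rng.normal(0.0, cfg.noise_sigma * scale, size=img.shape)
    else:
        out = img * scale
    nominal = (
        cfg.decoy_nominal_pixel_size
        if cfg.decoy_nominal_pixel_size is not None
        else cfg.true_pixel_size
    )
    return Micrograph(out, nominal_pixel_size=nominal, source_path=f"<synthetic:{cfg.seed}>")


def generate_dataset(
    cfg: SyntheticSceneConfig, n_micrographs: int, out_dir: str | Path
) -> list[Path]:
    """Write ``n_micrographs`` seeded variants as MRC2014 plus a truth sidecar.

    Per-image seeds are cfg.seed + index, so a fixed master seed gives
    bitwise-reproducible files.  The MRC headers carry the decoy nominal
    pixel size if one is configured — never the truth, which lives only in
    ``ground_truth.json`` next to the images (the calibration pipeline must
    not read it).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    truth = {
        "true_pixel_size": cfg.true_pixel_size,
        "spacings": [list(s) for s in cfg.spacings],
        "anisotropy_stretch": cfg.anisotropy[0],
        "anisotropy_angle_rad": cfg.anisotropy[1],
        "master_seed": cfg.seed,
        "config": asdict(cfg),
        "files": [],
    }
    for i in range(n_micrographs):
        sub = replace(cfg, seed=cfg.seed + i)
        m = generate_micrograph(sub)
        path = out_dir / f"synthetic_{i:04d}.mrc"
        write_mrc(path, m.pixels.astype(np.float32), m.nominal_pixel_size)
        truth["files"].append({"path": path.name, "seed": sub.seed})
        paths.append(path)
    (out_dir / "ground_truth.json").write_text(json.dumps(truth, indent=2) + "\n")
    return paths
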