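"""Seeded phantom measurement-cell images with a known color-response law.

Each phantom emulates a photograph of a backlit measurement cell: a flat,
uniformly colored square inlet (the liquid chamber) embedded in a
higher-texture background (the cell housing).  The inlet color follows a
Beer-Lambert-style law per channel,

    I_i(conc) = I0_i * 10^(-k_i * f(conc)) + noise,      i in {R, G, B}

where ``f`` maps concentration to a normalized response in [0, 1]:
identity-like (``linear``), saturating-log (``log``) or sigmoid
(``logistic``).  Choosing ``f`` forces the matching calibration model to be
the true score-concentration relationship, which makes model-selection
recovery testable end to end.  All randomness flows through numpy's seeded
PCG64 generator, so identical specs render bit-identical images.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

RESPONSE_LAWS = ("linear", "log", "logistic")
BACKGROUND_KINDS = ("checkerboard", "speckle")

#: the calibration concentration grid used throughout (pg/mL)
DEFAULT_LEVELS = (880.0, 352.0, 132.0, 44.0, 17.6, 0.0)


@dataclass
class PhantomSpec:
    """Full parameterization of one synthetic measurement-cell image.

    ``k_rgb`` are per-channel extinction-like rates: the channel attenuation
    at full response (f = 1) is 10^(-k).  The defaults mimic a TMB-type
    yellow reaction under a warm-white backlight: blue absorbs strongly,
    green mildly, red barely.  ``conc_scale`` normalizes concentration for
    the linear and log laws; ``logistic_center``/``logistic_width`` place
    the sigmoid inflection (in concentration units) for the logistic law.
    """

    image_height: int = 960
    image_width: int = 1280
    inlet_origin: tuple[int, int] = (350, 510)
    inlet_size: int = 260
    background_kind: str = "checkerboard"
    background_tile: int = 8
    background_contrast: float = 60.0
    base_color: tuple[float, float, float] = (235.0, 228.0, 210.0)
    response_law: str = "log"
    k_rgb: tuple[float, float, float] = (0.04, 0.12, 0.35)
    conc_scale: float = 880.0
    logistic_center: float = 150.0
    logistic_width: float = 60.0
    noise_sd: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        r0, c0 = self.inlet_origin
        if self.inlet_size <= 0 or self.image_height <= 0 or self.image_width <= 0:
            raise ValueError("image and inlet dimensions must be positive")
        if r0 < 0 or c0 < 0 or r0 + self.inlet_size > self.image_height or c0 + self.inlet_size > self.image_width:
            raise ValueError("inlet must lie fully inside the image")
        if self.background_kind not in BACKGROUND_KINDS:
            raise ValueError(f"background_kind must be one of {BACKGROUND_KINDS}")
        if self.response_law not in RESPONSE_LAWS:
            raise ValueError(f"response_law must be one of {RESPONSE_LAWS}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.conc_scale <= 0 or self.logistic_width <= 0:
            raise ValueError("conc_scale and logistic_width must be positive")
        if any(not (0 <= v <= 255) for v in self.base_color):
            raise ValueError("base_color intensities must lie in [0, 255]")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["inlet_origin"] = list(self.inlet_origin)
        d["base_color"] = list(self.base_color)
        d["k_rgb"] = list(self.k_rgb)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        for key in ("inlet_origin", "base_color", "k_rgb"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def response_fraction(spec: PhantomSpec, concentration: float) -> float:
    """Normalized color response f(conc) in [0, 1] with f(0) = 0."""
    c = float(concentration)
    if c < 0:
        raise ValueError("concentration must be >= 0")
    if spec.response_law == "linear":
        return c / spec.conc_scale
    if spec.response_law == "log":
        return np.log1p(c) / np.log1p(spec.conc_scale)
    # logistic: sigmoid in concentration, shifted/rescaled so f(0) = 0, f(inf) = 1
    s = 1.0 / (1.0 + np.exp(-(c - spec.logistic_center) / spec.logistic_width))
    s0 = 1.0 / (1.0 + np.exp(spec.logistic_center / spec.logistic_width))
    return (s - s0) / (1.0 - s0)


def inlet_color(spec: PhantomSpec, concentration: float) -> np.ndarray:
    """Noise-free inlet channel intensities at one concentration."""
    f = response_fraction(spec, concentration)
    base = np.asarray(spec.base_color, dtype=np.float64)
    k = np.asarray(spec.k_rgb, dtype=np.float64)
    return base * np.power(10.0, -k * f)


def _background(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    h, w = spec.image_height, spec.image_width
    mid = 128.0
    half = spec.background_contrast / 2.0
    if spec.background_kind == "checkerboard":
        rows = np.arange(h) // spec.background_tile
        cols = np.arange(w) // spec.background_tile
        tiles = (rows[:, None] + cols[None, :]) % 2
        gray = mid - half + tiles * spec.background_contrast
    else:  # speckle
        gray = rng.uniform(mid - half, mid + half, size=(h, w))
    return np.repeat(gray[:, :, None], 3, axis=2)


def render_phantom(
    spec: PhantomSpec,
    concentration: float,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render one phantom image (H x W x 3 uint8).

    ``rng`` defaults to a fresh generator seeded with ``spec.seed``; pass an
    explicit generator to draw several images from one stream.  The
    background is drawn first, then per-pixel Gaussian sensor noise is added
    to the inlet, so the draw order is part of the determinism contract.
    """
    spec.validate()
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    img = _background(spec, rng)
    r0, c0 = spec.inlet_origin
    n = spec.inlet_size
    color = inlet_color(spec, concentration)
    patch = np.broadcast_to(color, (n, n, 3)).copy()
    if spec.noise_sd > 0:
        patch += rng.normal(0.0, spec.noise_sd, size=(n, n, 3))
    img[r0 : r0 + n, c0 : c0 + n, :] = patch
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def derived_rng(seed: int, level_index: int, replicate_index: int) -> np.random.Generator:
    """Per-image generator: a reproducible function of (seed, level, replicate)."""
    ss = np.random.SeedSequence([int(seed), int(level_index), int(replicate_index)])
    return np.random.default_rng(ss)


def generate_calibration_set(
    spec: PhantomSpec,
    concentrations=DEFAULT_LEVELS,
    replicates: int = 3,
    out_dir: str | Path = ".",
) -> tuple[Path, pd.DataFrame]:
    """Write phantom PNGs plus a sample sheet consumable by calibration.

    Returns (sheet path, sheet frame).  The sheet has columns
    ``image_path`` (relative to the sheet), ``concentration`` and ``role``
    (always ``calibration``; zero-concentration rows double as blanks
    downstream).  Each image gets its own generator derived from
    (spec.seed, level index, replicate index), so regenerating any subset
    reproduces identical files.
    """
    concentrations = [float(c) for c in concentrations]
    if len(concentrations) < 3:
        raise ValueError("need at least 3 concentration levels")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    spec.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    rows = []
    for i, conc in enumerate(concentrations):
        for j in range(replicates):
            name = f"cal_L{i:02d}_r{j:02d}.png"
            img = render_phantom(spec, conc, rng=derived_rng(spec.seed, i, j))
            try:
                Image.fromarray(img).save(out_dir / name)
            except OSError as exc:
                raise OSError(f"failed writing phantom image {out_dir / name}: {exc}") from exc
            rows.append({"image_path": name, "concentration": conc, "role": "calibration"})
    sheet = pd.DataFrame(rows, columns=["image_path", "concentration", "role"])
    sheet_path = out_dir / "sheet.csv"
    sheet.to_csv(sheet_path, index=False)
    return sheet_path, sheet


def file_sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
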