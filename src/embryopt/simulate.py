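"""Synthetic factorial tissue-culture dataset generator.

The original raw measurements are not publicly available, so experiments are
emulated: a 24-treatment factorial design (PGR grid, carbohydrate arm, light
arm, zero-PGR control) with 45 replicates per treatment, and a smooth
noise-free response surface calibrated to two published anchors — the
optimized medium yields EF = 100 % and NSE = 12.83, and the low-PGR medium
yields no response at all.  Surface shapes (Gaussian bumps, multiplicative
structure, light-corner multipliers) are generator parameters, not measured
quantities.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Input feature columns, in canonical order.
FEATURES = ["d24", "bap", "suc", "glu", "fru", "r", "g", "b"]

#: Response columns, in canonical order.
RESPONSES = ["cf", "ef", "nse"]

#: All dataset columns as written to CSV.
CSV_COLUMNS = FEATURES + RESPONSES + ["treatment_id", "replicate"]

#: RGB coding of the four light-quality treatments.
LIGHT_RGB = {
    "darkness": (0, 0, 0),
    "white": (255, 255, 255),
    "blue": (0, 0, 255),
    "red": (255, 0, 0),
}

#: Input vector of the published optimum used as a calibration anchor
#: (d24, bap, suc, glu, fru, r, g, b).
ANCHOR_X = (1.53, 1.67, 13.74, 57.20, 0.39, 254.48, 0.57, 18.25)

#: Responses the generator is calibrated to reproduce, noise-free, at ANCHOR_X.
ANCHOR_EF = 100.0
ANCHOR_NSE = 12.83


@dataclass(frozen=True)
class GeneratorConfig:
    """Design size, noise levels, and response-surface shape parameters.

    The surface parameters below the noise block are free choices of the
    generator; only the anchors above are tied to published values.
    """

    n_treatments: int = 24
    n_replicates: int = 45  # 15 explants x 3 sets
    noise_sd_freq: float = 1.2  # percent points, on cf and ef
    noise_sd_nse: float = 0.4  # embryos per explant
    seed: int = 0

    # PGR response: shared Gaussian bump for 2,4-D and BAP, hard zero when
    # both regulators sit below the gate.  The bump is centered on the
    # reported 1.5 mg/L optimum and kept narrow so the growth regulators
    # carry more of the response variance than any single carbohydrate.
    pgr_center: float = 1.5
    pgr_width: float = 0.40
    pgr_gate: float = 0.75

    # Carbohydrate response: weighted sum of per-sugar bumps (suc, glu, fru),
    # each an asymmetric Gaussian (separate width left/right of the center);
    # the glucose bump declines slowly above 60 g/L so glucose level matters
    # less than the growth regulators, while no-glucose media stay poor.
    sugar_centers: tuple[float, float, float] = (30.0, 60.0, 60.0)
    sugar_widths: tuple[float, float, float] = (4.0, 25.0, 12.0)
    sugar_widths_right: tuple[float, float, float] = (18.0, 60.0, 12.0)
    sugar_weights: tuple[float, float, float] = (0.8, 1.0, 0.55)

    # Light response: multipliers at the four treatment corners.
    light_darkness: float = 0.85
    light_white: float = 0.72
    light_blue: float = 0.58
    light_red: float = 1.00

    # Embryo count rises super-linearly with embryogenesis frequency: media
    # that halve EF cut the embryo yield per explant by about four.
    nse_exponent: float = 2.0

    def __post_init__(self) -> None:
        if self.noise_sd_freq < 0 or self.noise_sd_nse < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def light_to_rgb(light_name: str) -> tuple[int, int, int]:
    """Return the RGB coding of a named light-quality treatment.

    Raises
    ------
    ValueError
        If ``light_name`` is not one of darkness/white/blue/red.
    """
    key = light_name.lower()
    if key not in LIGHT_RGB:
        valid = ", ".join(sorted(LIGHT_RGB))
        raise ValueError(f"unknown light treatment {light_name!r}; valid names: {valid}")
    return LIGHT_RGB[key]


def _pgr_factor(d24: float, bap: float, cfg: GeneratorConfig) -> float:
    if d24 < cfg.pgr_gate and bap < cfg.pgr_gate:
        return 0.0
    w2 = 2.0 * cfg.pgr_width**2
    return math.exp(-((d24 - cfg.pgr_center) ** 2) / w2) * math.exp(
        -((bap - cfg.pgr_center) ** 2) / w2
    )


def _sugar_factor(suc: float, glu: float, fru: float, cfg: GeneratorConfig) -> float:
    total = 0.0
    for x, c, wl, wr, wt in zip(
        (suc, glu, fru),
        cfg.sugar_centers,
        cfg.sugar_widths,
        cfg.sugar_widths_right,
        cfg.sugar_weights,
    ):
        w = wl if x < c else wr
        total += wt * math.exp(-((x - c) ** 2) / (2.0 * w**2))
    return total


def _light_factor(r: float, g: float, b: float, cfg: GeneratorConfig) -> float:
    # The four treatment codings form a square in the (R, B) plane: darkness
    # (0,0), red (255,0), blue (0,255), white (255,255) -- G is redundant in
    # the design and is ignored by the surface.
    u = r / 255.0
    v = b / 255.0
    return (
        (1 - u) * (1 - v) * cfg.light_darkness
        + u * (1 - v) * cfg.light_red
        + (1 - u) * v * cfg.light_blue
        + u * v * cfg.light_white
    )


def _raw_shape(x: np.ndarray, cfg: GeneratorConfig) -> float:
    d24, bap, suc, glu, fru, r, g, b = (float(v) for v in x)
    return (
        _pgr_factor(d24, bap, cfg)
        * _sugar_factor(suc, glu, fru, cfg)
        * _light_factor(r, g, b, cfg)
    )


def true_response(
    features, config: GeneratorConfig | None = None
) -> tuple[float, float, float]:
    """Noise-free (cf, ef, nse) means at an 8-feature input point.

    The embryogenesis frequency is the product of a PGR bump, a carbohydrate
    mix factor, and a light factor, jointly rescaled so that the published
    optimum input maps exactly to EF = 100 and NSE = 12.83; responses are
    zero whenever both growth regulators fall below the gate concentration.
    """
    cfg = config or GeneratorConfig()
    x = np.asarray(features, dtype=float)
    if x.shape != (8,):
        raise ValueError(f"expected an 8-feature vector, got shape {x.shape}")
    if np.any(x < 0):
        raise ValueError("features must be non-negative")
    if np.any(x[5:8] > 255):
        raise ValueError("RGB channels must lie in [0, 255]")

    anchor = _raw_shape(np.asarray(ANCHOR_X), cfg)
    ef = min(100.0, ANCHOR_EF * _raw_shape(x, cfg) / anchor)
    nse = ANCHOR_NSE * (ef / 100.0) ** cfg.nse_exponent
    d24, bap = float(x[0]), float(x[1])
    active = 1.0 if (d24 >= cfg.pgr_gate or bap >= cfg.pgr_gate) else 0.0
    cf = min(100.0, ef / 0.9 + 10.0 * active)
    return cf, ef, nse


def build_design(config: GeneratorConfig | None = None) -> list[tuple[int, np.ndarray]]:
    """Enumerate the factorial design as (treatment_id, feature-vector) rows.

    The 24 default treatments comprise a 3x3 PGR grid (on 30 g/L sucrose,
    white light), ten carbohydrate treatments (three levels each of sucrose,
    glucose and fructose alone plus a 20+20+20 g/L mix, at 1.5/1.5 mg/L
    PGRs, white light), the four light qualities (at 1.5/1.5 PGRs on 60 g/L
    glucose), and a zero-PGR control.  Each treatment repeats
    ``n_replicates`` times in the generated dataset.
    """
    cfg = config or GeneratorConfig()
    if cfg.n_treatments != 24:
        raise ValueError(
            "only the default 24-treatment design is built in; supply your own "
            "design table for other sizes"
        )

    white = LIGHT_RGB["white"]
    rows: list[tuple[int, np.ndarray]] = []
    tid = 0

    # PGR grid at 30 g/L sucrose under white light.
    for d24 in (0.5, 1.5, 2.5):
        for bap in (0.5, 1.5, 2.5):
            rows.append((tid, np.array([d24, bap, 30.0, 0.0, 0.0, *white], dtype=float)))
            tid += 1

    # Carbohydrate arm at 1.5/1.5 mg/L PGRs under white light.
    carb_mixes = (
        [(s, 0.0, 0.0) for s in (20.0, 30.0, 60.0)]
        + [(0.0, g, 0.0) for g in (30.0, 60.0, 90.0)]
        + [(0.0, 0.0, f) for f in (30.0, 60.0, 90.0)]
        + [(20.0, 20.0, 20.0)]
    )
    for suc, glu, fru in carb_mixes:
        rows.append((tid, np.array([1.5, 1.5, suc, glu, fru, *white], dtype=float)))
        tid += 1

    # Light arm at 1.5/1.5 mg/L PGRs on 60 g/L glucose.
    for name in ("darkness", "white", "blue", "red"):
        rgb = light_to_rgb(name)
        rows.append((tid, np.array([1.5, 1.5, 0.0, 60.0, 0.0, *rgb], dtype=float)))
        tid += 1

    # Zero-PGR control.
    rows.append((tid, np.array([0.0, 0.0, 30.0, 0.0, 0.0, *white], dtype=float)))
    tid += 1

    assert len(rows) == cfg.n_treatments
    return rows


def generate(config: GeneratorConfig | None = None) -> pd.DataFrame:
    """Generate the replicated dataset with additive Gaussian noise.

    Per replicate, independent noise is added to the noise-free treatment
    means (``noise_sd_freq`` on cf/ef, ``noise_sd_nse`` on nse); cf and ef
    are clipped to [0, 100] and nse to >= 0; nse is forced to zero wherever
    ef is zero; and cf is raised to ef wherever noise left embryos on an
    uncallused explant.  Bit-identical output for a fixed seed.
    """
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    design = build_design(cfg)

    records = []
    for tid, x in design:
        cf0, ef0, nse0 = true_response(x, cfg)
        n = cfg.n_replicates
        cf = cf0 + rng.normal(0.0, cfg.noise_sd_freq, size=n) if cfg.noise_sd_freq else np.full(n, cf0)
        ef = ef0 + rng.normal(0.0, cfg.noise_sd_freq, size=n) if cfg.noise_sd_freq else np.full(n, ef0)
        nse = nse0 + rng.normal(0.0, cfg.noise_sd_nse, size=n) if cfg.noise_sd_nse else np.full(n, nse0)
        cf = np.clip(cf, 0.0, 100.0)
        ef = np.clip(ef, 0.0, 100.0)
        nse = np.clip(nse, 0.0, None)
        nse[ef == 0.0] = 0.0
        violated = (ef > 0.0) & (cf <= 0.0)
        cf[violated] = ef[violated]
        for rep in range(n):
            records.append(
                [*x, cf[rep], ef[rep], nse[rep], tid, rep]
            )

    df = pd.DataFrame(records, columns=CSV_COLUMNS)
    df["treatment_id"] = df["treatment_id"].astype(int)
    df["replicate"] = df["replicate"].astype(int)
    return df


def write_csv(df: pd.DataFrame, path) -> None:
    """Write a dataset to CSV with the canonical column order."""
    df.loc[:, CSV_COLUMNS].to_csv(path, index=False)


def read_csv(path) -> pd.DataFrame:
    """Read a dataset CSV, validating the canonical header."""
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"dataset CSV missing columns: {missing}")
    return df.loc[:, CSV_COLUMNS]


def config_to_dict(cfg: GeneratorConfig) -> dict:
    return dataclasses.asdict(cfg)


def config_from_dict(d: dict) -> GeneratorConfig:
    d = dict(d)
    for key in ("sugar_centers", "sugar_widths", "sugar_widths_right", "sugar_weights"):
        if key in d:
            d[key] = tuple(d[key])
    return GeneratorConfig(**d)
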