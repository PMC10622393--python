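"""Synthetic plate images with exactly known dish and colony areas.

The generator emulates the imaging design of a mycelial heat-stress
growth experiment: a bright circular Petri dish (medium) on a dark
background with a brighter, roughly circular colony inside, photographed
for three treatment groups (a control and two heat-stress intensities),
three replicate plates per group, on imaging days 9 and 13.

A pixel ``(row i, col j)`` belongs to a disk iff the distance from its
centre ``(x=j+0.5, y=i+0.5)`` to the disk centre is at most the radius
(Euclidean, centre-of-pixel convention).  The ground-truth A_d and A_c
are exact discrete tallies under this single convention, shared with the
brute-force oracle used in the tests, so end-to-end NCAR recovery can be
checked exactly on noiseless plates.  Optional additive Gaussian
intensity noise (clipped to [0, 255]) is reproducible from the seed.

Colony radial growth is linear in time, capped at the dish radius:
``radius(t) = min(r0 + rate * (t - d0), dish_radius)``, with an optional
per-plate relative jitter on the rate to emulate replicate variation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .core import AreaIndices
from .io import RedChannelImage

#: Default class intensities (background, medium, colony), well separated.
DEFAULT_INTENSITIES = (10, 120, 230)


class PlateSpecError(ValueError):
    """Raised when a plate or growth specification is inconsistent."""


@dataclass(frozen=True)
class PlateSpec:
    """Parametric description of one synthetic plate image.

    Geometry is in pixels; ``dish_center``/``colony_center`` are (x, y).
    ``intensities`` are (background, medium, colony) red levels and must
    strictly increase (light-colony orientation).
    """

    image_size: int
    dish_center: tuple[float, float]
    dish_radius: float
    colony_center: tuple[float, float]
    colony_radius: float
    intensities: tuple[int, int, int] = DEFAULT_INTENSITIES
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size < 16:
            raise PlateSpecError(f"image_size must be >= 16, got {self.image_size}")
        if not (0 < self.dish_radius):
            raise PlateSpecError("dish_radius must be positive")
        if self.colony_radius < 0:
            raise PlateSpecError("colony_radius must be >= 0")
        off = math.dist(self.colony_center, self.dish_center)
        if off + self.colony_radius > self.dish_radius + 1e-9:
            raise PlateSpecError(
                f"colony (r={self.colony_radius}, offset {off:.3g}) extends beyond "
                f"dish (r={self.dish_radius})"
            )
        b, m, c = self.intensities
        if not (0 <= b < m < c <= 255):
            raise PlateSpecError(f"need background < medium < colony in [0,255], got {self.intensities}")
        if self.noise_sigma < 0:
            raise PlateSpecError("noise_sigma must be >= 0")


@dataclass(frozen=True)
class GrowthModelSpec:
    """Linear, capped radial growth for each treatment group.

    ``radial_rates`` maps group label to radial advance in pixels/day.
    All groups start from the same ``initial_radius`` at the first
    imaging day (replicates are inoculated identically and kept at the
    control temperature before treatment).  ``replicate_jitter`` is the
    relative SD of the per-plate rate.
    """

    initial_radius: float
    radial_rates: Mapping[str, float]
    days: tuple[int, ...] = (9, 13)
    replicate_jitter: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.initial_radius < 0:
            raise PlateSpecError("initial_radius must be >= 0")
        if len(self.days) < 1 or list(self.days) != sorted(self.days):
            raise PlateSpecError("days must be ascending and non-empty")
        if len(set(self.days)) != len(self.days):
            raise PlateSpecError("days must be distinct")
        if not self.radial_rates:
            raise PlateSpecError("radial_rates must name at least one group")
        if self.replicate_jitter < 0:
            raise PlateSpecError("replicate_jitter must be >= 0")


def disk_mask(image_size: int, center: tuple[float, float], radius: float) -> np.ndarray:
    """Boolean mask of pixels whose centres lie within the disk."""
    yy, xx = np.mgrid[0:image_size, 0:image_size].astype(np.float64) + 0.5
    cx, cy = center
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= radius**2


def render_plate(spec: PlateSpec, source_id: str = "", day: int = 0) -> tuple[RedChannelImage, AreaIndices]:
    """Rasterize a plate spec; return the red raster and exact ground truth."""
    dish = disk_mask(spec.image_size, spec.dish_center, spec.dish_radius)
    colony = disk_mask(spec.image_size, spec.colony_center, spec.colony_radius)
    b, m, c = spec.intensities
    img = np.full((spec.image_size, spec.image_size), float(b))
    img[dish] = float(m)
    img[colony] = float(c)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sigma, img.shape)
    values = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    truth = AreaIndices(
        A_d=int(np.count_nonzero(dish)),
        A_c=int(np.count_nonzero(colony)),
        plate_id=source_id,
        day=day,
    )
    return RedChannelImage(values=values, source_id=source_id, day=day), truth


def colony_radius_at(growth: GrowthModelSpec, rate: float, day: int, cap: float) -> float:
    """Capped linear radius at a given day for one plate's jittered rate."""
    r = growth.initial_radius + rate * (day - growth.days[0])
    return min(max(r, 0.0), cap)


def radial_rates_for_ncar_rates(
    template: PlateSpec,
    initial_radius: float,
    days: tuple[int, int],
    ncar_rates_pp_per_day: Mapping[str, float],
) -> dict[str, float]:
    """Radial rates (px/day) that realize target NCAR growth rates (pp/day).

    Inverts the continuous-area relation eta = 100 * (r / R)^2: given the
    target NCAR gain per day g for a group, the end radius solves
    r2 = sqrt(r1^2 + (g/100) * dt * R^2) and the radial rate is
    (r2 - r1) / dt.  Discrete pixelation makes the realized NCAR rate
    deviate slightly from the target.
    """
    d1, d2 = days
    if d2 <= d1:
        raise PlateSpecError("need two ascending days")
    dt = d2 - d1
    big_r = template.dish_radius
    out: dict[str, float] = {}
    for g, pp in ncar_rates_pp_per_day.items():
        r2_sq = initial_radius**2 + (pp / 100.0) * dt * big_r**2
        if r2_sq < 0:
            raise PlateSpecError(f"group {g!r}: target NCAR rate {pp} pp/day not realizable")
        out[g] = (math.sqrt(r2_sq) - initial_radius) / dt
    return out


def simulate_timeseries(
    growth: GrowthModelSpec,
    plate_template: PlateSpec,
    n_replicates: int = 3,
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Render a replicated multi-day plate series with exact ground truth.

    Returns ``(manifest, truth)`` data frames.  The manifest has columns
    ``path, group, replicate, day`` (``path`` empty when ``out_dir`` is
    None, in which case no PNGs are written); the truth table has one row
    per rendered plate with the exact pixel areas and NCAR, i.e. columns
    ``group, replicate, plate_id, day, A_d, A_c, ratio, eta_percent``.

    Per-plate rates are jittered multiplicatively (clipped at zero) and
    every random draw derives deterministically from ``growth.seed``.
    """
    if n_replicates < 1:
        raise PlateSpecError("n_replicates must be >= 1")
    if growth.initial_radius > plate_template.dish_radius + 1e-9:
        raise PlateSpecError(
            f"initial_radius: colony ({growth.initial_radius}) exceeds dish "
            f"radius ({plate_template.dish_radius})"
        )
    groups = sorted(growth.radial_rates)
    ss = np.random.SeedSequence(growth.seed)
    jitter_rng = np.random.default_rng(ss.spawn(1)[0])
    noise_seeds = iter(s.generate_state(1)[0] % (2**31) for s in ss.spawn(
        len(groups) * n_replicates * len(growth.days)
    ))

    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)

    manifest_rows: list[dict] = []
    truth_rows: list[dict] = []
    for group in groups:
        base_rate = growth.radial_rates[group]
        for rep in range(1, n_replicates + 1):
            eps = jitter_rng.normal(0.0, growth.replicate_jitter) if growth.replicate_jitter > 0 else 0.0
            rate = max(base_rate * (1.0 + eps), 0.0)
            plate_id = f"{group}_r{rep}"
            for day in growth.days:
                radius = colony_radius_at(growth, rate, day, plate_template.dish_radius)
                spec = replace(
                    plate_template, colony_radius=radius, seed=int(next(noise_seeds))
                )
                img, truth = render_plate(spec, source_id=plate_id, day=day)
                rel = ""
                if out_path is not None:
                    rel = f"{plate_id}_day{day}.png"
                    rgb = np.repeat(img.values[:, :, None], 3, axis=2)
                    Image.fromarray(rgb, mode="RGB").save(out_path / rel)
                manifest_rows.append(
                    {"path": rel, "group": group, "replicate": rep, "day": day}
                )
                truth_rows.append(
                    {
                        "group": group,
                        "replicate": rep,
                        "plate_id": plate_id,
                        "day": day,
                        "A_d": truth.A_d,
                        "A_c": truth.A_c,
                        "ratio": truth.A_c / truth.A_d,
                        "eta_percent": 100.0 * truth.A_c / truth.A_d,
                    }
                )
    manifest = pd.DataFrame(manifest_rows)
    truth = pd.DataFrame(truth_rows)
    if out_path is not None:
        manifest.to_csv(out_path / "manifest.csv", index=False)
        truth.to_csv(out_path / "ground_truth.csv", index=False)
    return manifest, truth


def default_plate_template(image_size: int = 1024, noise_sigma: float = 0.0, seed: int = 0) -> PlateSpec:
    """Concentric dish filling 88% of the frame (a 90 mm dish emulation)."""
    c = image_size / 2.0
    return PlateSpec(
        image_size=image_size,
        dish_center=(c, c),
        dish_radius=0.44 * image_size,
        colony_center=(c, c),
        colony_radius=0.0,
        noise_sigma=noise_sigma,
        seed=seed,
    )


def default_study_spec(
    image_size: int = 1024, noise_sigma: float = 0.0, replicate_jitter: float = 0.05, seed: int = 0
) -> tuple[GrowthModelSpec, PlateSpec, int]:
    """The bundled default study: 3 groups x 3 replicates x days 9 and 13.

    Groups emulate a 25 C control (CK-like), a moderate heat stress
    (MHT-like) and a severe heat stress (SHT-like) with measured radial
    rates of 2.385, 3.28 and 0.29 mm/day (half the reported diameter
    rates of 4.77, 6.56 and 0.58 mm/day).  The 90 mm dish spans 88% of
    the frame, fixing the mm-to-pixel scale; all colonies start from the
    same radius at day 9 (about 23 mm: a 1.5 mm inoculum plug grown 9
    days at the control rate).
    """
    template = default_plate_template(image_size, noise_sigma=noise_sigma, seed=seed)
    px_per_mm = (2 * template.dish_radius) / 90.0
    rates_mm = {"CK": 2.385, "MHT": 3.28, "SHT": 0.29}
    growth = GrowthModelSpec(
        initial_radius=(1.5 + 9 * 2.385) * px_per_mm,
        radial_rates={g: r * px_per_mm for g, r in rates_mm.items()},
        days=(9, 13),
        replicate_jitter=replicate_jitter,
        seed=seed,
    )
    return growth, template, 3
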