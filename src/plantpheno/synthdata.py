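"""Synthetic greenhouse scenes and simulated co-culture cohorts.

Every downstream stage of the pipeline is testable against known ground
truth: :func:`render_scene` draws plants (vertical stem plus elliptical leaf
lobes) on a dark felt-like background next to an achromatic white-reference
ruler strip, applies a per-channel illuminant cast multiplicatively and adds
Gaussian sensor noise; :func:`simulate_cohort` produces per-plant tables with
the randomized-complete-block structure of the host-range experiment
(5 blocks x 27 pots: 6 hosts x 3 replicate pots + 9 host-free control pots,
7 parasites per pot, weekly survivorship over 5 weeks).

A single latent "parasitism intensity" per host couples weekly mortality,
the green/red reflectance (paleness), dry mass and height, reproducing the
qualitative host ordering of the experiment: hosts inducing the highest
mortality leave "pale and plump" survivors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .imaging import RGBImage, mask_perimeter

__all__ = [
    "PlantSpec",
    "SceneSpec",
    "CohortDesign",
    "EffectModel",
    "GroundTruth",
    "plant_from_base",
    "render_scene",
    "render_scene_with_meta",
    "simulate_cohort",
    "cohort_scenes",
    "DEFAULT_HOSTS",
    "CONTROL",
]

CONTROL = "control"
DEFAULT_HOSTS = ("juncus", "oryza", "arabidopsis", "medicago", "zea", "solanum")

#: Latent parasitism intensity per host: drives mortality, paleness,
#: mass gain and height reduction (0 = host-free control).
PARASITISM = {
    CONTROL: 0.0,
    "juncus": 0.05,
    "oryza": 0.10,
    "arabidopsis": 0.35,
    "medicago": 0.45,
    "zea": 0.85,
    "solanum": 0.90,
}


@dataclass(frozen=True)
class PlantSpec:
    """Ground-truth description of one plant to be rendered."""

    plant_id: str
    height_cm: float
    plumpness: float = 0.0
    chlorophyll: float = 0.5
    mass_mg: float = 15.0

    def __post_init__(self):
        if self.height_cm <= 0:
            raise ValueError("height_cm must be positive")
        if not 0.0 <= self.plumpness <= 1.0:
            raise ValueError("plumpness must be in [0, 1]")
        if not 0.0 <= self.chlorophyll <= 1.0:
            raise ValueError("chlorophyll must be in [0, 1]")
        if self.mass_mg <= 0:
            raise ValueError("mass_mg must be positive")

    @property
    def reflectance(self) -> np.ndarray:
        """True linear RGB reflectance; G/R = 1 + 2*chlorophyll."""
        r = 0.22
        return np.array([r, r * (1.0 + 2.0 * self.chlorophyll), 0.10])


def plant_from_base(
    plant_id: str,
    base_height_cm: float,
    plumpness: float,
    chlorophyll: float = 0.5,
    mass_mg: float = 15.0,
) -> PlantSpec:
    """Build a PlantSpec trading height for girth along the plumpness axis.

    Plumpness p shortens the plant (height <- base*(1-0.5p)); the renderer
    widens stem and leaf lobes by (1+1.5p), mimicking shortened internodes
    and altered leaf morphology.
    """
    return PlantSpec(
        plant_id=plant_id,
        height_cm=base_height_cm * (1.0 - 0.5 * plumpness),
        plumpness=plumpness,
        chlorophyll=chlorophyll,
        mass_mg=mass_mg,
    )


@dataclass(frozen=True)
class SceneSpec:
    """One photograph: plants, scale, illuminant cast, noise, ruler strip."""

    plants: tuple[PlantSpec, ...]
    pixels_per_cm: float = 86.05
    illuminant_gains: tuple[float, float, float] = (1.0, 1.0, 1.0)
    background_level: float = 0.05
    noise_sd: float = 0.0
    ruler: tuple[int, int, int, int] | None = None  # (row0, col0, h, w); None = auto
    white_reflectance: float = 0.70

    def __post_init__(self):
        object.__setattr__(self, "plants", tuple(self.plants))
        if self.pixels_per_cm <= 0:
            raise ValueError("pixels_per_cm must be positive")
        if any(g <= 0 for g in self.illuminant_gains):
            raise ValueError("illuminant gains must be positive")
        if not 0.0 <= self.background_level <= 0.15:
            raise ValueError("background_level must be in [0, 0.15]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not self.plants:
            raise ValueError("scene must contain at least one plant")


@dataclass(frozen=True)
class GroundTruth:
    """True morphometry and reflectance color of one rendered plant."""

    plant_id: str
    area_px2: float
    perimeter_px: float
    bbox_height_px: int
    gr_reflectance: float
    centroid_col: float


def _plant_silhouette(
    spec: PlantSpec, ppcm: float, rng: np.random.Generator
) -> np.ndarray:
    """Binary silhouette of one plant in its own canvas.

    Vertical rectangular stem of exactly round(height_cm*ppcm) rows, with
    2-6 elliptical leaf lobes along the stem; lobe/stem widths scale with
    plumpness.  The apex row and soil row are guaranteed occupied so the
    bounding-box height equals the rounded true height.
    """
    h_px = max(3, int(round(spec.height_cm * ppcm)))
    widen = 1.0 + 1.5 * spec.plumpness
    stem_w = max(2, int(round(0.05 * h_px * widen)))
    lobe_a = max(2, int(round(0.16 * h_px * widen)))  # horizontal semi-axis
    lobe_b = max(2, int(round(0.07 * h_px)))  # vertical semi-axis
    half_w = lobe_a + stem_w
    w_px = 2 * half_w + 3
    canvas = np.zeros((h_px, w_px), dtype=bool)
    cx = w_px // 2
    canvas[:, cx - stem_w // 2 : cx - stem_w // 2 + stem_w] = True

    n_lobes = int(rng.integers(2, 7))
    rows = np.arange(h_px)[:, None]
    cols = np.arange(w_px)[None, :]
    for i in range(n_lobes):
        frac = 0.15 + 0.7 * i / max(1, n_lobes - 1)
        cy = int(frac * (h_px - 1))
        cy = min(max(cy, lobe_b), h_px - 1 - lobe_b)  # keep lobes inside bbox
        side = 1 if i % 2 == 0 else -1
        ccx = cx + side * (stem_w // 2 + lobe_a // 2)
        ellipse = ((rows - cy) / lobe_b) ** 2 + ((cols - ccx) / lobe_a) ** 2 <= 1.0
        canvas |= ellipse
    # trim empty columns, never rows (row extent is the true height)
    occupied = canvas.any(axis=0)
    first, last = np.argmax(occupied), len(occupied) - 1 - np.argmax(occupied[::-1])
    return canvas[:, first : last + 1]


def render_scene(
    scene: SceneSpec, seed: int
) -> tuple[RGBImage, list[GroundTruth]]:
    """Render a scene to a linear-light RGB image with per-plant ground truth.

    Pixel color = reflectance * illuminant_gains + Gaussian noise, clipped
    to [0, 1].  Truth records area, marching-squares perimeter and bbox
    height recomputed from each plant's noise-free binary silhouette, plus
    the true green/red reflectance ratio.  Raises if plant silhouettes
    overlap (segmentation ground truth would be ill-defined).
    """
    image, truths, _ = render_scene_with_meta(scene, seed)
    return image, truths


def render_scene_with_meta(
    scene: SceneSpec, seed: int
) -> tuple[RGBImage, list[GroundTruth], dict]:
    """Like :func:`render_scene`, also returning scene metadata.

    The metadata dict records the resolved ruler rectangle (row0, col0,
    height, width), image size and pixels_per_cm — what a downstream
    white-reference sampler needs.
    """
    rng = np.random.default_rng(seed)
    ppcm = scene.pixels_per_cm
    silhouettes = [_plant_silhouette(p, ppcm, rng) for p in scene.plants]

    margin = max(6, int(round(0.2 * ppcm)))
    ruler_w = scene.ruler[3] if scene.ruler is not None else max(12, int(round(0.5 * ppcm)))
    max_h = max(s.shape[0] for s in silhouettes)
    H = max_h + 2 * margin
    x = (ruler_w if scene.ruler is None else 0) + 2 * margin
    placements = []  # (row0, col0, silhouette)
    for sil in silhouettes:
        placements.append((H - margin - sil.shape[0], x, sil))
        x += sil.shape[1] + margin
    W = x + margin

    if scene.ruler is None:
        ruler = (margin, 2, H - 2 * margin, ruler_w)
    else:
        ruler = scene.ruler
    r0, c0, rh, rw = ruler
    if r0 < 0 or c0 < 0 or r0 + rh > H or c0 + rw > W:
        raise ValueError("ruler region outside the image")

    occupancy = np.zeros((H, W), dtype=np.uint8)
    occupancy[r0 : r0 + rh, c0 : c0 + rw] += 1
    reflectance = np.full((H, W, 3), scene.background_level, dtype=float)
    reflectance[r0 : r0 + rh, c0 : c0 + rw] = scene.white_reflectance

    truths = []
    for spec, (pr, pc, sil) in zip(scene.plants, placements):
        occupancy[pr : pr + sil.shape[0], pc : pc + sil.shape[1]] += sil
        reflectance[pr : pr + sil.shape[0], pc : pc + sil.shape[1]][sil] = spec.reflectance
        rows, cols = np.nonzero(sil)
        truths.append(
            GroundTruth(
                plant_id=spec.plant_id,
                area_px2=float(sil.sum()),
                perimeter_px=mask_perimeter(sil),
                bbox_height_px=int(rows.max() - rows.min() + 1),
                gr_reflectance=float(spec.reflectance[1] / spec.reflectance[0]),
                centroid_col=float(pc + cols.mean()),
            )
        )
    if occupancy.max() > 1:
        raise ValueError("plant silhouettes overlap each other or the ruler")

    gains = np.asarray(scene.illuminant_gains, dtype=float)
    pixels = reflectance * gains
    if scene.noise_sd > 0:
        pixels = pixels + rng.normal(0.0, scene.noise_sd, pixels.shape)
    pixels = np.clip(pixels, 0.0, 1.0)
    image = RGBImage(pixels=pixels, provenance=f"synthetic:seed={seed}")
    meta = {
        "ruler": [int(v) for v in ruler],
        "height_px": int(H),
        "width_px": int(W),
        "pixels_per_cm": scene.pixels_per_cm,
        "illuminant_gains": list(scene.illuminant_gains),
        "noise_sd": scene.noise_sd,
        "seed": int(seed),
    }
    return image, truths, meta


@dataclass(frozen=True)
class CohortDesign:
    """Randomized-complete-block co-culture layout."""

    n_blocks: int = 5
    hosts: tuple[str, ...] = DEFAULT_HOSTS
    control: str = CONTROL
    reps_per_host: int = 3
    control_reps: int = 9
    plants_per_pot: int = 7
    n_weeks: int = 5

    def __post_init__(self):
        object.__setattr__(self, "hosts", tuple(self.hosts))
        for name in ("n_blocks", "reps_per_host", "control_reps", "plants_per_pot", "n_weeks"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.control in self.hosts:
            raise ValueError("control label must not appear among hosts")

    @property
    def treatments(self) -> tuple[str, ...]:
        return (self.control,) + self.hosts

    @property
    def pots_per_block(self) -> int:
        return len(self.hosts) * self.reps_per_host + self.control_reps

    @property
    def n_plants(self) -> int:
        return self.n_blocks * self.pots_per_block * self.plants_per_pot


@dataclass(frozen=True)
class EffectModel:
    """Host-dependent effect sizes for the cohort simulator.

    Per-host weekly survival probability and lognormal mass/height and
    normal green/red parameters; a shared additive block effect (SD
    ``block_sd``, applied on the log scale for mass/height).
    """

    weekly_survival_prob: dict[str, float]
    mass_mu: dict[str, float]
    mass_sigma: float = 0.35
    height_mu: dict[str, float] = None  # type: ignore[assignment]
    height_sigma: float = 0.20
    gr_mean: dict[str, float] = None  # type: ignore[assignment]
    gr_sd: float = 0.15
    block_sd: float = 0.05

    def __post_init__(self):
        for p in self.weekly_survival_prob.values():
            if not 0.0 < p <= 1.0:
                raise ValueError("weekly survival probabilities must be in (0, 1]")
        for sd in (self.mass_sigma, self.height_sigma, self.gr_sd, self.block_sd):
            if sd < 0:
                raise ValueError("all SDs must be non-negative")

    @classmethod
    def default(cls, treatments: tuple[str, ...] = (CONTROL,) + DEFAULT_HOSTS) -> "EffectModel":
        """Host effects driven by the latent parasitism intensity.

        Control weekly survival 0.87 (~50% after 5 weeks); the strongest
        hosts reach ~0.78/week (~28% after 5 weeks).  Paleness (lower G/R),
        mass gain and height reduction scale with the same latent factor.
        """
        pi = {t: PARASITISM.get(t, 0.5) for t in treatments}
        return cls(
            weekly_survival_prob={t: 0.87 - 0.105 * pi[t] for t in treatments},
            mass_mu={t: np.log(15.0) + 0.8 * pi[t] for t in treatments},
            height_mu={t: np.log(80.0) - 0.45 * pi[t] for t in treatments},
            gr_mean={t: 2.0 - 0.8 * pi[t] for t in treatments},
        )

    @classmethod
    def null(cls, treatments: tuple[str, ...] = (CONTROL,) + DEFAULT_HOSTS) -> "EffectModel":
        """All hosts identical to the control (for calibration studies)."""
        return cls(
            weekly_survival_prob={t: 0.87 for t in treatments},
            mass_mu={t: np.log(15.0) for t in treatments},
            height_mu={t: np.log(80.0) for t in treatments},
            gr_mean={t: 2.0 for t in treatments},
        )


def simulate_cohort(
    design: CohortDesign, effects: EffectModel, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one co-culture cohort.

    Returns ``(plant_table, weekly_survival_table)``.  Each plant follows a
    Bernoulli survival chain with its host's weekly survival probability
    (dead plants stay dead); final survivors receive mass (mg), height (mm)
    and a green/red ratio drawn with host plus additive block effects.
    """
    rng = np.random.default_rng(seed)
    treatments = design.treatments
    missing = [t for t in treatments if t not in effects.weekly_survival_prob]
    if missing:
        raise ValueError(f"effects missing treatments: {missing}")

    rows = []
    for b in range(1, design.n_blocks + 1):
        pot_i = 0
        for host in treatments:
            reps = design.control_reps if host == design.control else design.reps_per_host
            for _ in range(reps):
                pot_i += 1
                pot_id = f"b{b}p{pot_i:02d}"
                for j in range(1, design.plants_per_pot + 1):
                    rows.append((f"{pot_id}_{j}", b, pot_id, host))
    plants = pd.DataFrame(rows, columns=["plant_id", "block", "pot_id", "host"])
    n = len(plants)

    p_week = plants["host"].map(effects.weekly_survival_prob).to_numpy()
    alive = np.ones(n, dtype=bool)
    for w in range(1, design.n_weeks + 1):
        alive &= rng.random(n) < p_week
        plants[f"alive_week_{w}"] = alive
    plants["alive_final"] = alive

    # additive block effects, one draw per (block, response)
    blocks = np.arange(1, design.n_blocks + 1)
    be = {
        resp: dict(zip(blocks, rng.normal(0.0, effects.block_sd, len(blocks))))
        for resp in ("mass", "height", "gr")
    }
    bidx = plants["block"].to_numpy()
    host = plants["host"]
    mass = np.exp(
        host.map(effects.mass_mu).to_numpy()
        + np.vectorize(be["mass"].get)(bidx)
        + rng.normal(0.0, effects.mass_sigma, n)
    )
    height = np.exp(
        host.map(effects.height_mu).to_numpy()
        + np.vectorize(be["height"].get)(bidx)
        + rng.normal(0.0, effects.height_sigma, n)
    )
    gr = (
        host.map(effects.gr_mean).to_numpy()
        + np.vectorize(be["gr"].get)(bidx)
        + rng.normal(0.0, effects.gr_sd, n)
    )
    gr = np.clip(gr, 0.05, None)
    plants["mass_mg"] = np.where(alive, mass, np.nan)
    plants["height_mm"] = np.where(alive, height, np.nan)
    plants["gr_ratio"] = np.where(alive, gr, np.nan)

    week_cols = [f"alive_week_{w}" for w in range(1, design.n_weeks + 1)]
    counts = plants.groupby(["pot_id", "block", "host"], sort=True)[week_cols].sum()
    weekly = counts.reset_index().melt(
        id_vars=["pot_id", "block", "host"], var_name="week", value_name="n_alive"
    )
    weekly["week"] = weekly["week"].str.removeprefix("alive_week_").astype(int)
    weekly["n_planted"] = design.plants_per_pot
    weekly["proportion"] = weekly["n_alive"] / weekly["n_planted"]
    weekly = weekly.sort_values(["pot_id", "week"]).reset_index(drop=True)
    return plants, weekly


def cohort_scenes(
    plant_table: pd.DataFrame,
    pixels_per_cm: float = 12.0,
    illuminant_gains: tuple[float, float, float] = (1.0, 1.0, 1.0),
    background_level: float = 0.05,
    noise_sd: float = 0.0,
) -> dict[str, SceneSpec]:
    """One SceneSpec per pot, rendering that pot's final survivors.

    Plant height comes from the simulated height (mm), chlorophyll from the
    simulated G/R ratio (gr = 1 + 2*chlorophyll inverted, clipped to [0,1])
    and plumpness from the mass:height ratio, so the photographs are
    consistent with the tabular twin.  Pots with no survivors get no scene.
    """
    scenes: dict[str, SceneSpec] = {}
    for pot_id, grp in plant_table[plant_table["alive_final"]].groupby("pot_id", sort=True):
        specs = []
        for _, row in grp.sort_values("plant_id").iterrows():
            mh = row["mass_mg"] / row["height_mm"]
            plump = float(np.clip((mh - 0.1) / 0.6, 0.0, 1.0))
            chl = float(np.clip((row["gr_ratio"] - 1.0) / 2.0, 0.0, 1.0))
            specs.append(
                PlantSpec(
                    plant_id=row["plant_id"],
                    height_cm=max(0.5, row["height_mm"] / 10.0),
                    plumpness=plump,
                    chlorophyll=chl,
                    mass_mg=row["mass_mg"],
                )
            )
        scenes[pot_id] = SceneSpec(
            plants=tuple(specs),
            pixels_per_cm=pixels_per_cm,
            illuminant_gains=illuminant_gains,
            background_level=background_level,
            noise_sd=noise_sd,
        )
    return scenes
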