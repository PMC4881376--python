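"""Synthetic NanoSIMS data with the statistical structure of a multi-isotope
SIP experiment.

Three levels of realism, each feeding a different pipeline stage:

1. :func:`generate_ratio_table` — diagonal-Gaussian mixture in 6-dim ratio
   space (one component per isotope phenotype), parameterized by the
   per-condition presets.
2. :func:`generate_count_table` — inverts the ratio definitions to expected
   per-channel ion counts at a chosen CN total, then draws Poisson counts.
3. :func:`generate_ion_scene` — paints cells (filaments, cocci, rods) on a
   multi-plane, multi-channel ion image with Poisson shot noise and optional
   per-plane stage drift, returning the ground-truth ROI mask and FISH table.

All outputs are deterministic functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import presets as _p
from .io import CHANNEL_LABELS, IonImageStack, MassChannel
from .isotope import COUNT_COLUMNS, KEY_COLUMNS

_RATIOS = list(_p.ALL_RATIOS)


@dataclass
class ComponentSpec:
    """One mixture component = one isotope phenotype."""

    name: str
    n_rois: int
    means: dict[str, float]           # all 6 ratio columns
    sds: dict[str, float]
    taxon_mix: dict[str, float] = field(default_factory=lambda: {"gamma": 1.0})
    morphology: str = "coccus"

    def __post_init__(self):
        if self.n_rois < 0:
            raise ValueError("n_rois must be >= 0")
        if any(s < 0 for s in self.sds.values()):
            raise ValueError("sds must be >= 0")
        tot = sum(self.taxon_mix.values())
        if abs(tot - 1.0) > 1e-9:
            raise ValueError("taxon_mix must sum to 1")


@dataclass
class MixtureSpec:
    """A full mixture: list of components plus sampling policy."""

    components: list[ComponentSpec]
    name: str = "custom"
    ratio_floor: float = 1e-6

    def __post_init__(self):
        if sum(c.n_rois for c in self.components) <= 0:
            raise ValueError("mixture must contain at least one ROI")

    @property
    def total_n(self) -> int:
        return sum(c.n_rois for c in self.components)


def preset_mixture(name: str) -> MixtureSpec:
    """Build the five-component mixture for a preset condition.

    ``name`` is one of day2/day7/day10/unlabeled/killed (aliases NL, K).
    Components with zero ROIs (phenotype b at day 10) are dropped.
    """
    key = _p.PRESET_ALIASES.get(name)
    if key is None:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(_p.PRESET_ALIASES)}")
    block = _p.PRESET_BLOCKS[key]
    comps = []
    for cname in _p.CLUSTER_NAMES:
        n, means, sds = block[cname]
        if n == 0:
            continue
        means = dict(means, r34S=_p.R34S_MEAN)
        sds = dict(sds, r34S=_p.R34S_SD)
        comps.append(ComponentSpec(cname, n, means, sds,
                                   taxon_mix=dict(_p.DEFAULT_TAXON_MIX[cname]),
                                   morphology=_p.DEFAULT_MORPHOLOGY[cname]))
    return MixtureSpec(comps, name=key)


def generate_ratio_table(spec: MixtureSpec, seed: int = 0
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a per-ROI ratio table plus ground-truth component/taxon labels.

    Each component contributes ``n_rois`` independent draws from a diagonal
    Gaussian over the six ratio columns.  Draws with any coordinate at or
    below ``ratio_floor`` are rejected and resampled (truncation without a
    point mass at the floor).  ROIs are keyed (synthetic, <preset>, i).
    """
    rng = np.random.default_rng(seed)
    rows, truth_rows = [], []
    for comp in spec.components:
        mu = np.array([comp.means[r] for r in _RATIOS])
        sd = np.array([comp.sds[r] for r in _RATIOS])
        got = []
        # rejection sampling below the floor; sd=0 columns pass iff mean > floor
        guard = 0
        while len(got) < comp.n_rois:
            draw = rng.normal(mu, sd, size=(max(comp.n_rois, 16), 6))
            ok = (draw > spec.ratio_floor).all(axis=1)
            got.extend(draw[ok])
            guard += 1
            if guard > 1000:
                raise RuntimeError(f"component {comp.name}: cannot satisfy ratio_floor")
        got = np.array(got[:comp.n_rois])
        taxa = rng.choice(list(comp.taxon_mix), size=comp.n_rois,
                          p=list(comp.taxon_mix.values()))
        rows.append(got)
        truth_rows.append(pd.DataFrame({
            "component": comp.name, "taxon": taxa, "morphology": comp.morphology}))
    X = np.vstack(rows)
    n = len(X)
    index = pd.MultiIndex.from_arrays(
        [np.repeat("synthetic", n), np.repeat(spec.name, n), np.arange(1, n + 1)],
        names=KEY_COLUMNS)
    ratios = pd.DataFrame(X, columns=_RATIOS, index=index)
    truth = pd.concat(truth_rows, ignore_index=True)
    truth.index = index
    return ratios, truth


def expected_channel_counts(ratios: pd.DataFrame, total_cn) -> pd.DataFrame:
    """Invert the ratio definitions to expected per-channel counts.

    Given a CN total per ROI: nc14 = CN/(1+r15N), nc15 = CN·r15N/(1+r15N);
    total C = rC_CN·CN split by r13C; total S = rS_CN·CN with
    s32 = S/(1+r33S+r34S) and s33, s34 as the corresponding multiples.
    """
    cn = np.broadcast_to(np.asarray(total_cn, dtype=float), (len(ratios),))
    if (cn <= 0).any():
        raise ValueError("total CN counts must be > 0")
    r = ratios
    if ((r[_RATIOS] < 0).any().any()):
        raise ValueError("ratios must be >= 0")
    nc14 = cn / (1.0 + r["r15N"])
    nc15 = cn - nc14
    ctot = r["rC_CN"] * cn
    c12 = ctot / (1.0 + r["r13C"])
    c13 = ctot - c12
    stot = r["rS_CN"] * cn
    denom = 1.0 + r["r33S"] + r["r34S"]
    s32 = stot / denom
    s33 = s32 * r["r33S"]
    s34 = s32 * r["r34S"]
    if (s32 < 0).any():
        raise ValueError("inconsistent sulfur ratios imply negative 32S share")
    return pd.DataFrame({"c12": c12, "c13": c13, "nc14": nc14, "nc15": nc15,
                         "s32": s32, "s33": s33, "s34": s34}, index=ratios.index)


def generate_count_table(ratios: pd.DataFrame, total_cn=1_000_000.0,
                         seed: int = 0, area_px: int = 100,
                         n_planes: int = 1) -> pd.DataFrame:
    """Poisson-realized ROI count table consistent with target ratios.

    Expected channel counts are computed with
    :func:`expected_channel_counts`, then each channel count is drawn as an
    independent Poisson variate (ion counting statistics).  Centroids are
    placed on a grid purely for bookkeeping.
    """
    rng = np.random.default_rng(seed)
    exp = expected_channel_counts(ratios, total_cn)
    counts = pd.DataFrame(rng.poisson(exp.to_numpy()),
                          columns=COUNT_COLUMNS, index=ratios.index)
    n = len(counts)
    side = int(np.ceil(np.sqrt(n)))
    tab = counts.reset_index()
    tab["centroid_x"] = (np.arange(n) % side) * 10.0
    tab["centroid_y"] = (np.arange(n) // side) * 10.0
    tab["area_px"] = area_px
    tab["n_planes"] = n_planes
    return tab


# ---------------------------------------------------------------------------
# image-level scene


@dataclass
class SceneSpec:
    """Geometry and signal levels of a synthetic ion-image scene."""

    n_cells: int = 30
    pixels: int = 256
    raster_um: float = 15.0
    dwell_time: float = 0.015
    cn_counts_per_cell: float = 5e5     # expected accumulated CN total per cell
    background_rate: float = 0.05      # expected counts/pixel/plane, all channels
    n_planes: int = 3
    drift_per_plane: tuple[int, int] = (0, 0)   # (dy, dx) per successive plane
    filament_length_px: int = 60
    filament_width_px: int = 5
    coccus_radius_px: int = 6
    rod_length_px: int = 14
    rod_width_px: int = 4
    margin_px: int = 16
    max_placement_tries: int = 2000


def _paint_cell(shape, morphology, rng, spec: SceneSpec):
    """Boolean pixel mask for one cell placed at a random pose."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    m = spec.margin_px
    cy = rng.integers(m, h - m)
    cx = rng.integers(m, w - m)
    if morphology == "coccus":
        r = spec.coccus_radius_px
        return (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
    length = spec.filament_length_px if morphology == "filament" else spec.rod_length_px
    width = spec.filament_width_px if morphology == "filament" else spec.rod_width_px
    theta = rng.uniform(0, np.pi)
    dy, dx = np.sin(theta), np.cos(theta)
    py, px = yy - cy, xx - cx
    along = py * dy + px * dx
    perp = -py * dx + px * dy
    return (np.abs(along) <= length / 2) & (np.abs(perp) <= width / 2)


def generate_ion_scene(scene: SceneSpec, mixture: MixtureSpec, seed: int = 0):
    """Full image-level simulation.

    Cells are placed without overlap (uniform random poses, retry on
    collision), each assigned a mixture component with probability
    proportional to component sizes.  Per-channel expected counts for the
    cell are spread uniformly over its pixels and over planes; each plane is
    an independent Poisson draw, optionally shifted by a cumulative integer
    drift.  Returns (stack, roi_mask, fish_table, truth_table).
    """
    rng = np.random.default_rng(seed)
    h = w = scene.pixels
    labels = np.zeros((h, w), dtype=np.uint16)
    comp_sizes = np.array([c.n_rois for c in mixture.components], dtype=float)
    comp_probs = comp_sizes / comp_sizes.sum()
    ratios_drawn, cells = [], []
    placed = 0
    tries = 0
    while placed < scene.n_cells:
        tries += 1
        if tries > scene.max_placement_tries:
            raise RuntimeError("cell placement failed; lower n_cells or density")
        ci = rng.choice(len(mixture.components), p=comp_probs)
        comp = mixture.components[ci]
        mask = _paint_cell((h, w), comp.morphology, rng, spec=scene)
        if not mask.any() or (labels[mask] != 0).any():
            continue
        placed += 1
        labels[mask] = placed
        mu = np.array([comp.means[r] for r in _RATIOS])
        sd = np.array([comp.sds[r] for r in _RATIOS])
        while True:
            draw = rng.normal(mu, sd)
            if (draw > mixture.ratio_floor).all():
                break
        ratios_drawn.append(draw)
        taxon = rng.choice(list(comp.taxon_mix), p=list(comp.taxon_mix.values()))
        cells.append((comp.name, taxon, comp.morphology, mask))
    index = pd.MultiIndex.from_arrays(
        [["synthetic"] * placed, [mixture.name] * placed, np.arange(1, placed + 1)],
        names=KEY_COLUMNS)
    ratios = pd.DataFrame(ratios_drawn, columns=_RATIOS, index=index)
    exp = expected_channel_counts(ratios, scene.cn_counts_per_cell)
    # per-pixel expected rate per plane, per channel
    rate = np.full((7, h, w), scene.background_rate, dtype=float)
    for i, (_, _, _, mask) in enumerate(cells):
        npx = mask.sum()
        for ch_i, col in enumerate(COUNT_COLUMNS):
            rate[ch_i][mask] += exp.iloc[i, ch_i] / (npx * scene.n_planes)
    planes = np.empty((7, scene.n_planes, h, w), dtype=np.uint32)
    dy, dx = scene.drift_per_plane
    for p in range(scene.n_planes):
        shifted = np.roll(np.roll(rate, p * dy, axis=1), p * dx, axis=2)
        planes[:, p] = rng.poisson(shifted)
    channels = [MassChannel(lab) for lab in CHANNEL_LABELS]
    stack = IonImageStack(channels=channels, counts=planes,
                          dwell_time=scene.dwell_time, raster_size=scene.raster_um,
                          session_meta={"session": "synthetic", "region": mixture.name})
    fish = pd.DataFrame({
        "session": "synthetic", "region": mixture.name,
        "roi_id": np.arange(1, placed + 1),
        "taxon": [c[1] for c in cells],
        "morphology": [c[2] for c in cells]})
    truth = pd.DataFrame({"component": [c[0] for c in cells]}, index=index)
    truth = truth.join(ratios)
    return stack, labels, fish, truth


def default_full_simulation(seed: int = 0) -> dict[str, tuple[pd.DataFrame, pd.DataFrame]]:
    """Ratio tables for all five preset conditions (the full study design).

    Returns a mapping preset -> (ratios, truth).  The concatenated row count
    reproduces the full single-cell ROI census of the study design.
    """
    out = {}
    for i, name in enumerate(_p.PRESET_BLOCKS):
        out[name] = generate_ratio_table(preset_mixture(name), seed=seed + i)
    return out
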