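"""Synthetic landscapes, populations, genotypes and responses.

Emulates the study system — 5 x 5 km agricultural landscape windows with a
mosaic of land-use parcels, linear landscape elements with controllable
orientation bias, up to six forest-herb populations per window spanning
orders of magnitude in flowering-shoot count — with known ground truth, so
every pipeline stage can be tested closed-loop.

Land-use mosaics are Voronoi partitions of random seed points with classes
assigned to approach target area fractions.  Linear elements are
random-walk chains whose segment headings follow a von Mises distribution
(concentration kappa around a mean angle), giving controllable orientation
anisotropy.  Genotypes follow a Dirichlet hierarchy: ancestral allele
frequencies per locus are symmetric Dirichlet(1), each population draws
its frequencies from Dirichlet(ancestral * (1 - theta)/theta) with
divergence theta a logistic function of a configurable node-level driver —
not a coalescent simulation, but sufficient to exercise the statistics.
Responses are drawn exactly from the mixed-model generative process.

All generators are pure functions of (config, seed); each stage draws from
a named substream so changing one stage cannot shift another's draws.
"""

from __future__ import annotations

import itertools
import json
import math
import zlib
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import LineString, MultiPolygon, Point, Polygon, box
from shapely.ops import voronoi_diagram

from .landscape import (
    AREA_CLASSES,
    CROP_TYPES,
    CROP_YEARS,
    LINE_CLASSES,
    LandscapeWindow,
    LandusePolygon,
    LinearElement,
)

__all__ = [
    "ScenarioConfig",
    "generate_window",
    "place_populations",
    "simulate_genotypes",
    "simulate_responses",
    "generate_scenario",
    "make_golden_fixture",
]

DEFAULT_CLASS_FRACTIONS = {
    # realistic agricultural mosaic: arable-dominated with scattered forest
    "FOREST": 0.12,
    "GRASS": 0.18,
    "SEMNATGRASS": 0.03,
    "SEMNATVEG": 0.02,
    "ARABLE": 0.50,
    "ORCHARD": 0.01,
    "SETTLE": 0.06,
    "OTHER": 0.08,
}
DEFAULT_LINE_DENSITY = {  # m/ha over the window
    "LWOOD": 25.0,
    "LWATER": 12.0,
    "LFRINGE": 4.0,
    "LROAD": 15.0,
}
DEFAULT_CROP_PROBS = {"RAPE": 0.15, "MAIZE": 0.25, "CEREAL": 0.40, "OTHER": 0.20}


@dataclass
class ScenarioConfig:
    """Ground-truth parameters of a synthetic study.

    Defaults mirror the study conditions: 5 x 5 km windows, up to six
    populations per window separated by at least 200 m, flowering-shoot
    counts log-uniform between 15 and 1.2e7, crop records for 2008-2017.
    """

    seed: int = 0
    n_windows: int = 4
    window_size_m: float = 5000.0
    pops_per_window: int = 6
    n_parcels: int = 60
    class_fractions: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_FRACTIONS))
    line_density: dict = field(default_factory=lambda: dict(DEFAULT_LINE_DENSITY))
    line_kappa: float = 0.0  # von Mises concentration of segment headings
    line_mean_angle: float = 0.0  # radians
    crop_probs: dict = field(default_factory=lambda: dict(DEFAULT_CROP_PROBS))
    min_pop_size: float = 15.0
    max_pop_size: float = 1.2e7
    min_separation_m: float = 200.0
    # genetics
    ploidy: int = 2
    n_loci: int = 6
    alleles_per_locus: int = 8
    n_individuals: int = 20
    theta_intercept: float = -2.5  # logistic baseline divergence
    theta_slope: float = 0.0  # effect of the standardized driver on divergence
    # response model
    beta: dict = field(default_factory=dict)  # term -> true coefficient
    sigma2_window: float = 0.25
    sigma2_pop: float = 0.25
    sigma2_resid: float = 0.5

    def __post_init__(self) -> None:
        if self.pops_per_window > 6:
            raise ValueError("at most six populations per window")
        if sum(self.class_fractions.values()) > 1.0 + 1e-9:
            raise ValueError("class fractions sum above 1")
        if self.line_kappa < 0:
            raise ValueError("kappa must be non-negative")
        for v in (self.sigma2_window, self.sigma2_pop, self.sigma2_resid):
            if v < 0:
                raise ValueError("variances must be non-negative")


def _rng(config: ScenarioConfig, stage: str, index: int = 0) -> np.random.Generator:
    """Named substream: independent generator per (seed, stage, index)."""
    tag = zlib.crc32(stage.encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([config.seed, tag, index]))


# ---------------------------------------------------------------------------
# landscape generation

def _voronoi_partition(points: np.ndarray, extent: Polygon) -> list:
    """Clip the Voronoi diagram of the points to the window extent."""
    from shapely.geometry import MultiPoint

    cells = voronoi_diagram(MultiPoint([tuple(p) for p in points]), envelope=extent)
    out = []
    for cell in cells.geoms:
        clipped = cell.intersection(extent)
        if clipped.is_empty:
            continue
        if isinstance(clipped, MultiPolygon):
            out.extend(g for g in clipped.geoms if g.area > 0)
        elif clipped.area > 0:
            out.append(clipped)
    return out


def _assign_classes(
    cells: list, fractions: Mapping[str, float], rng: np.random.Generator
) -> list:
    """Greedy class assignment approaching the target area fractions."""
    total = sum(c.area for c in cells)
    targets = dict(fractions)
    residual = 1.0 - sum(targets.values())
    if residual > 1e-9:
        targets["OTHER"] = targets.get("OTHER", 0.0) + residual
    remaining = {k: v * total for k, v in targets.items()}
    order = rng.permutation(len(cells))
    classes = [None] * len(cells)
    for i in order:
        area = cells[i].area
        # assign to the class with the largest unmet demand
        cls = max(remaining, key=lambda k: remaining[k])
        classes[i] = cls
        remaining[cls] -= area
    return classes


def _random_walk_line(
    rng: np.random.Generator,
    extent: Polygon,
    kappa: float,
    mean_angle: float,
    n_segments: int,
    seg_len: float,
) -> LineString:
    minx, miny, maxx, maxy = extent.bounds
    x = rng.uniform(minx, maxx)
    y = rng.uniform(miny, maxy)
    pts = [(x, y)]
    for _ in range(n_segments):
        if kappa > 0:
            ang = rng.vonmises(mean_angle, kappa)
        else:
            ang = rng.uniform(-math.pi, math.pi)
        # undirected orientation: flip half the headings so anisotropy is in
        # orientation, not direction
        if rng.random() < 0.5:
            ang += math.pi
        x = min(max(x + seg_len * math.cos(ang), minx), maxx)
        y = min(max(y + seg_len * math.sin(ang), miny), maxy)
        pts.append((x, y))
    return LineString(pts)


def generate_window(config: ScenarioConfig, window_index: int) -> LandscapeWindow:
    """One seeded landscape window: Voronoi mosaic + anisotropic polylines."""
    rng = _rng(config, "window", window_index)
    size = config.window_size_m
    extent = box(0.0, 0.0, size, size)
    pts = rng.uniform(0, size, size=(config.n_parcels, 2))
    cells = _voronoi_partition(pts, extent)
    classes = _assign_classes(cells, config.class_fractions, rng)
    polygons = []
    for cell, cls in zip(cells, classes):
        green = float(rng.uniform(0.2, 0.8)) if cls == "SETTLE" else None
        crops = None
        if cls == "ARABLE":
            names = list(config.crop_probs)
            probs = np.array([config.crop_probs[n] for n in names], dtype=float)
            probs = probs / probs.sum()
            crops = {
                int(year): str(names[rng.choice(len(names), p=probs)])
                for year in CROP_YEARS
            }
        polygons.append(LandusePolygon(cell, cls, green_fraction=green, crop_years=crops))
    lines = []
    area_ha = extent.area / 10_000.0
    seg_len = 250.0
    n_segments = 8
    for lc in LINE_CLASSES:
        target_m = config.line_density.get(lc, 0.0) * area_ha
        drawn = 0.0
        while drawn < target_m:
            ls = _random_walk_line(
                rng, extent, config.line_kappa, config.line_mean_angle, n_segments, seg_len
            )
            lines.append(LinearElement(ls, lc))
            drawn += ls.length
    return LandscapeWindow(f"W{window_index}", extent, polygons, lines)


def place_populations(
    window: LandscapeWindow, config: ScenarioConfig, window_index: int = 0
) -> pd.DataFrame:
    """Population centres inside forest parcels with >= 200 m separation.

    Returns a frame with population, window, x, y, size (flowering shoots,
    log-uniform over the configured range) and a small patch polygon
    clipped to the host forest parcel.
    """
    rng = _rng(config, "populations", window_index)
    forests = [p for p in window.polygons if p.landuse == "FOREST"]
    if not forests:
        raise ValueError("window has no forest parcels")
    target = config.pops_per_window
    centres: list = []
    patches: list = []
    hosts: list = []
    attempts = 0
    while len(centres) < target and attempts < 4000:
        attempts += 1
        parcel = forests[rng.integers(len(forests))]
        minx, miny, maxx, maxy = parcel.geometry.bounds
        p = Point(rng.uniform(minx, maxx), rng.uniform(miny, maxy))
        if not parcel.geometry.covers(p):
            continue
        if any(p.distance(c) < config.min_separation_m for c in centres):
            continue
        centres.append(p)
        patches.append(p.buffer(50.0, quad_segs=16).intersection(parcel.geometry))
        hosts.append(parcel)
    if len(centres) < target:
        import logging

        logging.getLogger("landgen.synthetic").warning(
            "window %s: placed %d of %d populations", window.window_id, len(centres), target
        )
    sizes = np.exp(
        rng.uniform(math.log(config.min_pop_size), math.log(config.max_pop_size), len(centres))
    )
    rows = []
    for i, (c, patch, size) in enumerate(zip(centres, patches, sizes)):
        rows.append(
            {
                "population": f"{window.window_id}P{i}",
                "window": window.window_id,
                "x": c.x,
                "y": c.y,
                "size": float(size),
                "patch": patch,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# genotypes

def simulate_genotypes(
    nodes: pd.DataFrame,
    config: ScenarioConfig,
    driver: Mapping[object, float] | None = None,
    stream_index: int = 0,
):
    """Dirichlet-hierarchy genotypes with driver-dependent divergence.

    Per locus, ancestral frequencies ~ Dirichlet(1,..,1) over A alleles.
    Population i draws its frequency vector from
    Dirichlet(ancestral * (1 - theta_i)/theta_i) with
    theta_i = logistic(a + b * driver_i); theta -> 0 makes populations
    identical to the ancestor, theta -> 1 maximally diverged.  Individuals
    are i.i.d. draws of `ploidy` gene copies.
    """
    from .popgen import GenotypeTable

    if config.alleles_per_locus < 2:
        raise ValueError("need at least 2 alleles per locus")
    rng = _rng(config, "genotypes", stream_index)
    driver = driver or {}
    rows = []
    alleles = [f"A{j:02d}" for j in range(config.alleles_per_locus)]
    for locus_i in range(config.n_loci):
        locus = f"L{locus_i}"
        ancestral = rng.dirichlet(np.ones(config.alleles_per_locus))
        for _, node in nodes.iterrows():
            d = float(driver.get(node["population"], 0.0))
            theta = 1.0 / (1.0 + math.exp(-(config.theta_intercept + config.theta_slope * d)))
            theta = min(max(theta, 1e-6), 1 - 1e-6)
            conc = ancestral * (1.0 - theta) / theta
            pop_freq = rng.dirichlet(np.maximum(conc, 1e-8))
            for ind_i in range(config.n_individuals):
                copies = rng.choice(
                    config.alleles_per_locus, size=config.ploidy, p=pop_freq
                )
                geno = tuple(alleles[c] for c in copies)
                if config.ploidy == 4:
                    geno = tuple(sorted(set(geno)))  # dosage-unknown scoring
                rows.append(
                    (
                        node["window"],
                        node["population"],
                        f"{node['population']}I{ind_i}",
                        locus,
                        geno,
                    )
                )
    rec = pd.DataFrame(
        rows, columns=["window", "population", "individual", "locus", "alleles"]
    )
    return GenotypeTable(rec, ploidy=config.ploidy, dosage_known=config.ploidy == 2)


# ---------------------------------------------------------------------------
# responses

def simulate_responses(
    data: pd.DataFrame,
    config: ScenarioConfig,
    pair_cols: tuple | None = None,
    group_col: str = "window",
    response: str = "y",
    stream_index: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Draw a response exactly from the mixed-model generative process.

    y = X beta + window effect + (population effects for link rows) + noise,
    with X built from the columns named in config.beta (supporting I(col^2)
    and a:b syntax).  Returns (frame with the response column, truth record).
    """
    from .mixed import _term_column

    rng = _rng(config, "responses", stream_index)
    n = len(data)
    mean = np.zeros(n)
    for term, b in config.beta.items():
        mean = mean + b * _term_column(data, term)
    windows = pd.Categorical(data[group_col])
    w_eff = rng.normal(0.0, math.sqrt(config.sigma2_window), len(windows.categories))
    y = mean + w_eff[windows.codes]
    truth = {
        "beta": dict(config.beta),
        "sigma2_window": config.sigma2_window,
        "sigma2_resid": config.sigma2_resid,
    }
    if pair_cols is not None:
        pops = sorted(set(data[pair_cols[0]]) | set(data[pair_cols[1]]))
        idx = {p: i for i, p in enumerate(pops)}
        p_eff = rng.normal(0.0, math.sqrt(config.sigma2_pop), len(pops))
        y = y + np.array(
            [p_eff[idx[a]] + p_eff[idx[b]] for a, b in zip(data[pair_cols[0]], data[pair_cols[1]])]
        )
        truth["sigma2_pop"] = config.sigma2_pop
    y = y + rng.normal(0.0, math.sqrt(config.sigma2_resid), n)
    out = data.copy()
    out[response] = y
    return out, truth


# ---------------------------------------------------------------------------
# full scenarios & golden fixture

def generate_scenario(config: ScenarioConfig) -> dict:
    """Windows + populations + pairwise frame for end-to-end tests."""
    windows = [generate_window(config, i) for i in range(config.n_windows)]
    node_frames = [
        place_populations(w, config, window_index=i) for i, w in enumerate(windows)
    ]
    nodes = pd.concat(node_frames, ignore_index=True)
    pair_rows = []
    for w in windows:
        sub = nodes[nodes["window"] == w.window_id]
        for (ia, a), (ib, b) in itertools.combinations(sub.iterrows(), 2):
            pair_rows.append(
                {
                    "window": w.window_id,
                    "pop1": a["population"],
                    "pop2": b["population"],
                    "distance_m": math.hypot(a["x"] - b["x"], a["y"] - b["y"]),
                }
            )
    pairs = pd.DataFrame(pair_rows)
    return {"windows": windows, "nodes": nodes, "pairs": pairs}


GOLDEN_SEED = 20210612


def make_golden_fixture() -> dict:
    """A pinned mini-scenario (2 windows, 4 populations each, 5 loci) whose
    key outputs are stored for regression testing.  Runs end-to-end in
    seconds and loads through the same readers as real data."""
    from .popgen import differentiation_table, diversity_table

    config = ScenarioConfig(
        seed=GOLDEN_SEED,
        n_windows=2,
        pops_per_window=4,
        n_parcels=30,
        n_loci=5,
        alleles_per_locus=6,
        n_individuals=12,
        window_size_m=3000.0,
    )
    scen = generate_scenario(config)
    genotypes = simulate_genotypes(scen["nodes"], config)
    div = diversity_table(genotypes)
    centres = {
        r["population"]: (r["x"], r["y"]) for _, r in scen["nodes"].iterrows()
    }
    diff = differentiation_table(genotypes, centres=centres)
    return {
        "config": config,
        "scenario": scen,
        "genotypes": genotypes,
        "diversity": div,
        "differentiation": diff,
    }


def golden_summary(fixture: dict, ndigits: int = 10) -> dict:
    """Deterministic JSON-ready digest of the golden fixture outputs."""
    div = fixture["diversity"]
    diff = fixture["differentiation"]

    def r(x):
        return round(float(x), ndigits)

    return {
        "n_populations": int(len(div)),
        "n_pairs": int(len(diff)),
        "Ar": [r(v) for v in div["Ar"]],
        "He": [r(v) for v in div["He"]],
        "Ho": [r(v) for v in div["Ho"]],
        "F": [r(v) if np.isfinite(v) else None for v in div["F"]],
        "Gst_dp": [r(v) if np.isfinite(v) else None for v in diff["Gst_dp"]],
        "Dps": [r(v) if np.isfinite(v) else None for v in diff["Dps"]],
        "distance_m": [r(v) for v in diff["distance_m"]],
    }
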