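"""End-to-end node-level and link-level analyses and report rendering.

`run_node` models within-population diversity (Ar, He, Ho, F) as a
function of buffer-zone landscape metrics with population size and
Hanski-connectivity isolation as mandatory determinants; `run_link` models
pairwise differentiation (G''ST, D_PS) as a function of strip metrics with
geographic distance mandatory and the MLPE pair correlation active.
`render_report` prints a compact table of important effects using the
shape-code conventions: / positive, \\ negative, unimodal with a maximum
(cap) or minimum (cup), asymmetric variants when the vertex is off-centre,
X for distance interactions.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import landscape as ls
from . import popgen
from .mixed import ModelDesign, box_cox, standardize
from .selection import MetricFamily, SelectionConfig, run_selection

log = logging.getLogger("landgen.pipeline")

__all__ = ["RunConfig", "run_node", "run_link", "render_report", "shape_code"]

NODE_RESPONSES = ("Ar", "He", "Ho", "F")
LINK_RESPONSES = ("Gst_dp", "Dps")


@dataclass
class RunConfig:
    """Analysis constants; defaults replicate the study design."""

    species: str = "species"
    ploidy: int = 2
    buffer_distances: tuple = ls.BUFFER_DISTANCES
    strip_ratios: tuple = ls.STRIP_RATIOS
    alpha: float = 0.15
    delta_aicc: float = 2.0
    collinearity_r: float = 0.7
    max_terms_node: int = 4
    max_terms_link: int = 9
    importance_cutoff: float = 0.5
    connectivity: popgen.ConnectivityParams = field(
        default_factory=popgen.ConnectivityParams
    )
    crop_split: bool = True
    seed: int = 0

    def selection_config(self) -> SelectionConfig:
        return SelectionConfig(
            alpha=self.alpha,
            delta_aicc=self.delta_aicc,
            collinearity_r=self.collinearity_r,
            max_terms_node=self.max_terms_node,
            max_terms_link=self.max_terms_link,
            importance_cutoff=self.importance_cutoff,
        )


def default_families(
    scales: Sequence, crop_split: bool = True, link_level: bool = False
) -> list:
    """The full metric catalog as selection families.

    Linear-element families condition on their O:P ratio, settlement on
    PROPGREEN; crop families replace ARABLE when the crop split is active.
    """
    fams = []
    area = [c for c in ls.AREA_CLASSES if c != "OTHER"]
    if crop_split:
        area = [c for c in area if c != "ARABLE"] + list(ls.CROP_TYPES)
    for cls in area:
        cond = "PROPGREEN" if cls == "SETTLE" else None
        fams.append(
            MetricFamily(
                cls,
                tuple(scales),
                conditioning=cond,
                distance_interaction=link_level,
            )
        )
    for lc in ls.LINE_CLASSES:
        fams.append(
            MetricFamily(
                lc,
                tuple(scales),
                conditioning=f"OP_{lc}",
                distance_interaction=link_level,
            )
        )
    for idx in ("SHANNON", "EDGEDEN"):
        fams.append(MetricFamily(idx, tuple(scales), distance_interaction=link_level))
    return fams


def _transform_columns(df: pd.DataFrame, cols: Sequence[str]) -> pd.DataFrame:
    """Box-Cox + standardize each column, skipping constants."""
    out = df.copy()
    for c in cols:
        x = df[c].to_numpy(dtype=float)
        if not np.all(np.isfinite(x)) or np.ptp(x) == 0:
            continue
        try:
            _, y = box_cox(x)
        except ValueError:
            _, y = standardize(x)
        out[c] = y
    return out


def run_node(
    windows: Sequence[ls.LandscapeWindow],
    genotypes: popgen.GenotypeTable,
    nodes: pd.DataFrame,
    config: RunConfig | None = None,
    families: Sequence[MetricFamily] | None = None,
    responses: Sequence[str] = NODE_RESPONSES,
) -> dict:
    """Node-level analysis: diversity responses vs buffer metrics.

    `nodes` needs columns population, window, x, y, size.  Returns per
    response the AveragedModel plus the assembled data and metric tables.
    """
    cfg = config or RunConfig()
    if len(nodes) < 20:
        log.warning("only %d usable populations (study had 30-42)", len(nodes))
    div = popgen.diversity_table(genotypes)
    conn = popgen.hanski_connectivity(nodes, cfg.connectivity)
    metric_frames = []
    for w in windows:
        sub = nodes[nodes["window"] == w.window_id]
        centres = {r["population"]: (r["x"], r["y"]) for _, r in sub.iterrows()}
        if centres:
            metric_frames.append(
                ls.compute_node_metrics(
                    w, centres, cfg.buffer_distances, crop_split=cfg.crop_split
                )
            )
    metrics = pd.concat(metric_frames)
    data = div.merge(nodes[["population", "size"]], on="population")
    data["isolation"] = [-conn[p] for p in data["population"]]
    data = data.merge(metrics, left_on="population", right_index=True)
    fams = list(
        families
        if families is not None
        else default_families(
            [ls._scale_label(s) for s in cfg.buffer_distances], cfg.crop_split
        )
    )
    predictor_cols = [c for c in metrics.columns] + ["size", "isolation"]
    results = {}
    for resp in responses:
        if data[resp].isna().any():
            usable = data.dropna(subset=[resp])
        else:
            usable = data
        tdata = _transform_columns(usable, [*predictor_cols, resp])
        base = ModelDesign(
            response=resp, fixed=("size", "isolation"), basic=("size", "isolation")
        )
        results[resp] = run_selection(
            fams,
            base,
            tdata,
            config=cfg.selection_config(),
            level="node",
        )
    return {"results": results, "data": data, "metrics": metrics, "diversity": div}


def run_link(
    windows: Sequence[ls.LandscapeWindow],
    genotypes: popgen.GenotypeTable,
    nodes: pd.DataFrame,
    config: RunConfig | None = None,
    families: Sequence[MetricFamily] | None = None,
    responses: Sequence[str] = LINK_RESPONSES,
) -> dict:
    """Link-level analysis: pairwise differentiation vs strip metrics with
    MLPE pair correlation.  Windows with a single population are skipped."""
    cfg = config or RunConfig()
    centres = {r["population"]: (r["x"], r["y"]) for _, r in nodes.iterrows()}
    patches = (
        {r["population"]: r["patch"] for _, r in nodes.iterrows()}
        if "patch" in nodes.columns
        else None
    )
    diff = popgen.differentiation_table(genotypes, patches=patches, centres=centres)
    metric_frames = []
    for w in windows:
        sub = diff[diff["window"] == w.window_id]
        if len(nodes[nodes["window"] == w.window_id]) < 2:
            log.warning("window %s has < 2 populations; skipped", w.window_id)
            continue
        pairs = {
            (r["pop1"], r["pop2"]): (centres[r["pop1"]], centres[r["pop2"]])
            for _, r in sub.iterrows()
        }
        if pairs:
            metric_frames.append(
                ls.compute_link_metrics(w, pairs, cfg.strip_ratios, crop_split=cfg.crop_split)
            )
    metrics = pd.concat(metric_frames)
    data = diff.set_index(["pop1", "pop2"]).join(metrics).reset_index()
    fams = list(
        families
        if families is not None
        else default_families(list(cfg.strip_ratios), cfg.crop_split, link_level=True)
    )
    predictor_cols = [c for c in metrics.columns] + ["distance_m"]
    results = {}
    for resp in responses:
        usable = data.dropna(subset=[resp])
        tdata = _transform_columns(usable, [*predictor_cols, resp])
        base = ModelDesign(
            response=resp,
            fixed=("distance_m",),
            basic=("distance_m",),
            pair_cols=("pop1", "pop2"),
        )
        results[resp] = run_selection(
            fams,
            base,
            tdata,
            config=cfg.selection_config(),
            distance_col="distance_m",
            level="link",
        )
    return {"results": results, "data": data, "metrics": metrics, "differentiation": diff}


# ---------------------------------------------------------------------------
# reporting

def shape_code(
    term: str,
    averaged_coef: Mapping[str, float],
    importance: Mapping[str, float],
    predictor_range: tuple = (-2.0, 2.0),
    cutoff: float = 0.5,
) -> str:
    """Effect-shape symbol for one metric term.

    Sign of the linear coefficient gives / or \\; an important quadratic
    turns the code into a cap (negative curvature) or cup (positive), with
    the trend prefix retained when the parabola vertex lies outside the
    central 50% of the predictor range; an important interaction yields X.
    """
    quad = f"I({term}^2)"
    inter = [
        t
        for t in averaged_coef
        if "*" in t and term in t.split("*") and importance.get(t, 0.0) >= cutoff
    ]
    if inter:
        return "X"
    b1 = averaged_coef.get(term, 0.0)
    b2 = averaged_coef.get(quad, 0.0) if importance.get(quad, 0.0) >= cutoff else 0.0
    if b2 == 0.0:
        return "/" if b1 >= 0 else "\\"
    vertex = -b1 / (2.0 * b2)
    lo, hi = predictor_range
    mid_lo = lo + 0.25 * (hi - lo)
    mid_hi = lo + 0.75 * (hi - lo)
    base = "∩" if b2 < 0 else "∪"  # cap / cup
    if mid_lo <= vertex <= mid_hi:
        return base
    return ("/" if b1 >= 0 else "\\") + base


def render_report(results: Mapping[str, dict], cutoff: float = 0.5) -> str:
    """Human-readable summary table of important effects and R^2 rows."""
    lines = []
    responses = list(results)
    width = max((len(r) for r in responses), default=8) + 2
    for resp in responses:
        avg = results[resp]["averaged"]
        lines.append(f"== {resp} ==")
        reported = [
            t
            for t in avg.importance
            if avg.importance[t] >= cutoff
            and t != "(Intercept)"
            and not t.startswith("I(")
            and "*" not in t
        ]
        for t in reported:
            code = shape_code(t, avg.averaged_coef, avg.importance, cutoff=cutoff)
            lines.append(
                f"  {t:<28s} {code:<3s} imp={avg.importance[t]:.2f} "
                f"beta={avg.averaged_coef.get(t, 0.0):+.3f}"
            )
        lines.append(f"  Marginal R2  : {avg.marginal_R2:.3f}")
        lines.append(f"  Landscape R2 : {avg.landscape_R2:.3f}")
        pct = avg.pct_landscape
        lines.append(
            f"  % Landscape  : {pct:.1f}" if math.isfinite(pct) else "  % Landscape  : NA"
        )
        lines.append("")
    return "\n".join(lines)


def results_to_json(results: Mapping[str, dict]) -> dict:
    out = {}
    for resp, res in results.items():
        out[resp] = {
            "chosen_scales": {k: str(v) for k, v in res["chosen_scales"].items()},
            "screen_p": res["screen_p"],
            "screened": res["screened"],
            "composites": res["composites"],
            "n_candidate_models": res["n_candidate_models"],
            "averaged": res["averaged"].to_dict(),
        }
    return out
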