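"""Three-step multimodel inference over landscape-metric candidates.

Step 1 — for each metric family, find its most influential spatial scale
(buffer distance or strip ratio) as the single-metric model with the
lowest AICc, optionally adding a quadratic term, the conditioning-variable
interaction (linear elements and settlement), and, at link level, a
geographic-distance interaction when AICc-improving.

Step 2 — keep only families whose chosen model beats the basic model in a
likelihood-ratio test at alpha = 0.15; then remove collinearity (|r| >=
0.7): intrinsically related clusters are replaced by their first
principal-component score, unrelated collinear pairs by the member with
the lower single-metric AICc.

Step 3 — fit all subsets of the surviving terms (marginality enforced,
term caps 4 at node and 9 at link level) by ML; models within 2 AICc
units of the best are refit by REML and fully averaged.  Importance of a
term is the summed Akaike weight of component models containing it;
landscape R^2 is the marginal R^2 of the averaged model minus that of the
basic model.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .mixed import FittedLMM, ModelDesign, aicc, fit_mixed, lrt, marginal_r2

log = logging.getLogger("landgen.selection")

__all__ = [
    "SelectionConfig",
    "MetricFamily",
    "AveragedModel",
    "select_scale",
    "screen",
    "reduce_collinearity",
    "enumerate_models",
    "average_models",
    "landscape_r2",
    "arable_vs_crops",
    "run_selection",
]

MAX_SUBSETS = 100_000


@dataclass
class SelectionConfig:
    """Thresholds of the three-step procedure (defaults are the study's)."""

    alpha: float = 0.15
    delta_aicc: float = 2.0
    collinearity_r: float = 0.7
    max_terms_node: int = 4
    max_terms_link: int = 9
    importance_cutoff: float = 0.5


@dataclass
class MetricFamily:
    """One landscape metric with its candidate scales and optional terms."""

    name: str
    scales: tuple
    quadratic: bool = True
    conditioning: str | None = None  # e.g. "OP_LWOOD" or "PROPGREEN"
    distance_interaction: bool = False  # link level only

    def __post_init__(self) -> None:
        self.scales = tuple(self.scales)
        if not self.scales:
            raise ValueError("family needs at least one candidate scale")

    def column(self, scale) -> str:
        return f"{self.name}_{scale}"

    def conditioning_column(self, scale) -> str | None:
        if self.conditioning is None:
            return None
        return f"{self.conditioning}_{scale}"


@dataclass
class ChosenModel:
    """Result of step-1 scale selection for one family."""

    family: MetricFamily
    scale: object
    terms: tuple  # metric-related fixed terms (columns/I()^2/interactions)
    fit: FittedLMM
    aicc: float


@dataclass
class AveragedModel:
    """Full model average over the DeltaAICc < 2 component set."""

    component_terms: list
    component_aicc: list
    component_delta: list
    weights: list
    averaged_coef: dict
    importance: dict
    marginal_R2: float
    basic_R2: float
    landscape_R2: float
    pct_landscape: float
    best_fit: FittedLMM | None = field(default=None, repr=False)

    def reported_terms(self, cutoff: float = 0.5) -> list:
        return [t for t, v in self.importance.items() if v >= cutoff]

    def to_dict(self) -> dict:
        return {
            "component_models": [
                {"terms": list(t), "AICc": a, "delta": d, "weight": w}
                for t, a, d, w in zip(
                    self.component_terms,
                    self.component_aicc,
                    self.component_delta,
                    self.weights,
                )
            ],
            "averaged_coefficients": self.averaged_coef,
            "importance": self.importance,
            "marginal_R2": self.marginal_R2,
            "basic_R2": self.basic_R2,
            "landscape_R2": self.landscape_R2,
            "pct_landscape": self.pct_landscape,
        }


# ---------------------------------------------------------------------------
# step 1: scale selection

def _make_design(base: ModelDesign, extra_terms: Sequence[str]) -> ModelDesign:
    return ModelDesign(
        response=base.response,
        fixed=tuple(base.basic) + tuple(extra_terms),
        basic=base.basic,
        group_col=base.group_col,
        pair_cols=base.pair_cols,
    )


def _try_fit(base: ModelDesign, terms: Sequence[str], data: pd.DataFrame):
    try:
        fit = fit_mixed(_make_design(base, terms), data, method="ML")
        return fit, aicc(fit)
    except Exception as exc:
        log.warning("fit failed for terms %s: %s", terms, exc)
        return None, math.inf


def _scale_sort_key(scale) -> float:
    """Numeric order for both buffer distances and 'w:l' ratio strings."""
    if isinstance(scale, str) and ":" in scale:
        a, b = scale.split(":")
        return float(a) / float(b)
    return float(scale)


def select_scale(
    family: MetricFamily,
    base: ModelDesign,
    data: pd.DataFrame,
    distance_col: str | None = None,
) -> ChosenModel | None:
    """Step 1: choose the family's most influential scale and term set.

    For each candidate scale the single-metric model always contains the
    linear term and the conditioning interaction (where defined); the
    quadratic term and, at link level, the distance interaction are added
    only when they lower AICc.  Ties break toward the smaller scale, then
    the simpler model.
    """
    candidates = []  # (aicc, scale_order, n_terms, terms, fit, scale)
    for scale in family.scales:
        col = family.column(scale)
        if col not in data.columns:
            continue
        if data[col].std() == 0:
            continue
        base_terms = [col]
        cond = family.conditioning_column(scale)
        if cond is not None and cond in data.columns and data[cond].std() > 0:
            base_terms += [cond, f"{col}*{cond}"]
        variants = [tuple(base_terms)]
        if family.quadratic:
            variants.append(tuple(base_terms) + (f"I({col}^2)",))
        if family.distance_interaction and distance_col is not None:
            for v in list(variants):
                variants.append(v + (f"{col}*{distance_col}",))
        for terms in variants:
            fit, a = _try_fit(base, terms, data)
            if fit is None:
                continue
            candidates.append(
                (a, _scale_sort_key(scale), len(terms), terms, fit, scale)
            )
    if not candidates:
        log.warning("family %s: all fits failed; dropped", family.name)
        return None
    candidates.sort(key=lambda c: (round(c[0], 9), c[1], c[2]))
    a, _, _, terms, fit, scale = candidates[0]
    return ChosenModel(family, scale, terms, fit, a)


# ---------------------------------------------------------------------------
# step 2: screening + collinearity

def screen(
    chosen: ChosenModel, base: ModelDesign, data: pd.DataFrame, alpha: float = 0.15
) -> tuple[bool, float]:
    """Keep the family iff the LRT of all its terms jointly has p < alpha."""
    basic_fit = fit_mixed(base, data, method="ML")
    if not set(basic_fit.term_names) <= set(chosen.fit.term_names):
        raise ValueError("basic model is not nested in the chosen model")
    stat, df, p = lrt(chosen.fit, basic_fit)
    return p < alpha, p


@dataclass
class Composite:
    """First-principal-component replacement for a collinear cluster."""

    name: str
    members: tuple
    loadings: np.ndarray
    scores: np.ndarray


def _pc1(cols: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """First principal component of standardized columns; returns
    (standardized scores, loadings)."""
    Z = (cols - cols.mean(axis=0)) / cols.std(axis=0, ddof=0)
    cov = np.cov(Z, rowvar=False, ddof=0)
    vals, vecs = np.linalg.eigh(cov)
    v1 = vecs[:, -1]
    scores = Z @ v1
    sd = scores.std(ddof=0)
    if sd > 0:
        scores = scores / sd
    return scores, v1


def reduce_collinearity(
    kept: Sequence[ChosenModel],
    data: pd.DataFrame,
    threshold: float = 0.7,
    intrinsic_groups: Sequence[Sequence[str]] | None = None,
) -> tuple[list, list, pd.DataFrame]:
    """Step 2b: resolve |r| >= threshold among the chosen metric columns.

    Collinear metrics that belong to a common intrinsic group (explicit
    grouping by metric name; all metrics are one group when none is given)
    are merged into the standardized first-principal-component score, sign
    oriented to correlate positively with the first-named member.  Collinear
    members of different groups are resolved by keeping the lower
    single-metric AICc.  Returns (surviving ChosenModels, composites,
    augmented data frame containing composite columns).
    """
    if not kept:
        return [], [], data
    cols = {cm.family.column(cm.scale): cm for cm in kept}
    names = list(cols)
    mat = data[names].to_numpy(dtype=float)
    r = np.corrcoef(mat, rowvar=False) if len(names) > 1 else np.ones((1, 1))

    def group_of(metric_name: str) -> int:
        if intrinsic_groups is None:
            return 0
        for gi, grp in enumerate(intrinsic_groups):
            if metric_name in grp:
                return gi
        return -1  # ungrouped: never intrinsically related

    # drop pass: unrelated collinear pairs -> keep lower AICc
    dropped = set()
    order = sorted(names, key=lambda n: cols[n].aicc)
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            b = names[j]
            if a in dropped or b in dropped:
                continue
            if abs(r[i, j]) < threshold:
                continue
            ga, gb = group_of(cols[a].family.name), group_of(cols[b].family.name)
            if ga == gb and ga != -1:
                continue  # intrinsic: handled by the composite pass
            loser = a if cols[a].aicc > cols[b].aicc else b
            dropped.add(loser)
            log.info("collinearity: dropping %s (|r|=%.2f with %s)", loser, abs(r[i, j]), a if loser == b else b)

    # composite pass: connected components of intrinsic collinear pairs
    survivors = [n for n in names if n not in dropped]
    adj = {n: set() for n in survivors}
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            b = names[j]
            if a in dropped or b in dropped or abs(r[i, j]) < threshold:
                continue
            ga, gb = group_of(cols[a].family.name), group_of(cols[b].family.name)
            if ga == gb and ga != -1:
                adj[a].add(b)
                adj[b].add(a)
    seen: set = set()
    clusters = []
    for n in survivors:
        if n in seen or not adj[n]:
            continue
        comp = {n}
        stack = [n]
        while stack:
            cur = stack.pop()
            for nb in adj[cur]:
                if nb not in comp:
                    comp.add(nb)
                    stack.append(nb)
        seen |= comp
        clusters.append(sorted(comp, key=names.index))

    out_data = data.copy()
    composites = []
    final = []
    clustered = set()
    for members in clusters:
        clustered |= set(members)
        scores, loadings = _pc1(data[members].to_numpy(dtype=float))
        first = data[members[0]].to_numpy(dtype=float)
        if np.corrcoef(scores, first)[0, 1] < 0:
            scores, loadings = -scores, -loadings
        cname = "pc" + "+".join(members)
        out_data[cname] = scores
        composites.append(Composite(cname, tuple(members), loadings, scores))
    for n in survivors:
        if n not in clustered:
            final.append(cols[n])
    return final, composites, out_data


# ---------------------------------------------------------------------------
# step 3: enumeration + averaging

@dataclass
class TermBlock:
    """A selectable unit: one fixed term with marginality dependencies."""

    term: str
    requires: tuple = ()


def _blocks_from_chosen(
    chosen: Sequence[ChosenModel], composites: Sequence[Composite]
) -> list:
    """Expand surviving families and composites into term blocks."""
    blocks = []
    for cm in chosen:
        col = cm.family.column(cm.scale)
        for t in cm.terms:
            if t.startswith("I("):
                blocks.append(TermBlock(t, requires=(col,)))
            elif "*" in t:  # interaction a*b — requires both main effects
                blocks.append(TermBlock(t, requires=tuple(t.split("*", 1))))
            else:
                blocks.append(TermBlock(t))
    for comp in composites:
        blocks.append(TermBlock(comp.name))
    # dedupe, preserve order
    seen = set()
    out = []
    for b in blocks:
        if b.term not in seen:
            seen.add(b.term)
            out.append(b)
    return out


def enumerate_models(
    blocks: Sequence[TermBlock],
    max_terms: int,
    basic: Sequence[str] = (),
) -> list:
    """All marginality-respecting subsets of term blocks up to the cap.

    Terms named in `basic` never count against the cap (they are mandatory
    and appear in every model).  A quadratic or interaction term may only
    appear together with its required main effects.
    """
    terms = [b.term for b in blocks]
    req = {b.term: set(b.requires) for b in blocks}
    n = len(terms)
    r_max = min(n, max_terms)
    n_subsets = sum(math.comb(n, r) for r in range(r_max + 1))
    if n_subsets > MAX_SUBSETS:
        raise ValueError(
            f"{n_subsets} candidate subsets exceed the {MAX_SUBSETS} limit; "
            "reduce the number of surviving terms first"
        )
    models = []
    for r in range(r_max + 1):
        for combo in itertools.combinations(terms, r):
            s = set(combo)
            if any(not req[t] <= (s | set(basic)) for t in combo):
                continue
            models.append(tuple(combo))
    return models


def average_models(
    subsets: Sequence[tuple],
    base: ModelDesign,
    data: pd.DataFrame,
    delta_max: float = 2.0,
    importance_cutoff: float = 0.5,
) -> AveragedModel:
    """Fit all subsets by ML, refit the DeltaAICc < 2 set by REML, and
    apply full model averaging.

    A term absent from a component model contributes 0 to its average;
    importance is the summed weight of component models containing it.
    Marginal R^2 is evaluated on the best model containing all important
    terms (REML refit), landscape R^2 as its excess over the basic model.
    """
    ml_fits = []
    for terms in subsets:
        fit, a = _try_fit(base, terms, data)
        if fit is not None:
            ml_fits.append((terms, fit, a))
    if not ml_fits:
        raise RuntimeError("no candidate model could be fitted")
    best_aicc = min(a for _, _, a in ml_fits)
    component = [(t, f, a) for t, f, a in ml_fits if a - best_aicc < delta_max]
    deltas = [a - best_aicc for _, _, a in component]
    raw_w = np.exp(-0.5 * np.array(deltas))
    weights = raw_w / raw_w.sum()

    # REML refits supply the averaged coefficients
    reml_fits = []
    for terms, _, _ in component:
        try:
            reml_fits.append(fit_mixed(_make_design(base, terms), data, method="REML"))
        except Exception as exc:
            log.warning("REML refit failed for %s: %s", terms, exc)
            reml_fits.append(None)

    all_terms: list = []
    for terms, _, _ in component:
        for t in ("(Intercept)",) + tuple(base.basic) + tuple(terms):
            if t not in all_terms:
                all_terms.append(t)
    averaged = {t: 0.0 for t in all_terms}
    importance = {t: 0.0 for t in all_terms}
    for (terms, ml_fit, _), w, reml_fit in zip(component, weights, reml_fits):
        fit = reml_fit if reml_fit is not None else ml_fit
        coefs = fit.coef()
        for t in coefs.index:
            averaged[t] += w * float(coefs[t])
            importance[t] += w
    importance = {t: min(1.0, v) for t, v in importance.items()}

    important = [
        t
        for t, v in importance.items()
        if v >= importance_cutoff and t != "(Intercept)" and t not in base.basic
    ]
    # R^2 model: best (lowest-AICc) component containing all important terms,
    # else a dedicated refit with exactly the important terms
    r2_terms = None
    for terms, _, a in sorted(component, key=lambda c: c[2]):
        if set(important) <= set(terms):
            r2_terms = terms
            break
    if r2_terms is None:
        r2_terms = tuple(important)
    r2_fit = fit_mixed(_make_design(base, r2_terms), data, method="REML")
    basic_fit = fit_mixed(base, data, method="REML")
    marg = marginal_r2(r2_fit)
    basic_r2 = marginal_r2(basic_fit)
    lr2 = marg - basic_r2
    pct = 100.0 * lr2 / marg if marg != 0 else float("nan")
    return AveragedModel(
        component_terms=[list(t) for t, _, _ in component],
        component_aicc=[a for _, _, a in component],
        component_delta=deltas,
        weights=[float(w) for w in weights],
        averaged_coef=averaged,
        importance=importance,
        marginal_R2=float(marg),
        basic_R2=float(basic_r2),
        landscape_R2=float(lr2),
        pct_landscape=float(pct),
        best_fit=r2_fit,
    )


def landscape_r2(avg: AveragedModel) -> tuple[float, float]:
    """(landscape R^2, %Landscape) of an averaged model; the difference may
    be negative and is reported as-is."""
    return avg.landscape_R2, avg.pct_landscape


def arable_vs_crops(
    result_crops: AveragedModel, result_arable: AveragedModel
) -> tuple[str, AveragedModel]:
    """Report whichever variant (crop split vs lumped arable) explains more
    variation in the final averaged model; ties favour the crop split."""
    if result_crops.marginal_R2 >= result_arable.marginal_R2:
        return "crops", result_crops
    return "arable", result_arable


# ---------------------------------------------------------------------------
# orchestration

def run_selection(
    families: Sequence[MetricFamily],
    base: ModelDesign,
    data: pd.DataFrame,
    config: SelectionConfig | None = None,
    distance_col: str | None = None,
    intrinsic_groups: Sequence[Sequence[str]] | None = None,
    level: str = "node",
) -> dict:
    """The full three-step procedure for one response variable.

    Returns a dict with the chosen scales, screening p-values, composites,
    and the AveragedModel.
    """
    cfg = config or SelectionConfig()
    max_terms = cfg.max_terms_node if level == "node" else cfg.max_terms_link

    chosen = []
    for fam in families:
        cm = select_scale(fam, base, data, distance_col=distance_col)
        if cm is not None:
            chosen.append(cm)
    screened = []
    pvals = {}
    for cm in chosen:
        keep, p = screen(cm, base, data, alpha=cfg.alpha)
        pvals[cm.family.name] = p
        if keep:
            screened.append(cm)
    surviving, composites, data_aug = reduce_collinearity(
        screened, data, threshold=cfg.collinearity_r, intrinsic_groups=intrinsic_groups
    )
    blocks = _blocks_from_chosen(surviving, composites)
    subsets = enumerate_models(blocks, max_terms, basic=base.basic)
    log.info(
        "selection: %d families -> %d screened -> %d terms -> %d candidate models",
        len(families),
        len(screened),
        len(blocks),
        len(subsets),
    )
    avg = average_models(
        subsets,
        base,
        data_aug,
        delta_max=cfg.delta_aicc,
        importance_cutoff=cfg.importance_cutoff,
    )
    return {
        "chosen_scales": {cm.family.name: cm.scale for cm in chosen},
        "screen_p": pvals,
        "screened": [cm.family.name for cm in screened],
        "composites": [
            {"name": c.name, "members": list(c.members), "loadings": c.loadings.tolist()}
            for c in composites
        ],
        "n_candidate_models": len(subsets),
        "averaged": avg,
        "data": data_aug,
    }
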