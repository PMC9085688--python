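"""Within-population diversity and pairwise differentiation from microsatellites.

Implements the node-level genetic response variables (rarefied allelic
richness Ar, expected/observed heterozygosity He/Ho, inbreeding coefficient
F = 1 - Ho/He) and the link-level differentiation measures (Hedrick's
standardized G''ST and the shared-allele distance D_PS), together with the
basic spatial determinants: edge-to-edge distance between habitat patches
and Hanski's incidence-function connectivity.

Genotypes are handled as a long table of (window, population, individual,
locus) records carrying 1..ploidy allele calls.  Ploidy 2 and 4 are
supported; tetraploid records with unknown allele dosage are expanded to
equal weights over the distinct alleles so that every record contributes
exactly `ploidy` gene copies.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Polygon
from shapely.validation import explain_validity

__all__ = [
    "GenotypeTable",
    "AlleleFrequencies",
    "ConnectivityParams",
    "read_genotype_csv",
    "read_genepop",
    "allele_frequencies",
    "allele_counts",
    "expected_heterozygosity",
    "observed_heterozygosity",
    "inbreeding_coefficient",
    "allelic_richness",
    "rarefaction_gene_count",
    "pairwise_dps",
    "pairwise_gst_dp",
    "edge_to_edge_distance",
    "hanski_connectivity",
    "diversity_table",
    "differentiation_table",
]

MIN_SHARED_LOCI = 3  # pairs with fewer scored loci in common are flagged missing


# ---------------------------------------------------------------------------
# containers

@dataclass
class GenotypeTable:
    """Long-format multilocus genotype records.

    Parameters
    ----------
    records
        DataFrame with columns ``window``, ``population``, ``individual``,
        ``locus`` and ``alleles`` (tuple of allele labels, 1..ploidy
        entries).  Missing data are absent rows, never sentinel alleles.
    ploidy
        2 (diploid) or 4 (tetraploid).
    dosage_known
        Whether allele dosage in partially homozygous records is known.
        With ``False`` (default for tetraploids scored from peak presence),
        a record listing d < ploidy distinct alleles is expanded to equal
        weights of ploidy/d copies each.
    """

    records: pd.DataFrame
    ploidy: int = 2
    dosage_known: bool = False

    def __post_init__(self) -> None:
        if self.ploidy not in (2, 4):
            raise ValueError(f"ploidy must be 2 or 4, got {self.ploidy}")
        required = {"window", "population", "individual", "locus", "alleles"}
        missing = required - set(self.records.columns)
        if missing:
            raise ValueError(f"records missing columns: {sorted(missing)}")
        for a in self.records["alleles"]:
            if not 1 <= len(a) <= self.ploidy:
                raise ValueError(
                    f"record has {len(a)} alleles; expected 1..{self.ploidy}"
                )
        dup = self.records.duplicated(["population", "individual", "locus"])
        if dup.any():
            raise ValueError("duplicate (population, individual, locus) records")

    @property
    def populations(self) -> list:
        return sorted(self.records["population"].unique())

    @property
    def loci(self) -> list:
        return sorted(self.records["locus"].unique())

    def window_of(self, population) -> object:
        w = self.records.loc[self.records["population"] == population, "window"]
        if w.empty:
            raise KeyError(f"no data for population {population!r}")
        return w.iloc[0]


@dataclass
class AlleleFrequencies:
    """Allele frequencies for one population at one locus."""

    population_id: object
    locus_id: object
    freqs: dict
    gene_count: float

    def __post_init__(self) -> None:
        total = sum(self.freqs.values())
        if self.freqs and abs(total - 1.0) > 1e-9:
            raise ValueError(f"frequencies sum to {total}, not 1")
        if any(v < 0 for v in self.freqs.values()):
            raise ValueError("negative allele frequency")
        if self.gene_count <= 0:
            raise ValueError("gene_count must be positive")


@dataclass
class ConnectivityParams:
    """Hanski incidence-function parameters.

    alpha is the inverse of the mean dispersal distance (1/m); b weighs the
    neighbour population size (flowering-shoot count).  The study cites an
    external parameterization without printing it, so both are configurable;
    defaults are alpha = 1/1000 m^-1 and b = 0.5.
    """

    alpha: float = 1e-3
    b: float = 0.5

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.b < 0:
            raise ValueError("b must be >= 0")


# ---------------------------------------------------------------------------
# I/O

def read_genotype_csv(path, ploidy: int = 2, dosage_known: bool = False) -> GenotypeTable:
    """Read the long genotype CSV dialect.

    Columns: window, population, individual, locus, allele_1..allele_4
    (blank for absent copies).
    """
    df = pd.read_csv(path, dtype=str)
    allele_cols = [c for c in df.columns if c.startswith("allele_")]
    rows = []
    for _, r in df.iterrows():
        alleles = tuple(r[c] for c in allele_cols if pd.notna(r[c]) and r[c] != "")
        if not alleles:
            continue  # fully missing record
        rows.append(
            (r["window"], r["population"], r["individual"], r["locus"], alleles)
        )
    rec = pd.DataFrame(
        rows, columns=["window", "population", "individual", "locus", "alleles"]
    )
    return GenotypeTable(rec, ploidy=ploidy, dosage_known=dosage_known)


def read_genepop(path, window: object = "W1") -> GenotypeTable:
    """Read a GENEPOP file with 4-digit diploid codes (read-only import).

    Each POP block becomes one population; '0000' codes a missing allele.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines:
        raise ValueError("empty GENEPOP file")
    body = lines[1:]  # first line is a title
    loci: list[str] = []
    i = 0
    while i < len(body) and body[i].strip().upper() != "POP":
        loci.extend(x.strip() for x in body[i].split(",") if x.strip())
        i += 1
    rows = []
    pop_idx = 0
    ind_idx = 0
    for ln in body[i:]:
        if ln.strip().upper() == "POP":
            pop_idx += 1
            ind_idx = 0
            continue
        if not ln.strip():
            continue
        name, _, geno = ln.partition(",")
        codes = geno.split()
        if len(codes) != len(loci):
            raise ValueError(f"{len(codes)} genotypes for {len(loci)} loci")
        ind_idx += 1
        ind = name.strip() or f"ind{ind_idx}"
        pop = f"pop{pop_idx}"
        for locus, code in zip(loci, codes):
            a1, a2 = code[:4], code[4:8]
            alleles = tuple(a for a in (a1, a2) if a and a != "0000")
            if alleles:
                rows.append((window, pop, f"{pop}:{ind}", locus, alleles))
    rec = pd.DataFrame(
        rows, columns=["window", "population", "individual", "locus", "alleles"]
    )
    return GenotypeTable(rec, ploidy=2, dosage_known=True)


# ---------------------------------------------------------------------------
# allele frequencies

def _record_weights(alleles: Sequence, ploidy: int, dosage_known: bool) -> dict:
    """Gene-copy weights contributed by one record (sums to `ploidy`)."""
    distinct = sorted(set(alleles))
    if len(alleles) == ploidy:
        out: dict = {}
        for a in alleles:
            out[a] = out.get(a, 0.0) + 1.0
        return out
    if dosage_known:
        # partial record with known dosage: count copies as given
        out = {}
        for a in alleles:
            out[a] = out.get(a, 0.0) + 1.0
        return out
    # unknown dosage: equal weights over distinct alleles, ploidy copies total
    w = ploidy / len(distinct)
    return {a: w for a in distinct}


def allele_counts(
    genotypes: GenotypeTable, population, locus
) -> tuple[dict, float]:
    """Weighted allele copy counts and total gene count for (population, locus)."""
    rec = genotypes.records
    sel = rec[(rec["population"] == population) & (rec["locus"] == locus)]
    if sel.empty:
        raise KeyError(f"no data for population {population!r} at locus {locus!r}")
    counts: dict = {}
    total = 0.0
    for alleles in sel["alleles"]:
        w = _record_weights(alleles, genotypes.ploidy, genotypes.dosage_known)
        for a, c in w.items():
            counts[a] = counts.get(a, 0.0) + c
        total += sum(w.values())
    return counts, total


def allele_frequencies(genotypes: GenotypeTable, population, locus) -> AlleleFrequencies:
    counts, total = allele_counts(genotypes, population, locus)
    freqs = {a: c / total for a, c in sorted(counts.items())}
    return AlleleFrequencies(population, locus, freqs, total)


# ---------------------------------------------------------------------------
# diversity

def expected_heterozygosity(freqs: AlleleFrequencies, corrected: bool = True) -> float:
    """Nei gene diversity 1 - sum p^2, optionally n/(n-1) corrected."""
    h = 1.0 - sum(p * p for p in freqs.freqs.values())
    if corrected:
        n = freqs.gene_count
        if n <= 1:
            raise ValueError("gene_count must exceed 1 for the corrected estimator")
        h *= n / (n - 1.0)
    return h


def observed_heterozygosity(genotypes: GenotypeTable, population) -> float:
    """Fraction of records with >= 2 distinct alleles, averaged over loci."""
    rec = genotypes.records
    sel = rec[rec["population"] == population]
    if sel.empty:
        raise ValueError(f"no scored records for population {population!r}")
    per_locus = []
    for _, grp in sel.groupby("locus"):
        het = [len(set(a)) >= 2 for a in grp["alleles"]]
        per_locus.append(float(np.mean(het)))
    return float(np.mean(per_locus))


def inbreeding_coefficient(ho: float, he: float) -> float:
    """F = 1 - Ho/He; NaN when He = 0 (monomorphic population)."""
    if ho < 0 or he < 0:
        raise ValueError("Ho and He must be non-negative")
    if he == 0:
        return float("nan")
    return 1.0 - ho / he


def _rarefied_locus_richness(counts: Iterable[float], g: int) -> float:
    """Hypergeometric rarefaction: expected allele count in g gene copies."""
    ints = [int(round(c)) for c in counts]
    n_total = sum(ints)
    if g < 1:
        raise ValueError("rarefaction size g must be >= 1")
    if g > n_total:
        raise ValueError(f"g = {g} exceeds total gene count {n_total}")
    ar = 0.0
    for ni in ints:
        # P(allele i absent from the subsample) = C(N-ni, g)/C(N, g)
        if n_total - ni < g:
            ar += 1.0
        else:
            ar += 1.0 - math.comb(n_total - ni, g) / math.comb(n_total, g)
    return ar


def allelic_richness(
    counts_per_locus: Mapping[object, Mapping[object, float]], g: int
) -> float:
    """Rarefied allelic richness averaged over loci.

    counts_per_locus maps locus -> {allele: copy count}; g is the common
    rarefaction gene count.
    """
    vals = [
        _rarefied_locus_richness(c.values(), g) for c in counts_per_locus.values()
    ]
    if not vals:
        raise ValueError("no loci provided")
    return float(np.mean(vals))


def rarefaction_gene_count(genotypes: GenotypeTable) -> int:
    """Default rarefaction size: the minimum per-locus gene count over all
    populations and loci of the table (deterministic, reproducible)."""
    gmin = math.inf
    for pop in genotypes.populations:
        rec = genotypes.records
        loci = rec.loc[rec["population"] == pop, "locus"].unique()
        for locus in loci:
            _, total = allele_counts(genotypes, pop, locus)
            gmin = min(gmin, total)
    if not math.isfinite(gmin):
        raise ValueError("empty genotype table")
    return int(gmin)


# ---------------------------------------------------------------------------
# differentiation

def _shared_loci(fa: Mapping, fb: Mapping) -> list:
    shared = sorted(set(fa) & set(fb))
    if not shared:
        raise ValueError("populations share no scored loci")
    return shared


def pairwise_dps(
    freqs_a: Mapping[object, AlleleFrequencies],
    freqs_b: Mapping[object, AlleleFrequencies],
) -> float:
    """Shared-allele distance: 1 - mean over loci of sum_a min(p_A, p_B)."""
    shared = _shared_loci(freqs_a, freqs_b)
    ps = []
    for locus in shared:
        pa, pb = freqs_a[locus].freqs, freqs_b[locus].freqs
        ps.append(sum(min(pa.get(al, 0.0), pb.get(al, 0.0)) for al in set(pa) | set(pb)))
    return 1.0 - float(np.mean(ps))


def pairwise_gst_dp(
    freqs_a: Mapping[object, AlleleFrequencies],
    freqs_b: Mapping[object, AlleleFrequencies],
    corrected: bool = False,
) -> float:
    """Hedrick's standardized G''ST for k = 2 populations.

    Per locus, HS is the mean within-population gene diversity and HT the
    diversity of the pooled (mean) frequency vector; the multilocus value
    applies the k = 2 standardization once to loci-averaged HS and HT.
    With ``corrected=True`` the Nei–Chesser sample-size-corrected HS_hat,
    HT_hat replace the plug-in values (harmonic-mean individual count,
    gene-level form without the Ho term).  Negative values are reported,
    not clamped; NaN when every shared locus is monomorphic in both
    populations (HS = HT).
    """
    shared = _shared_loci(freqs_a, freqs_b)
    k = 2.0
    hs_list, ht_list = [], []
    for locus in shared:
        fa, fb = freqs_a[locus], freqs_b[locus]
        hs_a = 1.0 - sum(p * p for p in fa.freqs.values())
        hs_b = 1.0 - sum(p * p for p in fb.freqs.values())
        hs = 0.5 * (hs_a + hs_b)
        alleles = set(fa.freqs) | set(fb.freqs)
        pbar = {al: 0.5 * (fa.freqs.get(al, 0.0) + fb.freqs.get(al, 0.0)) for al in alleles}
        ht = 1.0 - sum(p * p for p in pbar.values())
        if corrected:
            # harmonic mean "individual" count from gene counts / 2
            na, nb = fa.gene_count / 2.0, fb.gene_count / 2.0
            nh = 2.0 / (1.0 / na + 1.0 / nb)
            hs_hat = hs * (2.0 * nh) / (2.0 * nh - 1.0)
            ht_hat = ht + hs_hat / (2.0 * nh * k)
            hs, ht = hs_hat, ht_hat
        hs_list.append(hs)
        ht_list.append(ht)
    hs_bar = float(np.mean(hs_list))
    ht_bar = float(np.mean(ht_list))
    if ht_bar == 0.0:
        return float("nan")
    gst = (ht_bar - hs_bar) / ht_bar
    gst_max = (k - 1.0) * (1.0 - hs_bar) / (k - 1.0 + hs_bar)
    if gst_max == 0.0 or hs_bar == 1.0:
        return float("nan")
    # G'ST (Hedrick) = GST / GST_max; G''ST additionally corrects HS in GST
    gst_dp = k * (ht_bar - hs_bar) / ((k * ht_bar - hs_bar) * (1.0 - hs_bar))
    return gst_dp


# ---------------------------------------------------------------------------
# spatial determinants

def edge_to_edge_distance(patch_a: Polygon, patch_b: Polygon) -> float:
    """Minimum boundary-to-boundary distance in meters; 0 when touching or
    overlapping.  Inputs must be valid polygons in a projected CRS."""
    for p in (patch_a, patch_b):
        if not p.is_valid:
            raise ValueError(f"invalid polygon: {explain_validity(p)}")
    return float(patch_a.distance(patch_b))


def hanski_connectivity(
    nodes: pd.DataFrame,
    params: ConnectivityParams,
    distances: Mapping[tuple, float] | None = None,
) -> pd.Series:
    """Incidence-function connectivity S_i per population.

    S_i = sum over other populations j in the same window of
    exp(-alpha d_ij) * A_j^b, with A_j the flowering-shoot count.
    `nodes` needs columns population, window, x, y, size; `distances` may
    supply precomputed (edge-to-edge) distances keyed by unordered pair,
    else centre-to-centre Euclidean distance is used.
    """
    if nodes.empty:
        raise ValueError("no populations")
    s = {}
    for _, row in nodes.iterrows():
        acc = 0.0
        same = nodes[(nodes["window"] == row["window"]) & (nodes["population"] != row["population"])]
        for _, other in same.iterrows():
            key = tuple(sorted((row["population"], other["population"])))
            if distances is not None and key in distances:
                d = distances[key]
            else:
                d = math.hypot(row["x"] - other["x"], row["y"] - other["y"])
            acc += math.exp(-params.alpha * d) * other["size"] ** params.b
        s[row["population"]] = acc
    return pd.Series(s, name="connectivity")


# ---------------------------------------------------------------------------
# assembly

def _population_frequencies(
    genotypes: GenotypeTable, population
) -> dict[object, AlleleFrequencies]:
    rec = genotypes.records
    loci = rec.loc[rec["population"] == population, "locus"].unique()
    return {loc: allele_frequencies(genotypes, population, loc) for loc in sorted(loci)}


def diversity_table(
    genotypes: GenotypeTable,
    rarefaction_size: int | None = None,
    corrected_he: bool = True,
) -> pd.DataFrame:
    """Per-population Ar, He, Ho, F and sample size.

    Statistics average over scored loci only; Ar uses a common rarefaction
    gene count (default: table-wide per-locus minimum).
    """
    g = rarefaction_size if rarefaction_size is not None else rarefaction_gene_count(genotypes)
    rows = []
    for pop in genotypes.populations:
        freqs = _population_frequencies(genotypes, pop)
        he = float(
            np.mean([expected_heterozygosity(f, corrected=corrected_he) for f in freqs.values()])
        )
        ho = observed_heterozygosity(genotypes, pop)
        counts = {}
        for locus in freqs:
            c, _ = allele_counts(genotypes, pop, locus)
            counts[locus] = c
        ar = allelic_richness(counts, g)
        rec = genotypes.records
        n_ind = rec.loc[rec["population"] == pop, "individual"].nunique()
        rows.append(
            {
                "window": genotypes.window_of(pop),
                "population": pop,
                "Ar": ar,
                "He": he,
                "Ho": ho,
                "F": inbreeding_coefficient(ho, he),
                "n_individuals": n_ind,
                "rarefaction_size": g,
            }
        )
    return pd.DataFrame(rows)


def differentiation_table(
    genotypes: GenotypeTable,
    patches: Mapping[object, Polygon] | None = None,
    centres: Mapping[object, tuple] | None = None,
    corrected_gst: bool = False,
) -> pd.DataFrame:
    """All within-window population pairs with G''ST, D_PS and distance.

    Distance is edge-to-edge between patch polygons when `patches` is given,
    else centre-to-centre from `centres`, else NaN.  Pairs sharing fewer
    than MIN_SHARED_LOCI scored loci get NaN statistics.
    """
    freqs = {p: _population_frequencies(genotypes, p) for p in genotypes.populations}
    windows = {p: genotypes.window_of(p) for p in genotypes.populations}
    rows = []
    for a, b in itertools.combinations(genotypes.populations, 2):
        if windows[a] != windows[b]:
            continue
        shared = set(freqs[a]) & set(freqs[b])
        if len(shared) < MIN_SHARED_LOCI:
            gst, dps = float("nan"), float("nan")
        else:
            gst = pairwise_gst_dp(freqs[a], freqs[b], corrected=corrected_gst)
            dps = pairwise_dps(freqs[a], freqs[b])
        if patches is not None and a in patches and b in patches:
            dist = edge_to_edge_distance(patches[a], patches[b])
        elif centres is not None and a in centres and b in centres:
            dist = math.hypot(
                centres[a][0] - centres[b][0], centres[a][1] - centres[b][1]
            )
        else:
            dist = float("nan")
        rows.append(
            {
                "window": windows[a],
                "pop1": a,
                "pop2": b,
                "Gst_dp": gst,
                "Dps": dps,
                "distance_m": dist,
            }
        )
    return pd.DataFrame(rows)
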