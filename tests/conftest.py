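import numpy as np
import pandas as pd
import pytest
from shapely.geometry import LineString, Point, box

from landgen.landscape import LandscapeWindow, LandusePolygon, LinearElement
from landgen.popgen import GenotypeTable


def make_genotypes(rows, ploidy=2, dosage_known=True):
    rec = pd.DataFrame(
        rows, columns=["window", "population", "individual", "locus", "alleles"]
    )
    return GenotypeTable(rec, ploidy=ploidy, dosage_known=dosage_known)


@pytest.fixture
def two_class_window():
    """100 x 100 m window split into a forest half and an arable half, with
    one road crossing it."""
    ext = box(0, 0, 100, 100)
    crops = {y: "RAPE" for y in range(2008, 2013)}
    crops.update({y: "MAIZE" for y in range(2013, 2018)})
    return LandscapeWindow(
        "T",
        ext,
        [
            LandusePolygon(box(0, 0, 50, 100), "FOREST"),
            LandusePolygon(box(50, 0, 100, 100), "ARABLE", crop_years=crops),
        ],
        [LinearElement(LineString([(0, 50), (100, 50)]), "LROAD")],
    )


@pytest.fixture
def checkerboard_window():
    """100 x 100 m window tiled 2 x 2 with alternating classes."""
    ext = box(0, 0, 100, 100)
    polys = [
        LandusePolygon(box(0, 0, 50, 50), "FOREST"),
        LandusePolygon(box(50, 0, 100, 50), "GRASS"),
        LandusePolygon(box(0, 50, 50, 100), "GRASS"),
        LandusePolygon(box(50, 50, 100, 100), "FOREST"),
    ]
    return LandscapeWindow("C", ext, polys, [])


@pytest.fixture
def link_frame():
    """Balanced link-level frame: 4 windows x 4 populations = 24 pairs."""
    import itertools

    rows = []
    for w in range(4):
        pops = [f"W{w}P{i}" for i in range(4)]
        for a, b in itertools.combinations(pops, 2):
            rows.append({"window": f"W{w}", "pop1": a, "pop2": b})
    df = pd.DataFrame(rows)
    rng = np.random.default_rng(42)
    df["x"] = rng.normal(size=len(df))
    df["d"] = rng.normal(size=len(df))
    return df
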