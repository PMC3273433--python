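from __future__ import annotations

import itertools

import pytest

from xloss import io as xio


def enumerate_progeny_probs(d, l, p_x=0.5, v=None):
    """Brute-force oracle: exhaust {oocyte fate} x {4 meiotic products} x
    {sperm} x {viability} and return the conditional scored-class probabilities
    (f_x0_son, f_xxy_daughter, f_normal_son, f_normal_daughter) plus the total
    survival probability Z.

    Kept fully independent of the package's model module: only elementary
    arithmetic over the exhaustive outcome tree.
    """
    viab = {
        "x0": 1.0, "xxy": 1.0, "xxx": 0.0, "y0": 0.0, "xx": 1.0, "xy": 1.0,
    }
    if v:
        viab.update(v)
    # each fate maps to the X content of its four meiotic products
    fates = [
        (1.0 - d - l, ["one", "one", "one", "one"]),   # normal
        (d, ["two", "two", "zero", "zero"]),           # meiosis-I nondisjunction
        (l, ["zero", "one", "one", "one"]),            # broken X lost
    ]
    karyotype = {
        ("zero", "X"): "x0", ("zero", "Y"): "y0",
        ("one", "X"): "xx", ("one", "Y"): "xy",
        ("two", "X"): "xxx", ("two", "Y"): "xxy",
    }
    scored = {"x0": 0.0, "xxy": 0.0, "xy": 0.0, "xx": 0.0}
    z_total = 0.0
    for (p_fate, products), idx, (sperm, p_sperm) in itertools.product(
        fates, range(4), [("X", p_x), ("Y", 1.0 - p_x)]
    ):
        egg = products[idx]
        karyo = karyotype[(egg, sperm)]
        p = p_fate * 0.25 * p_sperm * viab[karyo]
        z_total += p
        if karyo in scored:
            scored[karyo] += p
    z_scored = sum(scored.values())
    return (
        scored["x0"] / z_scored,
        scored["xxy"] / z_scored,
        scored["xy"] / z_scored,
        scored["xx"] / z_scored,
    ), z_total


@pytest.fixture(scope="session")
def table3_exp1():
    return xio.read_cross_table(xio.fixture_path("table3_exp1_cross.tsv"))


@pytest.fixture(scope="session")
def table3_exp2():
    return xio.read_cross_table(xio.fixture_path("table3_exp2_cross.tsv"))


@pytest.fixture(scope="session")
def table2():
    return xio.read_fecundity_table(xio.fixture_path("table2_fecundity.tsv"))


@pytest.fixture(scope="session")
def fig1_cytology():
    return xio.read_cytology_table(xio.fixture_path("fig1_cytology.tsv"))


@pytest.fixture(scope="session")
def none_row(table3_exp1):
    return table3_exp1[0]
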