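"""Haplotype diversity, pruning, the screen and the matriline estimators."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from matrikin.errors import ConfigError
from matrikin.uniparental_stats import (
    diversity_relatedness_screen,
    haplotype_diversity,
    matriline_report,
    min_matriline_births,
    min_matriline_births_mc,
    prune_first_degree,
    site_panels,
)


from _oracles import brute_force_h, partitions


def test_h_examples():
    assert haplotype_diversity(["A", "A", "A"]) == 0.0
    assert haplotype_diversity(["A", "B"]) == 1.0
    assert haplotype_diversity(["A", "A", "A", "B"]) == pytest.approx(0.5)


def test_h_matches_bruteforce_on_all_multisets_up_to_8():
    for n in range(2, 9):
        for shape in partitions(n):
            labels = [
                f"L{i}" for i, count in enumerate(shape) for _ in range(count)
            ]
            assert haplotype_diversity(labels) == pytest.approx(
                brute_force_h(labels), abs=1e-12
            ), shape


def test_h_biased_variant():
    labels = ["A", "A", "B", "B"]
    assert haplotype_diversity(labels, unbiased=False) == pytest.approx(0.5)
    assert haplotype_diversity(labels) == pytest.approx(2 / 3)


def test_h_undefined_below_two():
    with pytest.raises(ValueError):
        haplotype_diversity(["A"])


@settings(deadline=None, derandomize=True)
@given(st.lists(st.integers(0, 5), min_size=2, max_size=40),
       st.randoms(use_true_random=False))
def test_h_invariances(labels, rnd):
    h = haplotype_diversity(labels)
    assert 0.0 <= h <= 1.0
    shuffled = list(labels)
    rnd.shuffle(shuffled)
    assert haplotype_diversity(shuffled) == pytest.approx(h)
    relabel = {l: f"perm{l}" for l in set(labels)}
    assert haplotype_diversity([relabel[l] for l in labels]) == pytest.approx(h)


def test_h_decreases_when_singleton_joins_modal_class():
    labels = ["A", "A", "A", "B", "C"]
    worse = ["A", "A", "A", "A", "C"]  # singleton B replaced by modal copy
    assert haplotype_diversity(worse) < haplotype_diversity(labels)


# --- pruning -----------------------------------------------------------------

def _pairs(rows):
    return pd.DataFrame(rows, columns=["id1", "id2", "degree"])


def test_prune_identity_without_first_degree():
    pairs = _pairs([("A", "B", 3)])
    assert prune_first_degree(pairs, ["A", "B", "C"]) == ["A", "B", "C"]


def test_prune_single_pair_removes_one():
    pairs = _pairs([("A", "B", 1)])
    kept = prune_first_degree(pairs, ["A", "B", "C"])
    assert len(kept) == 2 and "C" in kept


def test_prune_star_removes_hub_only():
    pairs = _pairs([("P", "C1", 1), ("P", "C2", 1), ("P", "C3", 1)])
    kept = prune_first_degree(pairs, ["P", "C1", "C2", "C3"])
    assert kept == ["C1", "C2", "C3"]


def test_prune_greedy_matches_bruteforce_on_random_graphs():
    """Greedy retains at least as many individuals as needed: no remaining
    first-degree pair, and retention is optimal on small random graphs."""
    rng = np.random.default_rng(2)
    for _ in range(25):
        ids = [f"I{i}" for i in range(7)]
        edges = [
            (a, b) for a, b in itertools.combinations(ids, 2)
            if rng.random() < 0.25
        ]
        pairs = _pairs([(a, b, 1) for a, b in edges])
        kept = set(prune_first_degree(pairs, ids))
        assert not any(a in kept and b in kept for a, b in edges)
        # brute force: maximum independent set size
        best = 0
        for r in range(len(ids), 0, -1):
            if any(
                not any(a in sub and b in sub for a, b in edges)
                for sub in map(set, itertools.combinations(ids, r))
            ):
                best = r
                break
        # greedy is not always optimal in general; it must be within 1 here
        assert len(kept) >= best - 1


# --- screen ------------------------------------------------------------------

def test_screen_perfectly_collinear():
    table = pd.DataFrame({
        "site": list("ABCD"),
        "h_mt": [1.0, 0.8, 0.6, 0.4],
        "r_norm": [0.0, 0.25, 0.5, 0.75],
    })
    res = diversity_relatedness_screen(table)
    assert res.iloc[0]["r"] == pytest.approx(-1.0)
    assert res.iloc[0]["p"] < 0.01


def test_screen_degenerate_variance_flagged():
    table = pd.DataFrame({
        "site": list("ABC"), "h_mt": [0.5, 0.5, 0.5], "r_norm": [0.1, 0.2, 0.3]
    })
    res = diversity_relatedness_screen(table)
    assert math.isnan(res.iloc[0]["r"])
    assert res.iloc[0]["note"] == "degenerate variance"


def test_screen_too_few_sites_flagged():
    table = pd.DataFrame({"site": ["A", "B"], "h_mt": [0.5, 0.6],
                          "r_norm": [0.1, 0.2]})
    res = diversity_relatedness_screen(table)
    assert res.iloc[0]["note"] == "fewer than 3 sites"


def test_screen_p_matches_permutation_oracle():
    """Reported Pearson p agrees with a two-sided permutation oracle."""
    rng = np.random.default_rng(5)
    diffs = []
    for trial in range(20):
        n = 12
        h = rng.uniform(0, 1, n)
        r = 0.5 * h + rng.normal(0, 0.3, n)
        table = pd.DataFrame({"site": range(n), "h_mt": h, "r_norm": r})
        rep = diversity_relatedness_screen(table).iloc[0]
        obs = abs(np.corrcoef(h, r)[0, 1])
        perm = 0
        n_perm = 2000
        for _ in range(n_perm):
            perm += abs(np.corrcoef(h, rng.permutation(r))[0, 1]) >= obs
        diffs.append(abs(perm / n_perm - rep["p"]))
    assert np.mean(diffs) < 0.03


def test_screen_grouping():
    rng = np.random.default_rng(1)
    table = pd.DataFrame({
        "site": [f"S{i}" for i in range(12)],
        "period": ["IA"] * 6 + ["BA"] * 6,
        "h_mt": rng.uniform(0, 1, 12),
        "r_norm": rng.uniform(0, 1, 12),
    })
    res = diversity_relatedness_screen(table, group_cols=["period"])
    assert set(res["group"]) == {"IA", "BA"}


# --- matriline reports -------------------------------------------------------

def test_matriline_all_distinct():
    rep = matriline_report(["A", "B", "C", "D"])
    assert rep.frequency == pytest.approx(0.25)
    assert rep.subclade_count == 0


def test_matriline_dominant_fraction_with_subclades():
    """24 of 34 kin in the dominant lineage with four derived subclades."""
    labels = (
        ["U5b1"] * 12
        + ["U5b1.1"] * 4 + ["U5b1.2"] * 4 + ["U5b1.3"] * 2 + ["U5b1.4"] * 2
        + [f"other{i}" for i in range(10)]
    )
    rep = matriline_report(labels)
    assert rep.n == 34 and rep.n_carriers == 24
    assert rep.frequency == pytest.approx(24 / 34)
    assert round(rep.frequency, 3) == 0.706
    assert rep.subclade_count == 4


def test_matriline_nested_subclades_counted_once_each():
    rep = matriline_report(["A", "A.1", "A.1.1", "A.1.1", "B"])
    assert rep.dominant_label == "A"
    assert rep.subclade_count == 2  # A.1 and A.1.1


# --- minimum matriline births ------------------------------------------------

def test_min_births_zero_mutations():
    assert min_matriline_births(0) == 0


def test_min_births_single_mutation_median():
    """k=1 at mu*L=7.8e-3: solve 1 - exp(-N mu L) >= 1/2 -> N = 89."""
    n = min_matriline_births(1, mu=7.8e-3 / 16_569, length_bp=16_569,
                             confidence=0.5)
    assert n == 89
    assert n == math.ceil(math.log(2) / 7.8e-3)


def test_min_births_four_subclades_fast_rate():
    """k=4 subclades at the fast mtDNA rate: N lands in the hundreds."""
    n = min_matriline_births(4)
    assert 300 < n < 900
    lam = n * 4.72e-7 * 16_569
    from scipy.stats import poisson
    assert poisson.sf(3, lam) >= 0.5
    assert poisson.sf(3, (n - 1) * 4.72e-7 * 16_569) < 0.5


def test_min_births_monotonicity():
    base = dict(mu=4.72e-7, length_bp=16_569, confidence=0.5)
    assert min_matriline_births(2, **base) <= min_matriline_births(4, **base)
    assert min_matriline_births(4, **{**base, "confidence": 0.9}) >= \
        min_matriline_births(4, **base)
    assert min_matriline_births(4, **{**base, "mu": 9.44e-7}) <= \
        min_matriline_births(4, **base)
    assert min_matriline_births(4, mu=4.72e-7, length_bp=33_138,
                                confidence=0.5) <= min_matriline_births(4, **base)


def test_min_births_invalid_inputs():
    with pytest.raises(ConfigError):
        min_matriline_births(1, confidence=0.0)
    with pytest.raises(ConfigError):
        min_matriline_births(1, confidence=1.5)
    with pytest.raises(ConfigError):
        min_matriline_births(-1)


def test_min_births_monte_carlo_agrees():
    exact = min_matriline_births(4)
    mc = min_matriline_births_mc(4, seed=1)
    assert abs(mc - exact) / exact < 0.1


# --- panels ------------------------------------------------------------------

def test_site_panels_matrilocal(matrilocal_panel):
    panels = site_panels(matrilocal_panel["metadata"], matrilocal_panel["pairs"])
    assert len(panels) == 1
    p = panels[0]
    assert p.n >= 2 and 0 <= p.h_mt <= 1
    assert p.r_norm is not None and 0 <= p.r_norm <= 1
    # no first-degree pair survives pruning
    pairs = matrilocal_panel["pairs"]
    kept = set(p.ids)
    deg1 = pairs[pairs["degree"].isin([0, 1])]
    assert not any(r.id1 in kept and r.id2 in kept for r in deg1.itertuples())


def test_matrilocal_panels_mt_less_diverse_than_y():
    """Across 100 seeded matrilocal communities, within-site mtDNA diversity
    is below Y diversity nearly always; patrilocal communities reverse it."""
    from matrikin.synthetic_data import SimConfig, generate_pedigree_retry

    def run(residence, seed):
        cfg = SimConfig(seed=seed, depth=4, residence=residence)
        ped, _ = generate_pedigree_retry(cfg)
        res = ped.residents
        mt = [n.mt_label for n in res]
        y = [n.y_label for n in res if n.y_label]
        if len(mt) < 4 or len(y) < 4:
            return None
        return haplotype_diversity(mt), haplotype_diversity(y)

    wins = trials = 0
    for seed in range(100):
        out = run("matrilocal", 10_000 + seed)
        if out:
            trials += 1
            wins += out[0] < out[1]
    assert trials >= 80 and wins / trials >= 0.9

    wins = trials = 0
    for seed in range(100):
        out = run("patrilocal", 20_000 + seed)
        if out:
            trials += 1
            wins += out[0] > out[1]
    assert trials >= 80 and wins / trials >= 0.9
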