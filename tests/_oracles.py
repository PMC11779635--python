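"""Independent oracles shared by unit and acceptance tests."""

import itertools
import math

import numpy as np


def brute_force_h(labels):
    """Fraction of discordant unordered pairs (haplotype diversity)."""
    pairs = list(itertools.combinations(labels, 2))
    return sum(a != b for a, b in pairs) / len(pairs)


def partitions(n, largest=None):
    """All integer partitions of n (label multiset shapes)."""
    largest = largest or n
    if n == 0:
        yield ()
        return
    for k in range(min(n, largest), 0, -1):
        for rest in partitions(n - k, k):
            yield (k,) + rest


def fisher_two_sided_oracle(table):
    """Exact two-sided Fisher p by enumerating the hypergeometric support."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def log_fact(x):
        return math.lgamma(x + 1)

    def log_p(x):
        return (
            log_fact(r1) - log_fact(x) - log_fact(r1 - x)
            + log_fact(r2) - log_fact(c1 - x) - log_fact(r2 - (c1 - x))
            - (log_fact(n) - log_fact(c1) - log_fact(n - c1))
        )

    lo, hi = max(0, c1 - r2), min(r1, c1)
    probs = {x: math.exp(log_p(x)) for x in range(lo, hi + 1)}
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-9))


def welch_oracle(x, y):
    """Welch's two-sided t statistic and p from first principles."""
    from scipy.stats import t as tdist

    x, y = np.asarray(x, float), np.asarray(y, float)
    vx, vy = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
    t = (x.mean() - y.mean()) / math.sqrt(vx + vy)
    df = (vx + vy) ** 2 / (vx**2 / (len(x) - 1) + vy**2 / (len(y) - 1))
    return t, 2 * tdist.sf(abs(t), df)


def canonical_relationship_pedigree():
    """One pedigree containing ten canonical relationships.

    Returns (pedigree, [(name, id_a, id_b, expected_kinship), ...]).
    """
    from matrikin.synthetic_data import Pedigree, PedigreeNode

    rows = [
        # id, sex, mother, father, generation
        ("A", "F", None, None, 0), ("B", "M", None, None, 0),
        ("B2", "M", None, None, 0),
        ("C", "F", "A", "B", 1), ("D", "M", "A", "B", 1),
        ("E", "M", "A", "B2", 1),
        ("E2", "M", None, None, 1), ("F2", "F", None, None, 1),
        ("G", "F", "C", "E2", 2), ("H", "M", "F2", "D", 2),
        ("H2", "M", None, None, 2), ("I2", "F", None, None, 2),
        ("I", "F", "G", "H2", 3), ("J", "M", "I2", "H", 3),
    ]
    ped = Pedigree()
    for nid, sex, mo, fa, gen in rows:
        ped[nid] = PedigreeNode(nid, sex, mo, fa, gen, "S1", True, False,
                                "MT001", "Y001" if sex == "M" else None)
    relationships = [
        ("parent-offspring", "A", "C", 1 / 4),
        ("full-sibs", "C", "D", 1 / 4),
        ("half-sibs", "C", "E", 1 / 8),
        ("grandmother", "A", "G", 1 / 8),
        ("avuncular", "D", "G", 1 / 8),
        ("half-avuncular", "E", "G", 1 / 16),
        ("first-cousins", "G", "H", 1 / 16),
        ("great-grandmother", "A", "I", 1 / 16),
        ("cousins-once-removed", "H", "I", 1 / 32),
        ("second-cousins", "I", "J", 1 / 64),
    ]
    return ped, relationships
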