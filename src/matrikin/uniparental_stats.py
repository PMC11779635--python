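"""Uniparental haplotype diversity and matriline statistics.

Per burial site, after greedy removal of first-degree relatives, this module
computes the unbiased haplotype diversity

    h = (n / (n - 1)) * (1 - sum_i p_i^2),

which equals the probability that two haplotypes sampled without replacement
differ, the normalized relative-pair statistic r_norm (relative pairs of
degree <= 7 over all pairs), the diversity-vs-relatedness correlation screen
across sites, dominant-matriline summaries, and a minimum-births bound for
the age of a matriline from its de novo subclade count.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError
from .kinship import MAX_DEGREE, UNRELATED
from .synthetic_data import mt_root_label


def haplotype_diversity(labels, unbiased: bool = True) -> float:
    """Probability that two randomly selected haplotypes are different.

    With ``unbiased=True`` (default) applies the n/(n-1) without-replacement
    correction, making the statistic exactly the discordant fraction of
    unordered pairs. Requires at least two haplotypes.
    """
    labels = list(labels)
    n = len(labels)
    if n < 2:
        raise ValueError("haplotype diversity needs at least two haplotypes")
    freqs = np.array(list(Counter(labels).values()), dtype=float) / n
    h = 1.0 - float(np.sum(freqs**2))
    return h * n / (n - 1) if unbiased else h


def prune_first_degree(pairs: pd.DataFrame, ids) -> list[str]:
    """Greedily remove individuals until no first-degree pair remains.

    Repeatedly drops the individual with the most remaining first-degree
    links (ties broken by ascending id), which retains the maximum number of
    individuals for star-shaped families (one parent with many children).
    """
    ids = set(ids)
    links: dict[str, set[str]] = {i: set() for i in ids}
    if len(pairs):
        deg1 = pairs[pairs["degree"].isin([0, 1])]
        for row in deg1.itertuples():
            if row.id1 in ids and row.id2 in ids:
                links[row.id1].add(row.id2)
                links[row.id2].add(row.id1)
    while True:
        worst = min(links, key=lambda i: (-len(links[i]), i))
        if not links[worst]:
            return sorted(links)
        for other in links.pop(worst):
            links[other].discard(worst)


@dataclass
class SitePanel:
    """Per-site summary after first-degree pruning."""

    site: str
    ids: list[str]
    n: int
    h_mt: float | None
    h_y: float | None
    n_y: int
    r_norm: float | None

    def as_row(self) -> dict:
        return {
            "site": self.site, "n": self.n, "h_mt": self.h_mt,
            "h_y": self.h_y, "n_y": self.n_y, "r_norm": self.r_norm,
        }


def _relative_pairs(pairs: pd.DataFrame, kept: set[str]) -> int:
    if not len(pairs):
        return 0
    rel = pairs[
        pairs["degree"].apply(lambda d: d != UNRELATED and int(d) <= MAX_DEGREE)
        & pairs["id1"].isin(kept) & pairs["id2"].isin(kept)
    ]
    return len({(min(r.id1, r.id2), max(r.id1, r.id2)) for r in rel.itertuples()})


def site_panels(metadata: pd.DataFrame, pairs: pd.DataFrame) -> list[SitePanel]:
    """Build pruned per-site panels with mtDNA and Y diversity and r_norm."""
    panels = []
    for site, grp in metadata.groupby("site"):
        site_ids = list(grp["id"])
        site_pairs = pairs[pairs["id1"].isin(site_ids) & pairs["id2"].isin(site_ids)] \
            if len(pairs) else pairs
        kept = prune_first_degree(site_pairs, site_ids)
        sub = grp[grp["id"].isin(kept)]
        n = len(sub)
        h_mt = haplotype_diversity(sub["mt_label"]) if n >= 2 else None
        if "sex" in sub.columns and "y_label" in sub.columns:
            y_labels = [y for y in sub.loc[sub["sex"] == "M", "y_label"] if y]
        else:
            y_labels = []
        h_y = haplotype_diversity(y_labels) if len(y_labels) >= 2 else None
        r_norm = None
        if n >= 2:
            r_norm = _relative_pairs(site_pairs, set(kept)) / (n * (n - 1) / 2)
        panels.append(SitePanel(str(site), sorted(kept), n, h_mt, h_y, len(y_labels), r_norm))
    return panels


def diversity_relatedness_screen(
    site_table: pd.DataFrame,
    group_cols: list[str] | None = None,
    h_col: str = "h_mt",
) -> pd.DataFrame:
    """Pearson correlation of haplotype diversity against r_norm per group.

    ``site_table`` needs one row per site with ``h_col`` and ``r_norm``
    (optionally grouping columns such as period and region). Groups with
    fewer than three usable sites or degenerate variance report NaN with a
    reason rather than failing.
    """
    rows = []
    groups = site_table.groupby(group_cols) if group_cols else [("all", site_table)]
    for name, grp in groups:
        sub = grp.dropna(subset=[h_col, "r_norm"])
        h = sub[h_col].to_numpy(float)
        r = sub["r_norm"].to_numpy(float)
        label = name if isinstance(name, str) else "/".join(map(str, np.atleast_1d(name)))
        row = {"group": label, "n_sites": len(sub), "r": math.nan,
               "p": math.nan, "slope": math.nan, "intercept": math.nan, "note": ""}
        if len(sub) < 3:
            row["note"] = "fewer than 3 sites"
        elif np.ptp(h) == 0 or np.ptp(r) == 0:
            row["note"] = "degenerate variance"
        else:
            res = stats.pearsonr(h, r)
            fit = np.polyfit(r, h, 1)
            row.update(r=float(res.statistic), p=float(res.pvalue),
                       slope=float(fit[0]), intercept=float(fit[1]))
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class MatrilineReport:
    """Dominant matriline of a site: modal root label, its frequency among
    carriers, and the number of distinct de novo subclades derived from it."""

    dominant_label: str
    frequency: float
    n_carriers: int
    n: int
    subclade_count: int


def matriline_report(labels) -> MatrilineReport:
    """Identify the dominant matriline and count its derived subclades.

    Root labels group de novo derivatives with their founding haplotype
    (``MT001.2.1`` descends from ``MT001``); the subclade count is the number
    of distinct derived labels observed within the dominant root lineage.
    """
    labels = list(labels)
    if not labels:
        raise ValueError("no labels supplied")
    roots = [mt_root_label(l) for l in labels]
    counts = Counter(roots)
    top = max(counts.values())
    dominant = min(l for l, c in counts.items() if c == top)
    carriers = [l for l, r in zip(labels, roots) if r == dominant]
    subclades = {l for l in carriers if l != dominant}
    return MatrilineReport(
        dominant_label=dominant,
        frequency=len(carriers) / len(labels),
        n_carriers=len(carriers),
        n=len(labels),
        subclade_count=len(subclades),
    )


def min_matriline_births(
    k: int,
    mu: float = 4.72e-7,
    length_bp: int = 16_569,
    confidence: float = 0.5,
) -> int:
    """Minimum number of births to lineage mothers implied by ``k`` de novo
    mutations.

    Models the number of de novo mtDNA mutations over N transmissions as
    Poisson with rate N * mu * length_bp and returns the smallest N for which
    P(X >= k) reaches ``confidence``. The default rate is a fast mtDNA
    estimate of 4.72e-7 mutations per site per generation over the 16,569-bp
    mitochondrial genome. Non-decreasing in k and confidence, non-increasing
    in mu and length.
    """
    if k < 0:
        raise ConfigError("k must be non-negative")
    if not 0.0 < confidence < 1.0:
        raise ConfigError("confidence must lie in (0, 1)")
    per_birth = mu * length_bp
    if not 0.0 < per_birth < 1.0:
        raise ConfigError("mu * length must lie in (0, 1)")
    if k == 0:
        return 0
    # P(X >= k) is increasing in N; bracket then bisect on integers
    lo, hi = 0, 1
    while stats.poisson.sf(k - 1, hi * per_birth) < confidence:
        lo, hi = hi, hi * 2
        if hi > 10**12:
            raise ConfigError("confidence unreachable at this rate")
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if stats.poisson.sf(k - 1, mid * per_birth) >= confidence:
            hi = mid
        else:
            lo = mid
    return hi


def min_matriline_births_mc(
    k: int,
    mu: float = 4.72e-7,
    length_bp: int = 16_569,
    confidence: float = 0.5,
    n_reps: int = 20_000,
    seed: int = 0,
) -> int:
    """Monte-Carlo backend for :func:`min_matriline_births`.

    Simulates mutation counts over candidate N by direct Poisson draws and
    returns the smallest N (on a geometric-then-linear refinement) whose
    simulated P(X >= k) reaches ``confidence``. Used as a cross-check.
    """
    if k == 0:
        return 0
    rng = np.random.default_rng(seed)
    per_birth = mu * length_bp

    def prob(n: int) -> float:
        draws = rng.poisson(n * per_birth, size=n_reps)
        return float(np.mean(draws >= k))

    hi = 1
    while prob(hi) < confidence:
        hi *= 2
        if hi > 10**9:
            raise ConfigError("confidence unreachable at this rate")
    lo = hi // 2
    step = max((hi - lo) // 40, 1)
    for n in range(lo, hi + 1, step):
        if prob(n) >= confidence:
            return n
    return hi
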