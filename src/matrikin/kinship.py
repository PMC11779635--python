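"""Pairwise kinship from IBD segment tables.

Builds, per unordered sample pair, the merged IBD picture: total shared cM,
the fractions of the autosomal map covered by one-haplotype (IBD1) and
two-haplotype (IBD2) sharing, the kinship coefficient

    phi = f_IBD1 / 4 + f_IBD2 / 2,

and a relationship degree assigned by the standard power-of-two bins

    degree d  <=>  phi in (2^-(d+3/2), 2^-(d+1/2)],   d = 1..7,

with "unrelated" below the degree-7 lower edge and 0 marking identical-level
sharing (phi above the degree-1 upper edge, e.g. duplicate genomes).

Physical coordinates are mapped to genetic ones with a per-chromosome
constant rate estimated from the table itself (for the package's synthetic
dialect this is exact since 1 cM = 1 Mb by construction; for external data
it is a documented linear approximation). IBD2 is the intersection of the
two per-haplotype union tracks of the lexicographically smaller sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import _intervals as iv
from .errors import DataFormatError
from .genome import DEFAULT_GENOME, GenomeModel
from .synthetic_data import IBD_COLUMNS, mt_root_label

UNRELATED = "unrelated"
MAX_DEGREE = 7

PAIR_COLUMNS = [
    "id1", "id2", "total_ibd_cm", "f_ibd1", "f_ibd2", "kinship",
    "degree", "relationship", "longest_segment_cm", "n_segments", "x_total_cm",
]


def degree_from_kinship(kinship: float) -> int | str:
    """Power-of-two degree bin for a kinship coefficient."""
    if kinship <= 2.0 ** -(MAX_DEGREE + 1.5):
        return UNRELATED
    if kinship > 2.0 ** -1.5:
        return 0
    for d in range(1, MAX_DEGREE + 1):
        if kinship > 2.0 ** -(d + 1.5):
            return d
    return UNRELATED  # unreachable


def read_ibd(path: str | Path) -> pd.DataFrame:
    """Read a tab-delimited refinedIBD-style segment table.

    Accepts files with or without a header line. Raises
    :class:`DataFormatError` naming the first offending line for malformed
    rows (wrong column count, non-numeric coordinates, non-positive lengths).
    """
    path = Path(path)
    if not path.exists():
        raise DataFormatError(f"{path}: no such file")
    with open(path) as fh:
        first = fh.readline()
    if not first.strip():
        return pd.DataFrame(columns=IBD_COLUMNS)
    has_header = first.split("\t")[0].strip() == "sample1"
    try:
        df = pd.read_csv(
            path, sep="\t",
            header=0 if has_header else None,
            names=None if has_header else IBD_COLUMNS,
            dtype={"chrom": str} if has_header else {4: str},
        )
    except (pd.errors.ParserError, ValueError) as exc:
        raise DataFormatError(f"{path}: {exc}") from exc
    if list(df.columns) != IBD_COLUMNS:
        raise DataFormatError(
            f"{path}: expected columns {IBD_COLUMNS}, got {list(df.columns)}"
        )
    offset = 2 if has_header else 1
    for col in ("start_bp", "end_bp", "lod", "length_cm"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            line = int(vals.index[vals.isna()][0]) + offset
            raise DataFormatError(f"{path}: line {line}: non-numeric {col!r}")
        df[col] = vals
    bad = (df["length_cm"] <= 0) | (df["end_bp"] <= df["start_bp"])
    if bad.any():
        line = int(df.index[bad][0]) + offset
        raise DataFormatError(f"{path}: line {line}: non-positive segment length")
    df["chrom"] = df["chrom"].astype(str)
    return df


def _canonical_pairs(segments: pd.DataFrame) -> pd.DataFrame:
    """Order every row so sample1 <= sample2 (haplotype indices follow)."""
    seg = segments.copy()
    flip = seg["sample1"] > seg["sample2"]
    if flip.any():
        cols = ["sample1", "hap1", "sample2", "hap2"]
        seg.loc[flip, cols] = seg.loc[flip, ["sample2", "hap2", "sample1", "hap1"]].values
    return seg


def _cm_per_bp(segments: pd.DataFrame) -> dict[str, float]:
    """Per-chromosome linear genetic rate fitted through the origin."""
    out = {}
    for chrom, grp in segments.groupby("chrom"):
        span = float((grp["end_bp"] - grp["start_bp"]).sum())
        out[chrom] = float(grp["length_cm"].sum()) / span if span > 0 else 1e-6
    return out


def merge_and_classify(
    segments: pd.DataFrame,
    model: GenomeModel = DEFAULT_GENOME,
    gap_cm: float = 1.0,
) -> pd.DataFrame:
    """Merge IBD segments per pair and assign kinship and degree.

    Self-pairs (ROH) are excluded — see :func:`summarize_roh`. X-chromosome
    segments are excluded from autosomal kinship and reported separately as
    ``x_total_cm``.
    """
    known = set(model.chromosome_lengths)
    if len(segments):
        unknown = set(segments["chrom"].astype(str)) - known
        if unknown:
            raise DataFormatError(
                f"segments reference chromosomes {sorted(unknown)} absent from the genome model"
            )
    if not len(segments):
        return pd.DataFrame(columns=PAIR_COLUMNS)
    seg = _canonical_pairs(segments)
    seg = seg[seg["sample1"] != seg["sample2"]]
    if not len(seg):
        return pd.DataFrame(columns=PAIR_COLUMNS)
    rates = _cm_per_bp(seg)
    map_cm = model.autosome_total_cm

    s1 = seg["sample1"].to_numpy(str)
    s2 = seg["sample2"].to_numpy(str)
    chrom = seg["chrom"].to_numpy(str)
    hap1 = seg["hap1"].to_numpy(int)
    rate = np.array([rates[c] for c in chrom])
    start = seg["start_bp"].to_numpy(float) * rate
    end = seg["end_bp"].to_numpy(float) * rate
    length_cm = seg["length_cm"].to_numpy(float)
    order = np.lexsort((start, hap1, chrom, s2, s1))

    rows = []
    i = 0
    n = len(order)
    while i < n:
        j = i
        a, b = s1[order[i]], s2[order[i]]
        while j < n and s1[order[j]] == a and s2[order[j]] == b:
            j += 1
        idx = order[i:j]
        i = j
        x_mask = chrom[idx] == "X"
        x_total = float(length_cm[idx[x_mask]].sum())
        total = 0.0
        ibd2 = 0.0
        longest = 0.0
        n_merged = 0
        auto_idx = idx[~x_mask]
        for c in np.unique(chrom[auto_idx]):
            cidx = auto_idx[chrom[auto_idx] == c]
            unions = []
            for u in (1, 2):
                uidx = cidx[hap1[cidx] == u]
                merged = iv.merge(list(zip(start[uidx], end[uidx])), gap=gap_cm)
                unions.append(merged)
                total += iv.total(merged)
                n_merged += len(merged)
                longest = max([longest] + [e - s for s, e in merged])
            ibd2 += iv.total(iv.intersect(unions[0], unions[1]))
        f2 = min(ibd2 / map_cm, 1.0)
        covered = total - 2.0 * ibd2  # exactly-one-haplotype coverage
        f1 = min(max(covered, 0.0) / map_cm, 1.0 - f2)
        phi = f1 / 4.0 + f2 / 2.0
        degree = degree_from_kinship(phi)
        relationship = ""
        if degree == 1:
            relationship = "PO" if (f2 < 0.02 and f1 > 0.9) else "FS"
        rows.append((
            a, b, round(total, 4), f1, f2, phi, degree, relationship,
            round(longest, 4), n_merged, round(x_total, 4),
        ))
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


def weighted_relatedness(pairs: pd.DataFrame, ids: list[str] | None = None) -> pd.DataFrame:
    """Per-individual relatedness score: sum over relatives of 1/degree.

    Counts every relative of degree <= 7 once (duplicate pair rows are
    dropped); identical-level pairs (degree 0) weigh 1. Individuals in
    ``ids`` with no relatives score 0.
    """
    seen: set[tuple[str, str]] = set()
    score: dict[str, float] = {}
    links: dict[str, int] = {}
    for row in pairs.itertuples():
        key = (min(row.id1, row.id2), max(row.id1, row.id2))
        if key in seen or row.degree == UNRELATED:
            continue
        seen.add(key)
        d = int(row.degree)
        if d > MAX_DEGREE:
            continue
        w = 1.0 / max(d, 1)
        for i in key:
            score[i] = score.get(i, 0.0) + w
            links[i] = links.get(i, 0) + 1
    all_ids = sorted(set(ids or []) | set(score))
    return pd.DataFrame(
        {
            "id": all_ids,
            "score": [score.get(i, 0.0) for i in all_ids],
            "n_links": [links.get(i, 0) for i in all_ids],
        }
    )


@dataclass
class SexBiasReport:
    """Welch and Fisher tests for sex differences in relatedness."""

    welch_t: float | None
    welch_p: float | None
    fisher_odds: float | None
    fisher_p: float | None
    table: list[list[int]] | None
    dominant_label: str | None
    mean_score: dict[str, float]
    skipped: dict[str, str]

    def to_dict(self) -> dict:
        return {
            "welch": {"t": self.welch_t, "p": self.welch_p},
            "fisher": {"odds_ratio": self.fisher_odds, "p": self.fisher_p,
                       "table": self.table},
            "dominant_matriline": self.dominant_label,
            "mean_score_by_sex": self.mean_score,
            "skipped": self.skipped,
        }


def sex_bias_tests(
    scores: pd.DataFrame,
    metadata: pd.DataFrame,
    dominant_label: str | None = None,
) -> SexBiasReport:
    """Test whether males differ from females in weighted relatedness and in
    dominant-matriline membership.

    Welch's two-sided t-test compares relatedness scores between the sexes;
    Fisher's exact two-sided test compares the 2x2 table of sex against
    membership of the dominant matriline (modal root mtDNA label unless one
    is given). For multi-site metadata each individual is tested against the
    dominant matriline of their own site. A stratum with fewer than two
    individuals of either sex skips the corresponding test with a reason.
    """
    cols = ["id", "sex", "mt_label"] + (["site"] if "site" in metadata.columns else [])
    merged = scores.merge(metadata[cols], on="id", how="inner")
    skipped: dict[str, str] = {}
    f = merged.loc[merged["sex"] == "F", "score"].to_numpy(float)
    m = merged.loc[merged["sex"] == "M", "score"].to_numpy(float)
    mean_score = {
        "F": float(np.mean(f)) if len(f) else math.nan,
        "M": float(np.mean(m)) if len(m) else math.nan,
    }

    welch_t = welch_p = None
    if len(f) >= 2 and len(m) >= 2:
        t, p = stats.ttest_ind(m, f, equal_var=False)
        welch_t, welch_p = float(t), float(p)
    else:
        skipped["welch"] = "need at least two individuals of each sex"

    roots = merged["mt_label"].map(mt_root_label)
    if dominant_label is not None:
        in_dom = roots == dominant_label
    elif "site" in merged.columns:
        # membership relative to each individual's own site's modal matriline
        site_dominant = (
            roots.groupby(merged["site"])
            .agg(lambda r: r.mode().sort_values().iloc[0])
        )
        dominant_label = ";".join(
            f"{s}:{l}" for s, l in site_dominant.sort_index().items()
        )
        in_dom = roots == merged["site"].map(site_dominant)
    elif len(roots):
        dominant_label = roots.mode().sort_values().iloc[0]
        in_dom = roots == dominant_label
    fisher_odds = fisher_p = None
    table = None
    if dominant_label is not None and len(f) and len(m):
        table = [
            [int(((merged["sex"] == "F") & in_dom).sum()),
             int(((merged["sex"] == "F") & ~in_dom).sum())],
            [int(((merged["sex"] == "M") & in_dom).sum()),
             int(((merged["sex"] == "M") & ~in_dom).sum())],
        ]
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        fisher_odds, fisher_p = float(odds), float(p)
    else:
        skipped["fisher"] = "need individuals of both sexes with mtDNA labels"

    return SexBiasReport(welch_t, welch_p, fisher_odds, fisher_p, table,
                         dominant_label, mean_score, skipped)


def between_site_relatives(
    pairs: pd.DataFrame,
    metadata: pd.DataFrame,
    min_total_cm: float = 24.0,
) -> pd.DataFrame:
    """Cross-site pairs sharing more than ``min_total_cm`` of IBD.

    Each retained pair is annotated with both site labels and whether the two
    individuals share a root mtDNA haplotype — under matrilocality with male
    exogamy, between-site relatives should rarely share one.
    """
    meta = metadata.set_index("id")
    out = pairs[pairs["total_ibd_cm"] > min_total_cm].copy()
    if not len(out):
        return out.assign(site1=[], site2=[], mt_match=[])
    out["site1"] = out["id1"].map(meta["site"])
    out["site2"] = out["id2"].map(meta["site"])
    out = out[out["site1"] != out["site2"]].copy()
    mt1 = out["id1"].map(meta["mt_label"]).map(mt_root_label)
    mt2 = out["id2"].map(meta["mt_label"]).map(mt_root_label)
    out["mt_match"] = (mt1 == mt2).astype(bool)
    return out.reset_index(drop=True)


def summarize_roh(
    segments: pd.DataFrame,
    ids: list[str] | None = None,
    model: GenomeModel = DEFAULT_GENOME,
) -> pd.DataFrame:
    """Per-individual runs of homozygosity from within-individual segments.

    ROH here are autosomal IBD segments between an individual's two
    haplotypes; the fraction is relative to the autosomal map and estimates
    the individual's inbreeding coefficient.
    """
    if len(segments):
        self_rows = segments[
            (segments["sample1"] == segments["sample2"]) & (segments["chrom"] != "X")
        ]
        totals = self_rows.groupby("sample1")["length_cm"].agg(["sum", "count"])
    else:
        totals = pd.DataFrame(columns=["sum", "count"])
    all_ids = sorted(set(ids or []) | set(totals.index))
    map_cm = model.autosome_total_cm
    return pd.DataFrame(
        {
            "id": all_ids,
            "roh_total_cm": [float(totals["sum"].get(i, 0.0)) for i in all_ids],
            "roh_n": [int(totals["count"].get(i, 0)) for i in all_ids],
            "roh_fraction": [float(totals["sum"].get(i, 0.0)) / map_cm for i in all_ids],
        }
    )
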