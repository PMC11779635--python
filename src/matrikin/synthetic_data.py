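"""Synthetic community pedigrees with realized IBD sharing.

This module generates the inputs the rest of the package consumes: pedigrees
of small burial communities practising matrilocal, patrilocal or mixed
post-marital residence; uniparental haplotype labels inherited strictly
through the maternal (mtDNA) and paternal (Y) lines; and tab-delimited IBD
segment tables produced by dropping recombining genomes down the pedigree.

The residence rule decides which children found families in their natal
community. Under matrilocality daughters stay and reproduce locally with
in-marrying husbands; sons either remain in the community as non-reproducing
members (buried with their matrilineal kin) or emigrate and become available
as marriage partners for other communities. Patrilocality swaps the sex
roles; under mixed residence each child stays with probability one half
regardless of sex. This is the mechanism that makes a single founding
matriline dominate a matrilocal cemetery while male in-migrants contribute a
spread of singleton mtDNA haplotypes — the signature the downstream
statistics are designed to detect.

Gene dropping is exact at the segment level: each transmission draws a
Poisson number of crossovers (mean = map length / 100) at uniform genetic
positions, so every genome is a mosaic of founder haplotypes, and IBD between
two haplotypes is the set of maximal intervals descending from the same
founder haplotype. The X chromosome recombines only in females and is never
transmitted father-to-son.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .errors import ConfigError, SimulationFailure
from .genome import DEFAULT_GENOME, GenomeModel

Sex = Literal["F", "M"]
Residence = Literal["matrilocal", "patrilocal", "mixed"]

IBD_COLUMNS = [
    "sample1", "hap1", "sample2", "hap2",
    "chrom", "start_bp", "end_bp", "lod", "length_cm",
]
METADATA_COLUMNS = ["id", "site", "sex", "mt_label", "y_label", "coverage", "period"]


@dataclass
class PedigreeNode:
    """One individual in a community pedigree."""

    id: str
    sex: Sex
    mother: str | None
    father: str | None
    generation: int
    site: str
    resident: bool
    immigrant: bool  # married in from outside any modelled community
    mt_label: str
    y_label: str | None  # None for females

    @property
    def is_founder(self) -> bool:
        return self.mother is None and self.father is None


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a community simulation run.

    The same config drives single-pedigree generation and multi-site
    fixtures. ``depth`` counts generations below the founders, so a
    seven-generation pedigree has ``depth=6``.
    """

    seed: int = 0
    depth: int = 4
    n_sites: int = 1
    founder_couples_per_site: int = 1
    residence: Residence = "matrilocal"
    offspring_dist: str = "poisson"
    offspring_mean: float = 2.5
    mt_mutation_rate: float = 0.05
    founder_scheme: str | dict[str, float] = "all-distinct"
    exchange_prob: float = 0.3
    nonlocal_burial_prob: float = 0.5
    min_cm: float = 7.0

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ConfigError("depth must be >= 1")
        if self.n_sites < 1 or self.founder_couples_per_site < 1:
            raise ConfigError("site and founder counts must be positive")
        if self.residence not in ("matrilocal", "patrilocal", "mixed"):
            raise ConfigError(f"unknown residence rule {self.residence!r}")
        if self.offspring_dist not in ("poisson", "fixed"):
            raise ConfigError(f"unknown offspring distribution {self.offspring_dist!r}")
        for name, p in (
            ("mt_mutation_rate", self.mt_mutation_rate),
            ("exchange_prob", self.exchange_prob),
            ("nonlocal_burial_prob", self.nonlocal_burial_prob),
        ):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.min_cm <= 0:
            raise ConfigError("min_cm must be positive")


class Pedigree(dict):
    """Mapping id -> :class:`PedigreeNode` with convenience accessors."""

    @property
    def residents(self) -> list[PedigreeNode]:
        return [n for n in self.values() if n.resident]

    def by_site(self) -> dict[str, list[PedigreeNode]]:
        out: dict[str, list[PedigreeNode]] = {}
        for node in self.values():
            if node.resident:
                out.setdefault(node.site, []).append(node)
        return out

    def sorted_nodes(self) -> list[PedigreeNode]:
        return [self[k] for k in sorted(self, key=lambda i: (self[i].generation, i))]


class _LabelFactory:
    """Founder labels and infinite-alleles de novo derivatives.

    A de novo mtDNA mutation appends ``.k`` to the mother's label, so the
    subclade structure of a matriline is reconstructible from the labels
    (the root label is everything before the first dot).
    """

    def __init__(self, prefix: str, scheme: str | dict[str, float], rng: np.random.Generator):
        self.prefix = prefix
        self.scheme = scheme
        self.rng = rng
        self._n_founders = 0
        self._deriv_counter: dict[str, int] = {}

    def founder_label(self) -> str:
        if isinstance(self.scheme, dict):
            labels = sorted(self.scheme)
            probs = np.array([self.scheme[l] for l in labels], dtype=float)
            return str(self.rng.choice(labels, p=probs / probs.sum()))
        self._n_founders += 1
        return f"{self.prefix}{self._n_founders:03d}"

    def derive(self, parent_label: str) -> str:
        k = self._deriv_counter.get(parent_label, 0) + 1
        self._deriv_counter[parent_label] = k
        return f"{parent_label}.{k}"


def mt_root_label(label: str) -> str:
    """Root (founder) haplotype of a possibly-derived mtDNA label."""
    return label.split(".", 1)[0]


def _n_offspring(config: SimConfig, rng: np.random.Generator) -> int:
    if config.offspring_dist == "fixed":
        return int(round(config.offspring_mean))
    return int(rng.poisson(config.offspring_mean))


def generate_pedigree(config: SimConfig, rng: np.random.Generator | None = None) -> Pedigree:
    """Build a community pedigree under the configured residence rule.

    Returns every individual ever attached to the community, including
    emigrants (``resident=False``) and in-marrying spouses. Raises
    :class:`SimulationFailure` when every local lineage dies out before the
    requested depth; the caller may retry with a fresh seed.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    ped = Pedigree()
    mt_labels = _LabelFactory("MT", config.founder_scheme, rng)
    y_labels = _LabelFactory("Y", config.founder_scheme, rng)
    counter = [0]
    # emigrants available as cross-site spouses, keyed by generation
    disperser_pool: dict[int, list[str]] = {}

    def new_id() -> str:
        counter[0] += 1
        return f"I{counter[0]:04d}"

    def add_immigrant(sex: Sex, generation: int, site: str) -> PedigreeNode:
        node = PedigreeNode(
            id=new_id(), sex=sex, mother=None, father=None,
            generation=generation, site=site, resident=True, immigrant=True,
            mt_label=mt_labels.founder_label(),
            y_label=y_labels.founder_label() if sex == "M" else None,
        )
        ped[node.id] = node
        return node

    def find_spouse(for_node: PedigreeNode) -> PedigreeNode:
        want_sex = "M" if for_node.sex == "F" else "F"
        pool = [
            i for i in disperser_pool.get(for_node.generation, [])
            if ped[i].sex == want_sex and ped[i].site != for_node.site
        ]
        if pool and rng.random() < config.exchange_prob:
            chosen = ped[pool[int(rng.integers(len(pool)))]]
            disperser_pool[for_node.generation].remove(chosen.id)
            # marries in: buried in the spouse's community from now on
            chosen.site = for_node.site
            chosen.resident = True
            return chosen
        return add_immigrant(want_sex, for_node.generation, for_node.site)

    lineage_sex = {"matrilocal": "F", "patrilocal": "M"}.get(config.residence)

    # founders: one lineage parent per couple plus an in-marrying spouse
    reproducers: dict[str, list[str]] = {}
    for s in range(config.n_sites):
        site = f"S{s + 1}"
        reproducers[site] = []
        for _ in range(config.founder_couples_per_site):
            founder_sex: Sex = lineage_sex or "F"
            node = PedigreeNode(
                id=new_id(), sex=founder_sex, mother=None, father=None,
                generation=0, site=site, resident=True, immigrant=False,
                mt_label=mt_labels.founder_label(),
                y_label=y_labels.founder_label() if founder_sex == "M" else None,
            )
            ped[node.id] = node
            reproducers[site].append(node.id)

    for gen in range(config.depth):
        next_reproducers: dict[str, list[str]] = {site: [] for site in reproducers}
        for site in sorted(reproducers):
            for parent_id in reproducers[site]:
                parent = ped[parent_id]
                spouse = find_spouse(parent)
                mother, father = (parent, spouse) if parent.sex == "F" else (spouse, parent)
                for _ in range(_n_offspring(config, rng)):
                    sex: Sex = "F" if rng.random() < 0.5 else "M"
                    mt = mother.mt_label
                    if rng.random() < config.mt_mutation_rate:
                        mt = mt_labels.derive(mt)
                    child = PedigreeNode(
                        id=new_id(), sex=sex, mother=mother.id, father=father.id,
                        generation=gen + 1, site=site, resident=True, immigrant=False,
                        mt_label=mt, y_label=father.y_label if sex == "M" else None,
                    )
                    ped[child.id] = child
                    if lineage_sex is None:
                        local = rng.random() < 0.5
                    else:
                        local = sex == lineage_sex
                    if local:
                        next_reproducers[site].append(child.id)
                    elif rng.random() >= config.nonlocal_burial_prob:
                        child.resident = False
                        disperser_pool.setdefault(child.generation, []).append(child.id)
        # a site whose local lineage dies out would be an abandoned cemetery;
        # the model targets continuously used sites, so any extinction retries
        if gen + 1 < config.depth and any(not v for v in next_reproducers.values()):
            raise SimulationFailure(
                f"local lineage extinct at generation {gen + 1} (seed {config.seed})"
            )
        reproducers = next_reproducers
    return ped


def generate_pedigree_retry(
    config: SimConfig, max_attempts: int = 400
) -> tuple[Pedigree, SimConfig]:
    """Retry :func:`generate_pedigree` with derived seeds on lineage extinction."""
    last: SimulationFailure | None = None
    for attempt in range(max_attempts):
        cfg = replace(config, seed=int((config.seed + 1_000_003 * attempt) % 2**31))
        try:
            return generate_pedigree(cfg), cfg
        except SimulationFailure as exc:
            last = exc
    raise SimulationFailure(f"no surviving lineage in {max_attempts} attempts") from last


# ---------------------------------------------------------------------------
# gene dropping

Haplotype = tuple[tuple[float, int], ...]  # ((end_cm, founder_hap_id), ...)


def _fresh_hap(length: float, next_id: list[int]) -> Haplotype:
    next_id[0] += 1
    return ((length, next_id[0] - 1),)


def _recombine(h1: Haplotype, h2: Haplotype, length: float, rng: np.random.Generator) -> Haplotype:
    k = int(rng.poisson(length / 100.0))
    first = int(rng.integers(2))
    if k == 0:
        return (h1, h2)[first]
    cuts = np.sort(rng.uniform(0.0, length, k))
    haps = (h1, h2)
    out: list[tuple[float, int]] = []
    cur = first
    prev = 0.0
    for cut in [*cuts.tolist(), length]:
        if cut > prev:
            hap = haps[cur]
            i = 0
            while hap[i][0] <= prev:
                i += 1
            while i < len(hap) and prev < cut:
                seg_end = min(hap[i][0], cut)
                fid = hap[i][1]
                if out and out[-1][1] == fid:
                    out[-1] = (seg_end, fid)
                else:
                    out.append((seg_end, fid))
                prev = seg_end
                i += 1
        cur ^= 1
    return tuple(out)


@dataclass
class Genomes:
    """Realized mosaic genomes for every pedigree member.

    ``autosomal[id][chrom]`` is a pair of haplotypes; ``x[id]`` holds two
    haplotypes for females and one for males. ``founder_of`` maps founder
    haplotype ids back to the individual that introduced them.
    """

    model: GenomeModel
    autosomal: dict[str, dict[str, tuple[Haplotype, Haplotype]]]
    x: dict[str, tuple[Haplotype, ...]]
    founder_of: dict[int, str]


def drop_genomes(
    pedigree: Pedigree,
    model: GenomeModel = DEFAULT_GENOME,
    seed: int | np.random.Generator = 0,
) -> Genomes:
    """Drop recombining autosomes and X chromosomes down the pedigree."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    next_id = [0]
    founder_of: dict[int, str] = {}
    autosomal: dict[str, dict[str, tuple[Haplotype, Haplotype]]] = {}
    x: dict[str, tuple[Haplotype, ...]] = {}

    for node in pedigree.sorted_nodes():
        if node.is_founder:
            chroms = {}
            for chrom, length in model.autosomes:
                start = next_id[0]
                chroms[chrom] = (_fresh_hap(length, next_id), _fresh_hap(length, next_id))
                for fid in range(start, next_id[0]):
                    founder_of[fid] = node.id
            if node.sex == "F":
                start = next_id[0]
                x[node.id] = (
                    _fresh_hap(model.x_length_cm, next_id),
                    _fresh_hap(model.x_length_cm, next_id),
                )
            else:
                start = next_id[0]
                x[node.id] = (_fresh_hap(model.x_length_cm, next_id),)
            for fid in range(start, next_id[0]):
                founder_of[fid] = node.id
            autosomal[node.id] = chroms
            continue
        if node.mother not in pedigree or node.father not in pedigree:
            raise ConfigError(f"non-founder {node.id} is missing a parent in the pedigree")
        mother, father = pedigree[node.mother], pedigree[node.father]
        chroms = {}
        for chrom, length in model.autosomes:
            mat = _recombine(*autosomal[mother.id][chrom], length, rng)
            pat = _recombine(*autosomal[father.id][chrom], length, rng)
            chroms[chrom] = (mat, pat)
        autosomal[node.id] = chroms
        mat_x = (
            _recombine(*x[mother.id], model.x_length_cm, rng)
            if len(x[mother.id]) == 2 else x[mother.id][0]
        )
        if node.sex == "F":
            x[node.id] = (mat_x, x[father.id][0])  # father's X passes intact
        else:
            x[node.id] = (mat_x,)  # no father-to-son X
    return Genomes(model=model, autosomal=autosomal, x=x, founder_of=founder_of)


def _shared_runs(a: Haplotype, b: Haplotype) -> list[tuple[float, float]]:
    """Maximal intervals where both haplotypes carry the same founder segment."""
    out: list[tuple[float, float]] = []
    i = j = 0
    prev = 0.0
    run_start: float | None = None
    run_fid = -1
    while i < len(a) and j < len(b):
        end = min(a[i][0], b[j][0])
        if a[i][1] == b[j][1]:
            if run_start is None or a[i][1] != run_fid:
                if run_start is not None:
                    out.append((run_start, prev))
                run_start, run_fid = prev, a[i][1]
        elif run_start is not None:
            out.append((run_start, prev))
            run_start = None
        prev = end
        if a[i][0] <= end:
            i += 1
        if j < len(b) and b[j][0] <= end:
            j += 1
    if run_start is not None:
        out.append((run_start, prev))
    return out


def emit_ibd_table(genomes: Genomes, min_cm: float = 7.0, include_x: bool = True) -> pd.DataFrame:
    """Tabulate maximal shared founder segments >= ``min_cm`` between all
    haplotype pairs, including within-individual pairs (ROH).

    The output follows the 9-column refinedIBD-style dialect with synthetic
    physical coordinates (1 cM = 1 Mb) and a length-proportional LOD stand-in.
    """
    if min_cm <= 0:
        raise ConfigError("min_cm must be positive")
    ids = sorted(genomes.autosomal)
    rows: list[tuple] = []

    def emit(s1: str, h1: int, s2: str, h2: int, chrom: str, runs: Iterable[tuple[float, float]]):
        for start, end in runs:
            length = end - start
            if length >= min_cm:
                rows.append((
                    s1, h1, s2, h2, chrom,
                    int(round(start * 1e6)), int(round(end * 1e6)),
                    round(3.0 * length, 2), round(length, 4),
                ))

    for a_idx, s1 in enumerate(ids):
        for s2 in ids[a_idx:]:
            for chrom, _length in genomes.model.autosomes:
                ha = genomes.autosomal[s1][chrom]
                hb = genomes.autosomal[s2][chrom]
                if s1 == s2:
                    emit(s1, 1, s2, 2, chrom, _shared_runs(ha[0], ha[1]))
                else:
                    for u in (0, 1):
                        for v in (0, 1):
                            emit(s1, u + 1, s2, v + 1, chrom, _shared_runs(ha[u], hb[v]))
            if include_x:
                xa, xb = genomes.x[s1], genomes.x[s2]
                if s1 == s2:
                    if len(xa) == 2:
                        emit(s1, 1, s2, 2, "X", _shared_runs(xa[0], xa[1]))
                else:
                    for u, hu in enumerate(xa):
                        for v, hv in enumerate(xb):
                            emit(s1, u + 1, s2, v + 1, "X", _shared_runs(hu, hv))
    return pd.DataFrame(rows, columns=IBD_COLUMNS)


# ---------------------------------------------------------------------------
# fixtures

def pedigree_metadata(pedigree: Pedigree, rng: np.random.Generator | None = None,
                      period: str = "IronAge") -> pd.DataFrame:
    """Metadata CSV rows (resident individuals only — the burial panel)."""
    rng = np.random.default_rng(0) if rng is None else rng
    rows = [
        (n.id, n.site, n.sex, n.mt_label, n.y_label if n.y_label else "",
         round(float(rng.uniform(0.5, 2.0)), 3), period)
        for n in sorted(pedigree.residents, key=lambda n: n.id)
    ]
    return pd.DataFrame(rows, columns=METADATA_COLUMNS)


def make_site_fixture(
    config: SimConfig,
    outdir: str | Path,
    model: GenomeModel = DEFAULT_GENOME,
) -> dict[str, Path]:
    """Generate a multi-site panel and write metadata CSV + IBD table.

    Writes ``metadata.csv``, ``ibd.tsv`` and a ``provenance.json`` sidecar
    recording the generating parameters; returns the three paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pedigree, used_cfg = generate_pedigree_retry(config)
    rng = np.random.default_rng(used_cfg.seed + 1)
    genomes = drop_genomes(pedigree, model, rng)
    ibd = emit_ibd_table(genomes, min_cm=config.min_cm)
    resident = {n.id for n in pedigree.residents}
    ibd = ibd[ibd["sample1"].isin(resident) & ibd["sample2"].isin(resident)]
    meta = pedigree_metadata(pedigree, rng)

    paths = {
        "metadata": outdir / "metadata.csv",
        "ibd": outdir / "ibd.tsv",
        "provenance": outdir / "provenance.json",
    }
    try:
        meta.to_csv(paths["metadata"], index=False)
        ibd.to_csv(paths["ibd"], sep="\t", index=False)
        prov = {
            "config": {k: v for k, v in vars(used_cfg).items()},
            "n_individuals": len(meta),
            "n_segments": int(len(ibd)),
            "genome_total_cm": model.autosome_total_cm,
        }
        paths["provenance"].write_text(json.dumps(prov, indent=2, default=str))
    except OSError as exc:
        raise OSError(f"failed writing fixture under {outdir}: {exc}") from exc
    return paths
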