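import numpy as np
import pytest

from matrikin.synthetic_data import (
    Pedigree,
    PedigreeNode,
    SimConfig,
    drop_genomes,
    emit_ibd_table,
    generate_pedigree_retry,
    pedigree_metadata,
)
from matrikin.kinship import merge_and_classify


def build_pedigree(rows):
    """rows: (id, sex, mother, father, generation)."""
    ped = Pedigree()
    for nid, sex, mo, fa, gen in rows:
        ped[nid] = PedigreeNode(
            id=nid, sex=sex, mother=mo, father=fa, generation=gen,
            site="S1", resident=True, immigrant=False,
            mt_label="MT001", y_label="Y001" if sex == "M" else None,
        )
    return ped


@pytest.fixture(scope="session")
def cousin_pedigree():
    """Two first cousins G (F) and H (M) through sibs C and D."""
    return build_pedigree([
        ("A", "F", None, None, 0), ("B", "M", None, None, 0),
        ("C", "F", "A", "B", 1), ("D", "M", "A", "B", 1),
        ("E", "M", None, None, 1), ("F", "F", None, None, 1),
        ("G", "F", "C", "E", 2), ("H", "M", "F", "D", 2),
    ])


@pytest.fixture(scope="session")
def matrilocal_panel():
    """One matrilocal community with genomes, IBD table and pair relations."""
    cfg = SimConfig(seed=3, depth=4, residence="matrilocal")
    ped, used = generate_pedigree_retry(cfg)
    genomes = drop_genomes(ped, seed=1)
    ibd = emit_ibd_table(genomes, min_cm=1e-6)
    pairs = merge_and_classify(ibd)
    meta = pedigree_metadata(ped, np.random.default_rng(9))
    return dict(config=used, pedigree=ped, genomes=genomes, ibd=ibd,
                pairs=pairs, metadata=meta)


@pytest.fixture(scope="session")
def multisite_fixture(tmp_path_factory):
    """Six-site matrilocal fixture bundle on disk."""
    from matrikin.synthetic_data import make_site_fixture

    outdir = tmp_path_factory.mktemp("fixture")
    cfg = SimConfig(seed=11, depth=4, n_sites=6, residence="matrilocal")
    paths = make_site_fixture(cfg, outdir)
    return paths
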