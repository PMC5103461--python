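import numpy as np
import pytest

import straindiverge as sd


@pytest.fixture(scope="session")
def small_pair():
    """200-kb ancestor/derived pair at p=0.044 with its planted truth."""
    cfg = sd.SimulationConfig(seed=101, scaffold_lengths=(200_000,),
                              difference_p=0.044)
    anc = sd.make_ancestor(cfg)
    der, truth = sd.evolve(anc, cfg)
    return anc, der, truth


@pytest.fixture(scope="session")
def planted_annotation():
    """200 intron-rich genes planted into a 1-Mb scaffold (study regime)."""
    cfg = sd.SimulationConfig(seed=202, scaffold_lengths=(1_000_000,),
                              n_genes=200, ipg_mean=7.5,
                              intron_mean_len=110.0, exon_mean_len=199.0)
    genome = sd.make_ancestor(cfg)
    return sd.plant_genes(genome, cfg), cfg


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(7)


# shared oracle helpers -------------------------------------------------------

def brute_force_best_hits(table, rule):
    """Exhaustive best-hit comparator, independent of the implementation."""
    out = {}
    for q in sorted({h.query for h in table}):
        rows = [h for h in table if h.query == q and h.evalue < rule.max_evalue
                and (rule.min_identity is None
                     or h.pct_identity > rule.min_identity)]
        if not rows:
            continue
        rows.sort(key=lambda h: (h.evalue, -h.aln_length, -h.bitscore, h.subject))
        out[q] = rows[0].subject
    return out


def random_hit_table(rng, nq=8, ns=8, rows=25):
    from straindiverge.formats import HitRecord
    return [
        HitRecord(query=f"q{rng.integers(nq)}", subject=f"s{rng.integers(ns)}",
                  pct_identity=float(rng.integers(30, 100)),
                  aln_length=int(rng.integers(50, 500)),
                  evalue=float(10.0 ** -rng.integers(0, 40)),
                  bitscore=float(rng.integers(40, 900)))
        for _ in range(rows)
    ]
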