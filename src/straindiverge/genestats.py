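"""Assembly and annotation statistics: size, N50/L50, %N, GC%, gene density,
intron-less gene fraction (ILG%), introns per gene (IPG), pooled mean
intron/exon lengths, and the canonical-CDS rate.

Conventions: N50 is the length at which cumulative descending-sorted
scaffold lengths first reach half the assembly size and L50 its rank; GC% is
computed over non-N bases; an intron is the gap between consecutive CDS
exons of the same gene; exon/intron length means are pooled over all
exons/introns, not per-gene means of means.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .formats import GeneModel, GenomeAssembly

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class AssemblyStats:
    size: int
    n_scaffolds: int
    n50: int
    l50: int
    pct_n: float
    pct_gc: float


@dataclass
class AnnotationStats:
    genes: int
    genes_per_mb: float
    ilg_count: int
    pct_ilg: float
    introns_per_gene: float
    mean_intron_len: float
    mean_exon_len: float
    pct_canonical_cds: float


def assembly_stats(assembly: GenomeAssembly) -> AssemblyStats:
    if len(assembly) == 0:
        raise ValueError("empty assembly")
    lengths = np.sort([len(r) for r in assembly])[::-1]
    total = int(lengths.sum())
    cum = np.cumsum(lengths)
    l50 = int(np.searchsorted(cum, total / 2.0) + 1)
    n50 = int(lengths[l50 - 1])
    n_count = gc_count = 0
    for rec in assembly:
        s = rec.residues
        a, c, g, t = s.count("A"), s.count("C"), s.count("G"), s.count("T")
        gc_count += c + g
        n_count += len(s) - (a + c + g + t)
    non_n = total - n_count
    return AssemblyStats(
        size=total, n_scaffolds=len(assembly), n50=n50, l50=l50,
        pct_n=100.0 * n_count / total,
        pct_gc=100.0 * gc_count / non_n if non_n else float("nan"),
    )


def is_canonical_cds(cds: str) -> tuple[bool, str | None]:
    """Canonical: starts ATG, ends with a stop, length divisible by 3, no
    internal stop.  Returns (flag, rejection reason)."""
    if len(cds) % 3 != 0:
        return False, "length not divisible by 3"
    if not cds.startswith("ATG"):
        return False, "no ATG start"
    if cds[-3:] not in _STOPS:
        return False, "no terminal stop"
    for i in range(3, len(cds) - 3, 3):
        if cds[i:i + 3] in _STOPS:
            return False, "internal stop"
    return True, None


def canonical_cds_filter(models: Sequence[GeneModel], assembly: GenomeAssembly,
                         ) -> tuple[list[GeneModel], list[tuple[GeneModel, str]]]:
    """Split models into canonical (ATG-STOP) and rejected-with-reason."""
    canonical, rejected = [], []
    for m in models:
        ok, reason = is_canonical_cds(m.spliced_cds(assembly))
        if ok:
            canonical.append(m)
        else:
            rejected.append((m, reason))
    return canonical, rejected


def annotation_stats(models: Sequence[GeneModel], assembly: GenomeAssembly,
                     ) -> AnnotationStats:
    n_genes = len(models)
    if n_genes == 0:
        return AnnotationStats(0, 0.0, 0, float("nan"), float("nan"),
                               float("nan"), float("nan"), float("nan"))
    exon_lens, intron_lens = [], []
    ilg = 0
    for m in models:
        exon_lens.extend(e - s for s, e in m.cds_exons)
        intron_lens.extend(e - s for s, e in m.introns)
        if m.n_exons == 1:
            ilg += 1
    canonical, _ = canonical_cds_filter(models, assembly)
    size_mb = assembly.total_length / 1e6
    return AnnotationStats(
        genes=n_genes,
        genes_per_mb=n_genes / size_mb,
        ilg_count=ilg,
        pct_ilg=100.0 * ilg / n_genes,
        introns_per_gene=len(intron_lens) / n_genes,
        mean_intron_len=float(np.mean(intron_lens)) if intron_lens else float("nan"),
        mean_exon_len=float(np.mean(exon_lens)),
        pct_canonical_cds=100.0 * len(canonical) / n_genes,
    )


#: column order of the combined statistics table (%repeat needs an external
#: repeat annotator and is emitted as NA)
TABLE_COLUMNS = [
    "genome", "size_mb", "scaffolds", "n50_kb", "l50", "pct_n", "pct_gc",
    "pct_repeat", "genes", "genes_per_mb", "pct_ilg", "introns_per_gene",
    "mean_intron_len", "mean_exon_len", "pct_canonical_cds",
]


def stats_table(entries: Sequence[tuple[str, GenomeAssembly, Sequence[GeneModel]]],
                ) -> pd.DataFrame:
    """One deterministic row per (name, assembly, models) triple."""
    rows = []
    for name, assembly, models in entries:
        a = assembly_stats(assembly)
        g = annotation_stats(models, assembly)
        rows.append({
            "genome": name,
            "size_mb": round(a.size / 1e6, 3),
            "scaffolds": a.n_scaffolds,
            "n50_kb": round(a.n50 / 1e3, 1),
            "l50": a.l50,
            "pct_n": round(a.pct_n, 3),
            "pct_gc": round(a.pct_gc, 2),
            "pct_repeat": "NA",
            "genes": g.genes,
            "genes_per_mb": round(g.genes_per_mb, 2),
            "pct_ilg": round(g.pct_ilg, 2),
            "introns_per_gene": round(g.introns_per_gene, 2),
            "mean_intron_len": round(g.mean_intron_len, 1),
            "mean_exon_len": round(g.mean_exon_len, 1),
            "pct_canonical_cds": round(g.pct_canonical_cds, 2),
        })
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def write_stats_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
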