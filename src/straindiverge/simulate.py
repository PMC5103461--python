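"""Seeded synthetic-data generators for every input the pipeline consumes.

The generators emulate the study regime of a small haploid fungal genome
project: a pair of strain genomes diverged under a Jukes–Cantor substitution
process, a multi-replicon genome (nuclear + high-copy organelle / plasmid /
tandem rDNA unit) sampled into error-bearing short reads, intron-rich gene
annotations, and all-vs-all protein hit tables with planted orthologs and
orphan genes.

Determinism: one root seed; every generator draws from a child stream keyed
by a fixed integer label, so sub-stage outputs are independent of call order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .formats import GenomeAssembly, GeneModel, HitRecord, ReadRecord, SequenceRecord
from . import seqarray as sa

# fixed child-stream labels (reproducibility independent of call order)
_LBL_ANCESTOR = 1
_LBL_EVOLVE = 2
_LBL_GENES = 3
_LBL_READS = 4
_LBL_HITS = 5

_STOPS = ("TAA", "TAG", "TGA")


def child_rng(seed: int, *labels: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), *[int(x) for x in labels]])


def jc_p_from_d(d: float) -> float:
    """Expected per-site difference fraction for a Jukes–Cantor distance d."""
    return 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))


def jc_d_from_p(p: float) -> float:
    """Jukes–Cantor distance for an observed difference fraction p."""
    if p >= 0.75:
        raise ValueError(f"difference fraction {p} is saturated (>= 0.75)")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class RepliconSpec:
    """One replicon of a multi-replicon genome (plan entry for read sampling)."""

    name: str
    length: int | None = None
    sequence: SequenceRecord | None = None
    copy_number: float = 1.0
    circular: bool = False

    def __post_init__(self) -> None:
        if self.length is None and self.sequence is None:
            raise ValueError(f"replicon {self.name}: need length or sequence")
        if self.sequence is not None:
            self.length = len(self.sequence)
        if self.copy_number < 1:
            raise ValueError(f"replicon {self.name}: copy_number must be >= 1")


@dataclass
class SimulationConfig:
    """All knobs of the synthetic-data generators.

    Defaults reproduce the sequenced-strain regime: GC 0.47, 115-nt reads,
    and an intron-rich gene architecture (7.5 introns/gene, 110-nt introns,
    199-nt exons).
    """

    seed: int = 0
    scaffold_lengths: Sequence[int] = (1_000_000,)
    gc: float = 0.47
    # divergence: exactly one of d (JC substitutions/site) or p (difference
    # fraction) must be set before calling evolve()
    divergence_d: float | None = None
    difference_p: float | None = None
    indel_rate: float = 0.0
    indel_mean_len: float = 3.0
    n_run_rate: float = 0.0
    n_run_mean_len: float = 50.0
    # reads
    read_length: int = 115
    base_coverage: float = 20.0
    read_error_rate: float = 0.01
    # gene plan
    n_genes: int = 200
    ipg_mean: float = 7.5
    intron_mean_len: float = 110.0
    intron_min_len: int = 20
    exon_mean_len: float = 199.0
    exon_min_len: int = 10
    noncanonical_fraction: float = 0.0
    intergenic_mean_len: float = 300.0

    def __post_init__(self) -> None:
        if not 0.0 < self.gc < 1.0:
            raise ValueError("gc must be in (0, 1)")
        if any(l <= 0 for l in self.scaffold_lengths):
            raise ValueError("scaffold lengths must be positive")
        if self.difference_p is not None and not 0.0 <= self.difference_p < 0.75:
            raise ValueError("difference fraction must be in [0, 0.75)")
        if self.divergence_d is not None and self.divergence_d < 0:
            raise ValueError("JC distance must be >= 0")
        if self.base_coverage <= 0:
            raise ValueError("base_coverage must be > 0")
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")

    def resolved_p(self) -> float:
        given = [x for x in (self.divergence_d, self.difference_p) if x is not None]
        if len(given) != 1:
            raise ValueError("set exactly one of divergence_d / difference_p")
        if self.difference_p is not None:
            return float(self.difference_p)
        return jc_p_from_d(float(self.divergence_d))


# ---------------------------------------------------------------------------
# ground truth containers
# ---------------------------------------------------------------------------

@dataclass
class ScaffoldTruth:
    """Truth for one scaffold of an evolved pair: the monotone ancestor->derived
    coordinate map (as aligned segments), planted substitution sites (ancestor
    coordinates) and planted N-run intervals."""

    anc_len: int
    der_len: int
    seg_anc: np.ndarray   # segment start, ancestor coords
    seg_der: np.ndarray   # segment start, derived coords
    seg_len: np.ndarray
    substitutions: np.ndarray          # ancestor coords, sorted
    n_runs: list[tuple[int, int]]      # ancestor coords, half-open

    @property
    def mapped_sites(self) -> int:
        """Aligned columns where both bases are callable (A/C/G/T)."""
        total = int(self.seg_len.sum())
        masked = sum(e - s for s, e in self.n_runs)
        return total - masked


@dataclass
class TruePairAlignment:
    """Ground truth emitted by :func:`evolve` for an ancestor/derived pair."""

    scaffolds: dict[str, ScaffoldTruth]

    @property
    def n_substitutions(self) -> int:
        return sum(len(t.substitutions) for t in self.scaffolds.values())

    @property
    def mapped_sites(self) -> int:
        return sum(t.mapped_sites for t in self.scaffolds.values())

    @property
    def planted_fraction(self) -> float:
        return self.n_substitutions / self.mapped_sites

    def count_mismatch_columns(self, ancestor: GenomeAssembly,
                               derived: GenomeAssembly) -> int:
        """Column-wise mismatch count of the truth-aligned pair (callable
        columns only); must equal ``n_substitutions`` exactly."""
        total = 0
        for name, t in self.scaffolds.items():
            a = sa.encode(ancestor[name].residues)
            d = sa.encode(derived[name].residues)
            for s_a, s_d, ln in zip(t.seg_anc, t.seg_der, t.seg_len):
                xa = a[s_a:s_a + ln]
                xd = d[s_d:s_d + ln]
                callable_ = (xa < 4) & (xd < 4)
                total += int(np.count_nonzero((xa != xd) & callable_))
        return total


# ---------------------------------------------------------------------------
# genome generation and evolution
# ---------------------------------------------------------------------------

def _random_codes(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    """i.i.d. base codes with P(G) + P(C) = gc."""
    at = (1.0 - gc) / 2.0
    cdf = np.array([at, at + gc / 2.0, at + gc, 1.0])
    return np.searchsorted(cdf, rng.random(n), side="right").astype(np.uint8)


def make_ancestor(config: SimulationConfig) -> GenomeAssembly:
    """Generate the ancestral (reference) genome from the configured plan."""
    rng = child_rng(config.seed, _LBL_ANCESTOR)
    records = []
    for i, length in enumerate(config.scaffold_lengths):
        if length <= 0:
            raise ValueError("zero-length scaffold in plan")
        codes = _random_codes(rng, int(length), config.gc)
        records.append(SequenceRecord(id=f"scaffold_{i + 1}", residues=sa.decode(codes)))
    return GenomeAssembly(records)


def evolve(genome: GenomeAssembly, config: SimulationConfig,
           ) -> tuple[GenomeAssembly, TruePairAlignment]:
    """Derive a diverged genome: independent per-site substitutions at the
    resolved difference fraction p (single hit per site), then indels, then
    N-runs; everything planted is recorded in the truth object."""
    p = config.resolved_p()
    if p >= 0.75:
        raise ValueError("difference fraction saturated (p >= 0.75)")
    rng = child_rng(config.seed, _LBL_EVOLVE)
    derived_records = []
    truths: dict[str, ScaffoldTruth] = {}
    for rec in genome:
        anc = sa.encode(rec.residues)
        L = len(anc)
        sub_pos = np.nonzero(rng.random(L) < p)[0] if p > 0 else np.empty(0, np.int64)
        mutated = anc.copy()
        if len(sub_pos):
            shift = rng.integers(1, 4, size=len(sub_pos)).astype(np.uint8)
            mutated[sub_pos] = (mutated[sub_pos] + shift) % 4

        # indels on the ancestor frame
        if config.indel_rate > 0:
            ev_pos = np.nonzero(rng.random(L) < config.indel_rate)[0]
        else:
            ev_pos = np.empty(0, np.int64)
        parts: list[np.ndarray] = []
        seg_anc, seg_der, seg_len = [], [], []
        cur, der_pos = 0, 0
        for pos in ev_pos:
            if pos < cur:
                continue  # swallowed by a previous deletion
            is_ins = rng.random() < 0.5
            ln = int(rng.geometric(1.0 / config.indel_mean_len))
            if pos > cur:
                parts.append(mutated[cur:pos])
                seg_anc.append(cur); seg_der.append(der_pos); seg_len.append(pos - cur)
                der_pos += pos - cur
            if is_ins:
                parts.append(_random_codes(rng, ln, config.gc))
                der_pos += ln
                cur = int(pos)
            else:
                cur = min(int(pos) + ln, L)
        if cur < L:
            parts.append(mutated[cur:])
            seg_anc.append(cur); seg_der.append(der_pos); seg_len.append(L - cur)
            der_pos += L - cur
        derived = np.concatenate(parts) if parts else np.empty(0, np.uint8)
        seg_anc = np.asarray(seg_anc, np.int64)
        seg_der = np.asarray(seg_der, np.int64)
        seg_len = np.asarray(seg_len, np.int64)

        # keep only substitutions that survived into an aligned column
        if len(sub_pos) and len(seg_anc):
            idx = np.searchsorted(seg_anc, sub_pos, side="right") - 1
            ok = (idx >= 0) & (sub_pos < seg_anc[idx] + seg_len[idx])
            sub_pos = sub_pos[ok]
        elif not len(seg_anc):
            sub_pos = np.empty(0, np.int64)

        # N-runs inside aligned segments (derived side), recorded in ancestor coords
        n_runs: list[tuple[int, int]] = []
        if config.n_run_rate > 0 and len(seg_anc):
            starts = np.nonzero(rng.random(L) < config.n_run_rate)[0]
            for s in starts:
                ln = int(rng.geometric(1.0 / config.n_run_mean_len))
                idx = int(np.searchsorted(seg_anc, s, side="right") - 1)
                if idx < 0:
                    continue
                seg_end = int(seg_anc[idx] + seg_len[idx])
                if s >= seg_end:
                    continue
                e = min(s + ln, seg_end)
                d0 = int(seg_der[idx] + (s - seg_anc[idx]))
                derived[d0:d0 + (e - s)] = sa.N
                n_runs.append((int(s), int(e)))
            if n_runs:
                n_runs = _merge_intervals(n_runs)
                keep = np.ones(len(sub_pos), bool)
                for s, e in n_runs:
                    keep &= ~((sub_pos >= s) & (sub_pos < e))
                sub_pos = sub_pos[keep]

        derived_records.append(
            SequenceRecord(id=rec.id, residues=sa.decode(derived))
        )
        truths[rec.id] = ScaffoldTruth(
            anc_len=L, der_len=len(derived),
            seg_anc=seg_anc, seg_der=seg_der, seg_len=seg_len,
            substitutions=np.sort(sub_pos), n_runs=n_runs,
        )
    return GenomeAssembly(derived_records), TruePairAlignment(truths)


def _merge_intervals(iv: list[tuple[int, int]]) -> list[tuple[int, int]]:
    iv = sorted(iv)
    out = [list(iv[0])]
    for s, e in iv[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [tuple(x) for x in out]


# ---------------------------------------------------------------------------
# gene planting
# ---------------------------------------------------------------------------

@dataclass
class PlantedGenes:
    assembly: GenomeAssembly
    models: list[GeneModel]
    cds: list[SequenceRecord]
    proteins: list[SequenceRecord]
    truth: pd.DataFrame  # gene_id, canonical, n_introns, exon/intron lengths


def _shifted_geometric(rng: np.random.Generator, mean: float, minimum: int,
                       size: int) -> np.ndarray:
    """Integer lengths >= minimum with the requested mean."""
    excess = max(mean - minimum, 0.0)
    if excess <= 0:
        return np.full(size, minimum, np.int64)
    return minimum + rng.geometric(1.0 / (excess + 1.0), size=size) - 1


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """Canonical CDS of n_codons codons: ATG, non-stop body, terminal stop."""
    stops = {48, 50, 56}  # TAA, TGA, TAG as 2-bit codon codes (T=3,A=0,G=2)
    body = rng.integers(0, 64, size=max(n_codons - 2, 0))
    for i in range(len(body)):
        while int(body[i]) in stops:
            body[i] = rng.integers(0, 64)
    codes = np.empty(3 * len(body), np.uint8)
    codes[0::3] = (body >> 4) & 3
    codes[1::3] = (body >> 2) & 3
    codes[2::3] = body & 3
    stop = _STOPS[int(rng.integers(0, 3))]
    return "ATG" + sa.decode(codes) + stop


def plant_genes(genome: GenomeAssembly, config: SimulationConfig) -> PlantedGenes:
    """Write intron-bearing genes into a copy of the genome.

    Genes are placed sequentially with geometric intergenic gaps, so they
    never overlap; running out of scaffold space raises.  A configurable
    fraction of genes is corrupted to be non-canonical (bad start, internal
    stop, or frame-breaking length).
    """
    rng = child_rng(config.seed, _LBL_GENES)
    scaffolds = {rec.id: sa.encode(rec.residues).copy() for rec in genome}
    order = list(scaffolds)
    models: list[GeneModel] = []
    cds_records, protein_records = [], []
    rows = []
    scaf_i, cursor = 0, 0
    for g in range(config.n_genes):
        n_introns = int(rng.poisson(config.ipg_mean))
        n_exons = n_introns + 1
        exon_lens = _shifted_geometric(rng, config.exon_mean_len,
                                       config.exon_min_len, n_exons)
        total = int(exon_lens.sum())
        pad = (-total) % 3
        exon_lens[-1] += pad
        total += pad
        if total < 6:
            exon_lens[-1] += 6 - total
            total = 6
        intron_lens = _shifted_geometric(rng, config.intron_mean_len,
                                         config.intron_min_len, n_introns)
        cds_seq = _random_cds(rng, total // 3)
        canonical = True
        if rng.random() < config.noncanonical_fraction:
            canonical = False
            mode = int(rng.integers(0, 3))
            if mode == 0:      # broken start
                cds_seq = "ATT" + cds_seq[3:]
            elif mode == 1:    # internal stop
                k = 3 * int(rng.integers(1, total // 3 - 1))
                cds_seq = cds_seq[:k] + _STOPS[int(rng.integers(0, 3))] + cds_seq[k + 3:]
            else:              # frame break
                cds_seq = cds_seq[:-1]
                exon_lens[-1] -= 1
                total -= 1

        # lay out exons and introns in transcription orientation
        region_parts, exon_iv, pos = [], [], 0
        offset = 0
        for i, el in enumerate(exon_lens):
            region_parts.append(cds_seq[offset:offset + int(el)])
            exon_iv.append((pos, pos + int(el)))
            pos += int(el)
            offset += int(el)
            if i < n_introns:
                il = int(intron_lens[i])
                region_parts.append(sa.decode(_random_codes(rng, il, config.gc)))
                pos += il
        region = "".join(region_parts)
        region_len = len(region)

        # place on a scaffold (advance through scaffolds as they fill up)
        gap = int(_shifted_geometric(rng, config.intergenic_mean_len, 20, 1)[0])
        placed = False
        while scaf_i < len(order):
            name = order[scaf_i]
            start = cursor + gap
            if start + region_len <= len(scaffolds[name]):
                placed = True
                break
            scaf_i += 1
            cursor = 0
        if not placed:
            raise ValueError(
                f"gene plan does not fit: placed {g} of {config.n_genes} genes"
            )
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            fwd_region = region
            fwd_iv = [(start + s, start + e) for s, e in exon_iv]
        else:
            fwd_region = sa.revcomp_str(region)
            fwd_iv = sorted(
                (start + region_len - e, start + region_len - s) for s, e in exon_iv
            )
        scaffolds[name][start:start + region_len] = sa.encode(fwd_region)
        cursor = start + region_len
        gene_id = f"g{g + 1:05d}"
        models.append(GeneModel(gene_id=gene_id, scaffold=name, strand=strand,
                                cds_exons=fwd_iv))
        cds_records.append(SequenceRecord(id=gene_id, residues=cds_seq))
        prot = str(Seq(cds_seq[: 3 * (len(cds_seq) // 3)]).translate()).rstrip("*")
        protein_records.append(ProteinRecord(gene_id, prot))
        rows.append(
            {"gene_id": gene_id, "canonical": canonical, "n_introns": n_introns,
             "cds_len": len(cds_seq),
             "mean_exon_len": float(np.mean(exon_lens)),
             "mean_intron_len": float(np.mean(intron_lens)) if n_introns else np.nan}
        )
    assembly = GenomeAssembly(
        [SequenceRecord(id=name, residues=sa.decode(codes))
         for name, codes in scaffolds.items()]
    )
    return PlantedGenes(assembly=assembly, models=models, cds=cds_records,
                        proteins=protein_records, truth=pd.DataFrame(rows))


@dataclass
class ProteinRecord:
    """Protein carrier (amino-acid alphabet; not a nucleotide SequenceRecord)."""
    id: str
    residues: str

    def __len__(self) -> int:
        return len(self.residues)


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

def simulate_reads(replicon_plan: Sequence[RepliconSpec], config: SimulationConfig,
                   ) -> tuple[list[ReadRecord], pd.DataFrame, dict[str, SequenceRecord]]:
    """Sample uniform reads from each replicon at depth base_coverage x copy_number.

    Returns the reads, a truth table (read_id, replicon, start, strand) and the
    replicon sequences (generated where the plan gives only a length).
    Circular replicons are sampled across the origin.
    """
    rl = config.read_length
    reads: list[ReadRecord] = []
    truth_rows = []
    sequences: dict[str, SequenceRecord] = {}
    const_quals = np.full(rl, 40, np.uint8)
    for ri, spec in enumerate(replicon_plan):
        rng = child_rng(config.seed, _LBL_READS, ri)
        if spec.sequence is not None:
            seq_codes = sa.encode(spec.sequence.residues)
            sequences[spec.name] = spec.sequence
        else:
            seq_codes = _random_codes(rng, spec.length, config.gc)
            sequences[spec.name] = SequenceRecord(id=spec.name,
                                                  residues=sa.decode(seq_codes))
        L = len(seq_codes)
        if rl > L:
            raise ValueError(f"read_length {rl} exceeds replicon {spec.name} ({L} bp)")
        n_reads = int(round(config.base_coverage * spec.copy_number * L / rl))
        if spec.circular:
            starts = rng.integers(0, L, size=n_reads)
        else:
            starts = rng.integers(0, L - rl + 1, size=n_reads)
        idx = (starts[:, None].astype(np.int64) + np.arange(rl)) % L
        mat = seq_codes[idx]
        if config.read_error_rate > 0:
            err = rng.random(mat.shape) < config.read_error_rate
            shift = rng.integers(1, 4, size=int(err.sum())).astype(np.uint8)
            flat = mat.reshape(-1)
            where = np.nonzero(err.reshape(-1))[0]
            flat[where] = (flat[where] + shift) % 4
        rev = rng.random(n_reads) < 0.5
        for i in range(n_reads):
            row = mat[i]
            if rev[i]:
                row = sa.revcomp(row)
            rid = f"{spec.name}_r{i}"
            reads.append(ReadRecord(id=rid, bases=sa.decode(row), quals=const_quals))
            truth_rows.append((rid, spec.name, int(starts[i]),
                               "-" if rev[i] else "+"))
    truth = pd.DataFrame(truth_rows, columns=["read_id", "replicon", "start", "strand"])
    return reads, truth, sequences


def depth_profile(truth: pd.DataFrame, replicon: RepliconSpec,
                  read_length: int) -> np.ndarray:
    """Per-position read depth of one replicon from the origin truth table."""
    L = replicon.length
    starts = truth.loc[truth["replicon"] == replicon.name, "start"].to_numpy()
    diff = np.zeros(L + 1, np.int64)
    np.add.at(diff, starts, 1)
    ends = starts + read_length
    np.add.at(diff, np.minimum(ends, L), -1)
    depth = np.cumsum(diff[:-1])
    if replicon.circular:
        wrapped = ends[ends > L] - L
        if len(wrapped):
            diff2 = np.zeros(L + 1, np.int64)
            np.add.at(diff2, np.zeros(len(wrapped), np.int64), 1)
            np.add.at(diff2, wrapped, -1)
            depth = depth + np.cumsum(diff2[:-1])
    return depth


def median_depths(truth: pd.DataFrame, plan: Sequence[RepliconSpec],
                  read_length: int) -> dict[str, float]:
    """Median per-position depth per replicon (the copy-number statistic)."""
    return {
        spec.name: float(np.median(depth_profile(truth, spec, read_length)))
        for spec in plan
    }


# ---------------------------------------------------------------------------
# hit tables with planted orthologs / orphans
# ---------------------------------------------------------------------------

@dataclass
class HitTables:
    """Synthetic all-vs-all protein search results plus evidence tables."""

    cross: dict[tuple[str, str], list[HitRecord]]   # directed species pairs
    relative_hits: list[HitRecord]                  # vs related species
    nr_hits: list[HitRecord]                        # vs a broad database
    expression: pd.DataFrame                        # gene_id, coverage
    domains: pd.DataFrame                           # gene_id, n_domains


def make_hit_tables(gene_sets: dict[str, Sequence[str]],
                    ortholog_map: Sequence[dict[str, str]],
                    planted_orphans: Iterable[str],
                    seed: int,
                    *,
                    orphan_expression: float = 0.8,
                    n_decoys_per_pair: int = 30,
                    orphan_domain_fraction: float = 188 / 286,
                    ) -> HitTables:
    """Build directed hit tables where planted ortholog groups are reciprocal
    best hits, decoys never beat them, planted orphans have no cross-database
    hits and carry the configured expression coverage."""
    rng = child_rng(seed, _LBL_HITS)
    species = sorted(gene_sets)
    id_sets = {s: set(gene_sets[s]) for s in species}
    orphans = set(planted_orphans)
    for grp in ortholog_map:
        for s, g in grp.items():
            if s not in id_sets or g not in id_sets[s]:
                raise ValueError(f"ortholog map references unknown gene {s}:{g}")

    def hit(q, s, ev, ln=None, ident=None):
        ln = int(ln if ln is not None else 200 + rng.integers(0, 300))
        ident = float(ident if ident is not None else 70 + 29 * rng.random())
        return HitRecord(query=q, subject=s, pct_identity=round(ident, 2),
                         aln_length=ln, evalue=float(ev),
                         bitscore=round(100 + 400 * rng.random(), 1))

    cross: dict[tuple[str, str], list[HitRecord]] = {
        (a, b): [] for a in species for b in species if a != b
    }
    ortho_members: dict[str, set[str]] = {s: set() for s in species}
    for grp in ortholog_map:
        present = sorted(grp)
        for a in present:
            ortho_members[a].add(grp[a])
        for a in present:
            for b in present:
                if a == b:
                    continue
                ev = 10.0 ** -(40 + 40 * rng.random())
                cross[(a, b)].append(hit(grp[a], grp[b], ev, ln=400 + rng.integers(0, 200)))
    # decoys: best decoy subject is always an ortholog member (whose reciprocal
    # best points at its partner), so decoys never create spurious RBH pairs
    for (a, b), rows in cross.items():
        pool_q = sorted(id_sets[a])
        pool_s = sorted(ortho_members[b]) or sorted(id_sets[b])
        for _ in range(n_decoys_per_pair):
            q = pool_q[int(rng.integers(0, len(pool_q)))]
            s = pool_s[int(rng.integers(0, len(pool_s)))]
            ev = 10.0 ** -(1 + 19 * rng.random())   # always worse than orthologs
            rows.append(hit(q, s, ev, ln=50 + rng.integers(0, 100)))

    # evidence tables are keyed on the first species' gene ids
    focal = species[0]
    focal_genes = sorted(id_sets[focal])
    relative_hits, nr_hits = [], []
    expr_rows, dom_rows = [], []
    for g in focal_genes:
        if g in orphans:
            expr_rows.append((g, orphan_expression))
            if rng.random() < 0.3:   # weak hits above the exclusion threshold
                nr_hits.append(hit(g, "db_weak", 10.0 ** -(1 + 3 * rng.random())))
            dom_rows.append((g, 1 if rng.random() < orphan_domain_fraction else 0))
        else:
            expr_rows.append((g, float(rng.random())))
            relative_hits.append(hit(g, "rel_sp", 10.0 ** -(10 + 40 * rng.random())))
            nr_hits.append(hit(g, "db_hit", 10.0 ** -(10 + 40 * rng.random())))
            dom_rows.append((g, int(rng.integers(0, 4))))
    return HitTables(
        cross=cross, relative_hits=relative_hits, nr_hits=nr_hits,
        expression=pd.DataFrame(expr_rows, columns=["gene_id", "coverage"]),
        domains=pd.DataFrame(dom_rows, columns=["gene_id", "n_domains"]),
    )
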