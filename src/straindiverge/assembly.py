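"""Targeted seed-and-extend assembly and copy-number estimation.

Re-implements the bespoke organelle/plasmid/rDNA recovery pipeline: recruit
reads against bait sequences (k-mer seeding, identity >= 0.95 over >= 40% of
the read), pick the seed read with maximal depth support, then iteratively
extend a consensus contig by stacking the overhanging bases of anchored
reads into columns and fixing each column only while its information content
IC = 2 - H (Shannon entropy in bits over {A,C,G,T}) exceeds ``ic_min`` and
its coverage reaches ``cov_min``.  Circularity is detected by a
suffix-to-prefix overlap test, and per-replicon copy number is the ratio of
median read depths.

Consensus stacking is ungapped (an aligned-column MSA view: gap columns
contribute nothing), so reads carrying indel errors simply fail the identity
gate.  ``cov_min`` defaults to 100, matching the extreme replicon depths of
the original study; desk-scale runs use lower values.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import edlib
import numpy as np

from .formats import GenomeAssembly, ReadRecord, SequenceRecord
from . import seqarray as sa

IC_MIN = 0.5
COV_MIN = 100
MIN_IDENTITY = 0.95
MIN_READ_COVERAGE = 0.40
SEED_K = 12
MIN_ANCHOR = 20
CIRC_MIN_OVERLAP = 100
CIRC_MIN_IDENTITY = 0.98


# ---------------------------------------------------------------------------
# information content
# ---------------------------------------------------------------------------

def column_ic(counts: Sequence[int] | dict[str, int]) -> tuple[float, float]:
    """Shannon entropy H and information content IC = 2 - H (bits) of a
    consensus column over {A,C,G,T}."""
    if isinstance(counts, dict):
        vec = [counts.get(b, 0) for b in "ACGT"]
    else:
        vec = list(counts)
    coverage = sum(vec)
    if coverage < 1:
        raise ValueError("column has zero coverage")
    if any(c < 0 for c in vec):
        raise ValueError("negative counts")
    h = 0.0
    for c in vec:
        if c > 0:
            p = c / coverage
            h -= p * math.log2(p)
    return h, 2.0 - h


@dataclass
class ConsensusColumn:
    counts: tuple[int, int, int, int]   # A, C, G, T
    coverage: int
    H: float
    IC: float
    fixed_base: str | None


def _make_column(vec: np.ndarray, ic_min: float, cov_min: int,
                 prev_base: int | None = None) -> ConsensusColumn:
    coverage = int(vec.sum())
    h, ic = column_ic(vec.tolist())
    fixed = None
    if ic > ic_min and coverage >= cov_min:
        top = int(vec.max())
        winners = [i for i in range(4) if vec[i] == top]
        if prev_base is not None and prev_base in winners:
            pick = prev_base       # tie resolved toward previous consensus
        else:
            pick = winners[0]      # fixed alphabet order A<C<G<T
        fixed = "ACGT"[pick]
    return ConsensusColumn(counts=tuple(int(x) for x in vec), coverage=coverage,
                           H=h, IC=ic, fixed_base=fixed)


# ---------------------------------------------------------------------------
# read pool / recruitment
# ---------------------------------------------------------------------------

@dataclass
class ReadAlignment:
    read_id: str
    start: int            # bait/contig coords, clipped to the target
    end: int
    orientation: str      # + / -
    identity: float
    read_coverage: float  # fraction of the read aligned
    target: str = ""      # bait id the alignment was found on


@dataclass
class ReadPool:
    """Recruited reads with their bait alignments and a k-mer placement index
    over both read orientations."""

    reads: list[ReadRecord]
    alignments: list[ReadAlignment]
    seed_k: int = SEED_K
    _codes: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)
    _index: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self._codes:
            self._codes = []
            index: dict[int, list[tuple[int, int, int]]] = defaultdict(list)
            for i, read in enumerate(self.reads):
                fwd = sa.encode(read.bases)
                rev = sa.revcomp(fwd)
                self._codes.append((fwd, rev))
                for orient, codes in ((0, fwd), (1, rev)):
                    km, pos = sa.kmer_codes(codes, self.seed_k)
                    for kv, kp in zip(km.tolist(), pos.tolist()):
                        index[kv].append((i, orient, kp))
            self._index = dict(index)

    def __len__(self) -> int:
        return len(self.reads)

    @classmethod
    def from_reads(cls, reads: Sequence[ReadRecord], seed_k: int = SEED_K,
                   ) -> "ReadPool":
        """Placement pool over a full read set (no bait alignments); the
        extension rounds re-align the whole set to the growing contig."""
        return cls(reads=list(reads), alignments=[], seed_k=seed_k)

    def codes(self, i: int, orient: int) -> np.ndarray:
        return self._codes[i][orient]

    def candidates(self, target_codes: np.ndarray, lo: int, hi: int,
                   ) -> dict[tuple[int, int], int]:
        """(read, orient) -> voted placement offset, from k-mers of
        target[lo:hi] (target coordinates)."""
        km, pos = sa.kmer_codes(target_codes[lo:hi], self.seed_k)
        votes: dict[tuple[int, int], Counter] = defaultdict(Counter)
        for kv, kp in zip(km.tolist(), pos.tolist()):
            for i, orient, rp in self._index.get(kv, ()):
                votes[(i, orient)][lo + kp - rp] += 1
        return {key: cnt.most_common(1)[0][0] for key, cnt in votes.items()}


def _overlap_identity(read_codes: np.ndarray, target_codes: np.ndarray,
                      offset: int, gap_tolerant: bool = False,
                      ) -> tuple[int, int, float]:
    """Identity of a diagonal placement of the read at ``offset`` on the
    target; returns (clip_start, clip_end, identity) in target coordinates."""
    rl = len(read_codes)
    lo = max(offset, 0)
    hi = min(offset + rl, len(target_codes))
    if hi <= lo:
        return lo, lo, 0.0
    rseg = read_codes[lo - offset: hi - offset]
    tseg = target_codes[lo:hi]
    if gap_tolerant:
        res = edlib.align(sa.decode(rseg), sa.decode(tseg), mode="NW")
        ident = 1.0 - res["editDistance"] / (hi - lo)
    else:
        valid = (rseg < 4) & (tseg < 4)
        matches = int(np.count_nonzero((rseg == tseg) & valid))
        ident = matches / (hi - lo)
    return lo, hi, ident


def bait_reads(reads: Sequence[ReadRecord], baits: GenomeAssembly,
               min_identity: float = MIN_IDENTITY,
               min_read_coverage: float = MIN_READ_COVERAGE,
               seed_k: int = SEED_K) -> ReadPool:
    """Recruit the reads having an alignment (either orientation) to some
    bait at identity >= ``min_identity`` over >= ``min_read_coverage`` of the
    read length, via k-mer seeding and gap-tolerant overlap verification."""
    if len(baits) == 0:
        raise ValueError("empty bait set")
    bait_index: dict[int, list[tuple[str, int]]] = defaultdict(list)
    bait_codes = {rec.id: sa.encode(rec.residues) for rec in baits}
    for bid, codes in bait_codes.items():
        km, pos = sa.kmer_codes(codes, seed_k)
        for kv, kp in zip(km.tolist(), pos.tolist()):
            bait_index[kv].append((bid, kp))
    kept_reads: list[ReadRecord] = []
    kept_alns: list[ReadAlignment] = []
    for read in reads:
        fwd = sa.encode(read.bases)
        best: ReadAlignment | None = None
        for orient, codes in (("+", fwd), ("-", sa.revcomp(fwd))):
            km, pos = sa.kmer_codes(codes, seed_k)
            votes: dict[tuple[str, int], int] = Counter()
            for kv, kp in zip(km.tolist(), pos.tolist()):
                for bid, bp in bait_index.get(kv, ()):
                    votes[(bid, bp - kp)] += 1
            for (bid, offset), _ in Counter(votes).most_common(3):
                lo, hi, ident = _overlap_identity(
                    codes, bait_codes[bid], offset, gap_tolerant=True)
                cov = (hi - lo) / len(read)
                if cov >= min_read_coverage and ident >= min_identity:
                    aln = ReadAlignment(read_id=read.id, start=lo, end=hi,
                                        orientation=orient, identity=ident,
                                        read_coverage=cov, target=bid)
                    if best is None or (aln.identity, aln.read_coverage) > \
                            (best.identity, best.read_coverage):
                        best = aln
        if best is not None:
            kept_reads.append(read)
            kept_alns.append(best)
    return ReadPool(reads=kept_reads, alignments=kept_alns, seed_k=seed_k)


def select_seed(pool: ReadPool, bait: SequenceRecord) -> ReadRecord:
    """The read whose bait-aligned footprint has maximal summed depth
    support; ties broken by longer alignment, then lexicographic read id."""
    if len(pool) == 0:
        raise ValueError("empty read pool")
    depth = np.zeros(len(bait) + 1, np.int64)
    for aln in pool.alignments:
        depth[aln.start] += 1
        depth[aln.end] -= 1
    depth = np.cumsum(depth[:-1])
    pref = np.concatenate([[0], np.cumsum(depth)])
    best_i, best_key = 0, None
    for i, aln in enumerate(pool.alignments):
        support = int(pref[aln.end] - pref[aln.start])
        key = (-support, -(aln.end - aln.start), pool.reads[i].id)
        if best_key is None or key < best_key:
            best_key, best_i = key, i
    return pool.reads[best_i]


# ---------------------------------------------------------------------------
# consensus extension
# ---------------------------------------------------------------------------

@dataclass
class Contig:
    consensus: str
    columns: list[ConsensusColumn]
    circular: bool
    rounds: int
    converged: bool = True

    def __len__(self) -> int:
        return len(self.consensus)


def extend_contig(seed: ReadRecord, pool: ReadPool, *,
                  ic_min: float = IC_MIN, cov_min: int = COV_MIN,
                  min_identity: float = MIN_IDENTITY,
                  min_anchor: int = MIN_ANCHOR,
                  max_rounds: int = 2000, max_length: int | None = None,
                  circ_min_overlap: int = CIRC_MIN_OVERLAP,
                  circ_min_identity: float = CIRC_MIN_IDENTITY) -> Contig:
    """Iterative consensus extension gated by per-column IC and coverage.

    Each round anchors pool reads in the already-fixed sequence near both
    contig ends (>= ``min_anchor`` aligned bases at >= ``min_identity``),
    stacks their overhanging bases into columns, and fixes the contiguous run
    of columns with IC > ``ic_min`` and coverage >= ``cov_min``; a side stops
    at its first non-qualifying column.  Extension terminates when neither
    end grows, on circularity, on ``max_length``, or (with a warning flag) on
    ``max_rounds``.
    """
    rl = max(len(r) for r in pool.reads) if len(pool) else len(seed)
    max_advance = rl - min_anchor
    contig = sa.encode(seed.bases).copy()
    columns: list[ConsensusColumn] = []
    for c in contig:
        if c < 4:
            vec = tuple(1 if i == c else 0 for i in range(4))
            columns.append(ConsensusColumn(counts=vec, coverage=1, H=0.0,
                                           IC=2.0, fixed_base="ACGT"[c]))
        else:
            columns.append(ConsensusColumn(counts=(0, 0, 0, 0), coverage=0,
                                           H=2.0, IC=0.0, fixed_base=None))
    # seed polishing: the contig is the MSA consensus from the start, so the
    # seed read's own sequencing errors are majority-voted away before the
    # identity-gated extension rounds begin (k-mer placement evidence only).
    counts0 = np.zeros((len(contig), 4), np.int64)
    for (i, orient), offset in pool.candidates(contig, 0, len(contig)).items():
        codes = pool.codes(i, orient)
        s, e, ident = _overlap_identity(codes, contig, offset)
        if e - s < min_anchor or ident < 0.5:
            continue
        seg = codes[s - offset: e - offset]
        ok = seg < 4
        np.add.at(counts0, (s + np.nonzero(ok)[0], seg[ok]), 1)
    for j in range(len(contig)):
        if counts0[j].sum() == 0:
            continue
        prev = int(contig[j]) if contig[j] < 4 else None
        col = _make_column(counts0[j], ic_min, cov_min, prev_base=prev)
        if col.fixed_base is not None:
            contig[j] = "ACGT".index(col.fixed_base)
            columns[j] = col
    circular = False
    rounds = 0
    converged = True
    while rounds < max_rounds:
        rounds += 1
        grew = False
        for side in ("right", "left"):
            n = len(contig)
            if side == "right":
                lo, hi = max(0, n - rl), n
            else:
                lo, hi = 0, min(rl, n)
            counts = np.zeros((max_advance, 4), np.int64)
            for (i, orient), offset in pool.candidates(contig, lo, hi).items():
                codes = pool.codes(i, orient)
                s, e, ident = _overlap_identity(codes, contig, offset)
                if e - s < min_anchor or ident < min_identity:
                    continue
                if side == "right" and offset + len(codes) > n:
                    over = codes[n - offset: n - offset + max_advance]
                    ok = over < 4
                    np.add.at(counts, (np.nonzero(ok)[0], over[ok]), 1)
                elif side == "left" and offset < 0:
                    over = codes[max(0, -offset - max_advance): -offset]
                    # right-align against the contig start
                    shift = max_advance - len(over)
                    ok = over < 4
                    np.add.at(counts, (shift + np.nonzero(ok)[0], over[ok]), 1)
            new_cols: list[ConsensusColumn] = []
            if side == "right":
                for j in range(max_advance):
                    if counts[j].sum() == 0:
                        break
                    col = _make_column(counts[j], ic_min, cov_min)
                    if col.fixed_base is None:
                        break
                    new_cols.append(col)
                if new_cols:
                    contig = np.concatenate(
                        [contig, sa.encode("".join(c.fixed_base for c in new_cols))])
                    columns.extend(new_cols)
                    grew = True
            else:
                for j in range(max_advance - 1, -1, -1):
                    if counts[j].sum() == 0:
                        break
                    col = _make_column(counts[j], ic_min, cov_min)
                    if col.fixed_base is None:
                        break
                    new_cols.append(col)   # collected outward; reverse below
                if new_cols:
                    new_cols.reverse()
                    contig = np.concatenate(
                        [sa.encode("".join(c.fixed_base for c in new_cols)), contig])
                    columns = new_cols + columns
                    grew = True
        seq = sa.decode(contig)
        circ = _closure_test(seq, circ_min_overlap, circ_min_identity)
        if circ is not None:
            trim_at, rot = circ
            circular = True
            contig = sa.encode(seq[:trim_at])
            contig = np.concatenate([contig[rot:], contig[:rot]])
            columns = columns[:trim_at]
            columns = columns[rot:] + columns[:rot]
            break
        if max_length is not None and len(contig) >= max_length:
            break
        if not grew:
            break
    else:
        converged = False
    seq = sa.decode(contig)
    return Contig(consensus=seq, columns=columns, circular=circular,
                  rounds=rounds, converged=converged)


# ---------------------------------------------------------------------------
# circularity
# ---------------------------------------------------------------------------

def _min_rotation_index(s: str) -> int:
    """Booth's algorithm: start index of the lexicographically minimal rotation."""
    ss = s + s
    f = [-1] * len(ss)
    k = 0
    for j in range(1, len(ss)):
        sj = ss[j]
        i = f[j - k - 1]
        while i != -1 and sj != ss[k + i + 1]:
            if sj < ss[k + i + 1]:
                k = j - i - 1
            i = f[i]
        if sj != ss[k + i + 1]:
            if sj < ss[k]:
                k = j
            f[j - k] = -1
        else:
            f[j - k] = i + 1
    return k


def _closure_test(seq: str, min_overlap: int, min_identity: float,
                  ) -> tuple[int, int] | None:
    """Find a suffix-to-prefix overlap; returns (trim_length, rotation_index)
    of the closed circle, or None."""
    n = len(seq)
    k = min(16, min_overlap)
    candidates = set()
    for probe_at in (0, min_overlap // 2):
        probe = seq[probe_at:probe_at + k]
        if len(probe) < k:
            continue
        start = probe_at + 1
        while True:
            p = seq.find(probe, start)
            if p == -1:
                break
            candidates.add(p - probe_at)
            start = p + 1
    for p in sorted(candidates):
        overlap = n - p
        if overlap < min_overlap or overlap >= n or p <= 0:
            continue
        suffix, prefix = seq[p:], seq[:overlap]
        dist = edlib.align(suffix, prefix, mode="NW")["editDistance"]
        if 1.0 - dist / overlap >= min_identity:
            return p, _min_rotation_index(seq[:p])
    return None


def detect_circular(contig: str | Contig, min_overlap: int = CIRC_MIN_OVERLAP,
                    min_identity: float = CIRC_MIN_IDENTITY,
                    ) -> tuple[bool, str | None]:
    """Closure test: a suffix of length >= ``min_overlap`` aligning to the
    contig prefix at >= ``min_identity`` marks the contig circular; the
    returned sequence (overlap trimmed) starts at its lexicographically
    minimal rotation."""
    seq = contig.consensus if isinstance(contig, Contig) else contig
    res = _closure_test(seq, min_overlap, min_identity)
    if res is None:
        return False, None
    p, rot = res
    circ = seq[:p]
    return True, circ[rot:] + circ[:rot]


def canonical_circular_form(seq: str) -> str:
    """Strand- and rotation-invariant representative of a circular sequence:
    the lexicographically smaller of the minimal rotations of the sequence
    and its reverse complement."""
    i = _min_rotation_index(seq)
    fwd = seq[i:] + seq[:i]
    rc = sa.revcomp_str(seq)
    j = _min_rotation_index(rc)
    rev = rc[j:] + rc[:j]
    return min(fwd, rev)


# ---------------------------------------------------------------------------
# copy number
# ---------------------------------------------------------------------------

@dataclass
class CopyNumberEstimate:
    ratio: float
    nearest: int


def estimate_copy_number(target_depth: float, nuclear_depth: float,
                         ) -> CopyNumberEstimate:
    """Copy number as the ratio of median per-position read depths."""
    if nuclear_depth <= 0:
        raise ValueError("nuclear depth must be positive")
    if target_depth <= 0:
        raise ValueError("target depth must be positive")
    ratio = target_depth / nuclear_depth
    return CopyNumberEstimate(ratio=ratio, nearest=int(round(ratio)))
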