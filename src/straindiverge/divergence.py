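"""Sliding-window genome divergence with flank smoothing.

The statistic: project pairwise alignments onto a reference, classify every
reference position as match / mismatch / uncalled per query (uncalled covers
unaligned, gap, N/ambiguity and multiply-covered positions), cut the track
into 1-kb windows, discard windows with fewer than 500 unambiguously called
positions, smooth each retained window with up to five retained flanking
windows per side, and report pooled per-scaffold and genome-wide rates.

Alignments come either from the built-in minimal anchor aligner (unique
shared k-mers chained by longest increasing subsequence, inter-anchor gaps
closed by global edit-distance alignment) or from an imported MAF file.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import edlib
import numpy as np
import pandas as pd
from numba import njit

from .formats import AlignmentBlock, GenomeAssembly, SequenceRecord
from . import seqarray as sa

WINDOW = 1000
STEP = 1000
MIN_CALLED = 500
FLANK = 5

_UNCALLED, _MATCH, _MISMATCH = 0, 1, 2

# ASCII -> callable flag (A/C/G/T only)
_CALLABLE = np.zeros(256, bool)
for _b in b"ACGT":
    _CALLABLE[_b] = True


# ---------------------------------------------------------------------------
# minimal anchor aligner
# ---------------------------------------------------------------------------

@njit(cache=True)
def _lis(q):
    """Indices of a longest strictly increasing subsequence of q."""
    n = q.shape[0]
    tails = np.empty(n, np.int64)
    tails_idx = np.empty(n, np.int64)
    parent = np.full(n, -1, np.int64)
    size = 0
    for i in range(n):
        x = q[i]
        lo, hi = 0, size
        while lo < hi:
            mid = (lo + hi) // 2
            if tails[mid] < x:
                lo = mid + 1
            else:
                hi = mid
        tails[lo] = x
        tails_idx[lo] = i
        parent[i] = tails_idx[lo - 1] if lo > 0 else -1
        if lo == size:
            size += 1
    out = np.empty(size, np.int64)
    k = tails_idx[size - 1] if size > 0 else -1
    for j in range(size - 1, -1, -1):
        out[j] = k
        k = parent[k]
    return out


def _shared_unique_kmers(rc: np.ndarray, qc: np.ndarray, k: int,
                         ) -> tuple[np.ndarray, np.ndarray]:
    """(ref_pos, query_pos) of k-mers occurring exactly once in each sequence."""
    rk, rp = sa.kmer_codes(rc, k)
    qk, qp = sa.kmer_codes(qc, k)
    rv, ri, rcnt = np.unique(rk, return_index=True, return_counts=True)
    qv, qi, qcnt = np.unique(qk, return_index=True, return_counts=True)
    rv, ri = rv[rcnt == 1], ri[rcnt == 1]
    qv, qi = qv[qcnt == 1], qi[qcnt == 1]
    shared, ra, qa = np.intersect1d(rv, qv, assume_unique=True,
                                    return_indices=True)
    rpos = rp[ri[ra]]
    qpos = qp[qi[qa]]
    order = np.argsort(rpos, kind="stable")
    return rpos[order], qpos[order]


def _gap_align(rseg: str, qseg: str) -> tuple[str, str]:
    """Close an inter-anchor gap with a global edit-distance alignment."""
    if not rseg:
        return "-" * len(qseg), qseg
    if not qseg:
        return rseg, "-" * len(rseg)
    res = edlib.align(qseg, rseg, mode="NW", task="path")
    rout, qout = [], []
    ri = qi = 0
    num = ""
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        if ch in "=X":
            rout.append(rseg[ri:ri + n]); qout.append(qseg[qi:qi + n])
            ri += n; qi += n
        elif ch == "I":      # present in query only
            rout.append("-" * n); qout.append(qseg[qi:qi + n])
            qi += n
        elif ch == "D":      # present in reference only
            rout.append(rseg[ri:ri + n]); qout.append("-" * n)
            ri += n
    return "".join(rout), "".join(qout)


def anchor_align(ref: SequenceRecord, query: SequenceRecord,
                 k: int = 16, max_gap: int = 2000) -> list[AlignmentBlock]:
    """Collinear pairwise alignment by unique-k-mer anchor chaining.

    Intended for closely related, largely collinear sequences (up to roughly
    15% divergence); returns an empty list when no anchors are found.
    """
    rc = sa.encode(ref.residues)
    qc = sa.encode(query.residues)
    rpos, qpos = _shared_unique_kmers(rc, qc, k)
    if len(rpos) == 0:
        return []
    chain = _lis(qpos)
    ar, aq = rpos[chain], qpos[chain]
    rseq, qseq = ref.residues, query.residues
    nr, nq = len(rseq), len(qseq)

    blocks: list[AlignmentBlock] = []
    pieces_r: list[str] = []
    pieces_q: list[str] = []
    # open first block, extended head-wards along the first anchor's diagonal
    head = min(int(ar[0]), int(aq[0]))
    r0, q0 = int(ar[0]) - head, int(aq[0]) - head
    fr, fq = r0, q0            # flushed-up-to coordinates
    pr, pq = int(ar[0]), int(aq[0])

    def flush_direct(to_r: int, to_q: int) -> None:
        nonlocal fr, fq
        assert to_r - fr == to_q - fq
        if to_r > fr:
            pieces_r.append(rseq[fr:to_r])
            pieces_q.append(qseq[fq:to_q])
            fr, fq = to_r, to_q

    def close_block() -> None:
        nonlocal pieces_r, pieces_q, r0, q0
        rt, qt = "".join(pieces_r), "".join(pieces_q)
        if rt:
            blocks.append(AlignmentBlock(
                ref_id=ref.id, ref_start=r0, query_id=query.id,
                query_start=q0, strand="+", ref_text=rt, query_text=qt,
            ))
        pieces_r, pieces_q = [], []

    for r_, q_ in zip(ar[1:], aq[1:]):
        r, q = int(r_), int(q_)
        if r - pr == q - pq:          # same diagonal: keep running
            pr, pq = r, q
            continue
        gr, gq = r - (pr + k), q - (pq + k)
        if gr < 0 or gq < 0:          # geometric conflict with previous anchor
            continue
        flush_direct(pr + k, pq + k)
        if max(gr, gq) <= max_gap:
            rg, qg = _gap_align(rseq[fr:r], qseq[fq:q])
            pieces_r.append(rg); pieces_q.append(qg)
            fr, fq = r, q
        else:
            close_block()
            r0, q0 = r, q
            fr, fq = r, q
        pr, pq = r, q
    tail = min(nr - (pr + k), nq - (pq + k))
    flush_direct(pr + k + tail, pq + k + tail)
    close_block()
    return blocks


# ---------------------------------------------------------------------------
# call track
# ---------------------------------------------------------------------------

class CallTrack:
    """Per-reference-position call states (match/mismatch/uncalled), one
    track per query.  Positions covered by more than one alignment column are
    uncalled (ambiguity rule); so are gap and N/ambiguity columns."""

    def __init__(self, ref: GenomeAssembly, queries: Sequence[str]):
        self.ref_lengths = {rec.id: len(rec) for rec in ref}
        self.queries = list(queries)
        self.states: dict[str, dict[str, np.ndarray]] = {
            q: {s: np.zeros(n, np.uint8) for s, n in self.ref_lengths.items()}
            for q in queries
        }
        self.n_overlap_uncalled = 0

    def called_mask(self, scaffold: str, query: str | None = None,
                    joint: bool = True) -> np.ndarray:
        """Calledness on one scaffold; with two queries and ``joint`` a
        position counts only if called for both queries."""
        if joint and len(self.queries) > 1:
            use = self.queries
        else:
            use = [query if query is not None else self.queries[0]]
        mask = np.ones(self.ref_lengths[scaffold], bool)
        for q in use:
            mask &= self.states[q][scaffold] != _UNCALLED
        return mask

    def mismatch_mask(self, scaffold: str, query: str) -> np.ndarray:
        return self.states[query][scaffold] == _MISMATCH


def build_call_track(blocks_by_query: dict[str, Iterable[AlignmentBlock]],
                     ref: GenomeAssembly) -> CallTrack:
    """Project alignment blocks onto the reference.

    A reference position is match/mismatch for a query iff it is covered by
    exactly one block column whose both residues are A/C/G/T; otherwise it is
    uncalled.
    """
    track = CallTrack(ref, list(blocks_by_query))
    for qname, blocks in blocks_by_query.items():
        cover = {s: np.zeros(n, np.int32) for s, n in track.ref_lengths.items()}
        for b in blocks:
            if b.ref_id not in track.ref_lengths:
                raise ValueError(f"block references unknown scaffold {b.ref_id!r}")
            rg = np.frombuffer(b.ref_text.encode(), np.uint8)
            qg = np.frombuffer(b.query_text.encode(), np.uint8)
            refcol = rg != ord("-")
            pos = b.ref_start + np.cumsum(refcol) - 1
            pos = pos[refcol]
            if len(pos) and pos[-1] >= track.ref_lengths[b.ref_id]:
                raise ValueError(f"block on {b.ref_id} exceeds scaffold bounds")
            rb, qb = rg[refcol], qg[refcol]
            ok = _CALLABLE[rb] & _CALLABLE[qb]
            st = track.states[qname][b.ref_id]
            st[pos[ok]] = np.where(rb[ok] == qb[ok], _MATCH, _MISMATCH)
            np.add.at(cover[b.ref_id], pos, 1)
        for s, cov in cover.items():
            multi = cov > 1
            n_multi = int(multi.sum())
            if n_multi:
                track.states[qname][s][multi] = _UNCALLED
                track.n_overlap_uncalled += n_multi
    return track


# ---------------------------------------------------------------------------
# windows, smoothing, summary
# ---------------------------------------------------------------------------

@dataclass
class WindowStat:
    scaffold: str
    start: int
    called: int
    mismatches: int
    value: float          # mismatches / called (nan when called == 0)
    retained: bool


@dataclass
class SmoothedPoint:
    scaffold: str
    start: int
    value: float


def window_stats(track: CallTrack, query: str | None = None,
                 window: int = WINDOW, step: int = STEP,
                 min_called: int = MIN_CALLED, joint: bool = True,
                 ) -> list[WindowStat]:
    """Per-window called/mismatch counts and divergence for one query.

    With two queries in the track and ``joint=True`` (the two-queries-vs-one-
    reference design), a position contributes only if called for *both*
    queries; the trailing partial window is kept under the same retention
    rule.
    """
    if window <= 0 or step <= 0:
        raise ValueError("window and step must be positive")
    if query is None:
        query = track.queries[0]
    stats: list[WindowStat] = []
    for scaffold, n in track.ref_lengths.items():
        called = track.called_mask(scaffold, query=query,
                                   joint=joint and len(track.queries) > 1)
        mism = track.mismatch_mask(scaffold, query) & called
        pc = np.concatenate([[0], np.cumsum(called)])
        pm = np.concatenate([[0], np.cumsum(mism)])
        for start in range(0, n, step):
            end = min(start + window, n)
            c = int(pc[end] - pc[start])
            m = int(pm[end] - pm[start])
            stats.append(WindowStat(
                scaffold=scaffold, start=start, called=c, mismatches=m,
                value=(m / c) if c else float("nan"),
                retained=c >= min_called,
            ))
    return stats


def smooth(stats: Sequence[WindowStat], flank: int = FLANK) -> list[SmoothedPoint]:
    """Flank smoothing: each retained window's value averaged with up to
    ``flank`` retained windows on each side of the same scaffold, skipping
    discarded windows; discarded windows yield no point."""
    points: list[SmoothedPoint] = []
    by_scaffold: dict[str, list[WindowStat]] = {}
    for w in stats:
        if w.retained:
            by_scaffold.setdefault(w.scaffold, []).append(w)
    for scaffold, ws in by_scaffold.items():
        vals = np.array([w.value for w in ws])
        for i, w in enumerate(ws):
            lo, hi = max(0, i - flank), min(len(ws), i + flank + 1)
            points.append(SmoothedPoint(scaffold=scaffold, start=w.start,
                                        value=float(vals[lo:hi].mean())))
    return points


def summarize(stats: Sequence[WindowStat]) -> dict:
    """Pooled (micro-averaged) per-scaffold and genome-wide divergence over
    retained windows; scaffolds with no retained window are flagged
    undefined, never reported as 0."""
    per_scaffold: dict[str, dict] = {}
    tot_c = tot_m = 0
    scaffolds = []
    for w in stats:
        if w.scaffold not in per_scaffold:
            per_scaffold[w.scaffold] = {"called": 0, "mismatches": 0,
                                        "retained_windows": 0}
            scaffolds.append(w.scaffold)
        if w.retained:
            d = per_scaffold[w.scaffold]
            d["called"] += w.called
            d["mismatches"] += w.mismatches
            d["retained_windows"] += 1
            tot_c += w.called
            tot_m += w.mismatches
    for s in scaffolds:
        d = per_scaffold[s]
        d["divergence"] = (d["mismatches"] / d["called"]) if d["called"] else None
    return {
        "per_scaffold": per_scaffold,
        "genome": {
            "called": tot_c,
            "mismatches": tot_m,
            "divergence": (tot_m / tot_c) if tot_c else None,
        },
    }


def windows_to_frame(stats: Sequence[WindowStat]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "scaffold": [w.scaffold for w in stats],
            "start": [w.start for w in stats],
            "called": [w.called for w in stats],
            "mismatches": [w.mismatches for w in stats],
            "value": [w.value for w in stats],
            "retained": [w.retained for w in stats],
        }
    )


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------

def align_assemblies(ref: GenomeAssembly, query: GenomeAssembly,
                     k: int = 16, max_gap: int = 2000) -> list[AlignmentBlock]:
    """Align a query assembly to a reference scaffold-by-scaffold.

    Ref scaffolds are matched to the same-named query scaffold when present,
    otherwise aligned against every query scaffold (the multiply-covered rule
    in the call track resolves any resulting ambiguity).
    """
    blocks: list[AlignmentBlock] = []
    for rrec in ref:
        if rrec.id in query:
            blocks.extend(anchor_align(rrec, query[rrec.id], k=k, max_gap=max_gap))
        else:
            for qrec in query:
                blocks.extend(anchor_align(rrec, qrec, k=k, max_gap=max_gap))
    return blocks


def divergence_pipeline(ref: GenomeAssembly,
                        queries: dict[str, GenomeAssembly],
                        *, maf_blocks: dict[str, list[AlignmentBlock]] | None = None,
                        window: int = WINDOW, step: int = STEP,
                        min_called: int = MIN_CALLED, flank: int = FLANK,
                        joint: bool = True, k: int = 16, max_gap: int = 2000,
                        ) -> dict:
    """Full sliding-window divergence analysis for 1 or 2 queries.

    Returns per-query window tables, smoothed tracks and pooled summaries.
    ``maf_blocks`` bypasses the built-in aligner for any query it names.
    """
    maf_blocks = maf_blocks or {}
    blocks_by_query = {
        name: maf_blocks.get(name) if name in maf_blocks
        else align_assemblies(ref, asm, k=k, max_gap=max_gap)
        for name, asm in queries.items()
    }
    track = build_call_track(blocks_by_query, ref)
    result: dict = {"queries": {}}
    for name in queries:
        stats = window_stats(track, query=name, window=window, step=step,
                             min_called=min_called, joint=joint)
        result["queries"][name] = {
            "windows": stats,
            "smoothed": smooth(stats, flank=flank),
            "summary": summarize(stats),
        }
    return result
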