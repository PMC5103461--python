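"""Alignment-free Kr distance from shustrings (shortest unique substrings).

For a position i of sequence X, the shulen l_i is the length of the shortest
substring of X starting at i that is absent from sequence Y (and, by default,
from Y's reverse complement).  Mean shulen shrinks as the pair diverges, so a
per-site difference probability can be read off a calibration curve of
expected mean shulen versus p at matched length and GC, and converted to
substitutions per site with the Jukes-Cantor correction
``kr = -(3/4) ln(1 - (4/3) pi)``.

The shulen core is exact: matching statistics are computed with a suffix
automaton built over the reversed index (longest match *starting* at i in
forward coordinates equals the longest match *ending* at the mirrored
position of the reversed pair), and is verified against brute-force
enumeration in the test suite.  Kr values above 0.3 are flagged unreliable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numba import njit
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq

from .formats import GenomeAssembly, SequenceRecord
from .simulate import SimulationConfig, evolve, jc_d_from_p, make_ancestor, child_rng
from . import seqarray as sa

#: Kr reliability cap (substitutions/site)
KR_RELIABLE_MAX = 0.3
#: minimum expected mismatch count before the estimate is flagged low-confidence
MIN_EXPECTED_MISMATCHES = 100.0

_LBL_CALIBRATION = 6

DEFAULT_P_GRID = (
    2e-4, 5e-4, 1e-3, 2e-3, 5e-3, 1e-2, 2e-2,
    4e-2, 7e-2, 0.11, 0.16, 0.25, 0.35, 0.45,
)


class CalibrationRangeError(ValueError):
    """Observed mean shulen falls outside the calibration grid; widen the grid."""


# ---------------------------------------------------------------------------
# suffix automaton (alphabet {0..4}; code 4 = uncallable, matches nothing)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _sam_build(seq):
    n = seq.shape[0]
    max_states = 2 * n + 5
    nxt = np.full((max_states, 5), -1, np.int32)
    link = np.full(max_states, -1, np.int32)
    length = np.zeros(max_states, np.int32)
    size = 1
    last = 0
    for i in range(n):
        c = seq[i]
        cur = size
        size += 1
        length[cur] = length[last] + 1
        p = last
        while p != -1 and nxt[p, c] == -1:
            nxt[p, c] = cur
            p = link[p]
        if p == -1:
            link[cur] = 0
        else:
            q = nxt[p, c]
            if length[p] + 1 == length[q]:
                link[cur] = q
            else:
                clone = size
                size += 1
                length[clone] = length[p] + 1
                link[clone] = link[q]
                for a in range(5):
                    nxt[clone, a] = nxt[q, a]
                while p != -1 and nxt[p, c] == q:
                    nxt[p, c] = clone
                    p = link[p]
                link[q] = clone
                link[cur] = clone
        last = cur
    return nxt[:size], link[:size], length[:size]


@njit(cache=True)
def _match_stats(x, nxt, link, length):
    """length of the longest substring of the indexed text ending at each
    position of x; code 4 in x matches nothing and resets the walk."""
    n = x.shape[0]
    ms = np.zeros(n, np.int32)
    v = 0
    l = 0
    for i in range(n):
        c = x[i]
        if c >= 4:
            v = 0
            l = 0
        else:
            while v != 0 and nxt[v, c] == -1:
                v = link[v]
                l = length[v]
            if nxt[v, c] != -1:
                v = nxt[v, c]
                l += 1
            else:
                l = 0
        ms[i] = l
    return ms


def _concat_codes(assembly: GenomeAssembly | SequenceRecord | str) -> list[np.ndarray]:
    if isinstance(assembly, str):
        return [sa.encode(assembly)]
    if isinstance(assembly, SequenceRecord):
        return [sa.encode(assembly.residues)]
    return [sa.encode(rec.residues) for rec in assembly]


def _index_automaton(y_parts: list[np.ndarray], include_revcomp: bool):
    """Automaton over the *reversed* index text: scaffolds of Y (and its
    reverse complement) joined by separator code 4 (matches nothing)."""
    sep = np.array([sa.N], np.uint8)
    pieces: list[np.ndarray] = []
    for part in y_parts:
        pieces.append(part)
        pieces.append(sep)
    if include_revcomp:
        for part in y_parts:
            pieces.append(sa.revcomp(part))
            pieces.append(sep)
    text = np.concatenate(pieces)[:-1][::-1].copy()
    return _sam_build(text)


# ---------------------------------------------------------------------------
# shulen profiles
# ---------------------------------------------------------------------------

@dataclass
class ShulenProfile:
    """Per-position shulen of X against Y, one array per X scaffold.

    Sentinel positions (every prefix up to the scaffold end occurs in Y) carry
    ``remaining_length + 1`` and are excluded from the mean.
    """

    direction: str
    shulens: list[np.ndarray]
    sentinel_mask: list[np.ndarray]

    @property
    def n_positions(self) -> int:
        return sum(len(a) for a in self.shulens)

    @property
    def n_sentinel(self) -> int:
        return sum(int(m.sum()) for m in self.sentinel_mask)

    def mean(self) -> float:
        """Mean shulen over non-sentinel positions (nan if all sentinel)."""
        total, count = 0.0, 0
        for arr, mask in zip(self.shulens, self.sentinel_mask):
            keep = ~mask
            total += float(arr[keep].sum())
            count += int(keep.sum())
        return total / count if count else float("nan")


def shulen_profile(X, Y, include_revcomp: bool = True,
                   direction: str = "X_vs_Y") -> ShulenProfile:
    """Exact per-position shortest-absent-substring lengths of X against Y."""
    x_parts = _concat_codes(X)
    y_parts = _concat_codes(Y)
    if not x_parts or any(len(p) == 0 for p in x_parts):
        raise ValueError("empty X sequence")
    if not y_parts or any(len(p) == 0 for p in y_parts):
        raise ValueError("empty Y sequence")
    nxt, link, length = _index_automaton(y_parts, include_revcomp)
    shulens, masks = [], []
    for part in x_parts:
        ms_rev = _match_stats(part[::-1].copy(), nxt, link, length)
        ms_start = ms_rev[::-1].astype(np.int64)  # longest match starting at i
        n = len(part)
        remaining = n - np.arange(n)
        sentinel = ms_start >= remaining
        sl = np.where(sentinel, remaining + 1, ms_start + 1)
        shulens.append(sl)
        masks.append(sentinel)
    return ShulenProfile(direction=direction, shulens=shulens, sentinel_mask=masks)


# ---------------------------------------------------------------------------
# calibration and estimation
# ---------------------------------------------------------------------------

@dataclass
class ShulenCalibration:
    """Monotone curve of expected mean shulen vs difference probability p,
    simulated at matched length and GC."""

    length: int
    gc: float
    include_revcomp: bool
    p_grid: np.ndarray
    mean_shulen: np.ndarray

    def invert(self, observed_mean: float) -> float:
        """Difference probability whose expected mean shulen matches the
        observation (monotone interpolation on log p)."""
        lo, hi = float(self.mean_shulen.min()), float(self.mean_shulen.max())
        if not lo <= observed_mean <= hi:
            raise CalibrationRangeError(
                f"observed mean shulen {observed_mean:.3f} outside calibrated "
                f"range [{lo:.3f}, {hi:.3f}]; widen the p grid"
            )
        logp = np.log(self.p_grid)
        interp = PchipInterpolator(logp, self.mean_shulen)
        f = lambda lp: float(interp(lp)) - observed_mean
        a, b = logp[0], logp[-1]
        if f(a) * f(b) > 0:  # observation at a grid endpoint
            return float(self.p_grid[int(np.argmin(np.abs(self.mean_shulen - observed_mean)))])
        return float(math.exp(brentq(f, a, b, xtol=1e-12)))


def calibrate_shulen(length: int, gc: float, seed: int,
                     p_grid: Sequence[float] = DEFAULT_P_GRID,
                     include_revcomp: bool = True) -> ShulenCalibration:
    """Monte-Carlo calibration: simulate one substitution-only pair per grid
    point and record its mean shulen."""
    p_grid = np.asarray(sorted(p_grid), float)
    means = np.empty(len(p_grid))
    for i, p in enumerate(p_grid):
        cfg = SimulationConfig(
            seed=int(child_rng(seed, _LBL_CALIBRATION, i).integers(2**31)),
            scaffold_lengths=(int(length),), gc=gc, difference_p=float(p),
        )
        anc = make_ancestor(cfg)
        der, _ = evolve(anc, cfg)
        means[i] = shulen_profile(anc, der, include_revcomp).mean()
    if not np.all(np.diff(means) < 0):
        # enforce strict monotonicity for the interpolator (MC noise at the
        # flat high-p end)
        means = np.minimum.accumulate(means)
        means -= 1e-9 * np.arange(len(means))
    return ShulenCalibration(length=int(length), gc=gc,
                             include_revcomp=include_revcomp,
                             p_grid=p_grid, mean_shulen=means)


@dataclass
class KrEstimate:
    """Jukes-Cantor-corrected alignment-free distance with reliability flag."""

    kr: float
    pi_hat: float
    kr_xy: float
    kr_yx: float
    reliable: bool
    low_confidence: bool

    def __post_init__(self) -> None:
        if self.kr > KR_RELIABLE_MAX:
            self.reliable = False


def _gc_of(parts: list[np.ndarray]) -> float:
    gc = tot = 0
    for p in parts:
        callable_ = p < 4
        gc += int(np.count_nonzero((p == sa.C) | (p == sa.G)))
        tot += int(np.count_nonzero(callable_))
    return gc / tot if tot else 0.5


def estimate_kr(X, Y, seed: int = 0, *, include_revcomp: bool = True,
                p_grid: Sequence[float] = DEFAULT_P_GRID,
                calibration: ShulenCalibration | None = None) -> KrEstimate:
    """Kr between two genomes: both directions estimated and averaged.

    A shared :class:`ShulenCalibration` may be passed to amortize the
    Monte-Carlo calibration across pairs of similar length and GC.
    """
    x_parts = _concat_codes(X)
    y_parts = _concat_codes(Y)
    nx = sum(len(p) for p in x_parts)
    ny = sum(len(p) for p in y_parts)
    if calibration is None:
        calibration = calibrate_shulen(
            (nx + ny) // 2, _gc_of(x_parts + y_parts), seed,
            p_grid=p_grid, include_revcomp=include_revcomp,
        )
    pis = []
    for direction, (a, b) in (("X_vs_Y", (X, Y)), ("Y_vs_X", (Y, X))):
        prof = shulen_profile(a, b, include_revcomp, direction)
        m = prof.mean()
        if math.isnan(m):  # X == Y up to sentinels: no absent substring at all
            pis.append(0.0)
            continue
        try:
            pis.append(calibration.invert(m))
        except CalibrationRangeError:
            if m > float(calibration.mean_shulen.max()):
                # longer matches than the least-diverged calibration point:
                # effectively identical sequences
                pis.append(0.0)
            else:
                raise
    pi_xy, pi_yx = pis
    pi_hat = 0.5 * (pi_xy + pi_yx)
    if pi_hat >= 0.75:
        raise ValueError("difference estimate saturated (pi >= 0.75)")
    kr_xy = jc_d_from_p(pi_xy)
    kr_yx = jc_d_from_p(pi_yx)
    kr = 0.5 * (kr_xy + kr_yx)
    low_conf = pi_hat * min(nx, ny) < MIN_EXPECTED_MISMATCHES
    return KrEstimate(kr=kr, pi_hat=pi_hat, kr_xy=kr_xy, kr_yx=kr_yx,
                      reliable=kr <= KR_RELIABLE_MAX, low_confidence=low_conf)


def kr_matrix(assemblies: dict[str, GenomeAssembly], seed: int = 0,
              *, include_revcomp: bool = True,
              p_grid: Sequence[float] = DEFAULT_P_GRID,
              ) -> tuple["np.ndarray", list[str], dict[tuple[str, str], KrEstimate]]:
    """All pairwise Kr estimates; unreliable cells are flagged in the result."""
    names = sorted(assemblies)
    if len(names) < 2:
        raise ValueError("need at least 2 assemblies")
    n = len(names)
    mat = np.zeros((n, n))
    estimates: dict[tuple[str, str], KrEstimate] = {}
    # one calibration at the average genome scale serves the whole matrix
    mean_len = int(np.mean([assemblies[x].total_length for x in names]))
    gc = _gc_of([c for x in names for c in _concat_codes(assemblies[x])])
    calib = calibrate_shulen(mean_len, gc, seed, p_grid=p_grid,
                             include_revcomp=include_revcomp)
    for i in range(n):
        for j in range(i + 1, n):
            est = estimate_kr(assemblies[names[i]], assemblies[names[j]],
                              seed, include_revcomp=include_revcomp,
                              p_grid=p_grid, calibration=calib)
            mat[i, j] = mat[j, i] = est.kr
            estimates[(names[i], names[j])] = est
    return mat, names, estimates


# ---------------------------------------------------------------------------
# brute-force oracle (test reference; O(n^2 m), small inputs only)
# ---------------------------------------------------------------------------

def shulen_brute_force(x: str, y: str, include_revcomp: bool = True) -> list[int]:
    """Literal enumeration of the shulen definition (oracle for tests)."""
    hay = [y]
    if include_revcomp:
        hay.append(sa.revcomp_str(y))

    def occurs(sub: str) -> bool:
        if "N" in sub:
            return False
        return any(sub in h for h in hay)

    n = len(x)
    out = []
    for i in range(n):
        l = 1
        while i + l <= n and occurs(x[i:i + l]):
            l += 1
        out.append(l)  # == remaining + 1 when no absent prefix exists
    return out
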