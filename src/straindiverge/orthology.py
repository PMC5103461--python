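"""Best-hit / reciprocal-best-hit orthology and the orphan-gene filter chain.

Best hits rank rows passing the e-value (and optionally identity) thresholds
by minimal e-value, then maximal aligned length, then maximal bitscore, then
lexicographic subject id (the last two declared for determinism).  Orphan
genes are core genes (shared by all three strains) with expression evidence
(read-to-gene coverage >= 0.5) and no hit below e = 1e-5 in either the
related-species tables or a broad protein database.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .formats import HitRecord

logger = logging.getLogger(__name__)

MAX_EVALUE = 1e-5
MIN_IDENTITY_ANNOT = 50.0
MIN_EXPRESSION_COVERAGE = 0.5


@dataclass
class BestHitRule:
    """Thresholds applied before ranking; ``min_identity`` is the annotation
    mode (identity > 50%) and is off by default."""

    max_evalue: float = MAX_EVALUE
    min_identity: float | None = None


@dataclass
class OrphanFilterConfig:
    min_expression_coverage: float = MIN_EXPRESSION_COVERAGE
    max_evalue: float = MAX_EVALUE

    def __post_init__(self) -> None:
        if self.max_evalue <= 0:
            raise ValueError("e-value threshold must be > 0")


def best_hits(table: Sequence[HitRecord], rule: BestHitRule | None = None,
              ) -> dict[str, str]:
    """Per-query best subject: minimal e-value, ties by maximal aligned
    length, then maximal bitscore, then lexicographic subject id.  Queries
    with no row passing the thresholds are absent from the map."""
    rule = rule or BestHitRule()
    best: dict[str, tuple] = {}
    out: dict[str, str] = {}
    for h in table:
        if not h.evalue < rule.max_evalue:
            continue
        if rule.min_identity is not None and not h.pct_identity > rule.min_identity:
            continue
        key = (h.evalue, -h.aln_length, -h.bitscore, h.subject)
        if h.query not in best or key < best[h.query]:
            best[h.query] = key
            out[h.query] = h.subject
    return out


def rbh(table_ab: Sequence[HitRecord], table_ba: Sequence[HitRecord],
        rule: BestHitRule | None = None) -> set[tuple[str, str]]:
    """Reciprocal best hits: (a, b) iff a's best is b and b's best is a."""
    ab = best_hits(table_ab, rule)
    ba = best_hits(table_ba, rule)
    return {(a, b) for a, b in ab.items() if ba.get(b) == a}


@dataclass
class ThreeWaySets:
    """Partition of RBH links among three genomes."""

    core: set[tuple[str, str, str]]                   # (a, b, c) closed triangles
    exclusive: dict[str, set[tuple[str, str]]]        # "AB"/"AC"/"BC" pair-only
    inconsistent: set[tuple[str, str, str]]           # open triangles
    singletons: dict[str, set[str]]                   # per genome label

    @property
    def counts(self) -> dict:
        return {
            "core": len(self.core),
            "exclusive": {k: len(v) for k, v in self.exclusive.items()},
            "inconsistent": len(self.inconsistent),
            "singletons": {k: len(v) for k, v in self.singletons.items()},
        }


def three_way_sets(rbh_ab: Iterable[tuple[str, str]],
                   rbh_ac: Iterable[tuple[str, str]],
                   rbh_bc: Iterable[tuple[str, str]],
                   genes_a: Iterable[str] = (), genes_b: Iterable[str] = (),
                   genes_c: Iterable[str] = ()) -> ThreeWaySets:
    """Core triples (all three pairwise links close a triangle), pair-
    exclusive links (neither member linked to the third genome), open
    triangles reported separately, and singletons."""
    ab = dict(rbh_ab)
    ac = dict(rbh_ac)
    bc = dict(rbh_bc)
    ba = {b: a for a, b in ab.items()}
    ca = {c: a for a, c in ac.items()}
    cb = {c: b for b, c in bc.items()}
    core: set[tuple[str, str, str]] = set()
    inconsistent: set[tuple[str, str, str]] = set()
    for a, b in ab.items():
        c_from_a = ac.get(a)
        c_from_b = bc.get(b)
        if c_from_a is None and c_from_b is None:
            continue  # candidate AB-exclusive link
        if c_from_a is not None and c_from_a == c_from_b:
            core.add((a, b, c_from_a))
        else:
            inconsistent.add((a, b, c_from_a or c_from_b or ""))
    # remaining two-link chains without an AB edge
    for a, c in ac.items():
        b_from_c = cb.get(c)
        if ab.get(a) is None and b_from_c is not None and ca.get(c) == a:
            if ab.get(a) != b_from_c:
                inconsistent.add((a, b_from_c, c))
    core_a = {t[0] for t in core}
    core_b = {t[1] for t in core}
    core_c = {t[2] for t in core}
    incons_members = {x for t in inconsistent for x in t if x}
    exclusive = {
        "AB": {(a, b) for a, b in ab.items()
               if a not in core_a and b not in core_b
               and ac.get(a) is None and bc.get(b) is None
               and a not in incons_members and b not in incons_members},
        "AC": {(a, c) for a, c in ac.items()
               if a not in core_a and c not in core_c
               and ab.get(a) is None and cb.get(c) is None
               and a not in incons_members and c not in incons_members},
        "BC": {(b, c) for b, c in bc.items()
               if b not in core_b and c not in core_c
               and ba.get(b) is None and ca.get(c) is None
               and b not in incons_members and c not in incons_members},
    }
    linked_a = set(ab) | set(ac) | incons_members
    linked_b = set(ab.values()) | set(bc) | incons_members
    linked_c = set(ac.values()) | set(bc.values()) | incons_members
    singletons = {
        "A": set(genes_a) - linked_a,
        "B": set(genes_b) - linked_b,
        "C": set(genes_c) - linked_c,
    }
    return ThreeWaySets(core=core, exclusive=exclusive,
                        inconsistent=inconsistent, singletons=singletons)


def orphan_filter(core_genes: Iterable[str],
                  expression_coverage: Mapping[str, float] | pd.DataFrame,
                  relative_hits: Sequence[HitRecord],
                  nr_hits: Sequence[HitRecord],
                  domains: Mapping[str, int] | pd.DataFrame | None = None,
                  config: OrphanFilterConfig | None = None,
                  ) -> tuple[set[str], int, dict[str, int]]:
    """Sequential orphan-gene filters: (1) core-set membership, (2)
    expression coverage >= threshold, (3) no related-species hit below the
    e-value cutoff, (4) no broad-database hit below the cutoff.  Returns the
    orphan set, how many survivors carry >= 1 protein domain (count only,
    never a filter), and per-stage survivor counts."""
    config = config or OrphanFilterConfig()
    if isinstance(expression_coverage, pd.DataFrame):
        expression_coverage = dict(
            zip(expression_coverage.iloc[:, 0], expression_coverage.iloc[:, 1]))
    if isinstance(domains, pd.DataFrame):
        domains = dict(zip(domains.iloc[:, 0], domains.iloc[:, 1]))
    survivors = set(core_genes)
    counts = {"core": len(survivors)}
    missing = [g for g in survivors if g not in expression_coverage]
    if missing:
        logger.warning("%d core genes missing from the expression table; "
                       "treated as coverage 0", len(missing))
    survivors = {g for g in survivors
                 if expression_coverage.get(g, 0.0) >= config.min_expression_coverage}
    counts["expressed"] = len(survivors)
    rel_excluded = {h.query for h in relative_hits if h.evalue < config.max_evalue}
    survivors -= rel_excluded
    counts["no_relative_hit"] = len(survivors)
    nr_excluded = {h.query for h in nr_hits if h.evalue < config.max_evalue}
    survivors -= nr_excluded
    counts["no_nr_hit"] = len(survivors)
    with_domain = sum(1 for g in survivors if domains and domains.get(g, 0) >= 1)
    return survivors, with_domain, counts
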