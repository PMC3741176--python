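"""Tryptic autolysis-site prediction and fragment-mass matching.

A trypsin digests itself after exposed, unstabilized Lys/Arg residues. This
module enumerates those candidate sites, filters them by structural context
(side-chain exposure, salt bridges, disulfide proximity), enumerates cleavage
patterns, and computes the disulfide-linked fragment groups each pattern
produces. Because fragments held together by disulfide bonds co-migrate as a
single band on a non-reducing gel, group masses — not raw fragment masses —
are matched against observed electrophoretic bands, and patterns are ranked
by how well they explain the gel.

Numbering is zymogen-based and 1-based throughout; intervals are closed on
both ends. Masses default to average (SDS-PAGE resolution justifies nothing
finer) and to the reduced convention (no -2H per disulfide); monoisotopic and
oxidized modes are opt-in.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

from .constants import (
    AVERAGE_RESIDUE_MASS,
    DISULFIDE_H2_LOSS,
    MONOISOTOPIC_RESIDUE_MASS,
    STANDARD_AA,
    WATER_AVERAGE,
    WATER_MONOISOTOPIC,
)
from .structure import ContactAnnotation, ExposureProfile

logger = logging.getLogger(__name__)

__all__ = [
    "Tag",
    "ProteinChain",
    "DisulfideTopology",
    "CleavageSite",
    "CleavagePattern",
    "FragmentGroup",
    "BandObservation",
    "RankedPattern",
    "enumerate_candidate_sites",
    "assess_site_lability",
    "enumerate_cleavage_patterns",
    "fragment_groups",
    "group_mass",
    "triad_disrupted",
    "match_bands_and_rank",
]

DEFAULT_EXPOSURE_THRESHOLD = 0.30
DEFAULT_REPORTABLE_FLOOR_KDA = 5.0  # smaller peptides migrate out of the gel
DEFAULT_BAND_TOLERANCE_KDA = 1.5


@dataclass(frozen=True)
class Tag:
    """A terminal tag (e.g. 6xHis) with its attachment end and mass in Da."""

    name: str
    attachment: str  # "N" | "C"
    mass: float

    def __post_init__(self) -> None:
        if self.attachment not in ("N", "C"):
            raise ValueError("tag attachment must be 'N' or 'C'")
        if self.mass < 0:
            raise ValueError("tag mass must be non-negative")


HIS6_TAG = Tag(name="6xHis", attachment="C", mass=6 * AVERAGE_RESIDUE_MASS["H"])


@dataclass(frozen=True)
class ProteinChain:
    """A mature chain with its zymogen-numbering offset and optional tags."""

    sequence: str
    first_residue_number: int = 1
    tags: tuple[Tag, ...] = ()

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("sequence must be non-empty")
        bad = set(self.sequence) - STANDARD_AA
        if bad:
            raise ValueError(f"nonstandard residue(s) in chain: {sorted(bad)}")
        if self.first_residue_number < 1:
            raise ValueError("first_residue_number must be >= 1")

    @property
    def last_residue_number(self) -> int:
        return self.first_residue_number + len(self.sequence) - 1

    def residue(self, number: int) -> str:
        if not (self.first_residue_number <= number <= self.last_residue_number):
            raise ValueError(f"residue number {number} outside chain")
        return self.sequence[number - self.first_residue_number]

    def subsequence(self, start: int, end: int) -> str:
        """Residues ``start``..``end`` inclusive (chain numbering)."""
        if start > end:
            raise ValueError("interval start must not exceed end")
        self.residue(start), self.residue(end)
        off = self.first_residue_number
        return self.sequence[start - off : end - off + 1]


@dataclass(frozen=True)
class DisulfideTopology:
    """Unordered cysteine pairs, validated against a chain when given."""

    pairs: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for a, b in self.pairs:
            if a == b:
                raise ValueError("a disulfide cannot pair a cysteine with itself")
            for r in (a, b):
                if r in seen:
                    raise ValueError(f"residue {r} appears in two disulfide pairs")
                seen.add(r)

    def validate_against(self, chain: ProteinChain) -> None:
        for a, b in self.pairs:
            for r in (a, b):
                if chain.residue(r) != "C":
                    raise ValueError(f"disulfide residue {r} is not a cysteine")

    @property
    def cysteines(self) -> tuple[int, ...]:
        return tuple(sorted(r for pair in self.pairs for r in pair))


@dataclass(frozen=True)
class CleavageSite:
    """A candidate tryptic self-cleavage site and its structural filters."""

    residue_number: int
    residue_type: str  # "K" | "R"
    exposure: float | None = None
    salt_bridged: bool | None = None
    near_disulfide: bool | None = None
    labile: bool | None = None
    followed_by_proline: bool = False
    unassessed: bool = False


@dataclass(frozen=True, order=True)
class CleavagePattern:
    """A sorted set of cut-after positions; the empty pattern is the intact
    protein."""

    cut_after: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "cut_after", tuple(sorted(set(self.cut_after))))

    def __len__(self) -> int:
        return len(self.cut_after)


@dataclass(frozen=True)
class FragmentGroup:
    """Disulfide-linked fragments that co-migrate as one band."""

    fragments: tuple[tuple[int, int], ...]  # closed residue-number intervals
    retains_tags: tuple[str, ...] = ()
    contains_triad_members: tuple[int, ...] = ()

    def contains(self, residue_number: int) -> bool:
        return any(a <= residue_number <= b for a, b in self.fragments)


@dataclass(frozen=True)
class BandObservation:
    """An observed gel band mass (kDa) with matching tolerance."""

    mass: float
    tolerance: float = DEFAULT_BAND_TOLERANCE_KDA
    tag_positive: bool | None = None

    def __post_init__(self) -> None:
        if self.mass <= 0 or self.tolerance <= 0:
            raise ValueError("band mass and tolerance must be positive")


@dataclass(frozen=True)
class RankedPattern:
    pattern: CleavagePattern
    score: tuple[int, int, int]
    band_assignments: tuple[int | None, ...]  # per band: index of explaining group
    group_masses_kda: tuple[float, ...]
    triad_disrupted: bool


# ---------------------------------------------------------------------------
# Site enumeration and filtering


def enumerate_candidate_sites(
    chain: ProteinChain, proline_rule: str = "exclude"
) -> list[CleavageSite]:
    """Every K/R with a scissile bond, honoring the trypsin proline rule.

    Trypsin cleaves after Lys/Arg but barely when the next residue is
    proline; those sites are excluded by default (``proline_rule="exclude"``)
    or kept flagged under ``"permissive"``. The C-terminal residue has no
    scissile bond and is never a site.
    """
    if proline_rule not in ("exclude", "permissive"):
        raise ValueError("proline_rule must be 'exclude' or 'permissive'")
    sites: list[CleavageSite] = []
    seq = chain.sequence
    for i, aa in enumerate(seq[:-1]):  # last residue excluded
        if aa not in ("K", "R"):
            continue
        followed_by_p = seq[i + 1] == "P"
        if followed_by_p and proline_rule == "exclude":
            continue
        sites.append(
            CleavageSite(
                residue_number=chain.first_residue_number + i,
                residue_type=aa,
                followed_by_proline=followed_by_p,
            )
        )
    return sites


def assess_site_lability(
    sites: list[CleavageSite],
    exposure: ExposureProfile,
    contacts: ContactAnnotation,
    threshold: float = DEFAULT_EXPOSURE_THRESHOLD,
) -> list[CleavageSite]:
    """Annotate candidate sites and decide lability.

    A site is labile when its side chain is exposed (relative exposure >=
    ``threshold``), it is not salt-bridged, and no disulfide is nearby. Sites
    lacking exposure or contact coverage are retained with an ``unassessed``
    flag rather than silently dropped.
    """
    out: list[CleavageSite] = []
    for site in sites:
        num = site.residue_number
        rel = exposure.relative(num) if num in exposure else None
        has_contacts = num in contacts
        if rel is None or not has_contacts:
            logger.warning("site %s%d lacks exposure/contact data; kept unassessed",
                           site.residue_type, num)
            out.append(replace(site, unassessed=True, labile=None))
            continue
        sb = contacts.salt_bridged(num)
        nd = contacts.near_disulfide(num)
        labile = (rel >= threshold) and not sb and not nd
        out.append(
            replace(
                site,
                exposure=rel,
                salt_bridged=sb,
                near_disulfide=nd,
                labile=labile,
                unassessed=False,
            )
        )
    return out


def enumerate_cleavage_patterns(
    sites: list[CleavageSite] | list[int],
    max_cuts: int | None = None,
    guard: int = 12,
) -> list[CleavagePattern]:
    """All subsets of the site set, by size then lexicographic position.

    The empty pattern (intact protein) comes first. ``guard`` caps the site
    count to keep the power set tractable; raise it explicitly if needed.
    """
    numbers = sorted(
        s.residue_number if isinstance(s, CleavageSite) else int(s) for s in sites
    )
    if len(numbers) > guard:
        raise ValueError("too many sites; raise guard explicitly")
    top = len(numbers) if max_cuts is None else min(max_cuts, len(numbers))
    patterns: list[CleavagePattern] = []
    for size in range(top + 1):
        for combo in itertools.combinations(numbers, size):
            patterns.append(CleavagePattern(cut_after=combo))
    return patterns


# ---------------------------------------------------------------------------
# Fragment groups


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def _intervals_from_pattern(
    chain: ProteinChain, pattern: CleavagePattern
) -> list[tuple[int, int]]:
    first, last = chain.first_residue_number, chain.last_residue_number
    for cut in pattern.cut_after:
        if not (first <= cut < last):
            raise ValueError(f"invalid cut: position {cut} outside chain")
    bounds = [first - 1, *pattern.cut_after, last]
    return [(bounds[i] + 1, bounds[i + 1]) for i in range(len(bounds) - 1)]


def fragment_groups(
    chain: ProteinChain,
    pattern: CleavagePattern,
    ss: DisulfideTopology,
    triad: tuple[int, ...] = (),
) -> list[FragmentGroup]:
    """Cut the chain and merge fragments connected by disulfide pairs.

    Groups are the connected components of the fragment/disulfide graph
    (union-find); each lists the terminal tags it retains (N-tag travels with
    the first fragment, C-tag with the last) and the catalytic-triad members
    it contains.
    """
    for t in triad:
        try:
            chain.residue(t)
        except ValueError as exc:
            raise ValueError(f"invalid triad annotation: {exc}") from None
    intervals = _intervals_from_pattern(chain, pattern)

    def interval_index(residue_number: int) -> int:
        for i, (a, b) in enumerate(intervals):
            if a <= residue_number <= b:
                return i
        raise ValueError(f"residue {residue_number} not covered by any fragment")

    uf = _UnionFind(len(intervals))
    for a, b in ss.pairs:
        uf.union(interval_index(a), uf.find(interval_index(b)))

    members: dict[int, list[int]] = {}
    for i in range(len(intervals)):
        members.setdefault(uf.find(i), []).append(i)

    groups: list[FragmentGroup] = []
    for root in sorted(members):
        idxs = sorted(members[root])
        frags = tuple(intervals[i] for i in idxs)
        tags = []
        for tag in chain.tags:
            anchor = 0 if tag.attachment == "N" else len(intervals) - 1
            if anchor in idxs:
                tags.append(tag.name)
        triad_members = tuple(
            t for t in sorted(triad) if any(a <= t <= b for a, b in frags)
        )
        groups.append(
            FragmentGroup(
                fragments=frags,
                retains_tags=tuple(tags),
                contains_triad_members=triad_members,
            )
        )
    return groups


def group_mass(
    group: FragmentGroup,
    chain: ProteinChain,
    ss: DisulfideTopology | None = None,
    oxidized: bool = False,
    monoisotopic: bool = False,
) -> float:
    """Mass of a disulfide-linked fragment group, Da.

    Sum of residue masses plus one water per fragment interval, plus retained
    tag masses; in oxidized mode, minus 2H per disulfide internal to the
    group.
    """
    if not group.fragments:
        raise ValueError("empty fragment group")
    table = MONOISOTOPIC_RESIDUE_MASS if monoisotopic else AVERAGE_RESIDUE_MASS
    water = WATER_MONOISOTOPIC if monoisotopic else WATER_AVERAGE
    mass = 0.0
    for a, b in group.fragments:
        mass += sum(table[aa] for aa in chain.subsequence(a, b)) + water
    for tag in chain.tags:
        if tag.name in group.retains_tags:
            mass += tag.mass
    if oxidized and ss is not None:
        for a, b in ss.pairs:
            if group.contains(a) and group.contains(b):
                mass -= DISULFIDE_H2_LOSS
    return mass


def triad_disrupted(groups: list[FragmentGroup], triad: tuple[int, ...]) -> bool:
    """True when catalytic-triad members end up in >= 2 different groups."""
    if len(triad) < 2:
        raise ValueError("triad needs at least 2 members")
    holders = [g for g in groups if any(g.contains(t) for t in triad)]
    covered = {t for g in holders for t in triad if g.contains(t)}
    if covered != set(triad):
        raise ValueError("invalid triad annotation: member outside every fragment")
    return len(holders) >= 2


# ---------------------------------------------------------------------------
# Band matching and ranking


def match_bands_and_rank(
    patterns: list[CleavagePattern],
    chain: ProteinChain,
    ss: DisulfideTopology,
    triad: tuple[int, ...],
    bands: list[BandObservation],
    reportable_floor_kda: float = DEFAULT_REPORTABLE_FLOOR_KDA,
    oxidized: bool = False,
    monoisotopic: bool = False,
) -> list[RankedPattern]:
    """Rank cleavage patterns by how well they explain the observed bands.

    A band is explained by a pattern when some fragment-group mass lies
    within the band's tolerance and, if the band carries a His-probe signal
    flag, the group's tag retention matches it. Scores compare
    lexicographically: more explained bands first, then fewer unexplained
    predicted groups above the reportable-mass floor (small peptides run off
    the gel and are not penalized), then fewer cuts (parsimony). Ties keep
    pattern enumeration order.
    """
    if not bands:
        raise ValueError("no observations: at least one band is required")
    if not patterns:
        raise ValueError("patterns must be non-empty")
    ranked: list[RankedPattern] = []
    for pattern in patterns:
        groups = fragment_groups(chain, pattern, ss, triad)
        masses_kda = tuple(
            group_mass(g, chain, ss, oxidized=oxidized, monoisotopic=monoisotopic) / 1000.0
            for g in groups
        )
        assignments: list[int | None] = []
        used: set[int] = set()
        for band in bands:
            best: int | None = None
            for gi, m in enumerate(masses_kda):
                if abs(m - band.mass) > band.tolerance:
                    continue
                if band.tag_positive is not None:
                    has_tag = bool(groups[gi].retains_tags)
                    if has_tag != band.tag_positive:
                        continue
                if best is None or abs(masses_kda[gi] - band.mass) < abs(
                    masses_kda[best] - band.mass
                ):
                    best = gi
            assignments.append(best)
            if best is not None:
                used.add(best)
        explained = sum(a is not None for a in assignments)
        unexplained_groups = sum(
            1
            for gi, m in enumerate(masses_kda)
            if gi not in used and m >= reportable_floor_kda
        )
        score = (explained, -unexplained_groups, -len(pattern))
        ranked.append(
            RankedPattern(
                pattern=pattern,
                score=score,
                band_assignments=tuple(assignments),
                group_masses_kda=masses_kda,
                triad_disrupted=triad_disrupted(groups, triad) if len(triad) >= 2 else False,
            )
        )
    # stable sort: descending score, ties keep enumeration order
    ranked_sorted = sorted(ranked, key=lambda rp: rp.score, reverse=True)
    if len(ranked_sorted) > 1 and ranked_sorted[0].score == ranked_sorted[1].score:
        logger.info("tie at the top of the pattern ranking; enumeration order kept")
    return ranked_sorted
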