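"""Alternative-splicing event construction from splice junctions.

Junctions are grouped by shared splice site (donor = 5' site, acceptor =
3' site, assigned transcriptionally, so swapped on the minus strand).  The
splicing ratio (SR) of a junction in a sample is its read count divided by
the summed counts of the junctions sharing that site: 5' SR over the donor
group, 3' SR over the acceptor group.

An alternative-splicing event is an unordered pair of junctions sharing one
splice site, spanning three exons (upstream/flanking exon, inclusion exon,
skipping-side exon).  Event types:

* CA (cassette exon): the nearer variable site matches an annotated exon
  boundary and that exon ends before the farther variable site — a
  skippable middle exon exists.
* A3SS / A5SS: alternative acceptor (shared donor) or donor (shared
  acceptor) with no skippable exon between the two variable sites.
* MXE: two reciprocal CA events over non-overlapping middle exons that are
  never annotated in the same transcript.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

from .io import ExonAnnotation, JunctionRecord

__all__ = [
    "JunctionKey",
    "Site",
    "SpliceSiteGroup",
    "SplicingRatio",
    "ASEvent",
    "EventDirection",
    "group_junctions_by_site",
    "compute_sr",
    "build_events",
    "classify_direction",
    "pair_event_id",
]

JunctionKey = tuple[str, int, int, str]  # (chrom, intron_start, intron_end, strand)
Site = tuple[str, int, str, str]  # (chrom, exonic position, strand, side)

DONOR = "donor"
ACCEPTOR = "acceptor"


def _donor_pos(key: JunctionKey) -> int:
    chrom, start, end, strand = key
    return start - 1 if strand != "-" else end + 1


def _acceptor_pos(key: JunctionKey) -> int:
    chrom, start, end, strand = key
    return end + 1 if strand != "-" else start - 1


@dataclass(frozen=True, slots=True)
class SpliceSiteGroup:
    """All junctions sharing one splice site (one side, one strand)."""

    site: Site
    members: tuple[JunctionKey, ...]

    @property
    def side(self) -> str:
        return self.site[3]


@dataclass(frozen=True, slots=True)
class SplicingRatio:
    """SR of one junction over one site group in one sample.

    ``value`` is in [0, 1], or ``None`` when the group had zero total
    coverage in the sample (SR undefined).
    """

    junction: JunctionKey
    site: Site
    sample_id: str
    value: float | None


@dataclass(frozen=True, slots=True)
class ASEvent:
    """A typed alternative-splicing event built from a junction pair."""

    event_id: str
    event_type: str  # CA | A3SS | A5SS | MXE
    chrom: str
    strand: str
    shared_side: str  # donor | acceptor | both (MXE)
    site: Site  # site whose SR drives detection (donor-side site for MXE)
    inclusion_junction: JunctionKey
    skipping_junction: JunctionKey
    inclusion_exon: tuple[int, int] | None
    second_exon: tuple[int, int] | None = None  # second middle exon (MXE only)
    gene_id: str | None = None
    low_confidence: bool = False

    @property
    def junctions(self) -> tuple[JunctionKey, JunctionKey]:
        return (self.inclusion_junction, self.skipping_junction)


@dataclass(frozen=True, slots=True)
class EventDirection:
    """Direction of change of an event in one comparison.

    For cassette exons: EX (inclusion junction lost SR, exon excluded) or
    IN (gained).  For other types: up/down of the inclusion-listed
    junction.  ``None`` flags a zero SR change (undirected).
    """

    event_id: str
    comparison_id: str
    direction: str | None


def group_junctions_by_site(
    junctions: Iterable[JunctionRecord | JunctionKey],
) -> list[SpliceSiteGroup]:
    """Group junction keys by shared donor site and by shared acceptor site.

    Every junction lands in exactly one donor-side and one acceptor-side
    group; singleton groups are kept.  Input may be records (keys are
    extracted, duplicates across samples collapse) or raw keys.
    """
    keys: list[JunctionKey] = []
    seen: set[JunctionKey] = set()
    for j in junctions:
        key = j.key if isinstance(j, JunctionRecord) else j
        if key not in seen:
            seen.add(key)
            keys.append(key)

    by_site: dict[Site, list[JunctionKey]] = {}
    for key in keys:
        chrom, _, _, strand = key
        for side, pos in ((DONOR, _donor_pos(key)), (ACCEPTOR, _acceptor_pos(key))):
            by_site.setdefault((chrom, pos, strand, side), []).append(key)
    return [
        SpliceSiteGroup(site=site, members=tuple(sorted(members)))
        for site, members in sorted(by_site.items())
    ]


def compute_sr(
    group: SpliceSiteGroup,
    counts: Mapping[JunctionKey, int],
    sample_id: str = "",
) -> list[SplicingRatio]:
    """Splicing ratios of a group's members in one sample.

    ``counts`` maps junction key to uniquely-mapped read count; absent
    members count 0.  With zero group total, all ratios are missing.
    """
    member_counts = [max(0, counts.get(k, 0)) for k in group.members]
    total = sum(member_counts)
    if total == 0:
        return [SplicingRatio(k, group.site, sample_id, None) for k in group.members]
    return [
        SplicingRatio(k, group.site, sample_id, c / total)
        for k, c in zip(group.members, member_counts)
    ]


def pair_event_id(j1: JunctionKey, j2: JunctionKey) -> str:
    """Deterministic event id for an unordered junction pair."""
    a, b = sorted((j1, j2))
    return f"{a[0]}:{a[3]}:{a[1]}-{a[2]}|{b[1]}-{b[2]}"


def _exon_index(
    annotation: Sequence[ExonAnnotation] | None,
) -> tuple[dict[tuple[str, int], list[ExonAnnotation]], dict[tuple[str, int], list[ExonAnnotation]]]:
    """Index annotated exons by (chrom, start) and (chrom, end)."""
    by_start: dict[tuple[str, int], list[ExonAnnotation]] = {}
    by_end: dict[tuple[str, int], list[ExonAnnotation]] = {}
    for exon in annotation or ():
        by_start.setdefault((exon.chrom, exon.exon_start), []).append(exon)
        by_end.setdefault((exon.chrom, exon.exon_end), []).append(exon)
    return by_start, by_end


def _strand_ok(group_strand: str, exon_strand: str) -> bool:
    return group_strand == "." or exon_strand == "." or group_strand == exon_strand


def _classify_pair(
    group: SpliceSiteGroup,
    j1: JunctionKey,
    j2: JunctionKey,
    by_start: dict,
    by_end: dict,
) -> ASEvent:
    chrom, _, strand, side = group.site
    # Variable-end exonic positions: the first exonic base after/before the
    # intron at the non-shared end of each junction.
    if side == DONOR:
        vpos = _acceptor_pos
        alt_type = "A3SS"
    else:
        vpos = _donor_pos
        alt_type = "A5SS"
    v1, v2 = vpos(j1), vpos(j2)
    # "inner" = variable end nearer the shared site along the genome
    if (side == DONOR) == (strand != "-"):
        # variable positions on the intron_end side: nearer = smaller coord;
        # a middle exon starts at the nearer position and ends before the farther
        (near_j, near_v), (far_j, far_v) = sorted(
            ((j1, v1), (j2, v2)), key=lambda t: t[1]
        )
        candidates = [
            e
            for e in by_start.get((chrom, near_v), [])
            if e.exon_end < far_v and _strand_ok(strand, e.strand)
        ]
    else:
        # variable positions on the intron_start side: nearer = larger coord;
        # a middle exon ends at the nearer position and starts after the farther
        (far_j, far_v), (near_j, near_v) = sorted(
            ((j1, v1), (j2, v2)), key=lambda t: t[1]
        )
        candidates = [
            e
            for e in by_end.get((chrom, near_v), [])
            if e.exon_start > far_v and _strand_ok(strand, e.strand)
        ]
    event_id = pair_event_id(j1, j2)
    if candidates:
        # smallest skippable exon at that boundary (deterministic choice)
        exon = min(candidates, key=lambda e: (e.exon_end - e.exon_start, e.transcript_id))
        return ASEvent(
            event_id=event_id,
            event_type="CA",
            chrom=chrom,
            strand=strand,
            shared_side=side,
            site=group.site,
            inclusion_junction=near_j,
            skipping_junction=far_j,
            inclusion_exon=(exon.exon_start, exon.exon_end),
            gene_id=exon.gene_id,
        )
    return ASEvent(
        event_id=event_id,
        event_type=alt_type,
        chrom=chrom,
        strand=strand,
        shared_side=side,
        site=group.site,
        inclusion_junction=near_j,
        skipping_junction=far_j,
        inclusion_exon=None,
        gene_id=None,
        low_confidence=True,
    )


def _merge_mxe(
    events: list[ASEvent], annotation: Sequence[ExonAnnotation] | None
) -> list[ASEvent]:
    """Merge reciprocal CA pairs into MXE events.

    Donor-side CA event X (middle exon Ma, skipping junction reaching Mb)
    and acceptor-side CA event Y (middle exon Mb, skipping junction leaving
    Ma) merge iff Ma and Mb do not overlap and no annotated transcript
    contains both.
    """
    exons_by_transcript: dict[str, set[tuple[int, int]]] = {}
    for exon in annotation or ():
        exons_by_transcript.setdefault(exon.transcript_id, set()).add(
            (exon.exon_start, exon.exon_end)
        )

    def co_annotated(ma: tuple[int, int], mb: tuple[int, int]) -> bool:
        return any(ma in exs and mb in exs for exs in exons_by_transcript.values())

    donor_ca = [e for e in events if e.event_type == "CA" and e.shared_side == DONOR]
    acceptor_ca = {
        (e.chrom, e.strand, e.inclusion_exon): e
        for e in events
        if e.event_type == "CA" and e.shared_side == ACCEPTOR
    }
    merged: dict[str, ASEvent] = {}
    consumed: set[str] = set()
    for x in donor_ca:
        ma = x.inclusion_exon
        # the donor-side skipping junction lands on the partner middle exon
        skip_acceptor = _acceptor_pos(x.skipping_junction)
        partner = None
        for (chrom, strand, mb), y in acceptor_ca.items():
            if chrom != x.chrom or strand != x.strand or mb is None:
                continue
            starts_at_skip = (
                mb[0] == skip_acceptor if strand != "-" else mb[1] == skip_acceptor
            )
            overlapping = not (ma[1] < mb[0] or mb[1] < ma[0])
            back_pos = _donor_pos(y.skipping_junction)
            returns_from_ma = ma[1] == back_pos if strand != "-" else ma[0] == back_pos
            if starts_at_skip and returns_from_ma and not overlapping and not co_annotated(ma, mb):
                partner = y
                break
        if partner is None:
            continue
        mxe_id = "MXE|" + "|".join(sorted((x.event_id, partner.event_id)))
        merged[mxe_id] = replace(
            x,
            event_id=mxe_id,
            event_type="MXE",
            shared_side="both",
            second_exon=partner.inclusion_exon,
        )
        consumed.update((x.event_id, partner.event_id))
    out = [e for e in events if e.event_id not in consumed]
    out.extend(merged.values())
    out.sort(key=lambda e: e.event_id)
    return out


def build_events(
    groups: Iterable[SpliceSiteGroup],
    annotation: Sequence[ExonAnnotation] | None = None,
) -> list[ASEvent]:
    """Construct typed events from every junction pair within each group.

    Without annotation (or with no matching exon) pairs default to
    A3SS/A5SS and are flagged ``low_confidence``: calling a cassette exon
    requires evidence of a skippable exon.
    """
    by_start, by_end = _exon_index(annotation)
    events: list[ASEvent] = []
    for group in groups:
        members = group.members
        for i in range(len(members)):
            for k in range(i + 1, len(members)):
                events.append(
                    _classify_pair(group, members[i], members[k], by_start, by_end)
                )
    return _merge_mxe(events, annotation)


def classify_direction(
    event: ASEvent, delta_sr_inclusion: float, comparison_id: str = ""
) -> EventDirection:
    """Direction of a detected event from the mean SR change of its
    inclusion junction (treatment minus control)."""
    if delta_sr_inclusion == 0:
        direction = None
    elif event.event_type == "CA":
        direction = "IN" if delta_sr_inclusion > 0 else "EX"
    else:
        direction = "up" if delta_sr_inclusion > 0 else "down"
    return EventDirection(event.event_id, comparison_id, direction)
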