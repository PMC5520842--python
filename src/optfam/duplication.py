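"""Tandem vs segmental duplication classification from gene positions.

Two duplicates on the same chromosome separated by at most a fixed number
of intervening gene models (default 20) are tandem duplicates.  Duplicates
sitting in large collinear blocks — chains of homologous gene pairs that
preserve order on both chromosomes with at most 100 kb between consecutive
anchors — are segmental duplicates.  When a pair satisfies both rules the
tandem call takes precedence (proximal duplicates inside a duplicated
segment are reported as tandem).

Coordinates are 1-based inclusive; strand is carried but ignored by the
classification rules.  Block detection is a transparent greedy anchor
chaining; externally computed block tables can be supplied instead to
mirror precomputed genome-duplication resources.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

DEFAULT_MAX_INTERVENING = 20
DEFAULT_MAX_GAP_BP = 100_000
DEFAULT_MIN_ANCHORS = 5


@dataclass(frozen=True)
class GeneLocus:
    id: str
    chromosome: str
    start: int
    end: int
    strand: str = "+"
    rank: int = 0  # ordinal position of the gene model on its chromosome

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.id}: start > end")


@dataclass
class CollinearBlock:
    block_id: str
    chrom_a: str
    chrom_b: str
    anchors: list[tuple[GeneLocus, GeneLocus]]
    span_a: tuple[int, int] = field(init=False)
    span_b: tuple[int, int] = field(init=False)

    def __post_init__(self) -> None:
        self.span_a = (
            min(a.start for a, _ in self.anchors),
            max(a.end for a, _ in self.anchors),
        )
        self.span_b = (
            min(b.start for _, b in self.anchors),
            max(b.end for _, b in self.anchors),
        )

    def anchor_ids(self) -> set[frozenset[str]]:
        return {frozenset((a.id, b.id)) for a, b in self.anchors}

    def contains_pair(self, a: GeneLocus, b: GeneLocus) -> bool:
        """Pair is an anchor, or its members fall inside the two spans."""
        if frozenset((a.id, b.id)) in self.anchor_ids():
            return True
        for x, y in ((a, b), (b, a)):
            if (
                x.chromosome == self.chrom_a
                and self.span_a[0] <= x.start and x.end <= self.span_a[1]
                and y.chromosome == self.chrom_b
                and self.span_b[0] <= y.start and y.end <= self.span_b[1]
            ):
                return True
        return False


@dataclass(frozen=True)
class DuplicationEvent:
    id_a: str
    id_b: str
    mechanism: str  # tandem | segmental | unclassified
    evidence: str = ""


def detect_tandem(
    pair: tuple[GeneLocus, GeneLocus],
    max_intervening: int = DEFAULT_MAX_INTERVENING,
) -> tuple[bool, int | None]:
    """Tandem iff same chromosome and ≤ max_intervening gene models between.

    Returns ``(is_tandem, intervening_count)``; the count is ``None`` for
    inter-chromosomal pairs.
    """
    a, b = pair
    if a.chromosome != b.chromosome:
        return False, None
    intervening = abs(a.rank - b.rank) - 1
    return intervening <= max_intervening, intervening


def _gap(left: GeneLocus, right: GeneLocus) -> int:
    """bp between two gene models (0 if overlapping)."""
    lo, hi = sorted((left, right), key=lambda g: g.start)
    return max(0, hi.start - lo.end)


def find_collinear_blocks(
    anchors: Sequence[tuple[GeneLocus, GeneLocus]],
    max_gap: int = DEFAULT_MAX_GAP_BP,
    min_anchors: int = DEFAULT_MIN_ANCHORS,
) -> list[CollinearBlock]:
    """Chain homologous gene pairs into collinear blocks.

    Anchors are grouped by chromosome pair, sorted along the first
    chromosome, and chained greedily while (a) consecutive gaps on both
    chromosomes stay ≤ max_gap and (b) positions on the second chromosome
    keep a consistent direction (forward or inverted).  Maximal chains
    with at least ``min_anchors`` anchors are returned; each anchor
    belongs to at most one block.
    """
    groups: dict[tuple[str, str], list[tuple[GeneLocus, GeneLocus]]] = {}
    for a, b in anchors:
        key = (a.chromosome, b.chromosome)
        if key[0] > key[1] or (key[0] == key[1] and a.start > b.start):
            a, b = b, a
            key = (a.chromosome, b.chromosome)
        groups.setdefault(key, []).append((a, b))
    blocks: list[CollinearBlock] = []
    for (ca, cb), group in sorted(groups.items()):
        group.sort(key=lambda ab: (ab[0].start, ab[1].start))
        chain: list[tuple[GeneLocus, GeneLocus]] = []
        direction = 0  # 0 undetermined, +1 forward, -1 inverted
        def flush():
            nonlocal chain, direction
            if len(chain) >= min_anchors:
                blocks.append(CollinearBlock(
                    block_id=f"block{len(blocks) + 1}",
                    chrom_a=ca, chrom_b=cb, anchors=chain,
                ))
            chain, direction = [], 0
        for a, b in group:
            if not chain:
                chain = [(a, b)]
                continue
            pa, pb = chain[-1]
            step = 1 if b.start >= pb.start else -1
            ok = (
                _gap(pa, a) <= max_gap
                and _gap(pb, b) <= max_gap
                and (direction == 0 or step == direction)
            )
            if ok:
                direction = direction or step
                chain.append((a, b))
            else:
                flush()
                chain = [(a, b)]
        flush()
    return blocks


def classify_duplication(
    pairs: Sequence[tuple[str, str]],
    loci: Mapping[str, GeneLocus],
    blocks: Iterable[CollinearBlock] = (),
    max_intervening: int = DEFAULT_MAX_INTERVENING,
) -> list[DuplicationEvent]:
    """Tandem / segmental / unclassified call for each duplicate pair.

    Tandem takes precedence over segmental when both rules hold.
    """
    blocks = list(blocks)
    events = []
    for ida, idb in pairs:
        for gid in (ida, idb):
            if gid not in loci:
                raise KeyError(f"gene {gid} not in the position table")
        a, b = loci[ida], loci[idb]
        is_tandem, intervening = detect_tandem((a, b), max_intervening)
        if is_tandem:
            events.append(DuplicationEvent(
                ida, idb, "tandem", evidence=f"intervening={intervening}",
            ))
            continue
        hit = next((blk for blk in blocks if blk.contains_pair(a, b)), None)
        if hit is not None:
            events.append(DuplicationEvent(
                ida, idb, "segmental", evidence=hit.block_id,
            ))
        else:
            events.append(DuplicationEvent(ida, idb, "unclassified"))
    return events
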