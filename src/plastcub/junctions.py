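"""Quadripartite partition detection and IR/SC junction gene placement.

A typical plastome is a circle of four regions — large single copy (LSC),
inverted repeat b (IRb), small single copy (SSC), inverted repeat a (IRa)
— where IRa is the reverse complement of IRb. The four junctions are
named JLB (LSC|IRb), JSB (IRb|SSC), JSA (SSC|IRa) and JLA (IRa|LSC).

Detection is seed-and-extend on exact 25-mers shared between the forward
sequence and its reverse complement: seed hits on a common anti-diagonal
are merged into maximal near-exact blocks (mismatch tolerance 0.1%, ends
trimmed to the last exactly matching base), and the top-scoring
non-overlapping pair defines the two IRs. Long near-identical plastome
IRs make exact-seed matching sufficient without a heavyweight aligner.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from ._genetics import revcomp
from .io import GeneModel, PlastomeRecord

__all__ = [
    "PartitionMap",
    "JunctionGeneRow",
    "detect_partition",
    "junction_gene_overlaps",
    "canonical_sequence",
]

JUNCTION_NAMES = ("JLB", "JSB", "JSA", "JLA")
REGION_ORDER = ("LSC", "IRb", "SSC", "IRa")

DEFAULT_JUNCTION_GENES = ("rps19", "rpl2", "ycf1", "ndhF", "trnH")


class NoQuadripartiteStructure(ValueError):
    """Raised when no inverted-repeat pair of sufficient length is found."""


@dataclass
class PartitionMap:
    """Quadripartite partition in the input sequence's coordinate frame.

    Regions are circular intervals (start, length); ``start`` is in
    [0, n). Region labels follow the forward reading direction of the
    input: IRb is the inverted-repeat copy that follows the LSC.
    """

    n: int
    regions: dict[str, tuple[int, int]]  # name -> (start, length)

    def __post_init__(self) -> None:
        if set(self.regions) != set(REGION_ORDER):
            raise ValueError("partition must contain exactly LSC, IRb, SSC, IRa")
        if sum(l for _, l in self.regions.values()) != self.n:
            raise ValueError("regions must tile the genome exactly")

    @property
    def lsc_length(self) -> int:
        return self.regions["LSC"][1]

    @property
    def ssc_length(self) -> int:
        return self.regions["SSC"][1]

    @property
    def ir_length(self) -> int:
        return self.regions["IRb"][1]

    @property
    def junctions(self) -> dict[str, int]:
        """Junction coordinates (input frame): each is the first base of
        the downstream region."""
        s_lsc, l_lsc = self.regions["LSC"]
        s_irb, l_irb = self.regions["IRb"]
        s_ssc, l_ssc = self.regions["SSC"]
        s_ira, l_ira = self.regions["IRa"]
        return {
            "JLB": (s_lsc + l_lsc) % self.n,
            "JSB": (s_irb + l_irb) % self.n,
            "JSA": (s_ssc + l_ssc) % self.n,
            "JLA": (s_ira + l_ira) % self.n,
        }

    def region_of(self, pos: int) -> str:
        pos %= self.n
        for name, (s, l) in self.regions.items():
            rel = (pos - s) % self.n
            if rel < l:
                return name
        raise AssertionError("unreachable: regions tile the circle")


@dataclass
class JunctionGeneRow:
    taxon: str
    junction: str
    gene: str
    value: int  # signed distance, or part length when straddling
    side: str   # region name; "absent" when the gene is missing
    status: str = "ok"


def _circular_kmers(seq: str, k: int) -> dict[str, list[int]]:
    n = len(seq)
    doubled = seq + seq[: k - 1]
    index: dict[str, list[int]] = {}
    for i in range(n):
        kmer = doubled[i : i + k]
        if "N" in kmer:
            continue
        index.setdefault(kmer, []).append(i)
    return index


def _maximal_runs(positions: list[int], n: int, k: int) -> list[tuple[int, int]]:
    """Merge sorted seed positions on one diagonal into maximal runs.

    Returns (start, length) runs on the circle, merging a wrap-around run
    across position 0.
    """
    runs: list[tuple[int, int]] = []  # (first seed, last seed) consecutive blocks
    positions = sorted(set(positions))
    start = prev = positions[0]
    for p in positions[1:]:
        if p == prev + 1:
            prev = p
        else:
            runs.append((start, prev))
            start = prev = p
    runs.append((start, prev))
    # a run ending at seed n-1 continues circularly into one starting at 0
    if len(runs) > 1 and runs[0][0] == 0 and runs[-1][1] == n - 1:
        first_a, first_b = runs.pop(0)
        last_a, _ = runs.pop()
        runs.append((last_a, first_b + n))
    return [(a % n, b - a + k) for a, b in runs]


def _bridge_runs(
    runs: list[tuple[int, int]], max_mismatch_rate: float
) -> list[tuple[int, int]]:
    """Merge same-diagonal runs across short gaps while the total mismatch
    rate (gap bases counted as mismatches) stays within tolerance. Ends
    remain exact-match bounded."""
    if len(runs) <= 1:
        return runs
    runs = sorted(runs)
    merged = [runs[0]]
    for s, l in runs[1:]:
        ps, pl = merged[-1]
        gap = s - (ps + pl)
        if 0 < gap and gap <= max_mismatch_rate * (s + l - ps):
            merged[-1] = (ps, s + l - ps)
        else:
            merged.append((s, l))
    return merged


def _intervals_disjoint(a: tuple[int, int], b: tuple[int, int], n: int) -> bool:
    sa, la = a
    sb, lb = b
    rel = (sb - sa) % n
    if rel < la:
        return False
    rel2 = (sa - sb) % n
    return rel2 >= lb


def detect_partition(
    sequence: str, min_ir_length: int = 1000, k: int = 25,
    max_mismatch_rate: float = 0.001,
) -> PartitionMap:
    """Locate the quadripartite LSC/IRb/SSC/IRa partition of a circular
    plastome sequence.

    Finds the longest pair of disjoint inverted repeats of at least
    ``min_ir_length`` and labels the longer single-copy gap LSC.
    """
    seq = sequence.upper()
    n = len(seq)
    if n < 4 * min_ir_length:
        raise NoQuadripartiteStructure(
            f"sequence ({n} bp) shorter than 4 x min_ir_length ({min_ir_length} bp)"
        )
    rc = revcomp(seq)
    rc_index = _circular_kmers(rc, k)
    fwd_doubled = seq + seq[: k - 1]

    # seed positions grouped by diagonal d = (i - p) mod n
    diagonals: dict[int, list[int]] = {}
    for i in range(n):
        kmer = fwd_doubled[i : i + k]
        for p in rc_index.get(kmer, ()):
            diagonals.setdefault((i - p) % n, []).append(i)

    best: tuple[int, tuple[int, int], tuple[int, int]] | None = None
    for d, seeds in diagonals.items():
        runs = _bridge_runs(_maximal_runs(seeds, n, k), max_mismatch_rate)
        for s, l in runs:
            if l < min_ir_length:
                continue
            p = (s - d) % n
            # R[p : p+l] == revcomp(S[n-p-l : n-p])
            partner = ((n - p - l) % n, l)
            if not _intervals_disjoint((s, l), partner, n):
                continue
            if best is None or l > best[0]:
                best = (l, (s, l), partner)
    if best is None:
        raise NoQuadripartiteStructure(
            f"no inverted-repeat pair >= {min_ir_length} bp found"
        )

    _, ir1, ir2 = best
    # single-copy gaps between the two IR copies
    (s1, l1), (s2, l2) = ir1, ir2
    gap_a = ((s1 + l1) % n, (s2 - s1 - l1) % n)       # after ir1, before ir2
    gap_b = ((s2 + l2) % n, (s1 - s2 - l2) % n)       # after ir2, before ir1
    if gap_a[1] >= gap_b[1]:
        lsc, ssc = gap_a, gap_b
        irb, ira = ir2, ir1    # IR following the LSC is IRb
    else:
        lsc, ssc = gap_b, gap_a
        irb, ira = ir1, ir2
    return PartitionMap(
        n=n, regions={"LSC": lsc, "IRb": irb, "SSC": ssc, "IRa": ira}
    )


def canonical_sequence(sequence: str, partition: PartitionMap | None = None,
                       min_ir_length: int = 1000) -> str:
    """Strand- and rotation-canonical representation of a plastome circle.

    Rotates the sequence so the LSC starts at coordinate 0 (order
    LSC-IRb-SSC-IRa); of the two strand representatives the
    lexicographically smaller string is returned, making the result
    invariant to rotation and full reverse complement of the input.
    """
    seq = sequence.upper()

    def rotated(s: str) -> str:
        part = detect_partition(s, min_ir_length=min_ir_length)
        start = part.regions["LSC"][0]
        return s[start:] + s[:start]

    fwd = rotated(seq if partition is None else _rotate_from(seq, partition))
    rev = rotated(revcomp(seq))
    return min(fwd, rev)


def _rotate_from(seq: str, partition: PartitionMap) -> str:
    start = partition.regions["LSC"][0]
    return seq[start:] + seq[:start]


def _gene_hull(gene: GeneModel, n: int) -> tuple[int, int]:
    """Smallest circular interval (start, length) covering all spans."""
    spans = sorted((s % n, e - s) for s, e in gene.spans)
    # try each span start as the anchor; pick the tightest cover
    best: tuple[int, int] | None = None
    for s0, _ in spans:
        end_rel = max(((s % n) - s0) % n + l for s, l in spans)
        if best is None or end_rel < best[1]:
            best = (s0, end_rel)
    assert best is not None
    return best


def junction_gene_overlaps(
    record: PlastomeRecord,
    partition: PartitionMap,
    genes_of_interest: Sequence[str] = DEFAULT_JUNCTION_GENES,
) -> list[JunctionGeneRow]:
    """Placement of named genes relative to the four junctions.

    A gene straddling a junction yields one row per side whose part
    lengths are positive and sum to the gene length; a gene wholly inside
    a region yields one row for its nearest junction with a signed
    distance (negative = the gene ends before the junction, positive =
    it starts after). Missing genes yield a row with status "absent".
    """
    n = partition.n
    junctions = partition.junctions
    rows: list[JunctionGeneRow] = []
    by_name: dict[str, GeneModel] = {}
    for g in record.genes:
        if g.name not in by_name or (by_name[g.name].is_ir_copy and not g.is_ir_copy):
            by_name[g.name] = g

    for name in genes_of_interest:
        gene = by_name.get(name)
        if gene is None:
            rows.append(JunctionGeneRow(record.taxon_label, "", name, 0, "absent", "absent"))
            continue
        g0, length = _gene_hull(gene, n)

        straddled = []
        for jname, j in junctions.items():
            rel = (j - g0) % n  # junction position relative to gene start
            if 0 < rel < length:
                straddled.append((jname, j, rel))
        if straddled:
            for jname, j, rel in straddled:
                before_region = partition.region_of((j - 1) % n)
                after_region = partition.region_of(j % n)
                rows.append(JunctionGeneRow(record.taxon_label, jname, name, rel, before_region))
                rows.append(JunctionGeneRow(record.taxon_label, jname, name, length - rel, after_region))
            continue

        # wholly inside one region: signed distance to the nearest junction
        best_row: JunctionGeneRow | None = None
        best_abs = None
        side = partition.region_of(g0)
        for jname, j in junctions.items():
            gap_before = (j - (g0 + length)) % n  # gene ends this far before j
            gap_after = (g0 - j) % n              # gene starts this far after j
            cand = -gap_before if gap_before <= gap_after else gap_after
            if best_abs is None or abs(cand) < best_abs:
                best_abs = abs(cand)
                best_row = JunctionGeneRow(record.taxon_label, jname, name, cand, side)
        assert best_row is not None
        rows.append(best_row)
    return rows
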