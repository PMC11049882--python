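"""Plastome record I/O and coding-sequence extraction.

Reads annotated plastomes from GenBank flat files into lightweight records
(0-based half-open coordinates internally; 1-based inclusive only at the
GenBank boundary), writes FASTA/GenBank, and extracts analysis-ready CDS
sets under the four-criteria filter (length >= 300 bp and divisible by 3,
valid start, valid stop, no internal stop).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from ._genetics import STOP_CODONS, revcomp

logger = logging.getLogger(__name__)

GENE_CATEGORIES = ("PCG", "tRNA", "rRNA", "pseudogene")

#: fraction of N-containing codons above which a gene is excluded outright
MAX_AMBIGUOUS_CODON_FRACTION = 0.05


@dataclass
class GeneModel:
    """One gene: spans are 0-based half-open on the forward strand, stored
    in transcription order (descending genome order for minus-strand genes,
    wrapping the origin where the annotation does)."""

    name: str
    category: str
    spans: list[tuple[int, int]]
    strand: str = "+"
    is_ir_copy: bool = False

    def __post_init__(self) -> None:
        if self.category not in GENE_CATEGORIES:
            raise ValueError(f"unknown gene category {self.category!r}")
        if not self.spans:
            raise ValueError(f"gene {self.name}: empty span list")
        if self.strand not in "+-":
            raise ValueError(f"gene {self.name}: strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.spans)

    def splice(self, sequence: str) -> str:
        """Spliced, strand-corrected gene sequence."""
        parts = [sequence[s:e] for s, e in self.spans]
        if self.strand == "-":
            return "".join(revcomp(p) for p in parts)
        return "".join(parts)


@dataclass
class PlastomeRecord:
    """A single taxon's plastome: forward-strand sequence plus gene models."""

    taxon_label: str
    sequence: str
    genes: list[GeneModel] = field(default_factory=list)
    source: str = ""

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError(f"{self.taxon_label}: empty sequence")
        n = len(self.sequence)
        for g in self.genes:
            for s, e in g.spans:
                if not (0 <= s < e <= n):
                    raise ValueError(
                        f"{self.taxon_label}/{g.name}: span ({s},{e}) outside [0,{n})"
                    )

    def __len__(self) -> int:
        return len(self.sequence)

    def genes_by_category(self, category: str) -> list[GeneModel]:
        return [g for g in self.genes if g.category == category]


@dataclass
class CdsFilterPolicy:
    """The four-criteria CDS filter used for codon-usage analysis."""

    min_length: int = 300
    require_triplet: bool = True
    valid_starts: frozenset[str] = frozenset({"ATG"})
    valid_stops: frozenset[str] = frozenset({"TAA", "TAG", "TGA"})
    forbid_internal_stops: bool = True

    def __post_init__(self) -> None:
        if self.min_length < 3:
            raise ValueError("min_length must be >= 3")
        if not self.valid_starts or not self.valid_stops:
            raise ValueError("start/stop codon sets must be non-empty")
        self.valid_starts = frozenset(c.upper() for c in self.valid_starts)
        self.valid_stops = frozenset(c.upper() for c in self.valid_stops)


@dataclass
class CdsRecord:
    """An in-frame coding sequence that passed the filter."""

    name: str
    sequence: str
    taxon: str = ""


class PlastomeParseError(ValueError):
    """Raised when a GenBank record cannot be interpreted."""


_CATEGORY_BY_FEATURE = {"CDS": "PCG", "tRNA": "tRNA", "rRNA": "rRNA"}


def _feature_name(feat: SeqFeature, index: int) -> str:
    for key in ("gene", "locus_tag", "product"):
        if key in feat.qualifiers:
            return str(feat.qualifiers[key][0])
    return f"feature_{index}"


def read_genbank(path: str | Path, taxon_label: str | None = None) -> PlastomeRecord:
    """Read one GenBank flat file into a :class:`PlastomeRecord`.

    CDS/tRNA/rRNA features become gene models; compound ``join`` locations
    are preserved as multi-span models (including spans that wrap the origin
    of a circular record); reverse-strand features keep ``strand='-'`` with
    the sequence stored forward.
    """
    path = Path(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            rec = SeqIO.read(str(path), "genbank")
        except Exception as exc:  # pragma: no cover - biopython message varies
            raise PlastomeParseError(f"{path}: cannot parse GenBank file: {exc}") from exc
    seq = str(rec.seq).upper()
    if not seq:
        raise PlastomeParseError(f"{path}: record {rec.id} has an empty sequence")

    genes: list[GeneModel] = []
    for i, feat in enumerate(rec.features):
        if feat.type not in _CATEGORY_BY_FEATURE:
            continue
        name = _feature_name(feat, i)
        if feat.location is None:
            raise PlastomeParseError(f"{path}: feature {name!r} has no location")
        category = _CATEGORY_BY_FEATURE[feat.type]
        if "pseudo" in feat.qualifiers or "pseudogene" in feat.qualifiers:
            category = "pseudogene"
        spans = [(int(p.start), int(p.end)) for p in feat.location.parts]
        strand = "-" if feat.location.strand == -1 else "+"
        genes.append(GeneModel(name=name, category=category, spans=spans, strand=strand))

    _flag_ir_copies(genes)
    label = taxon_label or rec.annotations.get("organism") or rec.id
    return PlastomeRecord(taxon_label=label, sequence=seq, genes=genes, source=str(path))


def _flag_ir_copies(genes: list[GeneModel]) -> None:
    """Mark second and later occurrences of a (name, category) as IR copies."""
    seen: set[tuple[str, str]] = set()
    for g in genes:
        key = (g.name, g.category)
        if key in seen:
            g.is_ir_copy = True
        else:
            seen.add(key)


def write_genbank(record: PlastomeRecord, path: str | Path) -> None:
    """Write a record back to GenBank (round-trips spans and sequence)."""
    seqrec = SeqRecord(Seq(record.sequence), id=record.taxon_label.replace(" ", "_")[:16],
                       name=record.taxon_label.replace(" ", "_")[:16],
                       description=record.taxon_label)
    seqrec.annotations["molecule_type"] = "DNA"
    seqrec.annotations["topology"] = "circular"
    seqrec.annotations["organism"] = record.taxon_label
    ftype = {v: k for k, v in _CATEGORY_BY_FEATURE.items()}
    for g in record.genes:
        strand = -1 if g.strand == "-" else 1
        locs = [SimpleLocation(s, e, strand=strand) for s, e in g.spans]
        loc = locs[0] if len(locs) == 1 else CompoundLocation(locs)
        quals = {"gene": [g.name]}
        if g.category == "pseudogene":
            feat = SeqFeature(loc, type="CDS", qualifiers={**quals, "pseudo": [""]})
        else:
            feat = SeqFeature(loc, type=ftype[g.category], qualifiers=quals)
        seqrec.features.append(feat)
    SeqIO.write([seqrec], str(path), "genbank")


def write_fasta(entries: Iterable[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    """Write (header, sequence) pairs as FASTA wrapped at ``width`` columns."""
    with open(path, "w") as fh:
        for header, seq in entries:
            fh.write(f">{header}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA into (header, uppercase sequence) pairs."""
    return [(r.description, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]


def write_cds_fasta(cds_set: Sequence[CdsRecord], path: str | Path) -> None:
    """Export a CDS set as multi-FASTA with ``>taxon|gene`` headers."""
    write_fasta(((f"{c.taxon}|{c.name}", c.sequence) for c in cds_set), path)


def _ambiguous_codon_fraction(seq: str) -> float:
    codons = [seq[i : i + 3] for i in range(0, len(seq) - len(seq) % 3, 3)]
    if not codons:
        return 0.0
    bad = sum(1 for c in codons if any(b not in "ACGT" for b in c))
    return bad / len(codons)


def passes_filter(seq: str, policy: CdsFilterPolicy) -> bool:
    """Apply the four filter criteria to one spliced coding sequence."""
    if len(seq) < policy.min_length:
        return False
    if policy.require_triplet and len(seq) % 3 != 0:
        return False
    if len(seq) % 3 != 0:
        # cannot assess codon structure out of frame
        return False
    if seq[:3] not in policy.valid_starts:
        return False
    if seq[-3:] not in policy.valid_stops:
        return False
    if policy.forbid_internal_stops:
        for i in range(3, len(seq) - 3, 3):
            if seq[i : i + 3] in STOP_CODONS:
                return False
    return True


def extract_filtered_cds(
    record: PlastomeRecord, policy: CdsFilterPolicy | None = None
) -> list[CdsRecord]:
    """Spliced, strand-corrected coding sequences passing all filter criteria.

    IR-duplicated genes are analyzed once (deduplicated by name, first copy
    kept). Genes whose codons contain >5% ambiguous (N) characters are
    excluded with a logged warning; downstream codon counting drops any
    remaining N-containing codons.
    """
    policy = policy or CdsFilterPolicy()
    out: list[CdsRecord] = []
    seen: set[str] = set()
    for gene in record.genes_by_category("PCG"):
        if gene.name in seen:
            continue
        seen.add(gene.name)
        seq = gene.splice(record.sequence)
        if _ambiguous_codon_fraction(seq) > MAX_AMBIGUOUS_CODON_FRACTION:
            logger.warning(
                "%s/%s excluded: >%.0f%% ambiguous codons",
                record.taxon_label, gene.name, 100 * MAX_AMBIGUOUS_CODON_FRACTION,
            )
            continue
        if passes_filter(seq, policy):
            out.append(CdsRecord(name=gene.name, sequence=seq, taxon=record.taxon_label))
    return out
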