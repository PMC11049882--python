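"""Synthetic plastome families with known ground truth.

The generator emulates the structures the analysis modules consume: a
circular quadripartite genome (LSC + IRb + SSC + IRa, with IRa the exact
reverse complement of IRb), protein-coding genes with a controllable
per-family codon-bias model, genes straddling IR/SC junctions with a
configurable overhang, and taxa evolved along a known tree under
Jukes-Cantor substitution with regional rate hotspots. IR copies
co-evolve: every substitution accepted in IRb is mirrored into IRa, so
the quadripartite invariant holds in every taxon. Indels are off, so the
taxon sequences ARE the true alignment and window coordinates are exact.

Codon bias model: within each synonymous family, codon probabilities are
proportional to weights w(c) = t(c) * b(c), where t(c) is gc3_target for
G/C-ending codons and 1 - gc3_target otherwise, and b(c) is the
preferred-codon boost (codon_weight, times high_bias_weight in the
high-bias gene subset). Expected RSCU is then k * w(c) / sum(w) in
closed form, giving analytic recovery targets.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np

from ._genetics import (
    AA_TO_CODONS,
    DEGENERACY,
    STOP_CODONS,
    SYNONYMOUS_AAS,
    revcomp,
)
from .diversity import Alignment
from .io import GeneModel, PlastomeRecord, write_fasta, write_genbank
from .junctions import PartitionMap

__all__ = ["SimConfig", "SyntheticTruth", "generate_family", "truth_report"]

_AAS = tuple(sorted(AA_TO_CODONS))  # 20 amino acids, fixed order
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


class SimConfigError(ValueError):
    """Infeasible simulation layout or invalid parameter."""


@dataclass
class SimConfig:
    """Generator parameters; defaults give the 20-kb mini test scale.

    ``genome_size=150_000`` with ``ir_length=25_000``, ``ssc_length=17_000``
    and more genes approximates a full-scale plastome.
    """

    seed: int = 0
    n_taxa: int = 4
    genome_size: int = 20_000
    ir_length: int = 4_000
    ssc_length: int = 2_000
    n_genes: int = 12
    gene_length_range: tuple[int, int] = (300, 900)
    gc3_target: float = 0.30
    gc3_jitter: float = 0.08
    preferred_codons: tuple[str, ...] = ()
    codon_weight: float = 1.0
    high_bias_weight: float = 1.0
    high_bias_fraction: float = 0.0
    high_bias_gc3: float | None = None
    aa_alpha: float = 5.0
    tree: str | None = None
    branch_length: float = 0.005
    hotspots: tuple[tuple[int, int, float], ...] = ()
    junction_genes: tuple[tuple[str, str, int], ...] = (("rps19", "JLB", 110),)
    junction_gene_length: int = 279
    ir_gene: bool = True
    intergenic_gc: float = 0.35
    minus_strand_fraction: float = 0.25

    def validate(self) -> None:
        if self.ir_length * 2 + self.ssc_length >= self.genome_size:
            raise SimConfigError("IRs + SSC do not leave room for an LSC")
        lsc = self.genome_size - 2 * self.ir_length - self.ssc_length
        if lsc < self.ssc_length:
            raise SimConfigError("LSC must be at least as long as SSC")
        lo, hi = self.gene_length_range
        if lo < 9 or hi < lo:
            raise SimConfigError("bad gene_length_range")
        if not 0.0 < self.gc3_target < 1.0:
            raise SimConfigError("gc3_target must be in (0, 1)")
        if self.codon_weight < 1.0 or self.high_bias_weight < 1.0:
            raise SimConfigError("codon weights must be >= 1")
        for name, junction, overhang in self.junction_genes:
            if junction not in ("JLB", "JSA"):
                raise SimConfigError(f"{name}: junction must be JLB or JSA")
            if not 0 < overhang < self.junction_gene_length:
                raise SimConfigError(f"{name}: overhang must be < gene length")
        for s, e, m in self.hotspots:
            if m < 0:
                raise SimConfigError("hotspot rate multipliers must be >= 0")
            if not 0 <= s < e <= self.genome_size:
                raise SimConfigError(f"hotspot ({s},{e}) outside genome")


@dataclass
class SyntheticTruth:
    """Everything the generator knows: the recovery targets for tests."""

    config: SimConfig
    ancestral_sequence: str
    records: list[PlastomeRecord]
    alignment: Alignment
    partition: PartitionMap
    genes: list[GeneModel]
    gene_bias: dict[str, dict]          # gene -> {gc3, boosted codons, weight}
    gene_codon_tally: dict[str, dict]   # gene -> ancestral codon counts
    tree_newick: str
    hotspots: list[tuple[int, int, float]]
    junction_overhangs: dict[str, int]

    def expected_rscu(self, gene: str, codon: str) -> float:
        """Closed-form expected RSCU of ``codon`` under the gene's weights."""
        bias = self.gene_bias[gene]
        aa = next(a for a in SYNONYMOUS_AAS if codon in AA_TO_CODONS[a])
        weights = [
            _codon_weight(c, bias["gc3"], set(bias["boosted"]), bias["weight"])
            for c in AA_TO_CODONS[aa]
        ]
        w = _codon_weight(codon, bias["gc3"], set(bias["boosted"]), bias["weight"])
        return DEGENERACY[aa] * w / sum(weights)


def _codon_weight(codon: str, gc3: float, boosted: set[str], boost: float) -> float:
    w = gc3 if codon[2] in "GC" else 1.0 - gc3
    if codon in boosted:
        w *= boost
    return w


def _sample_gene_codons(
    rng: np.random.Generator, n_body: int, gc3: float,
    boosted: set[str], boost: float, aa_probs: np.ndarray,
) -> list[str]:
    aas = rng.choice(len(_AAS), size=n_body, p=aa_probs)
    codons: list[str] = []
    for ai in aas:
        family = AA_TO_CODONS[_AAS[ai]]
        w = np.array([_codon_weight(c, gc3, boosted, boost) for c in family])
        codons.append(family[rng.choice(len(family), p=w / w.sum())])
    return codons


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])


class _GeneSite:
    """Per-gene map local index -> genome position, for codon checks."""

    def __init__(self, gene: GeneModel):
        self.gene = gene
        positions: list[int] = []
        for s, e in gene.spans:
            positions.extend(range(s, e))
        if gene.strand == "-":
            positions = positions[::-1]
        self.positions = positions            # local transcription order
        self.local_of = {p: i for i, p in enumerate(positions)}

    def codon_ok_after(self, genome: list[str], site: int, new_base: str) -> bool:
        """Would mutating ``site`` keep start/stop intact and introduce no
        internal stop?"""
        local = self.local_of[site]
        n_codons = len(self.positions) // 3
        ci = local // 3
        if ci == 0 or ci == n_codons - 1:
            return False  # protect start and stop codons
        bases = []
        for li in range(3 * ci, 3 * ci + 3):
            p = self.positions[li]
            b = new_base if p == site else genome[p]
            bases.append(_COMP[b] if self.gene.strand == "-" else b)
        return "".join(bases) not in STOP_CODONS


def generate_family(
    config: SimConfig, outdir: str | Path | None = None
) -> SyntheticTruth:
    """Build an ancestral quadripartite plastome, evolve a taxon family
    along the tree, and return the full ground truth.

    When ``outdir`` is given, writes per-taxon GenBank and FASTA, the true
    alignment as aligned FASTA, and the JSON truth manifest.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.genome_size
    lsc_len = n - 2 * config.ir_length - config.ssc_length
    lsc = (0, lsc_len)
    irb = (lsc_len, config.ir_length)
    ssc = (lsc_len + config.ir_length, config.ssc_length)
    ira = (lsc_len + config.ir_length + config.ssc_length, config.ir_length)
    partition = PartitionMap(n=n, regions={"LSC": lsc, "IRb": irb, "SSC": ssc, "IRa": ira})
    jlb = irb[0]
    jsa = ira[0]

    # plan the interior gene layout first so an infeasible configuration
    # fails before any sequence sampling
    n_high = math.ceil(config.high_bias_fraction * config.n_genes)
    lo, hi = config.gene_length_range
    reserved_lsc_tail = max(
        (config.junction_gene_length for _ in config.junction_genes), default=0
    ) + 50
    layout_rng = np.random.default_rng(config.seed + 1)
    lengths = []
    for gi in range(config.n_genes):
        length_nt = int(layout_rng.integers(lo, hi + 1))
        length_nt -= length_nt % 3
        if gi == config.n_genes - 1 and length_nt > config.ssc_length - 200:
            length_nt = (config.ssc_length - 200) - (config.ssc_length - 200) % 3
        lengths.append(length_nt)
    lsc_lengths = lengths[:-1]  # the last interior gene sits in the SSC
    lsc_limit = lsc_len - reserved_lsc_tail
    if 200 + sum(lsc_lengths) + 50 * len(lsc_lengths) > lsc_limit:
        raise SimConfigError(
            f"gene layout infeasible: {config.n_genes} genes of {lo}-{hi} bp "
            f"do not fit the {lsc_len} bp LSC"
        )
    layout: list[tuple[str, int, int, str, bool]] = []
    cursor = 200
    for gi, length_nt in enumerate(lengths):
        high_bias = gi < n_high
        if gi == config.n_genes - 1:
            start = lsc_len + config.ir_length + 100
        else:
            start = cursor
            cursor += length_nt
            remaining = lsc_lengths[gi + 1 :]
            gap_max = lsc_limit - cursor - (sum(remaining) + 50 * len(remaining))
            gap = min(50 + int(layout_rng.integers(0, 151)), gap_max)
            cursor += gap
        strand = "-" if layout_rng.random() < config.minus_strand_fraction else "+"
        layout.append((f"gene{gi + 1:02d}", length_nt, start, strand, high_bias))

    genome = list(_random_bases(rng, n, config.intergenic_gc))

    genes: list[GeneModel] = []
    gene_bias: dict[str, dict] = {}
    gene_tally: dict[str, dict] = {}
    junction_overhangs: dict[str, int] = {}

    def make_gene(name: str, length_nt: int, start: int, strand: str,
                  boosted: set[str], boost: float,
                  high_bias: bool = False) -> GeneModel:
        base_gc3 = (
            config.high_bias_gc3
            if high_bias and config.high_bias_gc3 is not None
            else config.gc3_target
        )
        gc3 = float(np.clip(
            base_gc3 + rng.uniform(-config.gc3_jitter, config.gc3_jitter),
            0.02, 0.98,
        ))
        aa_probs = rng.dirichlet(np.full(len(_AAS), config.aa_alpha))
        body = _sample_gene_codons(rng, length_nt // 3 - 2, gc3, boosted, boost, aa_probs)
        seq = "ATG" + "".join(body) + "TAA"
        tally: dict[str, int] = {"ATG": 1}
        for c in body:
            tally[c] = tally.get(c, 0) + 1
        placed = seq if strand == "+" else revcomp(seq)
        for i, b in enumerate(placed):
            genome[(start + i) % n] = b
        gene = GeneModel(name=name, category="PCG",
                         spans=_wrap_spans(start, length_nt, n), strand=strand)
        gene_bias[name] = {"gc3": gc3, "boosted": sorted(boosted), "weight": boost,
                           "high_bias": high_bias}
        gene_tally[name] = tally
        return gene

    # junction-straddling genes first: they own fixed footprints
    for name, junction, overhang in config.junction_genes:
        j = jlb if junction == "JLB" else jsa
        length_nt = config.junction_gene_length
        length_nt -= length_nt % 3
        start = (j - (length_nt - overhang)) % n
        genes.append(make_gene(name, length_nt, start, "+", set(), 1.0))
        junction_overhangs[name] = overhang

    # interior genes: most in the LSC, one in the SSC
    for name, length_nt, start, strand, high_bias in layout:
        boosted = set(config.preferred_codons)
        boost = config.codon_weight * (config.high_bias_weight if high_bias else 1.0)
        genes.append(make_gene(name, length_nt, start, strand,
                               boosted, boost, high_bias=high_bias))

    if config.ir_gene:
        length_nt = 300
        start = irb[0] + config.ir_length // 2
        primary = make_gene("irpcg1", length_nt, start, "+", set(), 1.0)
        genes.append(primary)

    # enforce the quadripartite invariant IRa == revcomp(IRb): bases a
    # junction gene wrote into the IRa overhang are first mirrored back
    # into IRb, then the whole IRa is rebuilt from IRb
    def _mirror_of(p: int) -> int:
        return irb[0] + irb[1] - 1 - (p - ira[0])

    ira_gene_sites = [
        p for g in genes if not g.is_ir_copy
        for s, e in g.spans for p in range(s, e)
        if ira[0] <= p < ira[0] + ira[1]
    ]
    for p in ira_gene_sites:
        genome[_mirror_of(p)] = _COMP[genome[p]]
    irb_seq = "".join(genome[irb[0] : irb[0] + irb[1]])
    genome[ira[0] : ira[0] + ira[1]] = list(revcomp(irb_seq))

    # break accidental one-base IR extensions so the planted junction
    # coordinates are exactly the maximal-repeat boundaries: the IR pair
    # would extend iff base(JLB-1) pairs with base(0) or base(JSB) pairs
    # with base(JSA-1); the intergenic member of each pair is adjusted
    boundary_fixed: list[int] = []
    for free, partner in ((0, (jlb - 1) % n), (jlb + config.ir_length, jsa - 1)):
        if genome[free] == _COMP[genome[partner]]:
            genome[free] = next(b for b in "ACGT" if b != _COMP[genome[partner]]
                                and b != genome[free])
        boundary_fixed.extend([free, partner])

    if config.ir_gene:
        # annotate the mirrored IRa copy of the IR-internal gene
        s, e = genes[-1].spans[0]
        off_end = irb[0] + irb[1] - e
        a_start = ira[0] + off_end
        genes.append(GeneModel(name="irpcg1", category="PCG",
                               spans=[(a_start, a_start + (e - s))],
                               strand="-", is_ir_copy=True))

    ancestral = "".join(genome)

    tree_newick = config.tree or (
        "(" + ",".join(
            f"taxon{i + 1:02d}:{config.branch_length}" for i in range(config.n_taxa)
        ) + ");"
    )
    tree = dendropy.Tree.get(data=tree_newick, schema="newick",
                             preserve_underscores=True)

    mult = np.ones(n)
    for s, e, m in config.hotspots:
        mult[s:e] = m
    # IRa sites co-evolve with IRb and are never mutated independently;
    # IRb sites whose mirror falls inside a gene annotated in IRa are kept
    # fixed so the mirrored copy cannot silently break a coding constraint
    mutable = np.ones(n, dtype=bool)
    mutable[ira[0] : ira[0] + ira[1]] = False
    for p in ira_gene_sites:
        mutable[_mirror_of(p)] = False
    # junction-flanking bases stay fixed so planted IR boundaries remain
    # the maximal-repeat boundaries in every taxon
    mutable[boundary_fixed] = False

    site_maps: dict[int, _GeneSite] = {}
    for g in genes:
        if g.is_ir_copy:
            continue
        gs = _GeneSite(g)
        for p in gs.positions:
            site_maps[p] = gs

    def evolve(seq: list[str], bl: float) -> list[str]:
        child = list(seq)
        if bl <= 0:
            return child
        p_sub = 0.75 * (1.0 - np.exp(-(4.0 / 3.0) * bl * mult))
        hits = np.flatnonzero((rng.random(n) < p_sub) & mutable)
        for site in hits:
            site = int(site)
            current = child[site]
            alt = [b for b in "ACGT" if b != current]
            new_base = alt[int(rng.integers(3))]
            gs = site_maps.get(site)
            if gs is not None and not gs.codon_ok_after(child, site, new_base):
                continue  # rejected: would break the coding constraint
            child[site] = new_base
        irb_now = "".join(child[irb[0] : irb[0] + irb[1]])
        child[ira[0] : ira[0] + ira[1]] = list(revcomp(irb_now))
        return child

    seqs: dict[int, list[str]] = {id(tree.seed_node): list(ancestral)}
    taxa_seqs: dict[str, str] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent_seq = seqs[id(node.parent_node)]
        bl = node.edge.length or 0.0
        child_seq = evolve(parent_seq, bl)
        if node.is_leaf():
            taxa_seqs[node.taxon.label] = "".join(child_seq)
        else:
            seqs[id(node)] = child_seq

    taxa = sorted(taxa_seqs)
    records = [
        PlastomeRecord(taxon_label=t, sequence=taxa_seqs[t],
                       genes=[GeneModel(g.name, g.category, list(g.spans), g.strand,
                                        g.is_ir_copy) for g in genes],
                       source="simulated")
        for t in taxa
    ]
    alignment = Alignment(taxa=list(taxa), rows=[taxa_seqs[t] for t in taxa])

    truth = SyntheticTruth(
        config=config, ancestral_sequence=ancestral, records=records,
        alignment=alignment, partition=partition, genes=genes,
        gene_bias=gene_bias, gene_codon_tally=gene_tally,
        tree_newick=tree_newick, hotspots=[tuple(h) for h in config.hotspots],
        junction_overhangs=junction_overhangs,
    )
    if outdir is not None:
        _write_outputs(truth, Path(outdir))
    return truth


def _wrap_spans(start: int, length: int, n: int) -> list[tuple[int, int]]:
    start %= n
    if start + length <= n:
        return [(start, start + length)]
    return [(start, n), (0, (start + length) % n)]


def _write_outputs(truth: SyntheticTruth, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    for rec in truth.records:
        write_fasta([(rec.taxon_label, rec.sequence)], outdir / f"{rec.taxon_label}.fasta")
        write_genbank(rec, outdir / f"{rec.taxon_label}.gb")
    write_fasta(
        zip(truth.alignment.taxa, truth.alignment.rows), outdir / "alignment.fasta"
    )
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth_report(truth), fh, indent=1)


def truth_report(truth: SyntheticTruth) -> dict:
    """Machine-readable manifest of every true parameter.

    ``SimConfig(**manifest['config'])`` regenerates the family
    byte-identically.
    """
    cfg = asdict(truth.config)
    cfg["gene_length_range"] = list(cfg["gene_length_range"])
    return {
        "config": cfg,
        "n_taxa": len(truth.records),
        "taxa": [r.taxon_label for r in truth.records],
        "genome_size": len(truth.ancestral_sequence),
        "partition": {k: list(v) for k, v in truth.partition.regions.items()},
        "junctions": truth.partition.junctions,
        "genes": [
            {"name": g.name, "category": g.category, "spans": [list(s) for s in g.spans],
             "strand": g.strand, "is_ir_copy": g.is_ir_copy}
            for g in truth.genes
        ],
        "gene_bias": truth.gene_bias,
        "gene_codon_tally": truth.gene_codon_tally,
        "tree": truth.tree_newick,
        "hotspots": [list(h) for h in truth.hotspots],
        "junction_overhangs": truth.junction_overhangs,
    }
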