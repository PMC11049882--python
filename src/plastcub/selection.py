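"""Mutation-vs-selection analyses of codon usage.

Three classic diagnostics:

* **ENC plot** — observed ENC against the mutation-only expectation
  ENC* = 2 + GC3s + 29 / [GC3s^2 + (1 - GC3s)^2]; genes far below the
  curve indicate selection on codon choice.
* **Neutrality plot** — OLS regression of GC12 on GC3. The slope measures
  relative neutrality (mutation pressure, as a percentage 100*b) against
  relative constraint (selection, 100*(1 - b)); their ratio b/(1 - b)
  summarizes the balance.
* **ΔRSCU optimal codons** — pool codon counts within the lowest-ENC
  (high-bias) and highest-ENC (low-bias) gene groups; a codon is optimal
  when ΔRSCU = RSCU(high-bias) - RSCU(low-bias) exceeds the threshold
  (default 0.08) with RSCU > 1 in the high-bias group and < 1 in the
  low-bias group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from scipy import stats

from ._genetics import CODON_TO_AA
from .codon import CodonCountTable, GeneCubProfile, count_codons, rscu
from .io import CdsRecord

__all__ = [
    "NeutralityFit",
    "OptimalCodonResult",
    "enc_expected",
    "enc_plot_table",
    "neutrality_fit",
    "select_enc_groups",
    "optimal_codons",
]


@dataclass
class NeutralityFit:
    """OLS fit of GC12 on GC3 with its mutation/selection decomposition."""

    slope: float
    intercept: float
    r: float
    n_genes: int

    @property
    def neutrality_pct(self) -> float:
        return 100.0 * self.slope

    @property
    def constraint_pct(self) -> float:
        return 100.0 * (1.0 - self.slope)

    @property
    def ratio(self) -> float:
        return self.slope / (1.0 - self.slope)


@dataclass
class OptimalCodonRow:
    codon: str
    amino_acid: str
    rscu_high_bias: float
    rscu_low_bias: float
    delta_rscu: float
    is_optimal: bool


@dataclass
class OptimalCodonResult:
    high_bias_genes: list[str]
    low_bias_genes: list[str]
    rows: list[OptimalCodonRow]

    @property
    def optimal(self) -> list[str]:
        return [r.codon for r in self.rows if r.is_optimal]


def enc_expected(gc3s: float) -> float:
    """Mutation-drift expectation of ENC at a given GC3s.

    ENC* = 2 + s + 29 / (s^2 + (1 - s)^2) for s in [0, 1].
    """
    if not 0.0 <= gc3s <= 1.0:
        raise ValueError(f"gc3s must lie in [0, 1], got {gc3s}")
    return 2.0 + gc3s + 29.0 / (gc3s**2 + (1.0 - gc3s) ** 2)


def enc_plot_table(profiles: Sequence[GeneCubProfile]) -> list[dict]:
    """Per-gene ENC-plot rows; ``below_curve`` uses strict enc < enc*."""
    rows = []
    for p in profiles:
        if math.isnan(p.enc) or math.isnan(p.gc3s):
            continue
        expected = enc_expected(p.gc3s)
        rows.append(
            {
                "gene": p.gene,
                "taxon": p.taxon,
                "gc3s": p.gc3s,
                "enc": p.enc,
                "enc_expected": expected,
                "deviation": expected - p.enc,
                "below_curve": p.enc < expected,
            }
        )
    return rows


def fraction_below_curve(rows: Sequence[dict]) -> float:
    if not rows:
        return math.nan
    return sum(r["below_curve"] for r in rows) / len(rows)


def neutrality_fit(profiles: Sequence[GeneCubProfile]) -> NeutralityFit:
    """Ordinary least squares of GC12 on GC3 across genes."""
    pts = [
        (p.gc3, p.gc12)
        for p in profiles
        if not (math.isnan(p.gc3) or math.isnan(p.gc12))
    ]
    if len(pts) < 3:
        raise ValueError(f"neutrality fit needs >= 3 genes, got {len(pts)}")
    xs = [x for x, _ in pts]
    if max(xs) == min(xs):
        raise ValueError("neutrality fit degenerate: all GC3 values equal")
    res = stats.linregress(xs, [y for _, y in pts])
    return NeutralityFit(
        slope=float(res.slope), intercept=float(res.intercept),
        r=float(res.rvalue), n_genes=len(pts),
    )


def select_enc_groups(
    profiles: Sequence[GeneCubProfile], fraction: float = 0.05
) -> tuple[list[str], list[str]]:
    """(lowest-ENC genes, highest-ENC genes), group size ceil(fraction * n).

    Ties are broken by gene name so the selection is deterministic and
    invariant to input order. Group size is at least 1 and the groups are
    disjoint.
    """
    if not 0.0 < fraction < 0.5:
        raise ValueError("fraction must lie in (0, 0.5)")
    usable = [p for p in profiles if not math.isnan(p.enc)]
    if len(usable) < 2:
        raise ValueError("need >= 2 genes with defined ENC")
    m = max(1, math.ceil(fraction * len(usable)))
    by_low = sorted(usable, key=lambda p: (p.enc, p.gene))
    by_high = sorted(usable, key=lambda p: (-p.enc, p.gene))
    low = [p.gene for p in by_low[:m]]
    high = [p.gene for p in by_high if p.gene not in low][:m]
    return low, high


def optimal_codons(
    cds_by_gene: Mapping[str, CdsRecord | Sequence[CdsRecord]],
    groups: tuple[Sequence[str], Sequence[str]],
    delta_threshold: float = 0.08,
) -> OptimalCodonResult:
    """ΔRSCU optimal-codon identification from grouped, pooled counts.

    ``groups`` is (low-ENC i.e. high-bias gene names, high-ENC i.e.
    low-bias gene names). Group RSCU is computed from POOLED codon counts,
    not averaged per-gene RSCU.
    """
    low_enc, high_enc = (list(g) for g in groups)
    if not low_enc or not high_enc:
        raise ValueError("both ENC groups must be non-empty")
    if set(low_enc) & set(high_enc):
        raise ValueError("ENC groups must be disjoint")

    def pooled(genes: Sequence[str]) -> CodonCountTable:
        cds: list[CdsRecord] = []
        for g in genes:
            entry = cds_by_gene[g]
            cds.extend([entry] if isinstance(entry, CdsRecord) else list(entry))
        table = count_codons(cds)
        if table.n_codons == 0:
            raise ValueError(f"group {genes} has no usable codons")
        return table

    rscu_high_bias = rscu(pooled(low_enc)).values
    rscu_low_bias = rscu(pooled(high_enc)).values
    rows = []
    for codon, hi in rscu_high_bias.items():
        lo = rscu_low_bias[codon]
        delta = hi - lo
        is_opt = (
            not math.isnan(delta)
            and delta > delta_threshold
            and hi > 1.0
            and lo < 1.0
        )
        rows.append(
            OptimalCodonRow(
                codon=codon, amino_acid=CODON_TO_AA[codon],
                rscu_high_bias=hi, rscu_low_bias=lo,
                delta_rscu=delta, is_optimal=is_opt,
            )
        )
    rows.sort(key=lambda r: r.codon)
    return OptimalCodonResult(high_bias_genes=low_enc, low_bias_genes=high_enc, rows=rows)
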