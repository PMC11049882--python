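"""End-to-end orchestration: CDS filter -> codon metrics -> selection
analyses -> diversity/HVRs -> junctions -> clustering, with TSV/BED/
newick/JSON outputs and a summary of the key statistics.

Floating-point values are carried at full precision internally and
rounded only at write time (4 decimal places by default).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import clustering, codon, diversity, junctions, selection
from .io import (
    CdsFilterPolicy,
    CdsRecord,
    PlastomeRecord,
    extract_filtered_cds,
    read_genbank,
    write_cds_fasta,
)

logger = logging.getLogger(__name__)

ROUND_DP = 4


class PipelineError(RuntimeError):
    """A stage failed; the message is tagged with the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Inputs, policy overrides and output location for a full run."""

    genbank_paths: list[str] = field(default_factory=list)
    alignment_path: str | None = None
    outdir: str = "plastcub_out"
    min_length: int = 300
    window_length: int = 600
    step: int = 200
    fraction: float = 0.05
    delta_threshold: float = 0.08
    min_ir_length: int = 1000
    metric: str = "euclidean"
    verbosity: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Flat key=value config file; '#' starts a comment."""
        kwargs: dict = {}
        valid = {f.name: f.type for f in fields(cls)}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise PipelineError("config", f"{path}:{lineno}: expected key=value")
            key, _, value = (x.strip() for x in line.partition("="))
            if key not in valid:
                raise PipelineError("config", f"{path}:{lineno}: unknown key {key!r}")
            if key == "genbank_paths":
                kwargs[key] = [v for v in value.split(",") if v]
            elif key in ("min_length", "window_length", "step", "min_ir_length", "verbosity"):
                kwargs[key] = int(value)
            elif key in ("fraction", "delta_threshold"):
                kwargs[key] = float(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)


def _write_tsv(rows: Sequence[dict], path: Path) -> None:
    df = pd.DataFrame(rows)
    for c in df.columns:
        if df[c].dtype == float:
            df[c] = df[c].round(ROUND_DP)
    df.to_csv(path, sep="\t", index=False)


def run_pipeline(config: RunConfig) -> dict:
    """Run every applicable stage; returns the summary dictionary.

    Writes profiles.tsv, neutrality.tsv, encplot.tsv, optimal_codons.tsv,
    rscu_ordered.tsv, nj_tree.nwk, windows.tsv + hvrs.bed (when an
    alignment is given), partition.tsv + junction report, cds.fasta and
    summary.json under ``config.outdir``.
    """
    if not config.genbank_paths:
        raise PipelineError("input", "no GenBank inputs given")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    records: list[PlastomeRecord] = []
    for p in config.genbank_paths:
        if not Path(p).exists():
            raise PipelineError("input", f"missing input file {p}")
        try:
            records.append(read_genbank(p))
        except Exception as exc:
            raise PipelineError("input", f"{p}: {exc}") from exc

    policy = CdsFilterPolicy(min_length=config.min_length)
    logger.info("cds filter policy: %s", policy)
    summary: dict = {"taxa": [r.taxon_label for r in records]}

    # ---- CDS filtering and per-gene codon metrics -----------------------
    cds_by_taxon: dict[str, list[CdsRecord]] = {}
    all_profiles: list[codon.GeneCubProfile] = []
    for rec in records:
        cds = sorted(extract_filtered_cds(rec, policy), key=lambda c: c.name)
        cds_by_taxon[rec.taxon_label] = cds
        all_profiles.extend(codon.gene_profiles(cds))
    write_cds_fasta([c for cs in cds_by_taxon.values() for c in cs], outdir / "cds.fasta")
    _write_tsv(codon.profiles_to_rows(all_profiles), outdir / "profiles.tsv")
    summary["n_cds"] = {t: len(cs) for t, cs in cds_by_taxon.items()}

    defined = [p for p in all_profiles if not math.isnan(p.enc)]
    if defined:
        pmax = max(defined, key=lambda p: p.enc)
        pmin = min(defined, key=lambda p: p.enc)
        summary["enc_max"] = {"taxon": pmax.taxon, "gene": pmax.gene, "enc": pmax.enc}
        summary["enc_min"] = {"taxon": pmin.taxon, "gene": pmin.gene, "enc": pmin.enc}

    # ---- selection analyses, per taxon ---------------------------------
    neut_rows, enc_rows, opt_rows = [], [], []
    slopes = []
    for rec in records:
        taxon = rec.taxon_label
        cds = cds_by_taxon[taxon]
        profiles = [p for p in all_profiles if p.taxon == taxon]
        enc_rows.extend(selection.enc_plot_table(profiles))
        try:
            fit = selection.neutrality_fit(profiles)
            neut_rows.append({
                "taxon": taxon, "slope": fit.slope, "intercept": fit.intercept,
                "r": fit.r, "neutrality_pct": fit.neutrality_pct,
                "constraint_pct": fit.constraint_pct, "ratio": fit.ratio,
            })
            slopes.append(fit.slope)
        except ValueError as exc:
            logger.warning("neutrality fit skipped for %s: %s", taxon, exc)
        try:
            groups = selection.select_enc_groups(profiles, fraction=config.fraction)
            result = selection.optimal_codons(
                {c.name: c for c in cds}, groups, delta_threshold=config.delta_threshold
            )
            for row in result.rows:
                opt_rows.append({
                    "taxon": taxon, "codon": row.codon, "aa": row.amino_acid,
                    "RSCU_high_bias": row.rscu_high_bias,
                    "RSCU_low_bias": row.rscu_low_bias,
                    "dRSCU": row.delta_rscu, "optimal": row.is_optimal,
                })
        except ValueError as exc:
            logger.warning("optimal codons skipped for %s: %s", taxon, exc)
    _write_tsv(neut_rows, outdir / "neutrality.tsv")
    _write_tsv(enc_rows, outdir / "encplot.tsv")
    _write_tsv(opt_rows, outdir / "optimal_codons.tsv")
    if slopes:
        summary["neutrality_slope_mean"] = float(np.mean(slopes))
        summary["neutrality_slopes"] = {r["taxon"]: r["slope"] for r in neut_rows}
    summary["optimal_codons"] = {
        t: sorted({r["codon"] for r in opt_rows if r["taxon"] == t and r["optimal"]})
        for t in cds_by_taxon
    }

    # ---- clustering -----------------------------------------------------
    if len(records) >= 2:
        pooled = {t: codon.count_codons(cs) for t, cs in cds_by_taxon.items() if cs}
        taxa, codons_, matrix = codon.rscu_matrix(pooled)
        rmat = clustering.RscuMatrix(taxa=taxa, codons=codons_, values=np.array(matrix))
        try:
            dist = clustering.rscu_distance(rmat, metric=config.metric)
            row_order, col_order = clustering.hierarchical_order(rmat)
            ordered = pd.DataFrame(
                rmat.values[np.ix_(row_order, col_order)],
                index=[taxa[i] for i in row_order],
                columns=[codons_[j] for j in col_order],
            ).round(ROUND_DP)
            ordered.to_csv(outdir / "rscu_ordered.tsv", sep="\t")
            if len(taxa) >= 3:
                tree = clustering.neighbor_joining(dist, taxa)
                (outdir / "nj_tree.nwk").write_text(tree.newick() + "\n")
                summary["nj_tree"] = tree.newick()
        except ValueError as exc:
            raise PipelineError("clustering", str(exc)) from exc

    # ---- diversity / HVRs ----------------------------------------------
    if config.alignment_path:
        try:
            aln = diversity.load_alignment(config.alignment_path)
            track = diversity.window_pi(aln, config.window_length, config.step)
            regions = diversity.call_hvrs(track)
        except Exception as exc:
            raise PipelineError("diversity", str(exc)) from exc
        _write_tsv(diversity.track_rows(track), outdir / "windows.tsv")
        diversity.hvrs_to_bed(regions, outdir / "hvrs.bed")
        summary["pi_mean"] = track.mean_pi
        summary["pi_sd"] = track.sd_pi
        summary["hvr_threshold"] = track.threshold
        summary["n_hvrs"] = len(regions)
        summary["hvr_pi_range"] = (
            [min(r.peak_pi for r in regions), max(r.peak_pi for r in regions)]
            if regions else None
        )

    # ---- junction analysis ----------------------------------------------
    part_rows, junc_rows = [], []
    ir_lengths = {}
    for rec in records:
        try:
            part = junctions.detect_partition(rec.sequence, min_ir_length=config.min_ir_length)
        except junctions.NoQuadripartiteStructure as exc:
            logger.warning("no quadripartite structure for %s: %s", rec.taxon_label, exc)
            continue
        ir_lengths[rec.taxon_label] = part.ir_length
        for name, (s, l) in part.regions.items():
            part_rows.append({"taxon": rec.taxon_label, "region": name,
                              "start": s, "end": (s + l) % part.n, "length": l})
        for row in junctions.junction_gene_overlaps(rec, part):
            junc_rows.append({"taxon": row.taxon, "junction": row.junction,
                              "gene": row.gene, "bp": row.value, "side": row.side,
                              "status": row.status})
    _write_tsv(part_rows, outdir / "partition.tsv")
    _write_tsv(junc_rows, outdir / "junctions.tsv")
    summary["ir_lengths"] = ir_lengths

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, default=float)
    return summary
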