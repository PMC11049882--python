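"""ENC plot, neutrality regression, and ΔRSCU optimal-codon identification."""

from __future__ import annotations

import math

import numpy as np
import pytest

from plastcub.codon import GeneCubProfile, gene_profiles
from plastcub.io import CdsRecord, extract_filtered_cds
from plastcub.selection import (
    enc_expected,
    enc_plot_table,
    neutrality_fit,
    optimal_codons,
    select_enc_groups,
)


def _profile(gene, enc=50.0, gc3=0.3, gc12=0.4, gc3s=0.3):
    return GeneCubProfile(gene=gene, enc=enc, gc3=gc3, gc12=gc12, gc3s=gc3s)


class TestEncExpected:
    @pytest.mark.parametrize("gc3s,expected", [(0.0, 31.0), (0.5, 60.5), (1.0, 32.0)])
    def test_spot_values(self, gc3s, expected):
        assert enc_expected(gc3s) == pytest.approx(expected)

    @pytest.mark.parametrize("bad", [-0.1, 1.0001, 5.0])
    def test_domain_error(self, bad):
        with pytest.raises(ValueError):
            enc_expected(bad)


class TestEncPlot:
    def test_gene_on_curve_has_zero_deviation(self):
        p = _profile("g", enc=enc_expected(0.3), gc3s=0.3)
        (row,) = enc_plot_table([p])
        assert row["deviation"] == pytest.approx(0.0)
        assert not row["below_curve"]

    def test_mutation_only_genes_near_curve(self):
        """With codon choice driven purely by third-position composition,
        observed ENC tracks the expected curve (median deviation small)."""
        import numpy as np
        from plastcub.simulate import SimConfig, generate_family

        truth = generate_family(
            SimConfig(seed=51, n_taxa=2, branch_length=0.0, gc3_target=0.5,
                      gc3_jitter=0.0, n_genes=10, gene_length_range=(1500, 2400),
                      genome_size=40_000, ir_length=6_000, ssc_length=4_000)
        )
        rows = enc_plot_table(gene_profiles(extract_filtered_cds(truth.records[0])))
        assert abs(float(np.median([r["deviation"] for r in rows]))) < 2.0

    def test_selection_pushes_genes_below_curve(self):
        """A preferred-codon boost in every family (selection on codon
        choice, composition unchanged) drops the majority of genes below
        the expected curve."""
        from plastcub._genetics import AA_TO_CODONS, SYNONYMOUS_AAS
        from plastcub.simulate import SimConfig, generate_family

        preferred = tuple(AA_TO_CODONS[aa][0] for aa in SYNONYMOUS_AAS)
        truth = generate_family(
            SimConfig(seed=52, n_taxa=2, branch_length=0.0, gc3_target=0.5,
                      gc3_jitter=0.0, preferred_codons=preferred, codon_weight=4.0,
                      n_genes=10, gene_length_range=(1500, 2400),
                      genome_size=40_000, ir_length=6_000, ssc_length=4_000)
        )
        rows = enc_plot_table(gene_profiles(extract_filtered_cds(truth.records[0])))
        below = sum(r["below_curve"] for r in rows)
        assert below > len(rows) / 2


class TestNeutralityFit:
    def test_perfect_mutation_line(self):
        profiles = [_profile(f"g{i}", gc3=x, gc12=x) for i, x in enumerate((0.1, 0.3, 0.5))]
        fit = neutrality_fit(profiles)
        assert fit.slope == pytest.approx(1.0)
        assert fit.neutrality_pct == pytest.approx(100.0)

    def test_decomposition_identities(self):
        profiles = [
            _profile(f"g{i}", gc3=x, gc12=0.35 + 0.2039 * x)
            for i, x in enumerate((0.10, 0.20, 0.25, 0.30, 0.40))
        ]
        fit = neutrality_fit(profiles)
        assert fit.slope == pytest.approx(0.2039, abs=1e-12)
        assert fit.neutrality_pct == pytest.approx(20.39)
        assert fit.constraint_pct == pytest.approx(79.61)
        assert fit.neutrality_pct + fit.constraint_pct == 100.0
        assert fit.ratio == pytest.approx(0.2039 / 0.7961, abs=1e-12)
        assert round(fit.ratio, 4) == 0.2561

    def test_degenerate_x_rejected(self):
        profiles = [_profile(f"g{i}", gc3=0.3, gc12=v) for i, v in enumerate((0.3, 0.4, 0.5))]
        with pytest.raises(ValueError, match="degenerate"):
            neutrality_fit(profiles)

    def test_slope_recovered_within_2_se(self):
        """GC12 = a + b*GC3 + noise: OLS recovers b within 2 SE
        (50 genes per replicate, 100 replicates, ~95% coverage)."""
        rng = np.random.default_rng(42)
        b_true, a_true, sigma = 0.25, 0.30, 0.01
        covered = 0
        for _ in range(100):
            gc3 = rng.uniform(0.15, 0.45, size=50)
            gc12 = a_true + b_true * gc3 + rng.normal(0, sigma, size=50)
            profiles = [
                _profile(f"g{i}", gc3=x, gc12=y) for i, (x, y) in enumerate(zip(gc3, gc12))
            ]
            fit = neutrality_fit(profiles)
            se = sigma / (math.sqrt(50) * np.std(gc3))
            covered += abs(fit.slope - b_true) < 2 * se
        assert covered >= 85


class TestSelectEncGroups:
    def test_group_size_is_ceiling(self):
        profiles = [_profile(f"g{i:02d}", enc=30 + i * 0.5) for i in range(53)]
        low, high = select_enc_groups(profiles, fraction=0.05)
        assert len(low) == len(high) == 3  # ceil(0.05 * 53)
        assert low == ["g00", "g01", "g02"]
        assert high == ["g52", "g51", "g50"]

    def test_minimum_group_size_one(self):
        profiles = [_profile(f"g{i}", enc=30 + i) for i in range(20)]
        low, high = select_enc_groups(profiles, fraction=0.05)
        assert len(low) == len(high) == 1

    def test_all_ties_resolved_by_name_and_disjoint(self):
        profiles = [_profile(f"g{i}", enc=45.0) for i in range(6)]
        low, high = select_enc_groups(profiles, fraction=0.2)
        assert set(low).isdisjoint(high)
        assert low == ["g0", "g1"]

    def test_invariant_to_input_order(self):
        rng = np.random.default_rng(3)
        profiles = [_profile(f"g{i:02d}", enc=float(e)) for i, e in
                    enumerate(rng.uniform(30, 60, size=30))]
        shuffled = list(profiles)
        rng.shuffle(shuffled)
        assert select_enc_groups(profiles) == select_enc_groups(shuffled)


def _gene_with_counts(name: str, family_counts: dict[str, int]) -> CdsRecord:
    """Build an in-frame CDS containing exactly the given codon counts."""
    body = "".join(c * k for c, k in family_counts.items())
    return CdsRecord(name=name, sequence="ATG" + body + "TAA")


class TestOptimalCodons:
    def test_identical_groups_give_zero_delta(self):
        g1 = _gene_with_counts("a", {"TTA": 5, "TTG": 5, "GGA": 4})
        g2 = _gene_with_counts("b", {"TTA": 5, "TTG": 5, "GGA": 4})
        res = optimal_codons({"a": g1, "b": g2}, (["a"], ["b"]))
        for row in res.rows:
            if not math.isnan(row.delta_rscu):
                assert row.delta_rscu == pytest.approx(0.0)
        assert res.optimal == []

    def test_worked_rscu_rows(self):
        """Pooled group counts chosen to give RSCU pairs 1.43/0.80 (CTA),
        1.79/0.93 (CGT) and 1.05/0.63 (GGG); the ΔRSCU differences and
        optimal flags follow."""
        low_enc = _gene_with_counts("hi", {
            # Leu: CTA at 143/600 of family usage -> RSCU 1.43
            "CTA": 143, "TTA": 100, "TTG": 100, "CTT": 90, "CTC": 87, "CTG": 80,
            # Arg: CGT at 179/600 -> RSCU 1.79
            "CGT": 179, "CGC": 90, "CGA": 90, "CGG": 81, "AGA": 80, "AGG": 80,
            # Gly: GGG at 105/400 -> RSCU 1.05
            "GGG": 105, "GGA": 99, "GGT": 98, "GGC": 98,
        })
        high_enc = _gene_with_counts("lo", {
            "CTA": 80, "TTA": 104, "TTG": 104, "CTT": 104, "CTC": 104, "CTG": 104,
            "CGT": 93, "CGC": 102, "CGA": 102, "CGG": 101, "AGA": 101, "AGG": 101,
            "GGG": 63, "GGA": 113, "GGT": 112, "GGC": 112,
        })
        res = optimal_codons({"hi": low_enc, "lo": high_enc}, (["hi"], ["lo"]))
        rows = {r.codon: r for r in res.rows}
        for codon, hi, lo in [("CTA", 1.43, 0.80), ("CGT", 1.79, 0.93), ("GGG", 1.05, 0.63)]:
            assert rows[codon].rscu_high_bias == pytest.approx(hi, abs=5e-3)
            assert rows[codon].rscu_low_bias == pytest.approx(lo, abs=5e-3)
            assert rows[codon].delta_rscu == pytest.approx(hi - lo, abs=1e-2)
            assert rows[codon].is_optimal

    def test_groups_must_be_disjoint_and_nonempty(self):
        g = _gene_with_counts("a", {"TTA": 5})
        with pytest.raises(ValueError):
            optimal_codons({"a": g}, (["a"], ["a"]))
        with pytest.raises(ValueError):
            optimal_codons({"a": g}, ([], ["a"]))

    def test_planted_optimal_codons_recovered_exactly(self, biased_family):
        """The designated boosted codons — and only those — satisfy the
        ΔRSCU optimality criteria on strong-effect simulated genes."""
        rec = biased_family.records[0]
        cds = extract_filtered_cds(rec)
        profiles = gene_profiles(cds)
        low, high = select_enc_groups(profiles, fraction=0.25)
        truth_high = {g for g, b in biased_family.gene_bias.items() if b["high_bias"]}
        assert set(low) == truth_high
        res = optimal_codons({c.name: c for c in cds}, (low, high))
        assert set(res.optimal) == set(biased_family.config.preferred_codons)
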