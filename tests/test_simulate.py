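"""Synthetic-cohort generator: determinism, marginals, pipeline closure."""

import numpy as np
import pytest
from scipy import stats

from spermqpcr import (
    FertilityRecord,
    MarkerSpec,
    SyntheticCohortConfig,
    aggregate_replicates,
    correlate,
    fit_efficiency,
    percent_change,
    read_cq_table,
    read_rna_qc_table,
    relative_expression_ddcq,
    simulate_cohort,
    simulate_dilution_series,
    simulate_melt_curves,
    write_cq_table,
    write_rna_qc_table,
)


def _log2_expression(ds, gene, arm, corrected):
    """Per-sample log2 expression (−Cq scale) for one marker and arm."""
    agg = aggregate_replicates(ds.subset(dnase=arm))
    exon = {m.sample_id: m.cq for m in agg if m.gene == gene and m.primer_class == "exon"}
    if not corrected:
        return {s: (None if c is None else -c) for s, c in exon.items()}
    from spermqpcr import gdna_corrected_cq

    intron = {m.sample_id: m.cq for m in agg
              if m.gene == gene and m.primer_class == "intron"}
    out = {}
    for s, e in exon.items():
        i = intron.get(s)
        if e is None or i is None:
            out[s] = None
        else:
            c = gdna_corrected_cq(e, i)
            out[s] = None if c is None else -c
    return out


class TestDeterminism:
    def test_same_config_same_output(self):
        cfg = SyntheticCohortConfig(seed=99)
        ds1, qc1, f1, t1 = simulate_cohort(cfg)
        ds2, qc2, f2, t2 = simulate_cohort(cfg)
        assert [m.key() for m in ds1] == [m.key() for m in ds2]
        assert [m.cq for m in ds1] == [m.cq for m in ds2]
        assert qc1 == qc2 and f1 == f2
        np.testing.assert_array_equal(t1.litter_size, t2.litter_size)

    def test_different_seeds_differ(self):
        a = simulate_cohort(SyntheticCohortConfig(seed=1))[3]
        b = simulate_cohort(SyntheticCohortConfig(seed=2))[3]
        assert not np.array_equal(a.litter_size, b.litter_size)

    def test_adding_marker_preserves_existing_draws(self):
        base = SyntheticCohortConfig(seed=5)
        extended = SyntheticCohortConfig(
            seed=5,
            markers=base.markers + (MarkerSpec("CRISP2", 0.2, 28.0),),
        )
        _, _, _, t1 = simulate_cohort(base)
        _, _, _, t2 = simulate_cohort(extended)
        np.testing.assert_array_equal(t1.litter_size, t2.litter_size)
        for gene in ("EQTN", "PRDX4"):
            np.testing.assert_array_equal(
                t1.abundance_z[gene]["untreated"], t2.abundance_z[gene]["untreated"]
            )

    def test_invalid_config_rejected_before_sampling(self):
        with pytest.raises(ValueError):
            SyntheticCohortConfig(dnase_yield_factor=0.0)
        with pytest.raises(ValueError):
            SyntheticCohortConfig(markers=(("X", 1.5, 25.0),))


class TestMarginals:
    def test_litter_and_correlation_at_large_n(self):
        cfg = SyntheticCohortConfig(seed=17, n_boars=10_000, n_replicates=1)
        _, _, _, truth = simulate_cohort(cfg)
        se = cfg.litter_sd / np.sqrt(cfg.n_boars)
        assert abs(truth.litter_size.mean() - cfg.litter_mean) < 3 * se
        for m in cfg.markers:
            assert abs(truth.realized_r[m.name]["untreated"] - m.target_r) < 0.03
            assert abs(truth.realized_r[m.name]["treated"]) < 0.03

    def test_null_marker_has_no_correlation(self):
        cfg = SyntheticCohortConfig(
            seed=3, n_boars=2000, n_replicates=1,
            markers=(MarkerSpec("NULL", 0.0, 26.0),),
        )
        _, _, _, truth = simulate_cohort(cfg)
        assert abs(truth.realized_r["NULL"]["untreated"]) < 0.1

    def test_dnase_yield_reduction_recovers_56_percent(self):
        pcts = []
        for seed in range(100):
            _, qc, _, _ = simulate_cohort(SyntheticCohortConfig(seed=seed))
            u = np.mean([r.concentration for r in qc if r.dnase == "untreated"])
            t = np.mean([r.concentration for r in qc if r.dnase == "treated"])
            pcts.append(percent_change(u, t))
        assert abs(np.mean(pcts) - 56.0) < 3.0

    def test_plate_offset_leaves_relative_expression_unchanged(self):
        def rel(offset):
            cfg = SyntheticCohortConfig(seed=4, plate_offset_cycles=offset)
            ds, _, _, _ = simulate_cohort(cfg)
            agg = aggregate_replicates(ds.subset(dnase="untreated"))
            res = relative_expression_ddcq(agg, "EQTN", "GAPDH", "boar001")
            return {r.sample_id: r.relative_expression for r in res}

        base, shifted = rel(0.0), rel(2.5)
        for s in base:
            assert shifted[s] == pytest.approx(base[s], rel=1e-9)

    def test_dnase_arm_narrows_exon_intron_gap(self, default_cohort):
        ds = default_cohort[0]

        def gap(arm):
            agg = aggregate_replicates(ds.subset(dnase=arm))
            e = {m.sample_id: m.cq for m in agg
                 if m.gene == "EQTN" and m.primer_class == "exon" and m.cq}
            i = {m.sample_id: m.cq for m in agg
                 if m.gene == "EQTN" and m.primer_class == "intron" and m.cq}
            return np.mean([i[s] - e[s] for s in e if s in i])

        assert gap("treated") < gap("untreated")


class TestPipelineClosure:
    def test_csv_roundtrip_feeds_full_analysis(self, tmp_path, default_cohort):
        ds, qc, fert, _ = default_cohort
        write_cq_table(ds, tmp_path / "cq.csv")
        write_rna_qc_table(qc, tmp_path / "qc.csv")
        ds2 = read_cq_table(tmp_path / "cq.csv")
        qc2 = read_rna_qc_table(tmp_path / "qc.csv")
        assert len(ds2) == len(ds) and qc2 == qc
        agg = aggregate_replicates(ds2.subset(dnase="untreated"))
        res = relative_expression_ddcq(agg, "EQTN", "GAPDH", "boar001",
                                       use_gdna_correction=True)
        expr = {r.sample_id: r.relative_expression for r in res}
        c = correlate(expr, fert)
        assert c.n + c.n_censored == 20

    def test_gdna_correction_improves_correlation_recovery(self):
        """With heavy gDNA contamination the corrected expression tracks the
        latent abundance better than raw exon Cq (paired over seeds)."""
        target = -0.5
        wins = 0
        trials = 0
        for seed in range(200):
            cfg = SyntheticCohortConfig(
                seed=seed, n_boars=20, n_replicates=1,
                markers=(MarkerSpec("EQTN", target, 26.0),),
                gdna_log2_offset=1.0,  # gDNA within a cycle of the mRNA signal
                gdna_contamination_sd=1.5,
            )
            ds, _, fert, _ = simulate_cohort(cfg)
            raw = _log2_expression(ds, "EQTN", "untreated", corrected=False)
            cor = _log2_expression(ds, "EQTN", "untreated", corrected=True)
            if sum(v is not None for v in cor.values()) < 10:
                continue
            r_raw = correlate(raw, fert).r
            r_cor = correlate(cor, fert).r
            trials += 1
            if abs(r_cor - target) < abs(r_raw - target):
                wins += 1
        assert trials >= 100
        p = stats.binomtest(wins, trials, 0.5, alternative="greater").pvalue
        assert p < 0.01


class TestDilutionSeries:
    @pytest.mark.parametrize("eff", [100.0, 90.0])
    def test_noise_free_exact_recovery(self, eff):
        s = simulate_dilution_series("GAPDH", eff)
        r = fit_efficiency(s)
        assert r.efficiency_percent == pytest.approx(eff, abs=1e-9)

    def test_slope_for_perfect_doubling(self):
        s = simulate_dilution_series("GAPDH", 100.0)
        assert fit_efficiency(s).slope == pytest.approx(-3.321928094887362, abs=1e-12)

    def test_noisy_series_covers_true_slope(self):
        true_slope = -1.0 / np.log10(2.0)
        covered = 0
        for seed in range(100):
            s = simulate_dilution_series("GAPDH", 100.0, noise_sd=0.2,
                                         seed=seed, replicates=2)
            amounts = np.log10([a for a, _ in s.points])
            cqs = [c for _, c in s.points]
            fit = stats.linregress(amounts, cqs)
            if abs(fit.slope - true_slope) <= 2 * fit.stderr:
                covered += 1
        assert 0.85 <= covered / 100 <= 1.0

    def test_invalid_efficiency_rejected(self):
        with pytest.raises(ValueError):
            simulate_dilution_series("G", 150.0)


class TestMeltCurves:
    def test_clean_set_has_no_exclusions(self):
        from spermqpcr import melt_qc

        curves = simulate_melt_curves(10, outlier_fraction=0.0, seed=1)
        assert all(not r.excluded for r in melt_qc(curves))

    def test_outlier_count_matches_fraction(self):
        from spermqpcr import melt_qc

        curves = simulate_melt_curves(20, outlier_fraction=0.2, tm_shift=4.0, seed=8)
        results = melt_qc(curves, tm_tolerance=1.5)
        assert sum(r.excluded for r in results) == 4
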