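"""Generator contracts: determinism, planted structure, physical models."""

import math

import numpy as np
import pandas as pd
import pytest

from cgimeth.errors import ValidationError
from cgimeth.selection import select_biomarkers
from cgimeth.simulate import (
    LABEL_TRUE,
    SimulationConfig,
    TruthTable,
    simulate_droplets,
    simulate_methylation_cohorts,
    simulate_patient_truth,
    simulate_protein,
    simulate_qpcr,
)


def _truth(cfg, **over):
    return TruthTable(
        cgi_labels=pd.Series(dtype=object),
        patients=simulate_patient_truth(cfg),
        expression_delta_delta_ct=over.get("ddct", dict(cfg.expression_delta_delta_ct)),
        protein_ratio_tumour=over.get("ratios", dict(cfg.protein_ratio_tumour)),
    )


class TestMethylationCohorts:
    def test_shapes_and_truth_partition(self):
        cfg = SimulationConfig(seed=7)
        disc, val, truth = simulate_methylation_cohorts(cfg)
        assert disc.shape == (74, 18 + 4)
        assert val.shape == (74, 100 + 40)
        assert (truth.cgi_labels == LABEL_TRUE).sum() == 24
        counts = truth.cgi_labels.value_counts()
        assert counts.sum() == 74  # labels partition the CGI universe
        assert set(disc.cgis) == set(truth.cgi_labels.index)

    def test_seed_determinism_bit_identical(self):
        d1, v1, t1 = simulate_methylation_cohorts(SimulationConfig(seed=3))
        d2, v2, t2 = simulate_methylation_cohorts(SimulationConfig(seed=3))
        assert d1.values.equals(d2.values)
        assert v1.values.equals(v2.values)
        assert t1.cgi_labels.equals(t2.cgi_labels)
        d3, _, _ = simulate_methylation_cohorts(SimulationConfig(seed=4))
        assert not d1.values.equals(d3.values)

    def test_zero_noise_point_masses_recover_exactly(self):
        """With point-mass β (infinite precision) the cascade recovers
        exactly the planted true set."""
        cfg = SimulationConfig(seed=0, beta_precision=math.inf)
        disc, val, truth = simulate_methylation_cohorts(cfg)
        records = select_biomarkers(disc, val)
        assert set(records.index[records["selected"]]) == set(truth.true_biomarkers)

    def test_inverted_effect_rejected(self):
        with pytest.raises(ValidationError):
            SimulationConfig(tumour_beta_mean=0.1, normal_beta_mean=0.5)

    def test_label_counts_must_partition(self):
        with pytest.raises(ValidationError):
            SimulationConfig(n_true_biomarkers=30)  # 30 + 50 != 74


class TestQpcr:
    def test_zero_copies_all_undetermined(self):
        cfg = SimulationConfig(seed=1, n_stool_dropout=1)
        truth = _truth(cfg)
        methylight, _ = simulate_qpcr(cfg, truth)
        dropout = truth.patients[~truth.patients["stool_sheds"]]["sample"].iloc[0]
        stool = [
            m
            for m in methylight
            if m.sample_id == dropout and m.matrix == "stool" and m.target != "Alu"
        ]
        assert stool and all(not m.ct or m.ct is None for m in stool)
        assert all(m.ct is None for m in stool)

    def test_ct_follows_log2_law(self):
        """Mean Ct tracks baseline − slope·log2(copies): an 8× template
        ratio shifts Ct by ≈ 3 cycles at slope 1 (noise averaged out)."""
        cfg = SimulationConfig(
            seed=2,
            ct_noise_sd=0.0,
            normal_background_ratio=0.125,
            n_low_purity=0,
            n_no_tumour_cells=0,
            tissue_conc_log10_sd=0.0,
            tissue_conc_median=4000.0,
        )
        truth = _truth(cfg)
        methylight, _ = simulate_qpcr(cfg, truth)
        by = {}
        for m in methylight:
            if m.target == "GRIA4" and m.matrix.startswith("tissue"):
                by.setdefault(m.matrix, []).append(m.ct)
        delta = np.mean(by["tissue_normal"]) - np.mean(by["tissue_tumour"])
        # Poisson template sampling adds a little spread around log2(mean)
        assert delta == pytest.approx(3.0, abs=0.1)

    def test_alu_independent_of_methylation(self):
        cfg = SimulationConfig(seed=5)
        truth = _truth(cfg)
        methylight, _ = simulate_qpcr(cfg, truth)
        alu = [m for m in methylight if m.target == "Alu"]
        assert all(m.amplified for m in alu)
        assert np.mean([m.ct for m in alu]) == pytest.approx(cfg.alu_ct_mean, abs=0.1)

    def test_seed_determinism(self):
        cfg = SimulationConfig(seed=9)
        a = simulate_qpcr(cfg, _truth(cfg))
        b = simulate_qpcr(cfg, _truth(cfg))
        assert a == b


class TestDroplets:
    def test_zero_concentration_no_positives(self):
        cfg = SimulationConfig(seed=1, n_stool_dropout=10)  # nobody sheds
        wells = simulate_droplets(cfg, _truth(cfg))
        assert wells and all(w.n_positive == 0 for w in wells)

    def test_three_wells_per_assay(self):
        cfg = SimulationConfig(seed=1)
        wells = simulate_droplets(cfg, _truth(cfg))
        counts = pd.DataFrame([(w.sample_id, w.target) for w in wells]).value_counts()
        assert (counts == 3).all()
        assert len(wells) == 10 * 2 * 3

    def test_closed_form_positive_mean(self, rng):
        """At λ = c·V_d = 0.1 the expected positives per 20000-droplet well
        are 20000·(1 − e^(−0.1)) ≈ 1903; the simulation lands within 3 SD."""
        p = 1 - math.exp(-0.1)
        draws = rng.binomial(20000, p, size=500)
        expected = 20000 * p
        sd = math.sqrt(20000 * p * (1 - p) / 500)
        assert abs(draws.mean() - expected) < 3 * sd

    def test_law_of_large_numbers_fraction(self):
        """The pooled positive fraction converges to 1 − e^(−cV_d) as the
        number of wells grows."""
        cfg = SimulationConfig(seed=11, tissue_conc_log10_sd=0.0,
                               n_stool_dropout=0, n_wells=60)
        truth = _truth(cfg)
        wells = simulate_droplets(cfg, truth)
        row = truth.patients.iloc[0]
        sub = [w for w in wells if w.sample_id == row["sample"] and w.target == row["target"]]
        c_rxn = row["stool_conc"] * cfg.ddpcr_input_ul / cfg.ddpcr_reaction_ul
        expected = 1 - math.exp(-c_rxn * cfg.droplet_volume_ul)
        frac = sum(w.n_positive for w in sub) / sum(w.n_total for w in sub)
        n = sum(w.n_total for w in sub)
        assert abs(frac - expected) < 4 * math.sqrt(expected * (1 - expected) / n)

    def test_seed_determinism(self):
        cfg = SimulationConfig(seed=2)
        assert simulate_droplets(cfg, _truth(cfg)) == simulate_droplets(cfg, _truth(cfg))


class TestProtein:
    def test_flat_truth_no_noise_gives_null(self):
        cfg = SimulationConfig(
            seed=1,
            protein_measurement_log_sd=0.0,
            protein_biological_log_sd=0.0,
        )
        truth = _truth(cfg, ratios={g: 1.0 for g in cfg.protein_ratio_tumour})
        bands = simulate_protein(cfg, truth)
        from cgimeth.expression import normalize_bands, welch_t

        norm = normalize_bands([b for b in bands if b.target == "GRIA4"])
        res = welch_t(
            norm[norm["group"] == "tumour"]["normalized"],
            norm[norm["group"] == "normal"]["normalized"],
        )
        assert res.degenerate and res.t == 0.0 and res.p == 1.0

    def test_seed_determinism(self):
        cfg = SimulationConfig(seed=4)
        assert simulate_protein(cfg, _truth(cfg)) == simulate_protein(cfg, _truth(cfg))


class TestNoiseMonotonicity:
    def test_noise_degrades_recovered_t(self):
        """Raising replicate noise lowers the average |t| for a fixed
        planted expression effect."""
        from cgimeth.expression import welch_t
        from cgimeth.pipeline import expression_report
        from cgimeth.config import RunConfig

        mean_abs_t = []
        for noise in (0.1, 1.0, 3.0):
            ts = []
            for seed in range(5):
                cfg = SimulationConfig(seed=seed, ct_noise_sd=noise)
                truth = _truth(cfg)
                _, expression_ct = simulate_qpcr(cfg, truth)
                report = expression_report(expression_ct, [], RunConfig())
                row = report[(report["gene"] == "GRIA4") & (report["assay"] == "mrna")]
                ts.append(abs(float(row["t"].iloc[0])))
            mean_abs_t.append(np.mean(ts))
        assert mean_abs_t[0] > mean_abs_t[1] > mean_abs_t[2]
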