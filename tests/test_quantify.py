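"""Sample quantitation, unit conversion, and the method-comparison table."""

import math

import pytest

from qlloq.quantify import (
    METHODS,
    amol_per_l_to_copies_per_ul,
    compare_methods,
    copies_per_ul_to_amol_per_l,
    quantify_run,
    summarize_comparison,
    volume_factor_from_equivalence,
)
from qlloq.synthetic import SimScenario, generate_run
from qlloq.types import CalibrationRun, CqValue


class TestUnitConversion:
    def test_round_trip_inverse(self):
        for conc in (16.9, 300.0, 1e6):
            copies = amol_per_l_to_copies_per_ul(conc, volume_factor=0.2)
            assert copies_per_ul_to_amol_per_l(copies, volume_factor=0.2) == pytest.approx(conc)

    def test_factor_from_stated_equivalence(self):
        """A dataset documented as 0.3 fmol/L = 36.7 copies/µL pins the factor."""
        vf = volume_factor_from_equivalence(300.0, 36.7)
        assert amol_per_l_to_copies_per_ul(300.0, vf) == pytest.approx(36.7)
        # the same chain maps the deeper calibrator floor to ~4.1 copies/µL
        assert amol_per_l_to_copies_per_ul(30.0, vf) == pytest.approx(3.67, rel=1e-6)

    def test_unit_factor_is_avogadro_scaled(self):
        # 1 amol/L = 6.022e5 copies/L = 0.6022 copies/µL at volume factor 1
        assert amol_per_l_to_copies_per_ul(1.0) == pytest.approx(0.602214076)


def study_run(seed=21, unknowns=(5e3, 1e2, 5e5)):
    return generate_run(
        SimScenario(
            cq_noise_sd=0.2,
            seed=seed,
            ntc_mode=("determined", 35.0, 0.3),
            unknowns=unknowns,
        )
    )


class TestQuantifyRun:
    def test_every_unknown_quantified_and_flagged(self):
        run = study_run()
        quants = quantify_run(run, "baseline_noise")
        assert len(quants) == len(run.unknowns)
        for q in quants:
            if q.copies_per_ul is not None:
                assert q.ci95_low <= q.copies_per_ul <= q.ci95_high
                assert q.below_lloq == (q.copies_per_ul < q.lloq_copies_per_ul)

    def test_bright_sample_not_flagged(self):
        run = study_run(unknowns=(5e5,))
        q = quantify_run(run, "logistic_se")[0]
        assert q.copies_per_ul is not None
        assert not q.below_lloq

    def test_censored_unknown_flagged_below_when_lloq_exists(self):
        run = study_run(unknowns=(5e3,))
        run.unknowns[0] = ("dark", CqValue.undetermined())
        q = quantify_run(run, "baseline_noise")[0]
        assert q.copies_per_ul is None
        assert q.below_lloq
        assert q.notes == "censored Cq"

    def test_replicate_wells_averaged(self):
        run = study_run(unknowns=(1e4, 1e4))
        run.unknowns = [("s", run.unknowns[0][1]), ("s", run.unknowns[1][1])]
        quants = quantify_run(run, "logistic_se")
        assert len(quants) == 1
        assert quants[0].n_replicates == 2

    def test_larger_lloq_never_unflags(self):
        """Flagging is threshold-consistent in the LLOQ."""
        run = study_run()
        base = quantify_run(run, "logistic_re")  # typically the lowest LLOQ
        strict = quantify_run(run, "baseline_noise")
        for a, b in zip(base, strict):
            if b.lloq_copies_per_ul is None or a.lloq_copies_per_ul is None:
                continue
            if b.lloq_copies_per_ul >= a.lloq_copies_per_ul and a.below_lloq:
                assert b.below_lloq

    def test_volume_factor_scales_everything_consistently(self):
        run = study_run()
        plain = quantify_run(run, "baseline_noise", volume_factor=1.0)
        scaled = quantify_run(run, "baseline_noise", volume_factor=0.2)
        for a, b in zip(plain, scaled):
            if a.copies_per_ul is None:
                continue
            assert b.copies_per_ul == pytest.approx(0.2 * a.copies_per_ul)
            assert a.below_lloq == b.below_lloq  # flags are scale-free

    def test_no_unknowns_rejected(self):
        run = generate_run(SimScenario(seed=1))
        with pytest.raises(ValueError):
            quantify_run(run)


class TestCompareMethods:
    def test_one_row_per_run_all_methods_present(self):
        runs = [study_run(seed=s) for s in range(4)]
        table = compare_methods(runs)
        assert len(table) == 4
        for m in METHODS:
            assert m in table.columns

    def test_lloqs_are_calibrator_concentrations_or_nan(self):
        runs = [study_run(seed=s) for s in range(6)]
        table = compare_methods(runs)
        for run, (_, row) in zip(runs, table.iterrows()):
            for m in METHODS:
                val = row[m]
                assert math.isnan(val) or any(
                    val == pytest.approx(c) for c in run.concentrations
                )
                assert math.isnan(val) or run.concentrations[0] <= val <= run.concentrations[-1]

    def test_clean_run_all_methods_agree_logistic_at_lowest(self):
        run = generate_run(SimScenario(cq_noise_sd=0.02, seed=2))
        table = compare_methods([run])
        summary = summarize_comparison(table)
        assert summary["logistic_re_pct_at_lowest_calibrator"] == 100.0
        assert summary["logistic_se_pct_at_lowest_calibrator"] == 100.0
        assert summary["re_se_agreement_runs"] == 1

    def test_plateaued_and_clean_pair_disagree(self):
        clean = generate_run(SimScenario(cq_noise_sd=0.02, seed=2))
        plateau = generate_run(
            SimScenario(true_params=(38.0, 1.2, 4.2), n_dilutions=12,
                        cq_noise_sd=0.15, seed=3)
        )
        summary = summarize_comparison(compare_methods([clean, plateau]))
        assert summary["re_se_agreement_runs"] == 1
        assert summary["n_discordant"] == 1
        assert summary["se_ge_re_among_discordant"] == 1

    def test_missing_ntc_tallied_not_fatal(self):
        run = study_run()
        bare = CalibrationRun("no-ntc", run.calibrators, ntc=None,
                              dilution_factor=3.0, unknowns=run.unknowns)
        table = compare_methods([bare])
        assert math.isnan(table["baseline_noise"].iloc[0])
        assert "error" in table["baseline_noise_path"].iloc[0]
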