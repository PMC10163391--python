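import numpy as np
import pandas as pd
import pytest

from gapscore import (
    SyntheticSpec,
    generate,
    planted_rank_recovery,
    score_table,
    validate_table,
)
from gapscore.pipeline import _disparity_for
from gapscore.synthetic import METRIC_MODEL, STRATIFICATIONS


class TestSpec:
    def test_roster_is_sixteen_innovation_metrics_in_six_categories(self):
        innovation = [m for m, (d, *_) in METRIC_MODEL.items() if d == "innovation"]
        assert len(innovation) == 16

    def test_too_few_conditions_rejected(self):
        with pytest.raises(ValueError, match="n_conditions"):
            SyntheticSpec(n_conditions=3)

    def test_planted_id_must_be_in_roster(self):
        with pytest.raises(ValueError, match="planted"):
            SyntheticSpec(planted_gap="c99")

    def test_planted_ids_must_be_distinct(self):
        with pytest.raises(ValueError, match="distinct"):
            SyntheticSpec(planted_gap="c01", planted_paradox="c01")


class TestGenerate:
    def test_same_seed_gives_identical_tables(self):
        spec = SyntheticSpec(seed=123, planted_gap="c02")
        t1, t2 = generate(spec), generate(spec)
        pd.testing.assert_frame_equal(t1.data, t2.data)

    def test_different_seeds_differ(self):
        t1 = generate(SyntheticSpec(seed=1))
        t2 = generate(SyntheticSpec(seed=2))
        assert not t1.data["value"].equals(t2.data["value"])

    def test_generated_tables_validate(self, synthetic_table):
        assert validate_table(synthetic_table) == []

    def test_minimal_table_validates(self):
        table = generate(SyntheticSpec(n_conditions=4, seed=5))
        assert validate_table(table) == []
        assert table.n_conditions == 4

    def test_planted_gap_separates_domain_means(self, planted_table):
        df = planted_table.data[planted_table.data["stratum"].isna()]
        domains = {m: d for m, (d, *_) in METRIC_MODEL.items()}
        for domain, expect_high in [("burden", True), ("cost", True), ("innovation", False)]:
            metrics = [m for m, d in domains.items() if d == domain]
            log_means = (
                df[df["metric_id"].isin(metrics)]
                .assign(logv=lambda x: np.log(x["value"] + 1.0))
                .groupby("condition_id")["logv"]
                .mean()
            )
            planted = log_means.pop("c05")
            if expect_high:
                assert planted > log_means.median()
            else:
                assert planted < log_means.median()

    def test_strata_cover_all_stratifications(self, synthetic_table):
        strat = synthetic_table.data.dropna(subset=["stratum"])
        prefixes = {s.split(":")[0] for s in strat["stratum"]}
        assert prefixes == set(STRATIFICATIONS)
        # one full set of groups per condition and stratification
        counts = strat.groupby("condition_id").size()
        expected = sum(len(g) for g in STRATIFICATIONS.values())
        assert (counts == expected).all()

    def test_disparity_ratios_concentrate_near_configured_ratio(self):
        ratio = 1.8
        table = generate(SyntheticSpec(seed=9, between_group_ratio=ratio))
        observed = [
            _disparity_for(table.data, cid, "mortality", 2019)
            for cid in table.conditions
        ]
        assert np.mean(observed) == pytest.approx(ratio, rel=0.10)


class TestRankRecovery:
    def test_planted_paradox_is_costly_and_innovative_not_an_opportunity(
        self, planted_table
    ):
        result = score_table(planted_table)
        paradox = next(r for r in result.results if r.condition_id == "c02")
        assert paradox.tiers["cost"] == "high"
        assert paradox.tiers["innovation"] == "high"
        assert not paradox.opportunity_flag
        assert "paradox" in paradox.reason

    def test_planted_gap_recovered_in_small_replicate_run(self):
        spec = SyntheticSpec(planted_gap="c07", seed=77)
        rec = planted_rank_recovery(spec, n_replicates=20)
        assert rec.n_replicates == 20
        assert len(rec.ranks) == 20
        assert rec.fraction >= 0.95

    def test_target_required_without_planted_condition(self):
        with pytest.raises(ValueError, match="target"):
            planted_rank_recovery(SyntheticSpec(seed=1), n_replicates=2)
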