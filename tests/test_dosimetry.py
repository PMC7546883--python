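"""DVH extraction, endpoint computation and constraint parsing/evaluation."""
import numpy as np
import pytest

from contourdose import (DoseGrid, StructureMask, builtin_constraints,
                         cumulative_dvh, dose_max, dose_mean,
                         evaluate_constraint, make_grid, parse_constraint,
                         volume_at_dose)
from contourdose.errors import (ConstraintParseError, EmptyStructureError,
                                IncompatibleGridsError)
from tests.conftest import random_blob


@pytest.fixture
def grid8():
    return make_grid((8, 8, 8), (1.0, 1.0, 1.0))


def full_mask(grid, name="m"):
    return StructureMask(grid, np.ones(grid.shape, bool), name)


class TestDVH:
    def test_uniform_dose_is_a_step(self, grid8):
        dose = DoseGrid(grid8, np.full(grid8.shape, 10.0))
        dvh = cumulative_dvh(dose, full_mask(grid8), bin_width=1.0)
        np.testing.assert_allclose(dvh.bin_edges, np.arange(12))
        np.testing.assert_allclose(dvh.cumulative_volume[:11], 100.0)
        assert dvh.cumulative_volume[11] == 0.0

    def test_two_level_dose(self, grid8):
        d = np.zeros(grid8.shape)
        d[:4] = 40.0
        dvh = cumulative_dvh(DoseGrid(grid8, d), full_mask(grid8), bin_width=1.0)
        assert dvh.cumulative_volume[0] == 100.0
        # value at the 20 Gy edge: half the voxels are at 40 Gy
        assert dvh.cumulative_volume[20] == pytest.approx(50.0)

    def test_integral_matches_mean_on_random_fields(self, grid8):
        rng = np.random.default_rng(5)
        for _ in range(20):
            mask = random_blob(grid8, rng)
            dose = DoseGrid(grid8, rng.uniform(0, 60, grid8.shape))
            dvh = cumulative_dvh(dose, mask, bin_width=0.1)
            assert dvh.cumulative_volume[0] == 100.0
            assert np.all(np.diff(dvh.cumulative_volume) <= 0)
            assert dvh.cumulative_volume[-1] == 0.0
            assert abs(dvh.integral_gy() - dose_mean(dose, mask)) <= 0.1

    def test_grid_mismatch_and_empty_mask(self, grid8):
        dose = DoseGrid(grid8, np.zeros(grid8.shape))
        other = make_grid((8, 8, 8), (2, 2, 2))
        with pytest.raises(IncompatibleGridsError):
            cumulative_dvh(dose, full_mask(other))
        empty = StructureMask(grid8, np.zeros(grid8.shape, bool), "e")
        with pytest.raises(EmptyStructureError):
            cumulative_dvh(dose, empty)


class TestEndpoints:
    def test_volume_at_dose_limits(self, grid8):
        dose = DoseGrid(grid8, np.full(grid8.shape, 7.0))
        m = full_mask(grid8)
        assert volume_at_dose(dose, m, 0.0) == 100.0
        assert volume_at_dose(dose, m, 7.0) == 100.0  # closed superlevel set
        assert volume_at_dose(dose, m, 7.01) == 0.0

    def test_volume_at_dose_fraction(self, grid8):
        v = np.zeros(grid8.shape, bool)
        v[0, 0, :8] = True  # 8-voxel mask, 3 hot voxels
        d = np.zeros(grid8.shape)
        d[0, 0, :3] = 50.0
        assert volume_at_dose(DoseGrid(grid8, d),
                              StructureMask(grid8, v, "m"), 10.0) == 37.5

    def test_max_and_mean(self, grid8):
        v = np.zeros(grid8.shape, bool)
        v[0, 0, 0] = v[0, 0, 1] = True
        d = np.zeros(grid8.shape)
        d[0, 0, 1] = 10.0
        dose = DoseGrid(grid8, d)
        m = StructureMask(grid8, v, "m")
        assert dose_max(dose, m) == 10.0
        assert dose_mean(dose, m) == 5.0

    def test_dvh_value_at_edge_equals_binfree(self, grid8):
        rng = np.random.default_rng(9)
        mask = random_blob(grid8, rng)
        dose = DoseGrid(grid8, rng.uniform(0, 30, grid8.shape))
        dvh = cumulative_dvh(dose, mask, bin_width=0.5)
        for i in (0, 10, 20, len(dvh.bin_edges) - 1):
            assert dvh.cumulative_volume[i] == pytest.approx(
                volume_at_dose(dose, mask, float(dvh.bin_edges[i])))


class TestParseConstraint:
    @pytest.mark.parametrize("text,metric,dose,limit,rel", [
        ("V40Gy ≥ 95%", "V_at_dose", 40.0, 95.0, "≥"),
        ("Max <52Gy", "max", None, 52.0, "<"),
        ("V45Gy <33%", "V_at_dose", 45.0, 33.0, "<"),
        ("Mean <40 Gy", "mean", None, 40.0, "<"),
        ("V20Gy ≤ 40%", "V_at_dose", 20.0, 40.0, "≤"),
        ("v16gy<=5%", "V_at_dose", 16.0, 5.0, "≤"),
        ("Mean >= 30Gy", None, None, None, None),  # coverage on mean: invalid
    ])
    def test_grammar(self, text, metric, dose, limit, rel):
        if metric is None:
            with pytest.raises(ValueError):
                parse_constraint(text)
            return
        c = parse_constraint(text, structure="S")
        assert (c.metric, c.dose_gy, c.limit, c.relation) == (metric, dose, limit, rel)
        assert c.source_text == text

    def test_round_trip(self):
        for text in ("V40Gy ≥ 95%", "Max <52Gy", "Mean ≤ 25Gy", "V45Gy <33%"):
            c = parse_constraint(text, structure="S")
            c2 = parse_constraint(c.render(), structure="S")
            assert c2.render() == c.render()
            assert (c2.metric, c2.dose_gy, c2.limit, c2.relation) == \
                   (c.metric, c.dose_gy, c.limit, c.relation)

    def test_unparseable_token_reported(self):
        with pytest.raises(ConstraintParseError, match="D50%"):
            parse_constraint("D50% < 20Gy")


class TestEvaluateConstraint:
    def test_max_pass_and_fail(self, grid8):
        m = full_mask(grid8)
        c = parse_constraint("Max <45Gy", structure="m")
        ok = evaluate_constraint(c, DoseGrid(grid8, np.full(grid8.shape, 10.0)), m)
        assert ok.achieved == 10.0 and ok.passed and ok.margin == 35.0
        bad = evaluate_constraint(c, DoseGrid(grid8, np.full(grid8.shape, 50.0)), m)
        assert bad.achieved == 50.0 and not bad.passed

    def test_strictness_at_the_limit(self, grid8):
        m = full_mask(grid8)
        dose = DoseGrid(grid8, np.full(grid8.shape, 45.0))
        strict = parse_constraint("Max <45Gy", structure="m")
        loose = parse_constraint("Max ≤45Gy", structure="m")
        assert not evaluate_constraint(strict, dose, m).passed
        assert evaluate_constraint(loose, dose, m).passed

    def test_coverage_constraint(self, grid8):
        v = np.ones(grid8.shape, bool)
        d = np.full(grid8.shape, 42.0)
        d.reshape(-1)[:20] = 0.0  # ~3.9% of voxels cold
        res = evaluate_constraint(parse_constraint("V40Gy ≥ 95%", structure="m"),
                                  DoseGrid(grid8, d), StructureMask(grid8, v, "m"))
        assert res.achieved == pytest.approx(100 * (512 - 20) / 512)
        assert res.passed

    def test_all_builtin_rows_against_direct_computation(self, grid8):
        """Every shipped clinical constraint row parses and evaluates exactly
        as a direct one-line voxel computation."""
        rng = np.random.default_rng(21)
        rows = builtin_constraints("prostate") + builtin_constraints("hn")
        assert len(rows) == 25
        for c in rows:
            mask = random_blob(grid8, rng)
            dose = DoseGrid(grid8, rng.uniform(0, 80, grid8.shape))
            res = evaluate_constraint(c, dose, mask)
            doses = dose.dose[mask.voxels]
            if c.metric == "V_at_dose":
                direct = 100.0 * np.mean(doses >= c.dose_gy)
            elif c.metric == "max":
                direct = doses.max()
            else:
                direct = doses.mean()
            assert res.achieved == direct
            ops = {"<": np.less, "≤": np.less_equal, "≥": np.greater_equal}
            assert res.passed == bool(ops[c.relation](direct, c.limit))
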