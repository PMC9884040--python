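import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phyloshape.morphometrics import (
    REGIONS,
    EcotypeLabelError,
    InsufficientRibsError,
    InvalidMeasurementError,
    MissingRegionError,
    SpecimenRecord,
    aggregate_species,
    compute_AEI,
    compute_body_depth,
    compute_body_length,
    compute_geometric_mean,
    compute_hbER,
    compute_head_ER,
    compute_limb_lengths,
    species_frame,
)

positive = st.floats(min_value=1e-3, max_value=1e4, allow_nan=False)


def make_record(specimen_id="s1", species="sp1", limb_bones=None, **overrides):
    rec = SpecimenRecord(
        specimen_id=specimen_id,
        species_id=species,
        cranial_length=40.0,
        cranial_height=16.0,
        vertebrae={
            "cervical": [(3.0, 6.0)] * 7,
            "thoracic": [(5.0, 8.0)] * 12,
            "lumbar": [(7.0, 9.0)] * 7,
            "sacral": [(4.0, 7.0)] * 3,
        },
        rib_lengths=[50.0, 48.0, 46.0, 44.0, 30.0],
        limb_bones=limb_bones or {},
    )
    for key, val in overrides.items():
        setattr(rec, key, val)
    return rec


class TestHbER:
    def test_unit_inputs(self):
        assert compute_hbER(1, 1, 1) == 2

    def test_scale_invariance_example(self):
        assert compute_hbER(10, 10, 10) == compute_hbER(1, 1, 1)

    def test_arithmetic(self):
        assert compute_hbER(4.2, 20.3, 6.1) == pytest.approx(24.5 / 6.1)

    @pytest.mark.parametrize("args", [(0, 1, 1), (1, -2, 1), (1, 1, 0)])
    def test_nonpositive_rejected(self, args):
        with pytest.raises(InvalidMeasurementError):
            compute_hbER(*args)

    @given(lh=positive, lb=positive, lr=positive, c=st.floats(min_value=1e-2, max_value=1e3))
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance_property(self, lh, lb, lr, c):
        assert compute_hbER(c * lh, c * lb, c * lr) == pytest.approx(
            compute_hbER(lh, lb, lr), rel=1e-9
        )


class TestBodyLength:
    def test_one_per_region(self):
        verts = {r: [(1.0, 1.0)] for r in REGIONS}
        assert compute_body_length(verts) == 4

    def test_sum(self):
        verts = {
            "cervical": [(2.0, 1.0)],
            "thoracic": [(3.0, 1.0)],
            "lumbar": [(4.0, 1.0)],
            "sacral": [(5.0, 1.0)],
        }
        assert compute_body_length(verts) == 14

    def test_random_matches_summation_oracle(self):
        rng = np.random.default_rng(0)
        verts = {r: [(float(v), 1.0) for v in rng.uniform(1, 9, size=5)] for r in REGIONS}
        oracle = sum(v for r in REGIONS for v, _ in verts[r])
        assert compute_body_length(verts) == pytest.approx(oracle, rel=1e-12)

    def test_empty_region(self):
        verts = {r: [(1.0, 1.0)] for r in REGIONS}
        verts["lumbar"] = []
        with pytest.raises(MissingRegionError):
            compute_body_length(verts)


class TestBodyDepth:
    def test_constant(self):
        assert compute_body_depth([3, 3, 3, 3]) == 3

    def test_four_largest(self):
        assert compute_body_depth([1, 2, 3, 4, 5, 6]) == pytest.approx(4.5)

    def test_too_few_ribs(self):
        with pytest.raises(InsufficientRibsError):
            compute_body_depth([2, 2, 2])


class TestHeadER:
    @pytest.mark.parametrize("lh,hh,expected", [(1, 1, 1), (3, 2, 1.5)])
    def test_simple(self, lh, hh, expected):
        assert compute_head_ER(lh, hh) == expected

    def test_division(self):
        assert compute_head_ER(41.7, 17.2) == pytest.approx(41.7 / 17.2)

    def test_nonpositive(self):
        with pytest.raises(InvalidMeasurementError):
            compute_head_ER(1.0, 0.0)


class TestAEI:
    def test_single_vertebra(self):
        assert compute_AEI([(2.0, 1.0)]) == 2

    def test_three_equal(self):
        assert compute_AEI([(1.0, 1.0)] * 3) == 3

    def test_arithmetic(self):
        verts = list(zip((4.1, 4.3, 4.0), (7.0, 8.0, 9.0)))
        assert compute_AEI(verts) == pytest.approx(12.4 / 8.0)

    def test_empty(self):
        with pytest.raises(MissingRegionError):
            compute_AEI([])


class TestGeometricMean:
    def test_constant(self):
        assert compute_geometric_mean([2.0] * 11) == pytest.approx(2.0)
        assert compute_geometric_mean([1.0] * 11) == pytest.approx(1.0)

    def test_log_sum_oracle(self):
        rng = np.random.default_rng(1)
        vals = rng.uniform(0.5, 80.0, size=11)
        oracle = float(np.prod(vals) ** (1 / 11))
        assert compute_geometric_mean(vals) == pytest.approx(oracle, rel=1e-10)

    def test_wrong_count(self):
        with pytest.raises(InvalidMeasurementError):
            compute_geometric_mean([1.0] * 10)

    @given(c=st.floats(min_value=0.01, max_value=100))
    @settings(max_examples=30, deadline=None)
    def test_scale_equivariance(self, c):
        rng = np.random.default_rng(2)
        vals = rng.uniform(1, 10, size=11)
        assert compute_geometric_mean(c * vals) == pytest.approx(
            c * compute_geometric_mean(vals), rel=1e-9
        )


class TestLimbLengths:
    ALL_ONES = {b: 1.0 for b in ("scapula", "humerus", "radius", "metacarpal3", "femur", "tibia", "metatarsal3")}

    def test_full(self):
        assert compute_limb_lengths(self.ALL_ONES, "full") == (4, 3)

    def test_reduced(self):
        assert compute_limb_lengths(self.ALL_ONES, "reduced") == (2, 2)

    def test_missing_scapula(self):
        bones = {k: v for k, v in self.ALL_ONES.items() if k != "scapula"}
        assert compute_limb_lengths(bones, "reduced")[0] == 2
        assert compute_limb_lengths(bones, "full")[0] is None


class TestAggregateSpecies:
    def test_single_specimen_identity(self):
        rec = make_record()
        traits = aggregate_species([rec], {"sp1": "tree"})
        assert len(traits) == 1
        from phyloshape.morphometrics import specimen_indices

        expected = specimen_indices(rec)
        for key, val in expected.items():
            if val is not None:
                assert traits[0].values[key] == pytest.approx(val)

    def test_mean_of_two(self):
        # hbER = (L_H + L_B)/depth; tweak cranial length to move hbER
        r1 = make_record("s1")
        r2 = make_record("s2")
        from phyloshape.morphometrics import specimen_indices

        h1 = specimen_indices(r1)["hbER"]
        r2.cranial_length = 60.0
        h2 = specimen_indices(r2)["hbER"]
        traits = aggregate_species([r1, r2], {"sp1": "tree"})
        assert traits[0].values["hbER"] == pytest.approx((h1 + h2) / 2)
        assert traits[0].n_specimens == 2

    def test_missing_ecotype(self):
        with pytest.raises(EcotypeLabelError, match="sp1"):
            aggregate_species([make_record()], {"other": "tree"})

    def test_invalid_specimen_excluded_not_fatal(self):
        bad = make_record("bad", rib_lengths=[1.0, 2.0])
        good = make_record("good")
        traits = aggregate_species([bad, good], {"sp1": "tree"})
        assert traits[0].n_specimens == 1

    def test_permutation_invariance(self):
        recs = [make_record(f"s{i}") for i in range(4)]
        for i, r in enumerate(recs):
            r.cranial_length = 35.0 + 3 * i
        fwd = aggregate_species(recs, {"sp1": "ground"})
        rev = aggregate_species(recs[::-1], {"sp1": "ground"})
        for key in fwd[0].values:
            assert fwd[0].values[key] == pytest.approx(rev[0].values[key], rel=1e-12)

    def test_ln_columns_consistent(self):
        df = species_frame(aggregate_species([make_record()], {"sp1": "gliding"}))
        assert df.loc["sp1", "ln_hbER"] == pytest.approx(math.log(df.loc["sp1", "hbER"]))

    def test_indices_of_means_rule_runs(self):
        recs = [make_record("a"), make_record("b")]
        recs[1].cranial_length = 50.0
        out = aggregate_species(recs, {"sp1": "tree"}, rule="indices_of_means")
        assert out[0].values["head_ER"] == pytest.approx((40.0 + 50.0) / 2 / 16.0)


def test_specimen_scale_invariance_of_ratios():
    """All ratio statistics are unit independent; size scales linearly."""
    from phyloshape.morphometrics import specimen_indices

    rec = make_record(limb_bones={"humerus": 30.0, "radius": 28.0, "femur": 35.0, "tibia": 33.0})
    base = specimen_indices(rec)
    c = 3.7
    scaled = make_record(
        limb_bones={"humerus": 30.0 * c, "radius": 28.0 * c, "femur": 35.0 * c, "tibia": 33.0 * c},
        cranial_length=rec.cranial_length * c,
        cranial_height=rec.cranial_height * c,
        vertebrae={r: [(lv * c, hv * c) for lv, hv in v] for r, v in rec.vertebrae.items()},
        rib_lengths=[x * c for x in rec.rib_lengths],
    )
    out = specimen_indices(scaled)
    for key in ("hbER", "head_ER", "cervical_AEI", "thoracic_AEI", "lumbar_AEI", "sacral_AEI"):
        assert out[key] == pytest.approx(base[key], rel=1e-9)
    assert out["body_size"] == pytest.approx(c * base["body_size"], rel=1e-9)
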