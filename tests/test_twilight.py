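import numpy as np
import pytest

from oracles import line_search_oracle
from twilightfold import (
    HQPoint,
    ProteinRecord,
    binned_twilight_zones,
    delimit_twilight_zone,
    find_discriminative_line,
    project_to_plane,
)
from twilightfold.indexes import mean_hydrophobicity, mean_net_charge
from twilightfold.seqio import FOLDED, UNCLASSIFIED, UNFOLDED


def points(xy, group, lengths=None):
    return [
        HQPoint(f"{group}{i}", float(x), float(y), group,
                None if lengths is None else int(lengths[i]))
        for i, (x, y) in enumerate(xy)
    ]


class TestProjectToPlane:
    def test_poly_E_has_unit_charge_coordinate(self):
        rec = ProteinRecord("pE", "E" * 40)
        (pt,) = project_to_plane([rec], {"pE": UNFOLDED})
        assert pt.net_charge == 1.0
        assert pt.group == UNFOLDED

    def test_poly_I_sits_at_hydrophobicity_maximum(self):
        rec = ProteinRecord("pI", "I" * 40)
        (pt,) = project_to_plane([rec], {"pI": FOLDED})
        assert pt.hydrophobicity == 1.0
        assert pt.net_charge == 0.0

    def test_coordinates_match_hq_machinery(self, rng):
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=80))
        rec = ProteinRecord("p", seq)
        (pt,) = project_to_plane([rec], {"p": FOLDED})
        assert pt.hydrophobicity == mean_hydrophobicity(rec)
        assert pt.net_charge == mean_net_charge(rec)

    def test_missing_verdict_rejected(self):
        with pytest.raises(ValueError, match="no group"):
            project_to_plane([ProteinRecord("p", "A" * 20)], {})


class TestFindDiscriminativeLine:
    def test_separable_clusters_get_zero_fp_line(self, rng):
        A = rng.normal([0.0, 0.0], 0.1, size=(10, 2))
        B = rng.normal([2.0, 2.0], 0.1, size=(10, 2))
        res = find_discriminative_line(A, B)
        assert res.feasible
        assert res.false_positive_fraction == 0.0
        assert res.sensitivity >= 0.80

    def test_matches_brute_force_on_seeded_configs(self, rng):
        for _ in range(15):
            na = int(rng.integers(3, 16))
            nb = int(rng.integers(3, 16))
            A = rng.normal([0.0, 0.0], 1.0, size=(na, 2))
            B = rng.normal([1.0, 0.5], 1.0, size=(nb, 2))
            got = find_discriminative_line(A, B)
            feasible, fp, sens = line_search_oracle(A, B)
            assert got.feasible == feasible
            if feasible:
                assert got.false_positive_fraction == pytest.approx(fp, abs=0)
                assert got.sensitivity == pytest.approx(sens, abs=0)

    def test_relaxed_sensitivity_gives_global_fp_minimum(self, rng):
        A = rng.normal(size=(8, 2))
        B = rng.normal(size=(8, 2))
        res = find_discriminative_line(A, B, min_sensitivity=0.0)
        _, fp, _ = line_search_oracle(A, B, min_sensitivity=0.0)
        assert res.false_positive_fraction == pytest.approx(fp, abs=0)

    def test_result_is_pareto_undominated(self, rng):
        A = rng.normal([0, 0], 0.8, size=(10, 2))
        B = rng.normal([0.8, 0.4], 0.8, size=(10, 2))
        res = find_discriminative_line(A, B)
        if not res.feasible:
            pytest.skip("infeasible configuration")
        # brute-force all pair-lines/orientations; nothing may dominate
        pts = np.vstack([A, B])
        for i in range(len(pts)):
            for j in range(i + 1, len(pts)):
                d = pts[j] - pts[i]
                nrm = np.hypot(*d)
                if nrm == 0:
                    continue
                a, b = -d[1] / nrm, d[0] / nrm
                c = -(a * pts[i][0] + b * pts[i][1])
                for flip in (1.0, -1.0):
                    fa, fb, fc = flip * a, flip * b, flip * c
                    sens = np.mean(B @ [fa, fb] + fc >= -1e-9)
                    fp = np.mean(A @ [fa, fb] + fc >= -1e-9)
                    dominates = (
                        sens >= res.sensitivity
                        and fp <= res.false_positive_fraction
                        and (sens > res.sensitivity
                             or fp < res.false_positive_fraction)
                    )
                    assert not (dominates and sens >= 0.8 - 1e-12)

    def test_translation_invariance(self, rng):
        A = rng.normal([0, 0], 0.5, size=(8, 2))
        B = rng.normal([1.5, 1.0], 0.5, size=(8, 2))
        res = find_discriminative_line(A, B)
        shift = np.array([2.5, -1.0])
        res2 = find_discriminative_line(A + shift, B + shift)
        assert res2.line.a == pytest.approx(res.line.a, abs=1e-9)
        assert res2.line.b == pytest.approx(res.line.b, abs=1e-9)
        expected_c = res.line.c - (res.line.a * shift[0] + res.line.b * shift[1])
        assert res2.line.c == pytest.approx(expected_c, abs=1e-9)

    def test_subsampling_is_seeded_and_recorded(self, rng):
        A = rng.normal(size=(400, 2))
        B = rng.normal([1, 1], 1.0, size=(400, 2))
        res1 = find_discriminative_line(A, B, max_points=100, random_state=7)
        res2 = find_discriminative_line(A, B, max_points=100, random_state=7)
        assert res1.subsampled and res2.subsampled
        assert res1.line.c == res2.line.c

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            find_discriminative_line(np.empty((0, 2)), [[0.0, 0.0]])


class TestDelimitTwilightZone:
    def test_sandwiched_unclassified_fully_covered(self, rng):
        folded = rng.normal([3.0, 0.0], 0.1, size=(15, 2))
        unfolded = rng.normal([-3.0, 0.0], 0.1, size=(15, 2))
        unclassified = rng.normal([0.0, 0.0], 0.2, size=(15, 2))
        zone = delimit_twilight_zone(folded, unfolded, unclassified,
                                     coverage=1.0)
        assert zone.feasible
        assert zone.contained_fraction == 1.0
        assert zone.contains(unclassified).all()

    def test_band_lines_are_parallel(self, rng):
        folded = rng.normal([2.0, 0.5], 0.3, size=(12, 2))
        unfolded = rng.normal([-2.0, 0.5], 0.3, size=(12, 2))
        unclassified = rng.normal([0.0, 0.5], 0.5, size=(12, 2))
        zone = delimit_twilight_zone(folded, unfolded, unclassified)
        assert zone.base_line.a == zone.offset_line.a
        assert zone.base_line.b == zone.offset_line.b

    def test_coverage_is_minimal_at_a_point_margin(self, rng):
        folded = rng.normal([2.0, 0.0], 0.4, size=(10, 2))
        unfolded = rng.normal([-2.0, 0.0], 0.4, size=(10, 2))
        unclassified = rng.normal([0.0, 0.0], 0.8, size=(20, 2))
        zone = delimit_twilight_zone(folded, unfolded, unclassified)
        assert zone.feasible
        assert zone.contained_fraction >= 0.75
        d = zone.base_line.signed_distance(unclassified)
        # the far band edge passes through an unclassified point...
        margins = np.abs(d - (zone.base_line.c - zone.offset_line.c))
        assert margins.min() < 1e-9
        # ...and any strictly smaller offset drops below coverage
        offset = zone.base_line.c - zone.offset_line.c
        inside = np.abs(d[np.sign(d) == np.sign(offset)])
        smaller = np.sort(inside)[::-1]
        smaller = smaller[smaller < abs(offset) - 1e-12]
        if smaller.size:
            lo, hi = sorted((0.0, np.sign(offset) * smaller[0]))
            frac = np.mean((d >= lo - 1e-9) & (d <= hi + 1e-9))
            assert frac < 0.75

    def test_infeasible_when_no_line_reaches_sensitivity(self):
        # classified and unclassified points coincide: no pair-line can put
        # 80% of the unclassified on one side without the same classified
        # fraction
        pts = [[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]]
        zone = delimit_twilight_zone(pts, pts, pts, min_sensitivity=1.01)
        assert not zone.feasible

    def test_no_unclassified_points_rejected(self):
        with pytest.raises(ValueError, match="no unclassified"):
            delimit_twilight_zone([[0, 0]], [[1, 1]], [])


class TestTwilightZoneDelimiterEstimator:
    def test_fit_predict_matches_functional_route(self, rng):
        from twilightfold import TwilightZoneDelimiter

        folded = rng.normal([2.0, 0.0], 0.3, size=(12, 2))
        unfolded = rng.normal([-2.0, 0.0], 0.3, size=(12, 2))
        unclassified = rng.normal([0.0, 0.0], 0.4, size=(12, 2))
        X = np.vstack([folded, unfolded, unclassified])
        y = [FOLDED] * 12 + [UNFOLDED] * 12 + [UNCLASSIFIED] * 12
        est = TwilightZoneDelimiter(random_state=0).fit(X, y)
        plain = delimit_twilight_zone(folded, unfolded, unclassified,
                                      random_state=0)
        assert est.zone_.width == plain.width
        assert est.predict(unclassified).mean() >= 0.75

    def test_param_protocol(self):
        from sklearn.base import clone

        from twilightfold import TwilightZoneDelimiter

        est = TwilightZoneDelimiter(coverage=0.9)
        assert clone(est).get_params()["coverage"] == 0.9
        with pytest.raises(ValueError, match="unknown parameter"):
            est.set_params(bogus=1)

    def test_missing_group_rejected(self, rng):
        from twilightfold import TwilightZoneDelimiter

        X = rng.normal(size=(10, 2))
        y = [FOLDED] * 5 + [UNFOLDED] * 5
        with pytest.raises(ValueError, match="unclassified"):
            TwilightZoneDelimiter().fit(X, y)


class TestBinnedZones:
    def test_single_bin_equals_plain_delimitation(self, rng):
        folded = points(rng.normal([2, 0], 0.3, size=(10, 2)), FOLDED,
                        lengths=[60] * 10)
        unfolded = points(rng.normal([-2, 0], 0.3, size=(10, 2)), UNFOLDED,
                          lengths=[60] * 10)
        unclassified = points(rng.normal([0, 0], 0.4, size=(10, 2)),
                              UNCLASSIFIED, lengths=[60] * 10)
        all_points = folded + unfolded + unclassified
        zones = binned_twilight_zones(all_points, bin_edges=(50, 100))
        assert set(zones) == {"50-99"}
        plain = delimit_twilight_zone(
            [p.xy for p in folded], [p.xy for p in unfolded],
            [p.xy for p in unclassified],
        )
        assert zones["50-99"].width == pytest.approx(plain.width, abs=1e-12)

    def test_empty_bin_reported_as_skipped(self, rng):
        folded = points(rng.normal([2, 0], 0.3, size=(5, 2)), FOLDED,
                        lengths=[60] * 5)
        unfolded = points(rng.normal([-2, 0], 0.3, size=(5, 2)), UNFOLDED,
                          lengths=[60] * 5)
        unclassified = points(rng.normal([0, 0], 0.3, size=(5, 2)),
                              UNCLASSIFIED, lengths=[60] * 5)
        zones = binned_twilight_zones(
            folded + unfolded + unclassified, bin_edges=(50, 100, 200)
        )
        assert zones["100-199"] is None
        assert zones["50-99"] is not None

    def test_band_width_narrows_when_scatter_shrinks_with_length(self, rng):
        # generator built so longer chains have tighter composition scatter:
        # the per-bin band width must decrease
        zones = {}
        all_points = []
        for lo, sd in ((50, 0.6), (100, 0.3), (200, 0.15)):
            n = 25
            length = [lo + 10] * n
            all_points += points(
                rng.normal([2, 0], sd, size=(n, 2)), FOLDED, length
            )
            all_points += points(
                rng.normal([-2, 0], sd, size=(n, 2)), UNFOLDED, length
            )
            all_points += points(
                rng.normal([0, 0], sd, size=(n, 2)), UNCLASSIFIED, length
            )
        zones = binned_twilight_zones(all_points, bin_edges=(50, 100, 200, 300))
        widths = [zones[k].width for k in ("50-99", "100-199", "200-299")]
        assert widths[0] > widths[1] > widths[2]
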