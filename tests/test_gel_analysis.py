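"""Spot detection, reference selection, matching and normalization."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import cKDTree

from bulb2de.cohort import random_gel, render_gel
from bulb2de.gel_analysis import (DegenerateGelError, GelSpotTable,
                                  RegistrationError, detect_spots,
                                  match_spots, normalize_volumes,
                                  select_reference)
from conftest import make_gel


class TestDetectSpots:
    def test_single_noiseless_spot_recovered_precisely(self):
        gel = make_gel("g", [("a", 400.3, 250.7, 500.0)])
        img = render_gel(gel, read_noise=0)
        table = detect_spots(img)
        assert len(table) == 1
        row = table.spots.iloc[0]
        assert abs(row.x - 400.3) < 0.5 and abs(row.y - 250.7) < 0.5
        assert row.volume == pytest.approx(20.0 * 500.0, rel=0.02)

    def test_blank_and_constant_images_give_empty_tables(self):
        assert len(detect_spots(np.zeros((64, 64)))) == 0
        assert len(detect_spots(np.full((64, 64), 300.0))) == 0

    def test_two_distant_spots_resolved(self):
        gel = make_gel("g", [("a", 300.0, 300.0, 400.0),
                             ("b", 300.0, 340.0, 400.0)])  # 10 sigma apart
        img = render_gel(gel, read_noise=0, spot_sigma=4.0)
        assert len(detect_spots(img)) == 2

    def test_noiseless_cohort_recovery(self, rng):
        """≥99% of resolvable planted spots recovered within 2% volume."""
        gel = random_gel("g", 400, rng, min_separation=14.0)
        img = render_gel(gel, read_noise=0, gain=50.0)
        table = detect_spots(img)
        tree = cKDTree(table.spots[["x", "y"]].to_numpy())
        d, i = tree.query(gel.spots[["x", "y"]].to_numpy())
        vols = table.spots["volume"].to_numpy()[i]
        truth = 50.0 * gel.spots["volume"].to_numpy()
        good = (d < 1.0) & (np.abs(vols - truth) / truth <= 0.02)
        assert good.mean() >= 0.99

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            detect_spots(np.zeros((8, 8)), min_volume=0)
        with pytest.raises(ValueError):
            detect_spots(np.zeros((4, 4, 3)))


class TestSelectReference:
    def test_argmax_and_tiebreak_and_closure(self, rng):
        gels = [random_gel("b", 30, rng), random_gel("a", 50, rng),
                random_gel("c", 40, rng)]
        assert select_reference(gels) == "a"
        tie = [random_gel("g2", 30, rng), random_gel("g1", 30, rng)]
        assert select_reference(tie) == "g1"
        assert select_reference(gels) in {g.gel_id for g in gels}

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            select_reference([])


class TestNormalizeVolumes:
    def test_exact_arithmetic(self):
        gel = make_gel("g", [("a", 0, 0, 1.0), ("b", 1, 1, 1.0),
                             ("c", 2, 2, 2.0)])
        out = normalize_volumes(gel)
        assert list(out.spots["normalized_volume"]) == [25.0, 25.0, 50.0]

    def test_scale_invariance_and_idempotence(self, rng):
        gel = random_gel("g", 25, rng)
        out1 = normalize_volumes(gel)
        scaled = make_gel("g", list(zip(
            gel.spots["spot_id"], gel.spots["x"], gel.spots["y"],
            7.0 * gel.spots["volume"])))
        out7 = normalize_volumes(scaled)
        assert np.allclose(out1.spots["normalized_volume"],
                           out7.spots["normalized_volume"])
        again = normalize_volumes(out1)
        assert np.allclose(again.spots["normalized_volume"],
                           out1.spots["normalized_volume"])

    def test_sums_to_100(self, rng):
        gel = random_gel("g", 40, rng)
        total = normalize_volumes(gel).spots["normalized_volume"].sum()
        assert total == pytest.approx(100.0, rel=1e-9)

    def test_degenerate_gel_rejected(self):
        gel = make_gel("g", [("a", 0, 0, 0.0)])
        with pytest.raises(DegenerateGelError):
            normalize_volumes(gel)


class TestMatchSpots:
    def test_identical_gels_fully_matched(self, rng):
        a = random_gel("a", 60, rng)
        b = GelSpotTable(gel_id="b", spots=a.spots.copy())
        clusters = match_spots([a, b], "a", radius=3.0)
        assert len(clusters) == 60
        assert all(set(c.members) == {"a", "b"} for c in clusters)

    def test_planted_affine_fully_recovered(self, rng):
        a = random_gel("a", 80, rng, min_separation=8.0)
        theta, s, (tx, ty) = 0.01, 1.01, (5.0, -3.0)
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        xy = a.spots[["x", "y"]].to_numpy() @ (s * rot).T + (tx, ty)
        b = make_gel("b", list(zip(a.spots["spot_id"], xy[:, 0], xy[:, 1],
                                   a.spots["volume"])))
        clusters = match_spots([a, b], "a", radius=3.0)
        correct = sum(
            1 for c in clusters
            if c.members.get("a") == c.members.get("b"))
        assert correct == 80

    def test_dropped_spot_recorded_absent(self, rng):
        a = random_gel("a", 40, rng, min_separation=8.0)
        b = GelSpotTable(gel_id="b", spots=a.spots.iloc[1:].copy())
        clusters = match_spots([a, b], "a", radius=3.0)
        dropped = a.spots["spot_id"].iloc[0]
        c = next(c for c in clusters if c.members.get("a") == dropped)
        assert "b" not in c.members

    def test_spots_absent_from_reference_form_one_cluster(self, rng):
        """A spot present only outside the reference group is still
        tracked as a single cluster across those gels."""
        a = random_gel("a", 40, rng, min_separation=8.0)
        extra = ("extra", 123.0, 456.0, 50.0)
        others = [
            make_gel(f"g{i}", list(zip(
                a.spots["spot_id"], a.spots["x"], a.spots["y"],
                a.spots["volume"])) + [extra])
            for i in range(3)]
        clusters = match_spots([a] + others, "a", radius=3.0)
        extras = [c for c in clusters if "a" not in c.members]
        assert len(extras) == 1
        assert set(extras[0].members) == {"g0", "g1", "g2"}

    def test_order_invariance_up_to_labels(self, rng):
        gels = [random_gel(g, 50, rng) for g in ("a", "b", "c")]
        c1 = match_spots(gels, "a", radius=3.0)
        c2 = match_spots(gels[::-1], "a", radius=3.0)
        as_sets = lambda cs: {frozenset(c.members.items()) for c in cs}
        assert as_sets(c1) == as_sets(c2)

    def test_too_few_pairs_raises_registration_error(self):
        a = make_gel("a", [("s1", 10, 10, 5.0)])
        b = make_gel("b", [("t1", 12, 11, 5.0)])
        with pytest.raises(RegistrationError):
            match_spots([a, b], "a", radius=3.0)

    def test_unknown_reference_rejected(self, rng):
        with pytest.raises(ValueError):
            match_spots([random_gel("a", 10, rng)], "zz", radius=3.0)


def test_spot_table_csv_roundtrip(tmp_path, rng):
    gel = normalize_volumes(random_gel("gelX", 12, rng))
    path = tmp_path / "spots.csv"
    gel.to_csv(path)
    back = GelSpotTable.from_csv(path)
    assert back.gel_id == "gelX"
    pd.testing.assert_frame_equal(back.spots, gel.spots)


def test_duplicate_spot_ids_rejected():
    with pytest.raises(ValueError):
        make_gel("g", [("a", 0, 0, 1.0), ("a", 1, 1, 2.0)])
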