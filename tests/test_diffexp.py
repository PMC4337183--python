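"""SVQ computation and the differential calling rules.

The calling logic is cross-checked against an independently written
exhaustive rule table (`oracle_call`) that re-states the published
procedure as literal nested conditions.
"""

import math

import numpy as np
import pytest

from bulb2de.cohort import EffectDesign, generate_cohort, plant_effects
from bulb2de.diffexp import (DifferentialCall, EmptyClusterError, SVQResult,
                             aggregate_protein, call_absence, call_cluster,
                             call_spot, compute_svq, summarize, tallies,
                             validate_thresholds)
from bulb2de.gel_analysis import MatchedSpotCluster, normalize_volumes
from conftest import make_gel


def oracle_call(svq, pres_ref, pres_cmp, low=0.6, high=1.67, min_gels=4,
                max_absent=1):
    """Independent exhaustive restatement of the calling rules."""
    if pres_ref >= min_gels and pres_cmp <= max_absent:
        return "absent_cmp"
    if pres_cmp >= min_gels and pres_ref <= max_absent:
        return "absent_p90"
    if not (pres_ref >= min_gels and pres_cmp >= min_gels):
        if math.isnan(svq):
            return "indeterminate"
        if low < svq < high:
            return "unchanged"
        if (0 < pres_ref < min_gels) or (0 < pres_cmp < min_gels):
            return "indeterminate"
    if math.isnan(svq):
        return "indeterminate"
    if svq <= low:
        return "up"
    if svq >= high:
        return "down"
    return "unchanged"


def res(svq, pres_ref, pres_cmp, cid="c"):
    return SVQResult(cluster_id=cid, svq=svq, presence_ref=pres_ref,
                     presence_cmp=pres_cmp)


def cluster_from(spot_id, gels):
    return MatchedSpotCluster(
        cluster_id="c0", x_ref=0.0, y_ref=0.0,
        members={g.gel_id: spot_id for g in gels
                 if spot_id in set(g.spots["spot_id"])})


class TestComputeSvq:
    def _gels(self, volumes_by_gel):
        gels = []
        for gid, vols in volumes_by_gel.items():
            rows = [(f"s{i}", 10.0 * i, 10.0 * i, v)
                    for i, v in enumerate(vols)]
            gels.append(normalize_volumes(make_gel(gid, rows)))
        return gels

    def test_equal_group_means_give_unity(self):
        ref = self._gels({"r1": [1, 1], "r2": [1, 1]})
        cmp_ = self._gels({"c1": [2, 2], "c2": [2, 2]})
        c = cluster_from("s0", ref + cmp_)
        out = compute_svq(c, ref, cmp_)
        assert out.svq == pytest.approx(1.0)
        assert (out.presence_ref, out.presence_cmp) == (2, 2)

    def test_swapping_groups_gives_reciprocal(self):
        ref = self._gels({"r1": [3, 1], "r2": [3, 1]})
        cmp_ = self._gels({"c1": [1, 1], "c2": [1, 1]})
        c = cluster_from("s0", ref + cmp_)
        forward = compute_svq(c, ref, cmp_).svq
        backward = compute_svq(c, cmp_, ref).svq
        assert forward == pytest.approx(1.0 / backward)

    def test_planted_noiseless_effect_recovered_exactly(self, small_catalog):
        design = EffectDesign(n_down=4, effect_size=2.5, noise_cv=0.0,
                              dropout=0.0, seed=21)
        truth = plant_effects(small_catalog, design)
        cmp_gels, ref_gels = generate_cohort(truth, design,
                                             affine_jitter=False,
                                             position_jitter=0.0)
        cmp_gels = [normalize_volumes(g) for g in cmp_gels]
        ref_gels = [normalize_volumes(g) for g in ref_gels]
        acc = next(a for a, c in truth.classes.items() if c == "down")
        sid = f"{acc}.0"
        c = cluster_from(sid, cmp_gels + ref_gels)
        # normalization rescales both groups by their (slightly different)
        # gel totals; compare against the truth-implied quotient
        cmp_tot = cmp_gels[0].spots["volume"].sum()
        ref_tot = ref_gels[0].spots["volume"].sum()
        expected = 2.5 * cmp_tot / ref_tot
        assert compute_svq(c, ref_gels, cmp_gels).svq == pytest.approx(
            expected, rel=1e-9)

    def test_empty_cluster_rejected(self):
        gels = self._gels({"r1": [1.0]})
        c = MatchedSpotCluster("c9", {}, 0.0, 0.0)
        with pytest.raises(EmptyClusterError):
            compute_svq(c, gels, [])


class TestCallingRules:
    def test_boundary_svq_06_is_up(self):
        assert call_spot(res(0.6, 6, 6)).status == "up"
        assert call_spot(res(1.67, 6, 6)).status == "down"

    def test_under_replicated_differential_is_indeterminate(self):
        assert call_spot(res(0.59, 6, 3)).status == "indeterminate"

    def test_unity_is_unchanged(self):
        assert call_spot(res(1.0, 6, 6)).status == "unchanged"

    def test_absence_patterns(self):
        assert call_absence(res(float("nan"), 6, 0)).status == "absent_cmp"
        assert call_absence(res(float("nan"), 0, 6)).status == "absent_p90"
        assert call_absence(res(1.0, 6, 6)) is None
        assert call_absence(res(1.0, 5, 2)).status == "indeterminate"

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            call_spot(res(1.0, 6, 6), low=1.2, high=1.67)

    def test_non_reciprocal_thresholds_warn(self):
        with pytest.warns(UserWarning, match="reciprocal"):
            validate_thresholds(0.5, 1.67)

    def test_oracle_equivalence_exhaustive(self):
        """call_cluster equals the independent rule table over the full
        presence grid and a sweep of SVQ values."""
        svqs = [float("nan"), 0.3, 0.6, 0.61, 1.0, 1.66, 1.67, 4.0]
        for pr in range(7):
            for pc in range(7):
                for svq in svqs:
                    got = call_cluster(res(svq, pr, pc)).status
                    want = oracle_call(svq, pr, pc)
                    assert got == want, (svq, pr, pc, got, want)

    def test_direction_antisymmetry(self):
        """Exchanging the groups maps up↔down and the absences.

        Exact antisymmetry needs exactly reciprocal thresholds; the
        published 1.67 is the two-decimal rounding of 1/0.6, so the pair
        (0.6, 1/0.6) is used here.
        """
        flip = {"up": "down", "down": "up", "absent_cmp": "absent_p90",
                "absent_p90": "absent_cmp", "unchanged": "unchanged",
                "indeterminate": "indeterminate"}
        low, high = 0.6, 1.0 / 0.6
        svqs = [0.3, 0.6, 1.0, 1.0 / 0.6, 4.0, float("nan")]
        for pr in range(7):
            for pc in range(7):
                for svq in svqs:
                    fwd = call_cluster(res(svq, pr, pc), low=low,
                                       high=high).status
                    inv = 1.0 / svq if svq and not math.isnan(svq) else svq
                    rev = call_cluster(res(inv, pc, pr), low=low,
                                       high=high).status
                    assert rev == flip[fwd], (svq, pr, pc, fwd, rev)


class TestAggregateProtein:
    def spot(self, svq, status, subject="P1"):
        return DifferentialCall(subject=subject, status=status,
                                svq_values=(svq,), mean_svq=svq,
                                presence_ref=6, presence_cmp=6)

    def test_single_spot_passthrough(self):
        call = aggregate_protein([self.spot(2.0, "down")])
        assert call.status == "down"
        assert call.mean_svq == pytest.approx(2.0)

    def test_conflicting_directions_flagged_up_down(self):
        call = aggregate_protein([self.spot(0.5, "up"),
                                  self.spot(2.0, "down")])
        assert call.status == "up_down"

    def test_mean_rule(self):
        call = aggregate_protein([self.spot(2.0, "down"),
                                  self.spot(2.2, "down")])
        assert call.mean_svq == pytest.approx(2.1)
        assert call.status == "down"

    def test_mean_can_soften_a_single_outlier(self):
        # one changed spot + one unchanged spot: mean decides
        call = aggregate_protein([self.spot(1.7, "down"),
                                  self.spot(1.0, "unchanged")])
        assert call.status == "unchanged"

    def test_absence_propagates_only_when_unanimous(self):
        absent = DifferentialCall(subject="P1", status="absent_cmp",
                                  svq_values=(float("nan"),),
                                  mean_svq=float("nan"),
                                  presence_ref=6, presence_cmp=0)
        assert aggregate_protein([absent, absent]).status == "absent_cmp"
        mixed = aggregate_protein([absent, self.spot(1.0, "unchanged")])
        assert mixed.status == "unchanged"

    def test_indeterminate_spots_carry_no_evidence(self):
        ind = DifferentialCall(subject="P1", status="indeterminate",
                               svq_values=(0.2,), mean_svq=0.2,
                               presence_ref=2, presence_cmp=6)
        assert aggregate_protein([ind]).status == "indeterminate"
        assert aggregate_protein([ind, self.spot(1.0, "unchanged")]
                                 ).status == "unchanged"

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            aggregate_protein([])


class TestSummarize:
    def test_empty_input_gives_all_zero_table(self):
        table = summarize([], {})
        assert int(table.to_numpy().sum()) == 0

    def test_accounting_identity(self):
        calls = {
            "A": DifferentialCall("A", "up", (0.5,), 0.5),
            "B": DifferentialCall("B", "down", (2.0,), 2.0),
            "C": DifferentialCall("C", "absent_cmp"),
            "D": DifferentialCall("D", "absent_p90"),
            "E": DifferentialCall("E", "unchanged", (1.0,), 1.0),
            "F": DifferentialCall("F", "up_down", (0.5, 2.0), 1.25),
        }
        cats = dict.fromkeys(calls, "pcm")
        t = tallies(summarize(calls, cats))
        assert t["total"] == t["up"] + t["down"] + t["absent_cmp"] + \
            t["absent_p90"] == 4
        assert t["up_down"] == 1 and t["unchanged"] == 1

    def test_unknown_category_warned_and_counted(self):
        calls = {"Z": DifferentialCall("Z", "up", (0.5,), 0.5)}
        with pytest.warns(UserWarning, match="no category"):
            table = summarize(calls, {})
        assert table.loc["unknown", "up"] == 1
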