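"""Hit-triage cascade: fingerprints, similarity, filters, clustering."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from dockpharm.triage import (
    Fingerprint,
    LigandRecord,
    MissingFingerprintError,
    SmilesParseError,
    analog_search,
    campaign_summary,
    fingerprint,
    hit_rate,
    leader_cluster,
    novelty_filter,
    percent_fulfilment,
    property_filter,
    tanimoto,
)

from helpers import brute_force_leader_partition


def rec(i, smiles="CCO", mw=400.0, clogp=4.0, score=-30.0):
    return LigandRecord(id=f"m{i}", smiles=smiles, mw=mw, clogp=clogp, score=score, rank=i)


class TestFingerprint:
    def test_deterministic_and_canonical(self):
        assert fingerprint("CCO") == fingerprint("CCO")
        assert fingerprint("CCO") == fingerprint("OCC")

    def test_unparseable_smiles_names_offender(self):
        with pytest.raises(SmilesParseError, match="not-a-smiles"):
            fingerprint("not-a-smiles")

    def test_dissimilar_molecules_have_low_tc(self):
        tc = tanimoto(fingerprint("c1ccccc1"), fingerprint("CCCCCC"))
        assert tc < 0.2


class TestTanimoto:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            (frozenset({1, 2, 3}), frozenset({1, 2, 3}), 1.0),
            (frozenset({1, 2}), frozenset({3, 4}), 0.0),
            (frozenset({1, 2, 3, 4}), frozenset({3, 4, 5}), 2 / 5),
        ],
    )
    def test_set_formula(self, a, b, expected):
        fa, fb = Fingerprint(bits=a), Fingerprint(bits=b)
        assert tanimoto(fa, fb) == pytest.approx(expected)

    def test_both_empty_defined_zero_with_warning(self):
        empty = Fingerprint(bits=frozenset())
        with pytest.warns(UserWarning):
            assert tanimoto(empty, empty) == 0.0

    def test_incompatible_parameters_rejected(self):
        with pytest.raises(ValueError):
            tanimoto(Fingerprint(bits=frozenset({1})), Fingerprint(bits=frozenset({1}), n_bits=1024))

    @given(
        a=st.frozensets(st.integers(0, 127), min_size=1, max_size=30),
        b=st.frozensets(st.integers(0, 127), min_size=1, max_size=30),
    )
    def test_symmetric_bounded_and_identity(self, a, b):
        fa, fb = Fingerprint(bits=a, n_bits=128), Fingerprint(bits=b, n_bits=128)
        tc = tanimoto(fa, fb)
        assert tc == tanimoto(fb, fa)
        assert 0.0 <= tc <= 1.0
        assert (tc == 1.0) == (a == b)


class TestPropertyFilter:
    def test_closed_interval_boundaries(self):
        inside = rec(1, mw=350.0, clogp=3.0)
        below = rec(2, mw=349.9, clogp=4.0)
        kept = property_filter([inside, below], 350, 500, 3, 5)
        assert kept == [inside]

    def test_matches_brute_force_predicate_and_preserves_order(self):
        records = [
            rec(i, mw=mw, clogp=cl)
            for i, (mw, cl) in enumerate(
                [(340, 4), (350, 3), (420, 5.2), (500, 5), (501, 4),
                 (460, 2.9), (355, 4.4), (480, 3.3), (390, 6), (350, 2.99)]
            )
        ]
        kept = property_filter(records, 350, 500, 3, 5)
        oracle = [r for r in records if 350 <= r.mw <= 500 and 3 <= r.clogp <= 5]
        assert kept == oracle
        assert len(kept) == 4

    def test_idempotent(self):
        records = [rec(i, mw=300 + 30 * i, clogp=2 + 0.5 * i) for i in range(8)]
        once = property_filter(records, 350, 500, 3, 5)
        assert property_filter(once, 350, 500, 3, 5) == once

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            property_filter([], 500, 350, 3, 5)
        with pytest.raises(ValueError):
            property_filter([], math.nan, 500, 3, 5)


class TestLeaderCluster:
    def test_identical_molecules_form_one_cluster(self):
        records = [rec(i, smiles="CCO", score=-30 + i) for i in range(5)]
        fps = {r.id: fingerprint(r.smiles) for r in records}
        clusters = leader_cluster(records, fps)
        assert len(clusters) == 1
        assert clusters[0].representative_id == records[0].id
        assert clusters[0].member_ids == [r.id for r in records]

    def test_all_dissimilar_are_singletons(self):
        smiles = ["CCO", "c1ccccc1", "C1CCCCC1", "CC(=O)O", "CCN"]
        records = [rec(i, smiles=s, score=-30 + i) for i, s in enumerate(smiles)]
        fps = {r.id: fingerprint(r.smiles) for r in records}
        clusters = leader_cluster(records, fps)
        assert len(clusters) == len(records)

    def test_partition_and_representative_invariants(self, small_library):
        records, fps = small_library
        clusters = leader_cluster(records, fps)
        members = [m for c in clusters for m in c.member_ids]
        assert sorted(members) == sorted(r.id for r in records)
        scores = {r.id: r.score for r in records}
        for c in clusters:
            assert c.representative_id in c.member_ids
            rep_fp = fps[c.representative_id]
            assert all(scores[c.representative_id] <= scores[m] for m in c.member_ids)
            assert all(tanimoto(rep_fp, fps[m]) >= 0.5 for m in c.member_ids)

    def test_matches_brute_force_oracle(self, small_library):
        records, fps = small_library
        subset = records[:50]
        clusters = leader_cluster(subset, {r.id: fps[r.id] for r in subset})
        oracle = brute_force_leader_partition(
            [r.id for r in subset],
            [set(fps[r.id].bits) for r in subset],
            [r.score for r in subset],
            threshold=0.5,
        )
        assert [c.member_ids for c in clusters] == oracle

    def test_unsorted_input_rejected(self):
        records = [rec(1, score=-20), rec(2, score=-30)]
        fps = {r.id: fingerprint(r.smiles) for r in records}
        with pytest.raises(ValueError, match="sorted"):
            leader_cluster(records, fps)

    def test_missing_fingerprint_keyed_error(self):
        records = [rec(1)]
        with pytest.raises(MissingFingerprintError, match="m1"):
            leader_cluster(records, {})


class TestNoveltyFilter:
    def test_identical_to_reference_rejected(self):
        reports = novelty_filter([rec(1, smiles="CCO")], ["CCO"])
        assert reports[0].max_tc == 1.0
        assert not reports[0].kept

    def test_empty_reference_set_keeps_all(self):
        reports = novelty_filter([rec(1, smiles="CCO")], [])
        assert reports[0].kept
        assert reports[0].max_tc == 0.0
        assert reports[0].nearest_reference_id is None

    def test_threshold_inclusive_on_rejection_side(self):
        # rejection applies at Tc >= threshold, so a candidate exactly at
        # the threshold is not pursued
        candidate = rec(1, smiles="CCCCCCCO")
        ref = "CCCCCCC"
        tc = tanimoto(fingerprint(candidate.smiles), fingerprint(ref))
        reports = novelty_filter([candidate], [ref], tc_threshold=tc)
        assert reports[0].max_tc == pytest.approx(tc)
        assert not reports[0].kept

    def test_monotone_in_threshold(self, small_library):
        records, _ = small_library
        candidates = records[:20]
        refs = [r.smiles for r in records[50:55]]
        kept_038 = {r.candidate_id for r in novelty_filter(candidates, refs, 0.38)}
        kept_060 = {r.candidate_id for r in novelty_filter(candidates, refs, 0.60)}
        kept_038_set = {
            r.candidate_id for r in novelty_filter(candidates, refs, 0.38) if r.kept
        }
        kept_060_set = {
            r.candidate_id for r in novelty_filter(candidates, refs, 0.60) if r.kept
        }
        assert kept_038_set <= kept_060_set
        assert kept_038 == kept_060  # report covers every candidate


class TestAnalogSearch:
    def test_hit_itself_first_with_unit_similarity(self, small_library):
        records, _ = small_library
        hit = records[0]
        analogs = analog_search(hit, records)
        assert analogs[0].smiles == hit.smiles

    def test_recovers_planted_family(self, small_library):
        from dockpharm.synth import planted_family

        records, _ = small_library
        hit = records[0]
        fam = planted_family(hit.id)
        analogs = analog_search(hit, records, tc_min=0.5)
        assert {planted_family(a.id) for a in analogs} == {fam}
        assert sorted(a.id for a in analogs) == sorted(
            r.id for r in records if planted_family(r.id) == fam
        )

    def test_unrelated_pool_empty(self):
        hit = rec(0, smiles="c1ccc2c(c1)oc(n2)CCNC(=O)C")
        pool = [rec(1, smiles="C1CCN(CC1)S(=O)(=O)c1ccc(cc1)OC")]
        assert analog_search(hit, pool) == []


class TestCampaignSummary:
    def test_orientations_times_conformations(self):
        s = campaign_summary(74_000_000, 18_000_000, 4706, 645)
        assert s.mean_poses_per_molecule == 3_035_370
        assert s.poses_per_molecule_millions == 3.04
        assert s.total_complexes == 18_000_000 * 3_035_370

    def test_zero_orientations(self):
        assert campaign_summary(10, 10, 0, 645).mean_poses_per_molecule == 0

    def test_small_product(self):
        assert campaign_summary(20, 10, 10, 10).total_complexes == 1000

    def test_fit_exceeding_input_rejected(self):
        with pytest.raises(ValueError):
            campaign_summary(10, 11, 1, 1)


class TestHitRate:
    def test_strictly_above_threshold(self):
        n, rate, rounded = hit_rate([60.0] * 9 + [50.0, 10.0] + [20.0] * 35)
        assert n == 9
        assert rounded == 20
        assert rate == pytest.approx(100 * 9 / 46)

    @pytest.mark.parametrize(
        "values, expected", [([10, 20], 0), ([60, 70, 200], 100)]
    )
    def test_extremes(self, values, expected):
        assert hit_rate(values)[2] == expected

    def test_empty_list_undefined(self):
        with pytest.raises(ValueError):
            hit_rate([])


def test_percent_fulfilment_rounding():
    exact, rounded = percent_fulfilment(52, 60)
    assert rounded == 87
    assert exact == pytest.approx(86.6666, abs=1e-3)
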