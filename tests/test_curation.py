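"""Unit conversion, class mapping, filtering and duplicate merging."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import solstack as ss
from solstack.curation import ExternalRecord, curate_external_records


class TestUnitConversion:
    def test_one_molar_is_zero(self):
        assert ss.to_logS(1.0, ss.Unit.MOL_L, 100.0) == 0.0

    def test_millimolar(self):
        assert ss.to_logS(0.001, ss.Unit.MOL_L, 100.0) == pytest.approx(-3.0)

    def test_gram_per_liter_inverse_of_validation_row(self):
        # 73.701 g/L of levodropropizine (MW 236.3) is Log S -0.506
        assert ss.to_logS(73.701, ss.Unit.G_L, 236.315) == pytest.approx(-0.506, abs=1e-3)

    def test_mg_per_ml_equals_g_per_l(self):
        assert ss.to_logS(5.0, ss.Unit.MG_ML, 200.0) == ss.to_logS(5.0, ss.Unit.G_L, 200.0)

    def test_logS_passes_through(self):
        assert ss.to_logS(-4.2, ss.Unit.LOGS, 123.0) == -4.2

    def test_nonpositive_linear_value_rejected(self):
        with pytest.raises(ValueError):
            ss.to_logS(0.0, ss.Unit.G_L, 100.0)
        with pytest.raises(ValueError):
            ss.to_logS(-1.0, ss.Unit.MOL_L, 100.0)

    def test_logS_to_gL(self):
        assert ss.logS_to_gL(0.0, 100.0) == pytest.approx(100.0)
        assert ss.logS_to_gL(-0.506, 236.315) == pytest.approx(73.701, abs=0.05)
        # deoxyinosine, MW 252.23
        assert ss.logS_to_gL(-1.163, 252.23) == pytest.approx(17.3, abs=0.05)

    @given(st.floats(-10, 2), st.floats(50, 800))
    @settings(max_examples=50, deadline=None)
    def test_round_trip(self, logS, mw):
        gL = ss.logS_to_gL(logS, mw)
        assert ss.to_logS(gL, ss.Unit.G_L, mw) == pytest.approx(logS, abs=1e-9)


class TestClassAssignment:
    @pytest.mark.parametrize("gL,cls", [
        (73.701, 2), (0.863, 5), (823.936, 1),
        (17.349, 3), (320.643, 1), (23.499, 3), (1.563, 4),
        (4.076, 4), (0.052, 6), (0.063, 6),
        (1e6, 0), (0.0, 6),
    ])
    def test_pinned(self, gL, cls):
        assert ss.assign_class(gL) == cls

    @pytest.mark.parametrize("gL,cls", [
        # boundary: exactly 1 mL/g stays in class 1 (left-closed mL intervals)
        (1000.0, 1), (100.0, 2), (1.0, 5), (0.1, 6),
    ])
    def test_boundaries_left_closed_on_ml_scale(self, gL, cls):
        assert ss.assign_class(gL) == cls

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            ss.assign_class(-0.1)

    @given(st.floats(1e-6, 1e7), st.floats(1e-6, 1e7))
    @settings(max_examples=200, deadline=None)
    def test_weakly_monotone(self, s1, s2):
        if s1 > s2:
            assert ss.assign_class(s1) <= ss.assign_class(s2)

    @given(st.floats(-9, 1.5), st.floats(60, 700))
    @settings(max_examples=100, deadline=None)
    def test_class_round_trip(self, logS, mw):
        cls = ss.logS_to_class(logS, mw)
        assert cls == ss.assign_class(ss.logS_to_gL(logS, mw))


class TestFilterRecord:
    def _rec(self, smiles, **kw):
        defaults = dict(value=1.0, unit=ss.Unit.G_L)
        defaults.update(kw)
        return ss.SolubilityRecord(smiles, **defaults)

    def test_single_atom_dropped(self):
        rec = self._rec("[He]")
        keep, reason = ss.filter_record(rec, ss.canonicalize("[He]"))
        assert not keep and reason == "single_atom"

    def test_charged_dropped(self):
        rec = self._rec("C[N+](C)(C)C")
        keep, reason = ss.filter_record(rec, ss.canonicalize("C[N+](C)(C)C"))
        assert not keep and reason == "charged"

    def test_neutral_metal_compound_kept(self):
        rec = self._rec("O[Na]", temperature_C=25.0, solvent="water")
        keep, reason = ss.filter_record(rec, ss.canonicalize("O[Na]"))
        assert keep and reason is None

    def test_temperature_window(self):
        rec = self._rec("CCO", temperature_C=40.0)
        keep, reason = ss.filter_record(rec, ss.canonicalize("CCO"))
        assert not keep and reason == "temperature"

    def test_missing_temperature_kept(self):
        rec = self._rec("CCO")
        keep, _ = ss.filter_record(rec, ss.canonicalize("CCO"))
        assert keep

    def test_non_aqueous_dropped(self):
        rec = self._rec("CCO", solvent="ethanol")
        keep, reason = ss.filter_record(rec, ss.canonicalize("CCO"))
        assert not keep and reason == "solvent"


class TestMergeDuplicates:
    def test_single_value(self):
        assert ss.merge_duplicates([-2.0]) == (-2.0, [-2.0])

    def test_two_values_always_averaged(self):
        consensus, kept = ss.merge_duplicates([-2.0, -2.6])
        assert consensus == pytest.approx(-2.3)
        assert kept == [-2.6, -2.0]

    def test_outlier_removed_iteratively(self):
        # SD of {-2.0,-2.1,-4.0} is 1.13 > 0.5; dropping -4.0 gives SD 0.07
        consensus, kept = ss.merge_duplicates([-2.0, -2.1, -4.0])
        assert consensus == pytest.approx(-2.05)
        assert kept == [-2.1, -2.0]

    def test_near_duplicates_collapse_to_one_occurrence(self):
        # two readings 0.005 apart count once; the third value then triggers
        # the two-record rule instead of outlier removal
        consensus, kept = ss.merge_duplicates([-2.000, -2.005, -4.0])
        assert len(kept) == 2
        assert consensus == pytest.approx((-2.0025 - 4.0) / 2)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ss.merge_duplicates([])

    @given(st.lists(st.floats(-8, 0), min_size=1, max_size=8))
    @settings(max_examples=200, deadline=None)
    def test_permutation_invariant_and_idempotent(self, values):
        rng = np.random.default_rng(0)
        consensus, kept = ss.merge_duplicates(values)
        shuffled = list(values)
        rng.shuffle(shuffled)
        assert ss.merge_duplicates(shuffled) == (consensus, kept)
        consensus2, kept2 = ss.merge_duplicates(kept)
        assert consensus2 == pytest.approx(consensus)

    @given(st.lists(st.floats(-8, 0), min_size=3, max_size=10))
    @settings(max_examples=200, deadline=None)
    def test_survivor_sd_bounded(self, values):
        _, kept = ss.merge_duplicates(values)
        if len(kept) > 2:
            assert np.std(kept, ddof=1) <= 0.5 + 1e-12


class TestCurateDataset:
    def test_same_molecule_two_records(self):
        recs = [ss.SolubilityRecord("CCO", -1.0, ss.Unit.LOGS),
                ss.SolubilityRecord("OCC", -1.5, ss.Unit.LOGS)]
        compounds, report = ss.curate_dataset(recs)
        assert len(compounds) == 1
        assert compounds[0].n_sources == 2
        assert compounds[0].logS == pytest.approx(-1.25)

    def test_disjoint_molecules(self):
        recs = [ss.SolubilityRecord("CCO", -1.0, ss.Unit.LOGS),
                ss.SolubilityRecord("CCN", -2.0, ss.Unit.LOGS)]
        compounds, _ = ss.curate_dataset(recs)
        assert len(compounds) == 2

    def test_accounting_exact(self, small_dataset):
        _, _, _, records = small_dataset
        records = records + [ss.SolubilityRecord("((", 1.0, ss.Unit.G_L),
                             ss.SolubilityRecord("[He]", 1.0, ss.Unit.G_L)]
        _, report = ss.curate_dataset(records)
        assert (report.n_records_kept + sum(report.drops_by_reason.values())
                == report.n_records_in)

    def test_class_consistent_with_consensus(self, small_dataset):
        _, _, _, records = small_dataset
        compounds, _ = ss.curate_dataset(records)
        for c in compounds:
            assert c.sol_class == ss.logS_to_class(c.logS, c.molecule.mol_weight)

    def test_multi_source_sd_within_threshold_on_noisy_data(self, small_dataset):
        _, _, _, records = small_dataset
        _, report = ss.curate_dataset(records)
        assert report.sd_multi_source, "fixture should contain >=3-source compounds"
        assert report.mean_sd_multi_source <= 0.5


class TestExcludeOverlap:
    def _compounds(self, smiles):
        return [ss.CuratedCompound(ss.canonicalize(s), -1.0, 1, None, 4)
                for s in smiles]

    def test_no_overlap(self):
        train = self._compounds(["CCO", "CCN"])
        kept, n = ss.exclude_overlap(train, [[ss.canonicalize("c1ccccc1")]])
        assert len(kept) == 2 and n == 0

    def test_full_overlap(self):
        train = self._compounds(["CCO"])
        kept, n = ss.exclude_overlap(train, [[ss.canonicalize("OCC")]])
        assert kept == [] and n == 1

    def test_partial_overlap(self):
        train = self._compounds(["CCO", "CCN", "CCC", "CCCC", "CCCCC"])
        kept, n = ss.exclude_overlap(train, [[ss.canonicalize("CCN")]])
        assert len(kept) == 4 and n == 1


class TestExternalRecords:
    def test_missing_units_dropped(self):
        (res,) = curate_external_records([ExternalRecord(
            "CCO", "very soluble indeed", source="db",
            temperature_C=25.0, solvent="water")])
        assert not res.keep and res.reason == "no_units"

    def test_missing_metadata_dropped(self):
        (res,) = curate_external_records([ExternalRecord("CCO", "1 g/L")])
        assert not res.keep and res.reason == "no_source"

    def test_upper_bound_becomes_class_only_record(self):
        (res,) = curate_external_records([ExternalRecord(
            "CCO", "< 0.01 g/L", source="db",
            temperature_C=25.0, solvent="water")])
        assert res.keep and res.class_only and res.sol_class == 6
        assert res.logS is None

    def test_ambiguous_bound_dropped(self):
        # "< 5 g/L" spans several classes: not convertible
        (res,) = curate_external_records([ExternalRecord(
            "CCO", "< 5 g/L", source="db",
            temperature_C=25.0, solvent="water")])
        assert not res.keep and res.reason == "ambiguous_range"

    def test_complete_record_kept_with_class(self):
        (res,) = curate_external_records([ExternalRecord(
            "CCO", "7.3 mg/mL", source="db",
            temperature_C=25.0, solvent="water")])
        assert res.keep and not res.class_only
        assert res.logS == pytest.approx(math.log10(7.3 / 46.069))
        assert res.sol_class == 4

    def test_temperature_rule(self):
        (res,) = curate_external_records([ExternalRecord(
            "CCO", "1 g/L", source="db", temperature_C=37.0, solvent="water")])
        assert not res.keep and res.reason == "temperature"
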