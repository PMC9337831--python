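import numpy as np
import pandas as pd
import pytest

from gatesite.contact_analysis import DifferentialContactTable
from gatesite.ensemble_io import ResidueID
from gatesite.family_alignment import FamilyAlignment
from gatesite.residue_triage import (
    STAGES,
    Candidate,
    ResidueAnnotation,
    TriageConfig,
    conservation_filter,
    differential_filter,
    proximity_filter,
    rank_and_suggest,
    run_triage,
    run_triage_fixture,
    structural_filter,
)
from gatesite.synthetic_data import GeneratorConfig, ResiduePlan, default_contact_plan, generate_ensembles

from test_contact_analysis import _profile_from_rows, _rid


def _table(rows):
    """rows: (rid, inhibitor_mean, natural_mean[, backbone_fraction])"""
    index = pd.Index([r[0] for r in rows], name="residue")
    inh = np.array([r[1] for r in rows], dtype=float)
    nat = np.array([r[2] for r in rows], dtype=float)
    bfrac = np.array([r[3] if len(r) > 3 else 0.0 for r in rows], dtype=float)
    return DifferentialContactTable(
        table=pd.DataFrame(
            {
                "inhibitor_mean": inh,
                "natural_mean": nat,
                "delta": inh - nat,
                "inhibitor_backbone_fraction": bfrac,
            },
            index=index,
        )
    )


class TestProximityFilter:
    def test_persistent_residue_retained(self):
        profile = _profile_from_rows([(_rid(1), 100, 0)], n_frames=100)
        assert proximity_filter(profile) == {_rid(1)}

    def test_single_frame_contact_dropped(self):
        profile = _profile_from_rows([(_rid(1), 1, 0)], n_frames=100)
        assert proximity_filter(profile) == set()

    def test_matches_raw_frame_recomputation(self):
        from oracles import naive_profile

        config = GeneratorConfig(seed=31, n_residues=20, n_frames=100)
        ens, _, _ = generate_ensembles(config)
        from gatesite.contact_analysis import residue_contact_profile

        profile = residue_contact_profile(ens)
        cfg = TriageConfig()
        expected = {
            rid
            for rid, rec in naive_profile(ens, 4.5).items()
            if rec["frames_with_contact"] / ens.n_frames >= cfg.min_occupancy
        }
        assert proximity_filter(profile, cfg) == expected


class TestStructuralFilter:
    def test_worked_example_yields_eight(self, worked_example):
        fixture = worked_example["fixture"]
        proximal = set(fixture.index)
        flags = {rid: bool(v) for rid, v in fixture["backbone_mediated"].items()}
        table = _table(
            [(rid, row["inhibitor_mean"], row["natural_mean"]) for rid, row in fixture.iterrows()]
        )
        surviving = structural_filter(
            proximal, table, worked_example["annotations"], backbone_flags=flags
        )
        assert {r.residue_number for r in surviving} == {593, 601, 617, 637, 650, 669, 671, 730}

    def test_no_annotations_no_backbone_is_identity(self):
        table = _table([(_rid(1), 2.0, 1.0, 0.1), (_rid(2), 1.0, 0.5, 0.0)])
        proximal = {_rid(1), _rid(2)}
        assert structural_filter(proximal, table, []) == proximal

    def test_all_critical_yields_empty(self):
        table = _table([(_rid(1), 2.0, 1.0), (_rid(2), 1.0, 0.5)])
        anns = [
            ResidueAnnotation("A", 1, "", True),
            ResidueAnnotation("A", 2, "", True),
        ]
        assert structural_filter({_rid(1), _rid(2)}, table, anns) == set()

    def test_backbone_fraction_threshold(self):
        table = _table([(_rid(1), 2.0, 1.0, 0.80), (_rid(2), 2.0, 1.0, 0.70)])
        surviving = structural_filter({_rid(1), _rid(2)}, table, [])
        assert surviving == {_rid(2)}  # 0.80 >= default 0.75 excluded

    def test_unknown_annotation_logged_and_ignored(self, caplog):
        table = _table([(_rid(1), 2.0, 1.0)])
        anns = [ResidueAnnotation("A", 99, "", True)]
        with caplog.at_level("WARNING", logger="gatesite.residue_triage"):
            surviving = structural_filter({_rid(1)}, table, anns)
        assert surviving == {_rid(1)}
        assert any("matches no proximal residue" in r.message for r in caplog.records)


class TestDifferentialFilter:
    def test_worked_example_five_then_three(self, worked_example):
        fixture = worked_example["fixture"]
        surviving = {
            rid for rid in fixture.index
            if rid.residue_number in {593, 601, 617, 637, 650, 669, 671, 730}
        }
        table = _table(
            [(rid, row["inhibitor_mean"], row["natural_mean"]) for rid, row in fixture.iterrows()]
        )
        flags = {rid: bool(v) for rid, v in fixture["low_contact"].items()}
        positive, sufficient = differential_filter(surviving, table, low_contact_flags=flags)
        assert {r.residue_number for r in positive} == {593, 637, 650, 669, 671}
        assert {r.residue_number for r in sufficient} == {593, 650, 671}

    def test_threshold_agrees_with_flags_on_worked_example(self, worked_example):
        # the bundled means are consistent: min_mean_contacts reproduces the flags
        fixture = worked_example["fixture"]
        surviving = {
            rid for rid in fixture.index
            if rid.residue_number in {593, 601, 617, 637, 650, 669, 671, 730}
        }
        table = _table(
            [(rid, row["inhibitor_mean"], row["natural_mean"]) for rid, row in fixture.iterrows()]
        )
        _, sufficient = differential_filter(surviving, table)
        assert {r.residue_number for r in sufficient} == {593, 650, 671}

    def test_tie_excluded(self):
        table = _table([(_rid(1), 2.0, 2.0)])
        positive, _ = differential_filter({_rid(1)}, table)
        assert positive == set()

    def test_matches_exhaustive_scan_oracle(self):
        rng = np.random.default_rng(41)
        rows = [
            (_rid(i), float(rng.uniform(0, 3)), float(rng.uniform(0, 3)))
            for i in range(50)
        ]
        table = _table(rows)
        surviving = {r[0] for r in rows}
        cfg = TriageConfig()
        positive, sufficient = differential_filter(surviving, table, cfg)
        exp_positive = {r for r, i, n in rows if i > n}
        exp_sufficient = {r for r, i, n in rows if i > n and i >= cfg.min_mean_contacts}
        assert positive == exp_positive
        assert sufficient == exp_sufficient

    def test_absent_residue_counts_as_zero(self):
        table = _table([(_rid(1), 2.0, 1.0)])
        positive, sufficient = differential_filter({_rid(1), _rid(2)}, table)
        assert positive == {_rid(1)}


class TestConservationFilter:
    def test_worked_example_drops_ile650(self, worked_example):
        sufficient = {
            ResidueID("A", 593, "", "LEU"),
            ResidueID("A", 650, "", "ILE"),
            ResidueID("A", 671, "", "LEU"),
        }
        kept = conservation_filter(sufficient, worked_example["family"], "MERTK")
        assert {r.residue_number for r in kept} == {593, 671}

    def test_identical_sequences_identity(self):
        aln = FamilyAlignment(sequences={"t": "LIVLIV", "a": "LIVLIV", "b": "LIVLIV"})
        sufficient = {_rid(2, "ILE"), _rid(5, "ILE")}
        assert conservation_filter(sufficient, aln, "t") == sufficient

    def test_gap_in_homolog_excludes(self):
        aln = FamilyAlignment(sequences={"t": "LIV", "a": "L-V"})
        assert conservation_filter({_rid(2, "ILE")}, aln, "t") == set()

    def test_unmappable_residue_names_it(self):
        from gatesite.errors import MappingError

        aln = FamilyAlignment(sequences={"t": "LIV", "a": "LIV"})
        with pytest.raises(MappingError, match="9"):
            conservation_filter({_rid(9, "ILE")}, aln, "t")


class TestRankAndSuggest:
    def test_delta_descending_order(self):
        table = _table([(_rid(593, "LEU"), 4.2, 1.0), (_rid(671, "LEU"), 2.6, 1.5)])
        ranked = rank_and_suggest({_rid(593, "LEU"), _rid(671, "LEU")}, table)
        assert [c.substitution for c in ranked] == ["L593G", "L671G"]
        assert ranked[0].delta == pytest.approx(3.2)
        assert ranked[1].delta == pytest.approx(1.1)

    def test_tie_breaks_by_residue_number(self):
        table = _table([(_rid(7, "VAL"), 2.0, 1.0), (_rid(3, "MET"), 2.0, 1.0)])
        ranked = rank_and_suggest({_rid(7, "VAL"), _rid(3, "MET")}, table)
        assert [c.residue.residue_number for c in ranked] == [3, 7]

    def test_single_candidate(self):
        table = _table([(_rid(10, "PHE"), 3.0, 0.5)])
        ranked = rank_and_suggest({_rid(10, "PHE")}, table)
        assert len(ranked) == 1
        assert ranked[0].substitution == "F10G"

    def test_glycine_candidate_flagged(self):
        table = _table([(_rid(4, "GLY"), 3.0, 0.5)])
        ranked = rank_and_suggest({_rid(4, "GLY")}, table)
        assert ranked[0].substitution is None
        assert "no side chain" in ranked[0].rationale


class TestRunTriage:
    def test_worked_example_end_to_end(self, worked_example):
        result = run_triage_fixture(
            worked_example["fixture"],
            worked_example["annotations"],
            worked_example["family"],
            worked_example["target"],
        )
        sizes = [len(result.stage_sets[s]) for s in STAGES]
        assert sizes == [19, 8, 5, 3, 2]
        assert [c.substitution for c in result.candidates] == ["L593G", "L671G"]

    def test_planted_gatekeeper_is_top_ranked(self):
        config = GeneratorConfig(seed=101, n_residues=50, n_frames=200)
        inh, nat, truth = generate_ensembles(config)
        result = run_triage(inh, nat, annotations=truth.annotations())
        assert result.candidates[0].residue == truth.gatekeeper

    def test_stage_sets_are_nested(self):
        config = GeneratorConfig(seed=103, n_residues=30, n_frames=80)
        inh, nat, truth = generate_ensembles(config)
        result = run_triage(inh, nat, annotations=truth.annotations())
        previous = None
        for stage in STAGES:
            members = result.stage_sets[stage]
            if previous is not None:
                assert members <= previous
            previous = members

    def test_zero_natural_baseline_keeps_contacting_survivors(self):
        # natural ligand makes no contacts: every proximal/structural survivor
        # with enough inhibitor contacts stays through the differential stage
        plan = [ResiduePlan(1.5, 0.0) for _ in range(6)]
        config = GeneratorConfig(
            seed=7, n_residues=6, n_frames=50, contact_plan=plan, gatekeeper_index=2
        )
        inh, nat, truth = generate_ensembles(config)
        result = run_triage(inh, nat)
        assert result.stage_sets["sufficient_contact"] == result.stage_sets["structural_ok"]

    def test_determinism_byte_identical_reports(self):
        def one_run():
            config = GeneratorConfig(seed=11, n_residues=25, n_frames=60)
            inh, nat, truth = generate_ensembles(config)
            return run_triage(inh, nat, annotations=truth.annotations()).to_json()

        assert one_run() == one_run()

    def test_agrees_with_naive_pipeline_reimplementation(self):
        """Full pipeline vs an independent dictionary/double-loop rebuild."""
        from oracles import naive_differential, naive_profile

        config = GeneratorConfig(seed=47, n_residues=20, n_frames=50)
        inh, nat, truth = generate_ensembles(config)
        cfg = TriageConfig()
        result = run_triage(inh, nat, annotations=truth.annotations(), config=cfg)

        inh_t = naive_profile(inh, 4.5)
        nat_t = naive_profile(nat, 4.5)
        diff = naive_differential(inh_t, nat_t, inh.n_frames, nat.n_frames)
        critical = {(a.chain_id, a.residue_number) for a in truth.annotations()}

        proximal = {
            r for r, rec in inh_t.items()
            if rec["frames_with_contact"] / inh.n_frames >= cfg.min_occupancy
        }
        structural = {
            r for r in proximal
            if (r.chain_id, r.residue_number) not in critical
            and inh_t[r]["backbone"] / inh_t[r]["total"] < cfg.backbone_fraction_threshold
        }
        positive = {r for r in structural if diff[r]["inhibitor_mean"] > diff[r]["natural_mean"]}
        sufficient = {r for r in positive if diff[r]["inhibitor_mean"] >= cfg.min_mean_contacts}
        ranked = sorted(sufficient, key=lambda r: (-diff[r]["delta"], r.residue_number))

        assert result.stage_sets["proximal"] == proximal
        assert result.stage_sets["structural_ok"] == structural
        assert result.stage_sets["differential_positive"] == positive
        assert result.stage_sets["sufficient_contact"] == sufficient
        assert [c.residue for c in result.candidates] == ranked
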