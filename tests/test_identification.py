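"""Tiered validation, grouping, FDR arithmetic and the exclusion filters."""

import networkx as nx
import numpy as np
import pytest

from pdeproteome.identification import (
    CalibrationUnavailableError,
    MASCOT_THRESHOLDS,
    PHENYX_THRESHOLDS,
    ProteinGroup,
    PSMRecord,
    UndefinedFDRError,
    ValidationThresholds,
    estimate_fdr,
    filter_keratins,
    merge_isoforms,
    recalibrate_masses,
    validate_proteins,
)


def psm(pep, prots, score, engine="mascot", sid=None, rt=10.0, mz=500.0, theo=None):
    return PSMRecord(
        spectrum_id=sid or f"s.{pep}.{score}",
        peptide=pep,
        proteins=tuple(prots) if isinstance(prots, (list, tuple, set)) else (prots,),
        engine=engine,
        score=score,
        retention_time=rt,
        precursor_mz=mz,
        theoretical_mz=theo,
    )


class TestRecalibration:
    def test_constant_offset_removed(self):
        theo = 500.0
        psms = [
            psm("PEPA", "P1", 50, mz=theo * (1 + 5e-6), theo=theo),
            psm("PEPB", "P1", 60, mz=theo * (1 + 5e-6), theo=theo),
        ]
        out = recalibrate_masses(psms, high_conf_score=40)
        for p in out:
            offset_ppm = (p.precursor_mz - theo) / theo * 1e6
            assert offset_ppm == pytest.approx(0.0, abs=1e-9)

    def test_median_of_mixed_offsets_removed(self):
        theo = 800.0
        offs = [4.0, 6.0, 5.0]
        psms = [
            psm(f"PEP{i}", "P1", 50, mz=theo * (1 + o * 1e-6), theo=theo)
            for i, o in enumerate(offs)
        ]
        out = recalibrate_masses(psms, high_conf_score=40)
        corrected = sorted((p.precursor_mz - theo) / theo * 1e6 for p in out)
        # second-order ppm cross-terms leave ~1e-5 ppm residuals
        assert corrected == pytest.approx([-1.0, 0.0, 1.0], abs=1e-4)

    def test_no_high_confidence_psms_is_an_error(self):
        psms = [psm("PEPA", "P1", 10, theo=500.0)]
        with pytest.raises(CalibrationUnavailableError):
            recalibrate_masses(psms, high_conf_score=40)


class TestValidationTiers:
    """Truth-table behaviour of the T1/T2/T3 rules, both engines."""

    @pytest.mark.parametrize(
        "engine,thr",
        [("mascot", MASCOT_THRESHOLDS), ("phenyx", PHENYX_THRESHOLDS)],
    )
    def test_two_unique_peptides_above_t1_accepted(self, engine, thr):
        psms = [
            psm("PEPTIDEAK", "P1", thr.T1 + 1, engine=engine),
            psm("PEPTIDEBK", "P1", thr.T1 + 4, engine=engine),
        ]
        groups = validate_proteins({engine: psms})
        assert [g.reporter for g in groups] == ["P1"]

    @pytest.mark.parametrize(
        "engine,thr",
        [("mascot", MASCOT_THRESHOLDS), ("phenyx", PHENYX_THRESHOLDS)],
    )
    def test_single_peptide_below_t2_rejected(self, engine, thr):
        psms = [psm("PEPTIDEAK", "P1", thr.T2 - 1, engine=engine)]
        assert validate_proteins({engine: psms}) == []

    @pytest.mark.parametrize(
        "engine,thr",
        [("mascot", MASCOT_THRESHOLDS), ("phenyx", PHENYX_THRESHOLDS)],
    )
    def test_single_peptide_above_t2_accepted(self, engine, thr):
        psms = [psm("PEPTIDEAK", "P1", thr.T2 + 0.5, engine=engine)]
        groups = validate_proteins({engine: psms})
        assert [g.reporter for g in groups] == ["P1"]

    def test_t3_augmentation_keeps_extra_peptide(self):
        psms = [
            psm("PEPTIDEAK", "P1", 17),
            psm("PEPTIDEBK", "P1", 20),
            psm("PEPTIDECK", "P1", 11),  # above T3=10, below T1=16
        ]
        (group,) = validate_proteins({"mascot": psms})
        assert "PEPTIDECK" in group.peptides

    def test_peptide_at_or_below_t3_not_kept_when_strict(self):
        psms = [
            psm("PEPTIDEAK", "P1", 17),
            psm("PEPTIDEBK", "P1", 20),
            psm("PEPTIDECK", "P1", 10.0),
        ]
        (group,) = validate_proteins({"mascot": psms})
        assert "PEPTIDECK" not in group.peptides
        (group,) = validate_proteins({"mascot": psms}, strict=False)
        assert "PEPTIDECK" in group.peptides

    def test_exact_threshold_scores_rejected_when_strict(self):
        # scores exactly at T1 do not count under the strict reading
        psms = [psm("PEPTIDEAK", "P1", 16.0), psm("PEPTIDEBK", "P1", 16.0)]
        assert validate_proteins({"mascot": psms}) == []
        assert len(validate_proteins({"mascot": psms}, strict=False)) == 1

    def test_shared_peptides_do_not_count_toward_t1_tier(self):
        # both peptides map to two proteins => not unique => no acceptance
        psms = [
            psm("PEPTIDEAK", ["P1", "P2"], 30),
            psm("PEPTIDEBK", ["P1", "P2"], 30),
        ]
        assert validate_proteins({"mascot": psms}) == []

    def test_spectral_conflicts_discarded_from_both_engines(self):
        shared_sid = "spectrum.1"
        psms_m = [
            psm("PEPTIDEAK", "P1", 50, engine="mascot", sid=shared_sid),
            psm("PEPTIDEBK", "P1", 50, engine="mascot"),
        ]
        psms_p = [psm("PEPTIDECK", "P2", 50, engine="phenyx", sid=shared_sid)]
        groups = validate_proteins({"mascot": psms_m, "phenyx": psms_p})
        # conflict removes both engines' evidence for that spectrum:
        # P1 keeps only PEPTIDEBK (accepted via T2), P2 loses everything
        assert [g.reporter for g in groups] == ["P1"]
        assert groups[0].peptides == {"PEPTIDEBK"}

    def test_missing_thresholds_rejected(self):
        with pytest.raises(ValueError, match="thresholds"):
            validate_proteins({"mascot": []}, thresholds={})

    def test_threshold_ordering_enforced(self):
        with pytest.raises(ValueError):
            ValidationThresholds(T1=5, T2=4, T3=1)

    def test_validation_monotone_in_thresholds(self, rng):
        """Raising any threshold never adds an accepted protein."""
        for trial in range(30):
            psms = [
                psm(
                    f"PEP{rng.integers(8)}K",
                    f"P{rng.integers(4)}",
                    float(rng.uniform(0, 50)),
                    sid=f"s{trial}.{i}",
                )
                for i in range(12)
            ]
            base = ValidationThresholds(16, 40, 10)
            accepted = {
                m
                for g in validate_proteins({"mascot": psms}, {"mascot": base})
                for m in g.members
            }
            for raised in (
                ValidationThresholds(20, 40, 10),
                ValidationThresholds(16, 45, 10),
                ValidationThresholds(16, 40, 14),
            ):
                higher = {
                    m
                    for g in validate_proteins({"mascot": psms}, {"mascot": raised})
                    for m in g.members
                }
                assert higher <= accepted


def brute_force_groups(protein_peptides):
    """Oracle: connected components of the peptide-sharing graph."""
    g = nx.Graph()
    g.add_nodes_from(protein_peptides)
    prots = list(protein_peptides)
    for i, a in enumerate(prots):
        for b in prots[i + 1 :]:
            if protein_peptides[a] & protein_peptides[b]:
                g.add_edge(a, b)
    return {frozenset(c) for c in nx.connected_components(g)}


class TestGrouping:
    def test_grouping_matches_brute_force_components(self, rng):
        """Random small instances against the networkx component oracle."""
        for _ in range(200):
            n_prot = int(rng.integers(1, 11))
            psms = [
                psm(
                    f"PEP{rng.integers(12)}K",
                    f"P{rng.integers(n_prot)}",
                    float(rng.uniform(0, 60)),
                    sid=f"s{_}.{i}",
                )
                for i in range(int(rng.integers(1, 31)))
            ]
            groups = validate_proteins({"mascot": psms})
            # oracle recomputes acceptance naively, then components
            accepted = {}
            by_pep = {}
            for p in psms:
                by_pep.setdefault(p.peptide, set()).update(p.proteins)
            for acc in {a for p in psms for a in p.proteins}:
                scores = {}
                for p in psms:
                    if acc in p.proteins:
                        scores[p.peptide] = max(scores.get(p.peptide, -1), p.score)
                uniq_t1 = [
                    q for q, s in scores.items() if s > 16 and len(by_pep[q]) == 1
                ]
                if len(uniq_t1) >= 2 or any(s > 40 for s in scores.values()):
                    accepted[acc] = {q for q, s in scores.items() if s > 10}
            expected = brute_force_groups(accepted)
            got = {g.members for g in groups}
            assert got == expected

    def test_no_validated_peptide_in_two_groups(self, rng):
        for _ in range(50):
            psms = [
                psm(
                    f"PEP{rng.integers(10)}K",
                    [f"P{rng.integers(6)}" for _ in range(int(rng.integers(1, 3)))],
                    float(rng.uniform(0, 60)),
                    sid=f"t{_}.{i}",
                )
                for i in range(20)
            ]
            groups = validate_proteins({"mascot": psms})
            seen = set()
            for g in groups:
                assert not (g.peptides & seen)
                seen |= g.peptides

    def test_reporter_is_deterministic_member(self):
        psms = [
            psm("PEPTIDEAK", "P2", 45),  # accepts P2 via T2
            psm("PEPTIDEBK", ["P2", "P9"], 45),  # accepts P9 via T2, shared
        ]
        (group,) = validate_proteins({"mascot": psms})
        assert group.members == {"P2", "P9"}
        assert group.reporter == "P2"  # most unique peptides wins


class TestFDR:
    def g(self, reporter, peptides):
        return ProteinGroup(
            reporter=reporter, members=frozenset([reporter]), peptides=frozenset(peptides)
        )

    def test_ratio_arithmetic(self):
        targets = [self.g(f"P{i}", [f"PEP{i}"]) for i in range(200)]
        decoys = [self.g("D1", ["QEPX"])]
        report = estimate_fdr(targets, decoys)
        assert report.protein_group_fdr == pytest.approx(0.005)
        assert report.peptide_fdr == pytest.approx(1 / 200)

    def test_zero_decoys_zero_fdr(self):
        targets = [self.g("P1", ["PEPA", "PEPB"])]
        report = estimate_fdr(targets, [])
        assert report.peptide_fdr == 0.0
        assert report.protein_group_fdr == 0.0

    def test_zero_targets_undefined(self):
        with pytest.raises(UndefinedFDRError):
            estimate_fdr([], [self.g("D1", ["QEPX"])])


class TestFilters:
    def g(self, reporter, peptides=("PEPA",), members=None):
        return ProteinGroup(
            reporter=reporter,
            members=frozenset(members or [reporter]),
            peptides=frozenset(peptides),
        )

    @pytest.mark.parametrize(
        "desc,kept",
        [
            ("Keratin, type I cuticular Ha1", False),
            ("Keratin, type II cytoskeletal 8", True),
            ("KERATIN, HAIR acidic protein", False),
            ("Hair growth associated protein", True),  # not a keratin
            ("Serum albumin", True),
        ],
    )
    def test_keratin_rule(self, desc, kept):
        groups = [self.g("P1")]
        out = filter_keratins(groups, {"P1": desc})
        assert bool(out) is kept

    def test_isoform_reporters_merged(self):
        groups = [
            self.g("P12345-1", ["PEPA"]),
            self.g("P12345-2", ["PEPB"]),
            self.g("P99999", ["PEPC"]),
        ]
        merged = merge_isoforms(groups)
        assert {g.reporter for g in merged} == {"P12345-1", "P99999"}
        big = next(g for g in merged if g.reporter == "P12345-1")
        assert big.peptides == {"PEPA", "PEPB"}
        assert big.members == {"P12345-1", "P12345-2"}

    def test_unrelated_accessions_unchanged(self):
        groups = [self.g("P11111"), self.g("P22222", ["PEPB"])]
        assert {g.reporter for g in merge_isoforms(groups)} == {"P11111", "P22222"}

    def test_merged_unique_peptides_recomputed_brute_force(self):
        groups = [
            self.g("P12345-1", ["PEPA", "PEPS"]),
            self.g("P12345-2", ["PEPB"]),
            self.g("P77777", ["PEPS", "PEPC"]),
        ]
        merged = merge_isoforms(groups)
        # brute force: peptide unique iff in exactly one merged peptide set
        counts = {}
        for g in merged:
            for pep in g.peptides:
                counts[pep] = counts.get(pep, 0) + 1
        for g in merged:
            assert g.unique_peptides == {p for p in g.peptides if counts[p] == 1}
        big = next(g for g in merged if g.reporter == "P12345-1")
        assert big.unique_peptides == {"PEPA", "PEPB"}
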