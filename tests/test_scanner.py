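"""Consensus matcher, whole-sequence scan, motif/domain assembly, null model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lrrscan import (HcsMatch, ProteinSequence, ResidueClassConfig,
                     assemble_motifs, infer_domains, match_window,
                     null_match_probability, scan_sequence,
                     uniform_frequencies)
from lrrscan.resources import load_table1_segments
from lrrscan.scanner import ScanError
from lrrscan.synthetic import gen_sequence

from conftest import oracle_match, oracle_scan

windows11 = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=11, max_size=11)
windows12 = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=12, max_size=12)


class TestMatchWindow:
    def test_all_published_segments_match_default_config(self, default_cfg):
        """Pinned fixture: every printed variant of the five published
        Panx1CT HCS segments satisfies the default consensus."""
        for seg in load_table1_segments():
            for window in (seg.window11, seg.window12):
                if window is not None:
                    assert match_window(window, default_cfg) is not None, \
                        f"{seg.hcs} variant {window} should match"

    def test_canonical_instantiation_matches(self, default_cfg):
        hit = match_window("LGGLGLGGNGL", default_cfg)
        assert hit is not None and hit.variant == 11
        assert all(ev.relaxation == "none" for ev in hit.evidence
                   if ev.role != "l_internal")

    def test_single_anchor_violation_rejected(self, default_cfg):
        # position 9 = G is outside the N class
        assert match_window("LGGLGLGGGGL", default_cfg) is None

    def test_relaxed_12mer_with_evidence_trail(self, default_cfg):
        # published segment with G at an internal anchor and a relaxed terminal
        hit = match_window("IIDGKIPTSLQT", default_cfg)
        assert hit is not None and hit.variant == 12
        by_pos = {ev.position: ev for ev in hit.evidence}
        assert by_pos[4].observed == "G"
        assert by_pos[4].relaxation == "hydrophobic_ext"
        assert by_pos[9].observed == "S" and by_pos[9].relaxation == "none"
        assert by_pos[12].observed == "T" and by_pos[12].relaxation == "terminal"

    def test_core_only_policy_rejects_extended_anchors(self):
        cfg = ResidueClassConfig(internal_anchor_policy="core_only")
        assert match_window("IIDGKIPTSLQT", cfg) is None   # G at position 4
        assert match_window("LYNLFLEENISE", cfg) is not None

    def test_strict_terminal_policy(self):
        cfg = ResidueClassConfig(terminal_policy="strict")
        assert match_window("LGGLGLGGNGL", cfg) is not None
        assert match_window("DGGLGLGGNGL", cfg) is None    # D terminal

    def test_x_never_satisfies_any_class(self, default_cfg):
        assert match_window("XGGLGLGGNGL", default_cfg) is None
        assert match_window("LGGXGLGGNGL", default_cfg) is None

    def test_wrong_length_and_bad_alphabet_are_errors(self, default_cfg):
        with pytest.raises(ScanError):
            match_window("LGGLGLGGN", default_cfg)
        with pytest.raises(ScanError):
            match_window("LGGLGLGGN1L", default_cfg)

    @given(window=st.one_of(windows11, windows12))
    @settings(max_examples=300, deadline=None)
    def test_agrees_with_brute_force_oracle(self, window):
        assert (match_window(window) is not None) == oracle_match(window)

    @given(window=st.one_of(windows11, windows12), data=st.data())
    @settings(max_examples=150, deadline=None)
    def test_enlarging_class_sets_never_removes_a_match(self, window, data):
        cfg = ResidueClassConfig()
        if match_window(window, cfg) is None:
            return
        extra = data.draw(st.sets(st.sampled_from("ACDEFGHIKLMNPQRSTVWY"),
                                  max_size=4))
        bigger = ResidueClassConfig(
            l_core=cfg.l_core | extra,
            l_hydrophobic_ext=cfg.l_hydrophobic_ext | extra | cfg.l_core,
            n_class=cfg.n_class | extra,
            c_class=cfg.c_class | extra,
        )
        assert match_window(window, bigger) is not None


class TestScanSequence:
    def test_exact_length_input(self, default_cfg):
        seq = ProteinSequence(id="s", residues="LGGLGLGGNGL")
        matches = scan_sequence(seq, default_cfg)
        assert [(m.start, m.variants) for m in matches] == [(1, (11,))]

    def test_planted_motifs_on_proline_background(self, default_cfg):
        residues = list("P" * 60)
        residues[9:20] = "LGGLGLGGNGL"
        residues[39:50] = "LGGLGLGGNGL"
        seq = ProteinSequence(id="s", residues="".join(residues))
        matches = scan_sequence(seq, default_cfg)
        assert [m.start for m in matches] == [10, 40]

    def test_region_scan_reports_full_protein_coordinates(self, default_cfg):
        residues = "P" * 20 + "LGGLGLGGNGL" + "P" * 20
        seq = ProteinSequence(id="s", residues=residues, offset=300)
        matches = scan_sequence(seq, default_cfg, region=(310, 340))
        assert [m.start for m in matches] == [320]

    def test_short_region_warns_and_returns_empty(self, default_cfg, caplog):
        seq = ProteinSequence(id="s", residues="A" * 30)
        with caplog.at_level("WARNING"):
            assert scan_sequence(seq, default_cfg, region=(1, 5)) == []
        assert "shorter" in caplog.text

    def test_same_start_11_and_12_merge_into_one_hit(self, default_cfg):
        # canonical 11-mer followed by P: the 12-window also matches
        # (position 9 = N is in the C class, terminal accepts P)
        seq = ProteinSequence(id="s", residues="LGGLGLGGNGLP")
        matches = scan_sequence(seq, default_cfg)
        assert len(matches) == 1
        assert matches[0].variants == (11, 12)
        assert matches[0].window11 == "LGGLGLGGNGL"
        assert matches[0].window12 == "LGGLGLGGNGLP"

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle_on_random_sequences(self, seed,
                                                            default_cfg):
        seq, _ = gen_sequence(length=500, seed=seed, seq_id=f"r{seed}")
        got = {m.start: set(m.variants)
               for m in scan_sequence(seq, default_cfg)}
        assert got == oracle_scan(seq.residues)

    def test_determinism(self, default_cfg):
        seq, _ = gen_sequence(length=300, seed=42)
        assert scan_sequence(seq, default_cfg) == scan_sequence(seq, default_cfg)


class TestAssembleMotifs:
    def _match(self, start, variants=(12,)):
        return HcsMatch(seq_id="s", start=start, variants=tuple(variants))

    def test_unobstructed_vs(self):
        motifs = assemble_motifs([self._match(329)], sequence_end=426)
        (motif,) = motifs
        assert (motif.vs_start, motif.vs_end) == (341, 347)
        assert motif.vs_putative

    def test_reproduces_published_21_residue_motif_extent(self):
        # HCS start 328 with a 14-residue HCS treated as ending at 341:
        # the trailing VS 342..348 completes the 21-residue unit
        motifs = assemble_motifs(
            [HcsMatch(seq_id="s", start=330, variants=(12,))],
            sequence_end=426)
        (motif,) = motifs
        assert motif.vs_start == 342 and motif.vs_end == 348
        assert motif.vs_end - 328 + 1 == 21

    def test_vs_truncated_by_next_hit(self):
        motifs = assemble_motifs([self._match(10), self._match(25)],
                                 sequence_end=100)
        first = motifs[0]
        # 12-mer ends at 21; next hit starts at 25 -> VS is 22..24
        assert (first.vs_start, first.vs_end) == (22, 24)

    def test_vs_absent_when_no_room(self):
        motifs = assemble_motifs([self._match(10), self._match(22)],
                                 sequence_end=100)
        assert motifs[0].vs_start is None and motifs[0].vs_end is None

    def test_vs_truncated_at_sequence_end(self):
        motifs = assemble_motifs([self._match(10)], sequence_end=24)
        assert (motifs[0].vs_start, motifs[0].vs_end) == (22, 24)


class TestInferDomains:
    def _matches(self, starts):
        return [HcsMatch(seq_id="s", start=s, variants=(11,)) for s in starts]

    def test_published_chain_forms_one_domain_of_five(self):
        domains = infer_domains(self._matches([305, 329, 344, 360, 376]))
        assert len(domains) == 1
        assert len(domains[0].members) == 5
        assert domains[0].span == (305, 386)

    def test_distant_pair_is_no_domain(self):
        assert infer_domains(self._matches([10, 100])) == []

    def test_boundary_gap_30_joins_31_splits(self):
        domains = infer_domains(self._matches([10, 40, 71]))
        assert len(domains) == 1
        assert [m.start for m in domains[0].members] == [10, 40]


class TestNullModel:
    def test_core_only_closed_form(self):
        cfg = ResidueClassConfig(internal_anchor_policy="core_only")
        null = null_match_probability(uniform_frequencies(), cfg)
        assert null.p11 == pytest.approx((4 / 20) ** 3)

    def test_hydrophobic_policy_closed_form(self):
        null = null_match_probability(uniform_frequencies())
        assert null.p11 == pytest.approx(0.5 * 0.5 * 0.2)
        assert null.p12 == pytest.approx(0.5 * 0.5 * (3 / 20))
        # default C class is a subset of the N class
        assert null.p_both == pytest.approx(null.p12)

    def test_bad_frequency_sum_is_error(self):
        freqs = uniform_frequencies()
        freqs["L"] += 0.01
        with pytest.raises(ScanError):
            null_match_probability(freqs)

    def test_monte_carlo_agreement(self):
        """Empirical match rate over random windows lies within 3 SE of
        the closed form (seeded)."""
        null = null_match_probability(uniform_frequencies())
        rng = np.random.default_rng(7)
        letters = np.array(sorted("ACDEFGHIKLMNPQRSTVWY"))
        n = 20_000
        draws = rng.choice(letters, size=(n, 11))
        hits = sum(match_window("".join(row)) is not None for row in draws)
        se = (null.p11 * (1 - null.p11) / n) ** 0.5
        assert abs(hits / n - null.p11) <= 3 * se

    def test_expected_hits_scales_with_length(self):
        null = null_match_probability(uniform_frequencies())
        assert null.expected_hits(11) == pytest.approx(null.p11)
        assert null.expected_hits(10) == 0.0
        n = 500
        expected = (n - 10) * null.p11 + (n - 11) * (null.p12 - null.p_both)
        assert null.expected_hits(n) == pytest.approx(expected)
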