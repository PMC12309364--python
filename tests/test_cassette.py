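"""Chassis assembly, coordinates, strand semantics, upstream-start screening."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from g4tune import (
    DEFAULT_CORE_PROMOTER,
    DEFAULT_REPORTER_CDS,
    DEFAULT_UTR_PLACEHOLDER,
    G4MotifSpec,
    InsertionSite,
    Level,
    all_fixed_loop_motifs,
    assemble_bpcu,
    assign_loops,
    candidate_sites,
    cds_offset_of,
    extract_template_motif,
    insert_motif,
    introduces_upstream_start,
    new_cassette,
    remove_insertion,
    reverse_complement,
    scan_upstream_starts,
    transcript_of,
)


class TestBPCU:
    def test_default_chassis_is_98_bp(self):
        bpcu = assemble_bpcu()
        assert len(bpcu.core_promoter) == 41
        assert len(bpcu.utr) == 57
        assert len(bpcu) == 98
        assert bpcu.tss_index == 41

    def test_custom_utr_shifts_nothing_upstream(self):
        bpcu = assemble_bpcu(utr="A" * 60)
        assert len(bpcu) == 101
        assert bpcu.tss_index == 41

    def test_empty_or_invalid_sequences_rejected(self):
        with pytest.raises(ValueError):
            assemble_bpcu(utr="")
        with pytest.raises(ValueError):
            assemble_bpcu(core_promoter="ACGU")

    def test_placeholder_utr_is_inert(self):
        # guanine-free: no quadruplex potential, no AUG contribution
        assert "G" not in DEFAULT_UTR_PLACEHOLDER
        assert "ATG" not in DEFAULT_UTR_PLACEHOLDER


class TestInsertionSites:
    def test_level_sign_rules(self):
        with pytest.raises(ValueError):
            InsertionSite(Level.DNA, 3)
        with pytest.raises(ValueError):
            InsertionSite(Level.RNA, -3)
        with pytest.raises(ValueError):
            InsertionSite(Level.DNA, 0)

    def test_default_panel_has_13_sites(self):
        sites = candidate_sites()
        assert len(sites) == 13
        assert sum(s.level is Level.DNA for s in sites) == 7
        assert sum(s.level is Level.RNA for s in sites) == 6

    def test_empty_config_gives_the_two_optima(self):
        sites = candidate_sites([])
        assert [(s.level, s.position) for s in sites] == [
            (Level.DNA, -1),
            (Level.RNA, 6),
        ]

    def test_config_entries_are_validated(self):
        with pytest.raises(ValueError):
            candidate_sites([(Level.DNA, 3)])


class TestInsertion:
    def test_dna_motif_reverse_complemented_onto_coding_strand(self, motif13_dna):
        cas = insert_motif(
            new_cassette(), motif13_dna.with_label("m13"), InsertionSite(Level.DNA, -1)
        )
        rc = reverse_complement(motif13_dna.sequence)
        core = DEFAULT_CORE_PROMOTER
        assert cas.assembled.startswith(core + rc + DEFAULT_UTR_PLACEHOLDER[:1])
        # template strand carries the G-rich motif
        assert extract_template_motif(cas, "m13") == motif13_dna.sequence

    def test_rna_motif_inserted_verbatim_at_plus6(self, motif13_spec_rna):
        m = assign_loops(motif13_spec_rna, "fixed", "ATC").with_label("r13")
        cas = insert_motif(new_cassette(), m, InsertionSite(Level.RNA, 6))
        utr = cas.engineered_utr
        assert utr == (
            DEFAULT_UTR_PLACEHOLDER[:6]
            + m.sequence.replace("U", "T")
            + DEFAULT_UTR_PLACEHOLDER[6:]
        )
        assert len(DEFAULT_UTR_PLACEHOLDER[6:]) == 51

    def test_level_mismatch_and_out_of_range_rejected(self, motif13_dna):
        with pytest.raises(ValueError):
            insert_motif(new_cassette(), motif13_dna, InsertionSite(Level.RNA, 6))
        with pytest.raises(ValueError):
            insert_motif(new_cassette(), motif13_dna, InsertionSite(Level.DNA, -99))

    def test_dual_insertion_tiles_exactly(self, motif13_dna, motif13_spec_rna):
        rna = assign_loops(motif13_spec_rna, "fixed", "ATC").with_label("r13")
        cas = insert_motif(new_cassette(), motif13_dna.with_label("d13"),
                           InsertionSite(Level.DNA, -1))
        cas = insert_motif(cas, rna, InsertionSite(Level.RNA, 6))
        segs = cas.segment_map
        assert segs[0][1] == 0 and segs[-1][2] == len(cas.assembled)
        for (_, _, e), (_, s, _) in zip(segs, segs[1:]):
            assert e == s
        names = [n for n, _, _ in segs]
        assert "insertion:d13" in names and "insertion:r13" in names

    def test_insert_remove_round_trip_is_byte_identical(self, motif13_dna):
        base = new_cassette()
        cas = insert_motif(base, motif13_dna.with_label("m"), InsertionSite(Level.DNA, -7))
        assert remove_insertion(cas, "m").assembled == base.assembled

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        dna_pos=st.lists(st.integers(-41, -1), unique=True, max_size=3),
        rna_pos=st.lists(st.integers(1, 57), unique=True, max_size=3),
    )
    def test_length_bookkeeping_for_arbitrary_insertion_sets(self, dna_pos, rna_pos):
        dna_m = assign_loops(G4MotifSpec(Level.DNA, 4, 4, (3, 3, 3)), "fixed", "ATC")
        rna_m = assign_loops(G4MotifSpec(Level.RNA, 4, 4, (3, 3, 3)), "fixed", "ATC")
        cas = new_cassette()
        for i, p in enumerate(dna_pos):
            cas = insert_motif(cas, dna_m.with_label(f"d{i}"),
                               InsertionSite(Level.DNA, p))
        for i, p in enumerate(rna_pos):
            cas = insert_motif(cas, rna_m.with_label(f"r{i}"),
                               InsertionSite(Level.RNA, p))
        assert len(cas.assembled) == sum(e - s for _, s, e in cas.segment_map)
        expected = 98 + len(DEFAULT_REPORTER_CDS) + 25 * (len(dna_pos) + len(rna_pos))
        assert len(cas.assembled) == expected


class TestTranscript:
    def test_unengineered_transcript_is_utr_plus_cds(self):
        cas = new_cassette()
        tr = transcript_of(cas)
        assert tr == (DEFAULT_UTR_PLACEHOLDER + DEFAULT_REPORTER_CDS).replace("T", "U")

    def test_dna_only_insertion_leaves_transcript_unchanged(self, motif13_dna):
        base = new_cassette()
        cas = insert_motif(base, motif13_dna, InsertionSite(Level.DNA, -1))
        assert transcript_of(cas) == transcript_of(base)

    def test_rna_insertion_appears_after_six_utr_nt(self, motif13_spec_rna):
        m = assign_loops(motif13_spec_rna, "fixed", "ATC")
        cas = insert_motif(new_cassette(), m, InsertionSite(Level.RNA, 6))
        tr = transcript_of(cas)
        assert tr[6:6 + 25] == m.sequence
        assert cds_offset_of(cas) == 57 + 25

    def test_cds_required(self):
        with pytest.raises(ValueError):
            transcript_of(new_cassette(cds=""))


class TestUpstreamStartScreen:
    def test_aau_loop_introduces_upstream_aug(self, motif13_spec_rna):
        m = assign_loops(motif13_spec_rna, "fixed", "AAT")
        cas = insert_motif(new_cassette(), m, InsertionSite(Level.RNA, 6))
        hits = scan_upstream_starts(transcript_of(cas), cds_offset_of(cas))
        assert hits  # ...A-A-U followed by the next tract's G

    def test_auc_loop_is_clean(self, motif13_spec_rna):
        m = assign_loops(motif13_spec_rna, "fixed", "ATC")
        cas = insert_motif(new_cassette(), m, InsertionSite(Level.RNA, 6))
        assert scan_upstream_starts(transcript_of(cas), cds_offset_of(cas)) == []

    def test_exactly_three_of_27_variants_flagged(self, motif13_spec_rna):
        flagged = {
            m.loop_seqs[0]
            for m in all_fixed_loop_motifs(motif13_spec_rna)
            if introduces_upstream_start(m)
        }
        assert flagged == {"AAU", "UAU", "CAU"}

    def test_scan_positions_are_zero_based_and_strictly_upstream(self):
        assert scan_upstream_starts("AUGCCAUGAUG", 8) == [0, 5]
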