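"""The architecture grammar, PIPK typing, reconstitution and inventories."""

import pytest

from gpcrmine import classify as cls
from gpcrmine import motif as mm
from gpcrmine import profiles, synthetic, topology
from gpcrmine.classify import (
    ArchitectureCall,
    classify_architecture,
    classify_pipk_type,
    inventory,
    reconstitute_fragments,
)
from gpcrmine.profiles import DomainHit
from gpcrmine.topology import TMSegment, TopologyModel


def make_topology(n_tm, helix=21, loop=20, offset=20, signal=False):
    segs = []
    pos = offset
    for _ in range(n_tm):
        segs.append(TMSegment(pos + 1, pos + helix, 3.5))
        pos += helix + loop
    topo = TopologyModel(segments=segs, n_terminus_side="extracellular")
    if signal:
        topo.signal_peptide = TMSegment(3, 14, 3.5)
    return topo


def tm_end(topo):
    return topo.segments[-1].end if topo.segments else 0


class TestArchitectureGrammar:
    def test_seven_tm_then_kinase_is_receptor_kinase(self):
        topo = make_topology(7)
        hit = DomainHit("PIPK", tm_end(topo) + 30, tm_end(topo) + 90, 120.0)
        call = classify_architecture("x", topo, [hit])
        assert call.class_label == cls.GPCR_PIPK

    def test_signal_plus_protease_before_c_terminal_block_is_ap_gpcr(self):
        topo = make_topology(7, offset=120, signal=True)
        hit = DomainHit("AP", 30, 85, 150.0)
        call = classify_architecture("x", topo, [hit])
        assert call.class_label == cls.AP_GPCR

    def test_tkl_with_downstream_dep_sets_the_flag(self):
        topo = make_topology(7)
        tkl = DomainHit("TKL", tm_end(topo) + 20, tm_end(topo) + 70, 110.0)
        dep = DomainHit("DEP", tkl.end + 10, tkl.end + 50, 80.0)
        call = classify_architecture("x", topo, [tkl, dep])
        assert call.class_label == cls.GPCR_TKL and call.has_dep

    def test_dep_without_tkl_does_not_flag(self):
        topo = make_topology(7)
        pipk = DomainHit("PIPK", tm_end(topo) + 20, tm_end(topo) + 80, 110.0)
        dep = DomainHit("DEP", pipk.end + 10, pipk.end + 50, 80.0)
        call = classify_architecture("x", topo, [pipk, dep])
        assert call.class_label == cls.GPCR_PIPK and not call.has_dep

    def test_eleven_tm_transporter_decoy_discarded(self):
        topo = make_topology(11)
        decoy = DomainHit("TRANSPORTER", tm_end(topo) + 10,
                          tm_end(topo) + 60, 100.0)
        call = classify_architecture("x", topo, [decoy])
        assert call.class_label == cls.NON_GPCR_TM

    def test_decoy_hit_overrides_catalytic_evidence(self):
        topo = make_topology(7)
        decoy = DomainHit("CHANNEL", tm_end(topo) + 10, tm_end(topo) + 60, 90.0)
        pipk = DomainHit("PIPK", tm_end(topo) + 70, tm_end(topo) + 130, 120.0)
        call = classify_architecture("x", topo, [decoy, pipk])
        assert call.class_label == cls.NON_GPCR_TM

    def test_no_segments_without_hits_is_soluble(self):
        call = classify_architecture("x", make_topology(0), [])
        assert call.class_label == cls.SOLUBLE

    def test_four_tm_channel_is_non_gpcr(self):
        call = classify_architecture("x", make_topology(4), [])
        assert call.class_label == cls.NON_GPCR_TM

    def test_passing_topology_without_catalytic_hit_is_plain_receptor(self):
        call = classify_architecture("x", make_topology(7), [])
        assert call.class_label == cls.GPCR_PLAIN

    def test_partial_topology_with_kinase_and_motif_is_truncated(self):
        topo = make_topology(2)
        hit = DomainHit("PIPK", tm_end(topo) + 10, tm_end(topo) + 70, 110.0)
        call = classify_architecture("x", topo, [hit], motif_present=True)
        assert call.class_label == cls.AMBIGUOUS_TRUNCATED

    def test_scattered_segments_do_not_form_a_receptor_block(self):
        # seven helices but separated by 200-residue loops: no block
        topo = make_topology(7, loop=200)
        hit = DomainHit("PIPK", tm_end(topo) + 10, tm_end(topo) + 70, 110.0)
        call = classify_architecture("x", topo, [hit])
        assert call.class_label == cls.NON_GPCR_TM

    def test_contradictory_overlapping_hits_resolved_by_score_then_start(self):
        topo = make_topology(7)
        base = tm_end(topo)
        weak = DomainHit("AC", base + 20, base + 70, 60.0)
        strong = DomainHit("INPP", base + 25, base + 75, 90.0)
        call = classify_architecture("x", topo, [weak, strong])
        assert call.class_label == cls.GPCR_INPP
        tied = DomainHit("PDE", base + 22, base + 72, 90.0)
        call = classify_architecture("x", topo, [strong, tied])
        # equal scores: the earlier start wins
        assert call.class_label == cls.GPCR_PDE

    def test_labels_mutually_exclusive_and_exhaustive_on_preset(
            self, preset, preset_analysis):
        records, _ = preset
        calls = [
            classify_architecture(
                r.id, preset_analysis[r.id]["topology"],
                preset_analysis[r.id]["hits"],
                bool(preset_analysis[r.id]["motif_hits"]))
            for r in records
        ]
        assert len(calls) == len(records)
        assert all(c.class_label in cls.ALL_CLASSES for c in calls)

    def test_dep_flag_restricted_to_tkl(self):
        with pytest.raises(ValueError):
            ArchitectureCall("x", cls.GPCR_PIPK, has_dep=True)


@pytest.fixture(scope="module")
def pipk_profile(profile_set):
    return profile_set["PIPK"]


class TestPIPKTyping:

    def _soluble_hits(self, seq, profile_set):
        return [h for p in profile_set.values()
                for h in profiles.scan_profile(seq, p)]

    def test_receptor_fused_kinase_is_type_iv(self, preset, preset_analysis,
                                              pipk_profile):
        records, truth = preset
        for r in records:
            if truth[r.id].class_label != cls.GPCR_PIPK:
                continue
            call = classify_pipk_type(
                r.id, preset_analysis[r.id]["hits"],
                preset_analysis[r.id]["topology"], r.seq,
                pipk_profile=pipk_profile)
            assert call.pipk_type == "IV"

    @pytest.mark.parametrize("label,expected", [
        ("SOLUBLE_PIPK_I", "I"),
        ("SOLUBLE_PIPK_II", "II"),
        ("SOLUBLE_PIPK_III", "III"),
    ])
    def test_soluble_kinases_typed_by_signature_table(
            self, preset, preset_analysis, pipk_profile, label, expected):
        records, truth = preset
        checked = 0
        for r in records:
            if truth[r.id].class_label != label:
                continue
            call = classify_pipk_type(
                r.id, preset_analysis[r.id]["hits"],
                preset_analysis[r.id]["topology"], r.seq,
                pipk_profile=pipk_profile)
            assert call.pipk_type == expected, r.id
            checked += 1
        assert checked > 0

    def test_isolated_fragment_without_context_is_ambiguous(self,
                                                            pipk_profile):
        hit = DomainHit("PIPK", 5, 64, 120.0)
        seq = "G" * 80  # no activation anchor, no accessory, no receptor
        call = classify_pipk_type("x", [hit], make_topology(0), seq,
                                  pipk_profile=pipk_profile)
        assert call.pipk_type == "ambiguous"

    def test_no_kinase_hit_rejected(self, pipk_profile):
        with pytest.raises(ValueError):
            classify_pipk_type("x", [], make_topology(0), "GGG",
                               pipk_profile=pipk_profile)


class TestReconstitution:
    @pytest.fixture()
    def split_pipks(self, profile_set, default_motif_model):
        records, truth = synthetic.generate_proteome(
            [synthetic.PlantSpec(cls.GPCR_PIPK, 4)], 0, seed=31,
            species="Rfilo")
        frags = []
        for r in records:
            pipk_start = [s for n, s, _ in truth[r.id].domains
                          if n == "PIPK"][0]
            a, b = synthetic.fragment_model(r, pipk_start - 3, truth,
                                            overlap=6)
            frags.extend([a, b])
        calls, motif_hits = [], {}
        for r in frags:
            topo = topology.predict_topology(r.seq)
            hits = [h for p in profile_set.values()
                    for h in profiles.scan_profile(r.seq, p)]
            hits.sort(key=lambda h: h.start)
            mh = mm.scan_motif(r.seq, default_motif_model)
            motif_hits[r.id] = mh
            calls.append(classify_architecture(r.id, topo, hits, bool(mh)))
        return frags, calls, motif_hits

    def test_planted_splits_reconstitute_as_receptor_kinases(self,
                                                             split_pipks):
        frags, calls, motif_hits = split_pipks
        merged = reconstitute_fragments(
            {r.id: r.seq for r in frags}, calls, motif_hits)
        assert merged
        planted_pairs = {
            (f"{base}_fragA", f"{base}_fragB")
            for base in {r.id.rsplit("_frag", 1)[0] for r in frags}
        }
        recovered = {m.evidence["members"] for m in merged}
        assert planted_pairs <= recovered
        assert all(m.class_label == cls.GPCR_PIPK for m in merged)
        assert all(m.reconstituted for m in merged)

    def test_unrelated_fragments_do_not_merge(self):
        calls = [
            ArchitectureCall("s|a", cls.GPCR_PLAIN,
                             evidence={"motif": False, "hits": [],
                                       "block": (1, 100)}),
            ArchitectureCall("s|b", cls.SOLUBLE,
                             evidence={"motif": False, "hits": []}),
        ]
        merged = reconstitute_fragments(
            {"s|a": "A" * 50, "s|b": "C" * 50}, calls, {})
        assert merged == []

    def test_ambiguous_partner_trio_flagged_unresolved(self):
        """Exhaustive-pairing oracle: one head, two equally good tails."""
        head_seq = "G" * 40 + "LRAAAAAAAAAGI" + "OVERLAP".replace("O", "W")
        tail_seq = head_seq[-6:] + "H" * 60
        pipk_hit = DomainHit("PIPK", 10, 60, 120.0)
        calls = [
            ArchitectureCall("s|head", cls.GPCR_PLAIN,
                             evidence={"motif": True, "hits": [],
                                       "block": (1, 30)}),
            ArchitectureCall("s|t1", cls.SOLUBLE,
                             evidence={"motif": False, "hits": [pipk_hit]}),
            ArchitectureCall("s|t2", cls.SOLUBLE,
                             evidence={"motif": False, "hits": [pipk_hit]}),
        ]
        seqs = {"s|head": head_seq, "s|t1": tail_seq, "s|t2": tail_seq}
        motif_hits = {"s|head": [(41, 30.0)]}
        merged = reconstitute_fragments(seqs, calls, motif_hits)
        # oracle: both pairings tie on overlap, so both are reported
        assert len(merged) == 2
        assert all(m.unresolved for m in merged)


class TestInventory:
    def test_empty_call_set_gives_all_zero_totals(self):
        table = inventory([])
        assert (table.loc["total"] == 0).all()

    def test_per_species_rows_sum_to_totals(self):
        calls = [
            ArchitectureCall("sp1|a", cls.GPCR_PIPK),
            ArchitectureCall("sp1|b", cls.GPCR_TKL),
            ArchitectureCall("sp2|c", cls.GPCR_PIPK),
            ArchitectureCall("sp2|d", cls.SOLUBLE),
        ]
        table = inventory(calls)
        body = table.drop(index="total")
        assert (table.loc["total"] == body.sum(axis=0)).all()
        assert table.loc["sp1", cls.GPCR_PIPK] == 1
        assert table.loc["sp2", cls.GPCR_PIPK] == 1

    def test_counts_are_nonnegative_integers(self, preset, preset_analysis):
        records, _ = preset
        calls = [
            classify_architecture(
                r.id, preset_analysis[r.id]["topology"],
                preset_analysis[r.id]["hits"],
                bool(preset_analysis[r.id]["motif_hits"]))
            for r in records
        ]
        table = inventory(calls)
        assert (table.to_numpy() >= 0).all()
        assert table.to_numpy().sum() == 2 * len(records)  # body + totals
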