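"""TM segmentation, NPA anchoring, the completeness screen, MW and pI."""

import pytest
from hypothesis import given, settings, strategies as st

from aqpkit.io_formats import ProteinRecord
from aqpkit.sequence_annotation import (
    AnchoringError,
    compute_mw,
    compute_pi,
    find_npa_anchors,
    predict_tm_segments,
    screen_record,
)
from aqpkit.synthetic_data import SIGNATURE_SPECS, CANONICAL_GROUPS, build_template


def _record(seq, rid="r"):
    return ProteinRecord(id=rid, sequence=seq)


class TestTmSegmentation:
    def test_single_hydrophobic_block(self):
        rec = _record("D" * 30 + "L" * 30 + "D" * 30)
        tm = predict_tm_segments(rec)
        assert len(tm) == 1
        start, end = tm.segments[0]
        # segment covers the core of the leucine run up to edge effects
        assert 30 <= start <= 36
        assert 54 <= end <= 60

    def test_all_polar_gives_no_segments(self):
        rec = _record("D" * 60)
        assert len(predict_tm_segments(rec)) == 0

    def test_sequence_shorter_than_window_rejected(self):
        with pytest.raises(ValueError, match="window"):
            predict_tm_segments(_record("MNPAVT"))

    @pytest.mark.parametrize("subfamily", sorted(CANONICAL_GROUPS))
    def test_six_planted_helices_recovered(self, subfamily):
        """Templates yield exactly 6 segments at >=80% reciprocal overlap."""
        from aqpkit.synthetic_data import FamilySpec, simulate_family

        key = (subfamily, CANONICAL_GROUPS[subfamily])
        records, manifest = simulate_family(
            FamilySpec(counts={key: 1}, divergence=0.0, seed=0)
        )
        (rec,) = records
        planted = manifest.records[rec.id].tm_intervals
        tm = predict_tm_segments(rec)
        assert len(tm) == 6
        for p, d in zip(planted, tm.segments):
            inter = min(p[1], d[1]) - max(p[0], d[0])
            assert inter / (p[1] - p[0]) >= 0.8
            assert inter / (d[1] - d[0]) >= 0.8


class TestNpaAnchoring:
    def _spaced(self, first, second, gap=110):
        seq = "G" * 30 + first + "S" * gap + second + "G" * 30
        return _record(seq)

    def test_canonical_pair_found_by_fallback(self):
        rec = self._spaced("SGGHINPAVT", "GTGINPARSLG")
        b, e = find_npa_anchors(rec, tm=None)
        assert (b.tripeptide, e.tripeptide) == ("NPA", "NPA")
        assert rec.sequence[b.n_index : b.n_index + 3] == "NPA"
        assert b.n_index < e.n_index

    def test_sip_like_variant_third_residue(self):
        rec = self._spaced("SGGHINPTVT", "GPSINPAFSKG")
        b, e = find_npa_anchors(rec, tm=None)
        assert (b.tripeptide, e.tripeptide) == ("NPT", "NPA")

    def test_single_motif_is_an_error(self):
        rec = _record("G" * 50 + "NPA" + "G" * 50)
        with pytest.raises(AnchoringError):
            find_npa_anchors(rec, tm=None)

    def test_pair_outside_separation_window_is_an_error(self):
        rec = self._spaced("SGGHINPAVT", "GTGINPARSLG", gap=300)
        with pytest.raises(AnchoringError):
            find_npa_anchors(rec, tm=None)

    def test_loop_regions_used_with_six_helices(self, references_by_key):
        t = references_by_key[("PIP", 1)]
        rec = _record(t.sequence, t.id)
        tm = predict_tm_segments(rec)
        b, e = find_npa_anchors(rec, tm)
        assert b.n_index == t.positions["NPA1_N"]
        assert e.n_index == t.positions["NPA2_N"]

    def test_invariant_to_terminal_padding(self, references_by_key):
        t = references_by_key[("TIP", 2)]
        pad = "GSTNQKDESTGSNQKDESTG"  # 20 polar residues
        rec = _record(pad + t.sequence + pad, "padded")
        b, e = find_npa_anchors(rec, tm=None)
        assert b.n_index == t.positions["NPA1_N"] + len(pad)
        assert e.n_index == t.positions["NPA2_N"] + len(pad)


class TestScreen:
    def _annotate(self, rec):
        try:
            tm = predict_tm_segments(rec)
        except ValueError:
            from aqpkit.sequence_annotation import TmSegmentation

            tm = TmSegmentation(segments=(), window=19, threshold=1.6)
        try:
            anchors = find_npa_anchors(rec, tm)
        except AnchoringError:
            anchors = None
        return tm, anchors

    @pytest.mark.parametrize("subfamily", sorted(CANONICAL_GROUPS))
    def test_complete_templates_pass(self, subfamily):
        t = build_template(subfamily)
        rec = _record(t.sequence, t.id)
        tm, anchors = self._annotate(rec)
        verdict = screen_record(rec, tm, anchors)
        assert verdict.status == "complete"
        assert verdict.reasons == ()

    def test_truncation_fails_length_and_anchors(self):
        t = build_template("PIP", 1)
        rec = _record(t.sequence[:120], "trunc")
        tm, anchors = self._annotate(rec)
        verdict = screen_record(rec, tm, anchors)
        assert verdict.status == "pseudogene_like"
        assert "length" in verdict.reasons
        assert "npa_anchors" in verdict.reasons

    def test_loop_e_motif_deletion_fails_anchor_rule(self):
        t = build_template("PIP", 1)
        n2 = t.positions["NPA2_N"]
        seq = t.sequence[:n2] + "G" + t.sequence[n2 + 3 :]  # excise the NPA, keep length-ish
        rec = _record(seq, "noLE")
        tm, anchors = self._annotate(rec)
        verdict = screen_record(rec, tm, anchors)
        assert verdict.status == "pseudogene_like"
        assert "npa_anchors" in verdict.reasons


class TestMolecularWeight:
    def test_single_glycine(self):
        mw = compute_mw(_record("G"))
        assert mw.kda == pytest.approx(0.0751, abs=0.0005)
        assert not mw.approximate

    def test_dipeptide_loses_one_water(self):
        mw = compute_mw(_record("GG"))
        assert mw.kda == pytest.approx(0.1321, abs=0.0005)

    def test_matches_per_residue_summation_oracle(self):
        import random

        from Bio.Data.IUPACData import protein_weights

        rng = random.Random(11)
        seq = "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(300))
        oracle = sum(protein_weights[aa] for aa in seq) - (len(seq) - 1) * 18.0153
        assert compute_mw(_record(seq)).kda == pytest.approx(oracle / 1000, abs=1e-4)

    def test_undetermined_residue_flags_approximate(self):
        assert compute_mw(_record("GXG")).approximate


class TestIsoelectricPoint:
    def test_acidic_bound(self):
        assert compute_pi(_record("DDDDDD")) < 4.5

    def test_basic_bound(self):
        assert compute_pi(_record("KKKKKK")) > 9.5

    def test_matches_grid_scan_oracle(self):
        from Bio.SeqUtils.IsoelectricPoint import IsoelectricPoint

        seq = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSGAEKAVQ"
        # oracle: 0.001-step scan of the same Bjellqvist charge curve
        ip = IsoelectricPoint(seq)
        best = min(
            (k * 0.001 for k in range(14001)),
            key=lambda ph: abs(ip.charge_at_pH(ph)),
        )
        assert compute_pi(_record(seq), tolerance=0.01) == pytest.approx(best, abs=0.01)

    @settings(derandomize=True, max_examples=20)
    @given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=5, max_size=40))
    def test_monotone_in_internal_charged_residues(self, seq):
        # insertion away from the termini: terminal-residue-specific pKas in
        # the Bjellqvist table would otherwise confound the comparison
        mid = len(seq) // 2
        base = compute_pi(_record(seq))
        with_k = seq[:mid] + "K" + seq[mid:]
        with_d = seq[:mid] + "D" + seq[mid:]
        assert compute_pi(_record(with_k)) >= base - 0.011
        assert compute_pi(_record(with_d)) <= base + 0.011
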