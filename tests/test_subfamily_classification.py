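"""Global alignment, nearest-reference classification and NJ trees."""

import itertools
import random

import pytest

from aqpkit.io_formats import ProteinRecord
from aqpkit.subfamily_classification import (
    align_global,
    build_nj_tree,
    classify_subfamily,
    identity_stats,
)
from aqpkit.synthetic_data import CANONICAL_GROUPS, FamilySpec, simulate_family

BLOSUM62 = None


def _blosum():
    global BLOSUM62
    if BLOSUM62 is None:
        from Bio.Align import substitution_matrices

        BLOSUM62 = substitution_matrices.load("BLOSUM62")
    return BLOSUM62


def _score_alignment(a, b):
    """Score two gapped strings under BLOSUM62 with affine gaps 10/1."""
    mat = _blosum()
    score = 0.0
    in_gap_a = in_gap_b = False
    for x, y in zip(a, b):
        if x == "-":
            score += -1.0 if in_gap_a else -10.0
            in_gap_a, in_gap_b = True, False
        elif y == "-":
            score += -1.0 if in_gap_b else -10.0
            in_gap_b, in_gap_a = True, False
        else:
            score += mat[x, y]
            in_gap_a = in_gap_b = False
    return score


def _enumerate_alignments(a, b):
    """All global alignments of two short sequences, as gapped string pairs."""
    if not a and not b:
        yield "", ""
        return
    if a:
        for ra, rb in _enumerate_alignments(a[1:], b):
            yield a[0] + ra, "-" + rb
    if b:
        for ra, rb in _enumerate_alignments(a, b[1:]):
            yield "-" + ra, b[0] + rb
    if a and b:
        for ra, rb in _enumerate_alignments(a[1:], b[1:]):
            yield a[0] + ra, b[0] + rb


class TestAlignGlobal:
    def test_identity_alignment(self):
        aln = align_global("MNPA", "MNPA")
        assert (aln.a, aln.b) == ("MNPA", "MNPA")
        assert identity_stats(aln) == (4, 4)

    @pytest.mark.parametrize(
        "a,b",
        [("MNPA", "MNA"), ("MNPAVT", "MNPVT"), ("ACDE", "ACWDE"), ("WWW", "WW")],
    )
    def test_optimal_score_matches_exhaustive_oracle(self, a, b):
        aln = align_global(a, b)
        oracle = max(
            _score_alignment(ga, gb) for ga, gb in _enumerate_alignments(a, b)
        )
        assert aln.score == pytest.approx(oracle)
        assert _score_alignment(aln.a, aln.b) == pytest.approx(oracle)

    def test_score_symmetric(self):
        rng = random.Random(5)
        for _ in range(100):
            a = "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(rng.randint(5, 30)))
            b = "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(rng.randint(5, 30)))
            assert align_global(a, b).score == pytest.approx(align_global(b, a).score)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            align_global("", "MNPA")


class TestClassification:
    def test_reference_classifies_to_itself(self, references):
        for ref in references:
            call = classify_subfamily(ref.as_record(), references)
            assert call.status == "classified"
            assert call.best_reference == ref.id
            assert call.score == pytest.approx(1.0)
            assert (call.subfamily, call.group) == (ref.subfamily, ref.group)

    def test_pip2_group_recovered_at_15pct_divergence(self, references):
        records, manifest = simulate_family(
            FamilySpec(counts={("PIP", 2): 50}, divergence=0.15, seed=7)
        )
        for rec in records:
            call = classify_subfamily(rec, references)
            assert (call.subfamily, call.group) == ("PIP", 2)

    def test_random_sequences_unclassified(self, references):
        for seed in range(20):
            rng = random.Random(seed)
            seq = "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(250))
            call = classify_subfamily(ProteinRecord(id=f"rand{seed}", sequence=seq), references)
            assert call.status == "unclassified"

    def test_empty_reference_set_rejected(self):
        with pytest.raises(ValueError):
            classify_subfamily(ProteinRecord(id="x", sequence="MNPA" * 30), [])


def _clades(newick):
    """Tip-name sets of every internal node of a newick tree."""
    from skbio import TreeNode
    from io import StringIO

    tree = TreeNode.read(StringIO(newick))
    out = []
    for node in tree.non_tips(include_self=True):
        out.append(frozenset(t.name for t in node.tips()))
    return tree, out


class TestNjTree:
    def test_three_leaves_unique_topology(self):
        records = [
            ProteinRecord(id=f"r{i}", sequence=seq)
            for i, seq in enumerate(["MNPAVT" * 30, "MNPAVS" * 30, "MNPGVT" * 30])
        ]
        newick = build_nj_tree(records)
        tree, _ = _clades(newick)
        assert {t.name for t in tree.tips()} == {"r0", "r1", "r2"}

    def test_four_leaf_additive_split_recovered(self):
        rng = random.Random(3)
        base = [rng.choice("ACDEFGHIKMQRSTWY") for _ in range(200)]

        def mutate(seq, positions):
            seq = list(seq)
            for p in positions:
                seq[p] = "L" if seq[p] != "L" else "V"
            return "".join(seq)

        # (a,b) vs (c,d) split: ab and cd differ little within pairs,
        # much across pairs -> additive distances
        a = "".join(base)
        b = mutate(a, range(0, 8))
        c = mutate(a, range(100, 160))
        d = mutate(c, range(10, 18))
        records = [ProteinRecord(id=n, sequence=s) for n, s in zip("abcd", [a, b, c, d])]

        # oracle: four-point condition picks the pairing with smallest sum
        from aqpkit.subfamily_classification import p_distance

        dist = {
            (x.id, y.id): p_distance(x.sequence, y.sequence)
            for x, y in itertools.combinations(records, 2)
        }
        sums = {
            "ab|cd": dist[("a", "b")] + dist[("c", "d")],
            "ac|bd": dist[("a", "c")] + dist[("b", "d")],
            "ad|bc": dist[("a", "d")] + dist[("b", "c")],
        }
        assert min(sums, key=sums.get) == "ab|cd"

        _, clades = _clades(build_nj_tree(records))
        all_tips = frozenset("abcd")
        assert any(
            c in (frozenset("ab"), frozenset("cd")) or all_tips - c in (frozenset("ab"), frozenset("cd"))
            for c in clades
        )

    def test_subfamilies_monophyletic(self):
        counts = {(s, CANONICAL_GROUPS[s]): 2 for s in CANONICAL_GROUPS}
        records, manifest = simulate_family(
            FamilySpec(counts=counts, divergence=0.1, seed=9)
        )
        from aqpkit.synthetic_data import build_template

        templates = [build_template(s) for s in sorted(CANONICAL_GROUPS)]
        leaves = records + [t.as_record() for t in templates]
        tree, clades = _clades(build_nj_tree(leaves))
        all_tips = frozenset(l.id for l in leaves)
        for s in CANONICAL_GROUPS:
            members = frozenset(l.id for l in leaves if s in l.id)
            assert len(members) == 3
            assert members in clades or (all_tips - members) in clades

    def test_newick_round_trip_preserves_leaf_set(self, references):
        records = [r.as_record() for r in references[:5]]
        tree, _ = _clades(build_nj_tree(records))
        assert {t.name for t in tree.tips()} == {r.id for r in records}

    def test_fewer_than_three_rejected(self, references):
        with pytest.raises(ValueError):
            build_nj_tree([r.as_record() for r in references[:2]])
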