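"""D-region typing, signature extraction, and the structural-group table."""

import itertools
import random

import pytest

from nicodh import (
    GROUP_LABELS, OTHERS, STRUCTURAL_GROUPS, StructuralSignature,
    assign_structural_group, build_signature, classify_d_region,
    classify_protein, generate_protein_for_group, map_anchor_positions,
)
from nicodh.classify import D_TYPES

import oracles


class TestClassifyDRegion:
    @pytest.mark.parametrize("region, expected", [
        ("AACWSCCAA", "I"),
        ("C" + "A" * 7 + "CC", "II"),
        ("C" + "A" * 13 + "CC", "II"),
        ("CWSC" + "AAAAA" + "C", "III"),
        ("AWSAA", None),
        ("C", None),
        ("", None),
        ("C" + "A" * 6 + "CC", None),   # spacer below the type II range
        ("C" + "A" * 14 + "CC", None),  # spacer above the type II range
    ])
    def test_motif_type_examples(self, region, expected):
        assert classify_d_region(region) == expected

    def test_agrees_with_brute_force_scanner(self):
        # exhaustive over {C,A} up to length 13, sampled for 14..18
        for n in range(0, 14):
            for tup in itertools.product("CA", repeat=n):
                s = "".join(tup)
                assert classify_d_region(s) == oracles.d_region_scan(s), s
        rng = random.Random(11)
        for _ in range(3000):
            n = rng.randrange(14, 19)
            s = "".join(rng.choice("CA") for _ in range(n))
            assert classify_d_region(s) == oracles.d_region_scan(s), s


class TestSignatureExtraction:
    def _signature(self, label, templates, anchor_by_clade, edit=None):
        tmpl = templates[label]
        seq = generate_protein_for_group(tmpl, 0.0, True, seed=0).sequence
        if edit:
            seq = edit(seq)
        anchor = anchor_by_clade[tmpl.clade]
        pmap = map_anchor_positions(label, seq, anchor)
        return build_signature(seq, pmap, anchor)

    def test_f1_realization_reads_complete_sites(self, templates, anchor_by_clade):
        sig = self._signature("F-1", templates, anchor_by_clade)
        assert sig.c_cluster == ("H", "C", "C", "C", "C", "C")
        assert sig.acid_base == ("H", "K")
        assert sig.b_complete
        assert sig.d_type == "II"
        assert sig.e_complete is None and sig.f_complete is None

    def test_b2_realization_reads_asp_at_cys2(self, templates, anchor_by_clade):
        sig = self._signature("B-2", templates, anchor_by_clade)
        assert sig.c_cluster == ("H", "C", "D", "C", "C", "C")

    def test_deleted_b_cluster_position_reads_absent(self, templates,
                                                     anchor_by_clade):
        anchor = anchor_by_clade["F"]
        pos = anchor.b_cluster[0]

        def drop(seq):
            return seq[: pos - 1] + seq[pos:]

        sig = self._signature("F-1", templates, anchor_by_clade, edit=drop)
        assert not sig.b_complete

    def test_terminal_cys_motifs_counted_in_window(self, templates,
                                                   anchor_by_clade):
        assert self._signature("F-2", templates, anchor_by_clade).nterm_cys_count == 2
        assert self._signature("C-1", templates, anchor_by_clade).nterm_cys_count == 3
        assert self._signature("F-1", templates, anchor_by_clade).nterm_cys_count == 0

    def test_his_rich_extensions_detected(self, templates, anchor_by_clade):
        b1 = self._signature("B-1", templates, anchor_by_clade)
        assert b1.nterm_his_rich and not b1.cterm_his_rich
        b3 = self._signature("B-3", templates, anchor_by_clade)
        assert b3.cterm_his_rich and not b3.nterm_his_rich

    def test_three_his_is_not_his_rich(self, templates, anchor_by_clade):
        # overwrite the planted repeat with one holding only 3 His
        tmpl = templates["B-1"]
        seq = list(generate_protein_for_group(tmpl, 0.0, True, seed=0).sequence)
        seq[7:14] = list("HAHAHAA")
        seq = "".join(seq)
        anchor = anchor_by_clade["B"]
        pmap = map_anchor_positions("q", seq, anchor)
        assert not build_signature(seq, pmap, anchor).nterm_his_rich

    def test_insertion_motifs(self, templates, anchor_by_clade):
        c4 = self._signature("C-4", templates, anchor_by_clade)
        assert c4.c_insertion_cys4
        a5 = self._signature("A-5", templates, anchor_by_clade)
        assert a5.extra_ef_cys4_count == 2
        f1 = self._signature("F-1", templates, anchor_by_clade)
        assert (f1.c_insertion_cys4, f1.extra_ef_cys4_count, f1.fusion) == \
            (False, 0, False)

    def test_fusion_flag_on_long_queries(self, templates, anchor_by_clade):
        def extend(seq):
            return seq + "W" * 201

        sig = self._signature("F-1", templates, anchor_by_clade, edit=extend)
        assert sig.fusion


def _sig(**kw):
    base = dict(
        d_type="II", c_cluster=("H", "C", "C", "C", "C", "C"),
        acid_base=("H", "K"), b_complete=True,
    )
    base.update(kw)
    return StructuralSignature(**base)


class TestAssignStructuralGroup:
    @pytest.mark.parametrize("clade, sig, label", [
        ("F", _sig(), "F-1"),
        ("F", _sig(nterm_cys_count=2), "F-2"),
        ("B", _sig(c_cluster=("H", "C", "D", "C", "C", "C"),
                   cterm_his_rich=True), "B-3"),
        ("B", _sig(c_cluster=("H", "C", "E", "C", "C", "C"),
                   nterm_his_rich=True), "B-1"),
        ("A", _sig(d_type="I", e_complete=True, f_complete=True), "A-1"),
        ("A", _sig(d_type=None, e_complete=True, f_complete=True,
                   extra_ef_cys4_count=2), "A-5"),
        ("A", _sig(d_type=None, e_complete=False, f_complete=False), "A-3"),
        ("A", _sig(d_type=None, e_complete=True, f_complete=True,
                   c_cluster=("D", "P", "C", "C", "C", "C"),
                   acid_base=("Q", "R")), "A-4"),
        ("E", _sig(d_type="III"), "E-2"),
        ("C", _sig(acid_base=("Y", "Q")), "C-2"),
        ("C", _sig(acid_base=("Y", "Q"), c_insertion_cys4=True), "C-4"),
        ("C", _sig(acid_base=("Y", "Q"), d_type=None), "C-3"),
        ("D", _sig(d_type="III", c_cluster=("H", "E", "C", "C", "C", "C"),
                   acid_base=("Y", "K")), "D-1"),
        ("D", _sig(d_type="III", acid_base=("N", "K")), "D-2"),
        ("G", _sig(d_type="III", c_cluster=("H", "T", "C", "C", "C", "C"),
                   acid_base=("Y", "K")), "G-1"),
        # no clade-C signature row permits His/Lys catalysts
        ("C", _sig(), OTHERS),
        ("F", _sig(b_complete=False), OTHERS),
        ("G", _sig(), OTHERS),
    ])
    def test_decision_rows(self, clade, sig, label):
        assert assign_structural_group(clade, sig).group_label == label

    def test_total_function_over_random_signatures(self):
        rng = random.Random(5)
        residues = ("H", "C", "D", "E", "N", "S", "T", "P", "absent")
        labels = set(GROUP_LABELS) | {OTHERS}
        for _ in range(2000):
            sig = StructuralSignature(
                d_type=rng.choice(("I", "II", "III", None)),
                c_cluster=tuple(rng.choice(residues) for _ in range(6)),
                acid_base=(rng.choice(("H", "Y", "N", "Q", "absent")),
                           rng.choice(("K", "Q", "R", "L", "absent"))),
                b_complete=rng.random() < 0.8,
                e_complete=rng.choice((True, False, None)),
                f_complete=rng.choice((True, False, None)),
                extra_ef_cys4_count=rng.randrange(4),
                nterm_cys_count=rng.randrange(5),
                nterm_his_rich=rng.random() < 0.3,
                cterm_his_rich=rng.random() < 0.3,
                c_insertion_cys4=rng.random() < 0.3,
            )
            clade = rng.choice("ABCDEFG")
            out = assign_structural_group(clade, sig)
            assert out.group_label in labels
            if out.group_label != OTHERS:
                assert out.group_label.startswith(out.clade)

    def test_scheme_size_matches_published_table(self):
        assert len(STRUCTURAL_GROUPS) == 24
        assert {row["clade"] for row in STRUCTURAL_GROUPS.values()} == \
            set("ABCDEFG")
        assert D_TYPES == ("I", "II", "III")


class TestRoundTrip:
    def test_all_templates_recover_their_label_without_noise(
            self, templates, anchors):
        for label, tmpl in templates.items():
            rec = generate_protein_for_group(tmpl, 0.0, True, seed=3)
            out = classify_protein(rec.id, rec.sequence, anchors)
            assert (out.clade, out.group_label) == (tmpl.clade, label)
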