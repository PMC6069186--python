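"""Locus merging, status/intactness rules, orthology, ids, exporters."""

from collections import namedtuple

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cvescreen import (
    Contig,
    DecayModel,
    OrthologGroup,
    assign_cve_ids,
    back_translate,
    call_intactness,
    call_status,
    export_loci,
    group_orthologs,
    insert_eve,
    loci_to_table,
    locus_from_truth,
    merge_hits_to_loci,
    random_peptide,
    read_loci_tsv,
)
from cvescreen.locus_annotation import Fragment, Locus
from cvescreen.synthetic_data import _random_seq

HitRec = namedtuple(
    "HitRec", "start end strand frame score assigned_gene assigned_group"
)


def _hit(start, end, strand="+", frame=1, score=100.0, gene="rep", group="Circovirus"):
    return HitRec(start, end, strand, frame, score, gene, group)


def _locus(start, end, strand="+", frame=1, species="sp", contig="c", gene="rep", group="Circovirus"):
    return Locus(
        species=species,
        contig_id=contig,
        nt_start=start,
        nt_end=end,
        strand=strand,
        fragments=[Fragment(start, end, frame, 100.0)],
        assigned_gene=gene,
        assigned_group=group,
    )


class TestMergeHits:
    def test_gap_within_threshold_merges(self):
        loci = merge_hits_to_loci(
            [_hit(100, 400), _hit(450, 700)], "sp", "c", max_gap=100
        )
        assert len(loci) == 1
        assert (loci[0].nt_start, loci[0].nt_end) == (100, 700)
        assert len(loci[0].fragments) == 2

    def test_gap_beyond_threshold_splits(self):
        loci = merge_hits_to_loci([_hit(100, 400), _hit(450, 700)], "sp", "c", max_gap=40)
        assert [(l.nt_start, l.nt_end) for l in loci] == [(100, 400), (450, 700)]

    def test_opposite_strands_never_merge(self):
        loci = merge_hits_to_loci(
            [_hit(100, 400, "+"), _hit(420, 700, "-", frame=-1)], "sp", "c", max_gap=100
        )
        assert len(loci) == 2
        assert {l.strand for l in loci} == {"+", "-"}

    def test_locus_classification_from_best_fragment(self):
        loci = merge_hits_to_loci(
            [
                _hit(100, 400, score=50, group="Circovirus"),
                _hit(450, 700, score=300, group="Cyclovirus"),
            ],
            "sp",
            "c",
        )
        assert loci[0].assigned_group == "Cyclovirus"

    @given(
        st.lists(
            st.tuples(
                st.integers(0, 3000),
                st.integers(10, 400),
                st.sampled_from("+-"),
                st.integers(1, 500),
            ),
            min_size=1,
            max_size=12,
        )
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_merge_is_idempotent(self, raw):
        hits = [
            _hit(s, s + ln, strand, frame=1 if strand == "+" else -1, score=float(sc))
            for s, ln, strand, sc in raw
        ]
        once = merge_hits_to_loci(hits, "sp", "c", max_gap=100)
        again = merge_hits_to_loci(
            [
                _hit(
                    l.nt_start,
                    l.nt_end,
                    l.strand,
                    l.fragments[0].frame,
                    max(f.score for f in l.fragments),
                )
                for l in once
            ],
            "sp",
            "c",
            max_gap=100,
        )
        assert [(l.nt_start, l.nt_end, l.strand) for l in again] == [
            (l.nt_start, l.nt_end, l.strand) for l in once
        ]


class TestStatus:
    def test_long_flanks_confirm(self):
        locus = _locus(3500, 4000)
        assert call_status(locus, 3500 + 500 + 4000) == "confirmed_cve"
        assert (locus.flank5, locus.flank3) == (3500, 4000)

    def test_threshold_is_strict(self):
        locus = _locus(3000, 3400)
        assert call_status(locus, 3000 + 400 + 5000) == "unconfirmed"

    def test_locus_spanning_short_contig_unconfirmed(self):
        locus = _locus(0, 1500)
        assert call_status(locus, 1500) == "unconfirmed"

    def test_out_of_bounds_error(self):
        with pytest.raises(ValueError):
            call_status(_locus(100, 900), 800)

    def test_growing_flanks_never_unconfirm(self, rng):
        # status monotonicity in both flank lengths
        for _ in range(50):
            f5, f3 = int(rng.integers(0, 6000)), int(rng.integers(0, 6000))
            locus = _locus(f5, f5 + 300)
            before = call_status(locus, f5 + 300 + f3)
            bigger = _locus(f5 + 1000, f5 + 1300)
            after = call_status(bigger, f5 + 1000 + 300 + f3 + 1000)
            if before == "confirmed_cve":
                assert after == "confirmed_cve"


class TestIntactness:
    def _coding_contig(self, n_aa, flank=600, seed=0):
        rng = np.random.default_rng(seed)
        pep = random_peptide(n_aa, rng, id="p")
        elem = back_translate(pep, rng)
        left = _random_seq(flank, 0.42, rng)
        right = _random_seq(flank, 0.42, rng)
        contig = Contig("c", left + elem + right)
        locus = _locus(flank, flank + len(elem), frame=(flank % 3) + 1)
        return contig, locus

    def test_short_region_not_intact(self):
        contig, locus = self._coding_contig(80)
        locus.nt_end = locus.nt_start + 199
        locus.fragments = [Fragment(locus.nt_start, locus.nt_end, locus.fragments[0].frame, 100.0)]
        assert call_intactness(locus, contig) is False

    def test_clean_single_frame_region_intact(self):
        contig, locus = self._coding_contig(100)
        assert call_intactness(locus, contig) is True

    def test_internal_stop_breaks_intactness(self):
        contig, locus = self._coding_contig(100, seed=3)
        s = locus.nt_start + 150 - (locus.nt_start + 150 - locus.nt_start) % 3
        mutated = contig.seq[:s] + "TAA" + contig.seq[s + 3 :]
        assert call_intactness(locus, Contig("c", mutated)) is False

    def test_frameshifted_fragments_not_intact(self):
        contig, locus = self._coding_contig(100)
        mid = (locus.nt_start + locus.nt_end) // 2
        f = locus.fragments[0]
        locus.fragments = [
            Fragment(f.nt_start, mid, f.frame, 100.0),
            Fragment(mid + 1, f.nt_end, f.frame % 3 + 1, 90.0),
        ]
        assert call_intactness(locus, contig) is False

    def test_one_nt_insertion_flips_intactness(self):
        # end-to-end against the simulator's truth records
        rng = np.random.default_rng(9)
        base = Contig("c", _random_seq(8000, 0.42, rng))
        pep = random_peptide(100, rng)
        clean, rec0 = insert_eve(base, pep, DecayModel(), 4000, "+", seed=1)
        assert rec0.true_intact
        assert call_intactness(locus_from_truth(rec0), clean) is True
        shifted, rec1 = insert_eve(base, pep, DecayModel(frameshift_rate=1), 4000, "+", seed=1)
        assert not rec1.true_intact
        assert call_intactness(locus_from_truth(rec1), shifted) is False


class TestOrthology:
    def _speciate(self, seq, divergence, rng):
        out = list(seq)
        n = round(divergence * len(out))
        for pos in rng.choice(len(out), size=n, replace=False):
            out[pos] = rng.choice([b for b in "ACGT" if b != out[pos]])
        return "".join(out)

    def test_shared_ancestral_insertion_groups_together(self, rng):
        ancestor = _random_seq(4000, 0.42, rng)
        elem = back_translate(random_peptide(100, rng), rng)
        ancestral = ancestor[:2000] + elem + ancestor[2000:]
        a = Contig("cA", self._speciate(ancestral, 0.05, rng))
        b = Contig("cB", self._speciate(ancestral, 0.05, rng))
        loci = [
            _locus(2000, 2000 + len(elem), species="spA", contig="cA"),
            _locus(2000, 2000 + len(elem), species="spB", contig="cB"),
        ]
        groups = group_orthologs(loci, {"spA": {"cA": a}, "spB": {"cB": b}})
        assert len(groups) == 1 and len(groups[0].members) == 2

    def test_same_element_unrelated_context_stays_separate(self, rng):
        elem = back_translate(random_peptide(100, rng), rng)
        a_seq = _random_seq(4000, 0.42, rng)
        b_seq = _random_seq(4000, 0.42, rng)
        a = Contig("cA", a_seq[:2000] + elem + a_seq[2000:])
        b = Contig("cB", b_seq[:1000] + elem + b_seq[1000:])
        loci = [
            _locus(2000, 2000 + len(elem), species="spA", contig="cA"),
            _locus(1000, 1000 + len(elem), species="spB", contig="cB"),
        ]
        groups = group_orthologs(loci, {"spA": {"cA": a}, "spB": {"cB": b}})
        assert len(groups) == 2

    def test_single_species_all_singletons(self, rng):
        contig = Contig("cA", _random_seq(9000, 0.42, rng))
        loci = [_locus(1000, 1400, species="spA", contig="cA"),
                _locus(6000, 6400, species="spA", contig="cA")]
        groups = group_orthologs(loci, {"spA": {"cA": contig}})
        assert len(groups) == 2


class TestIds:
    def test_first_allocation_format(self):
        locus = _locus(100, 400, group="Cyclovirus", species="pgra")
        registry = assign_cve_ids([OrthologGroup([locus])], {"pgra": "PGra"})
        assert locus.cve_id == "CVe-Cyclovirus.1-PGra"
        assert registry.iloc[0].cve_id == "CVe-Cyclovirus.1-PGra"

    def test_ortholog_pair_shares_number(self):
        a = _locus(100, 400, species="spA", group="Circovirus")
        b = _locus(100, 400, species="spB", group="Circovirus")
        c = _locus(900, 1200, species="spA", group="Circovirus")
        reg = assign_cve_ids(
            [OrthologGroup([a, b]), OrthologGroup([c])], {"spA": "A", "spB": "B"}
        )
        assert a.cve_id == "CVe-Circovirus.1-A" and b.cve_id == "CVe-Circovirus.1-B"
        assert c.cve_id == "CVe-Circovirus.2-A"
        assert len(reg) == 3

    def test_rerun_with_registry_is_stable(self):
        a = _locus(100, 400, species="spA")
        reg = assign_cve_ids([OrthologGroup([a])], {"spA": "A"})
        a2 = _locus(100, 400, species="spA")
        b = _locus(5000, 5300, species="spA")
        reg2 = assign_cve_ids(
            [OrthologGroup([b]), OrthologGroup([a2])], {"spA": "A"}, registry=reg
        )
        assert a2.cve_id == a.cve_id
        assert b.cve_id == "CVe-Circovirus.2-A"
        assert set(reg2.cve_id) == {a.cve_id, b.cve_id}

    def test_ids_invariant_to_input_order(self):
        def run(order):
            l1 = _locus(100, 400, species="spA")
            l2 = _locus(5000, 5300, species="spB")
            groups = [OrthologGroup([l1]), OrthologGroup([l2])]
            groups = groups if order else groups[::-1]
            groups.sort(key=lambda og: min((m.species, m.contig_id, m.nt_start) for m in og.members))
            assign_cve_ids(groups, {"spA": "A", "spB": "B"})
            return l1.cve_id, l2.cve_id

        assert run(True) == run(False)


class TestExport:
    def _loci(self, n=20, seed=0):
        rng = np.random.default_rng(seed)
        out = []
        for i in range(n):
            start = int(rng.integers(0, 5000))
            end = start + int(rng.integers(200, 900))
            strand = "+" if rng.random() < 0.5 else "-"
            l = _locus(start, end, strand, species=f"sp{i % 3}", contig=f"c{i}")
            l.flank5, l.flank3 = start, 1000
            l.status = "confirmed_cve" if rng.random() < 0.5 else "unconfirmed"
            l.intact = bool(rng.random() < 0.5)
            l.cve_id = f"CVe-Circovirus.{i + 1}-S{i % 3}"
            out.append(l)
        return out

    def test_gff3_one_based_coordinates(self, tmp_path):
        locus = _locus(100, 700)
        p = tmp_path / "out.gff3"
        export_loci([locus], p, "gff3")
        line = p.read_text().splitlines()[1].split("\t")
        assert (line[3], line[4]) == ("101", "700")
        assert line[2] == "endogenous_viral_element"

    def test_gff3_structure_valid(self, tmp_path):
        p = tmp_path / "out.gff3"
        loci = self._loci()
        export_loci(loci, p, "gff3")
        lines = p.read_text().splitlines()
        assert lines[0] == "##gff-version 3"
        for line in lines[1:]:
            cols = line.split("\t")
            assert len(cols) == 9
            assert int(cols[3]) >= 1 and int(cols[4]) >= int(cols[3])
            assert cols[6] in "+-"
            for attr in cols[8].split(";"):
                key, _, value = attr.partition("=")
                assert key and "=" not in value and ";" not in value

    def test_tsv_round_trip(self, tmp_path):
        p = tmp_path / "loci.tsv"
        loci = self._loci()
        export_loci(loci, p, "tsv")
        again = read_loci_tsv(p)
        assert loci_to_table(again).equals(loci_to_table(loci))

    def test_unknown_format_error(self, tmp_path):
        with pytest.raises(ValueError):
            export_loci(self._loci(2), tmp_path / "x", "bed")
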