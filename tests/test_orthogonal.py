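"""In-silico PCR, digest/probe prediction and allele classification."""
import re
import warnings

import numpy as np
import pytest

from vectorfree._encode import revcomp
from vectorfree.orthogonal import (
    ENZYMES,
    PrimerPair,
    classify_alleles,
    digest_and_probe,
    editing_efficiency,
    insilico_pcr,
    line_status,
    offtarget_check,
    presence_matrix,
    read_primer_panel,
    write_primer_panel,
)
from vectorfree.simulate import (
    Feature,
    TruthRecord,
    VectorMap,
    integrate,
    make_host_genome,
    make_vector,
)


def _random_seq(n, seed):
    rng = np.random.default_rng(seed)
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


F = "ACGTACGGTACGTTACGGAT"
R = "TTGCAGGCATTGCAGGCATT"


class TestInsilicoPcr:
    def test_absent_primers_no_product(self):
        assert insilico_pcr(_random_seq(500, 1), PrimerPair("P", F, R)) == []

    def test_constructed_single_product(self):
        mid = _random_seq(100, 2)
        tpl = F + mid + revcomp(R)
        hits = insilico_pcr(tpl, PrimerPair("P", F, R))
        assert len(hits) == 1
        assert (hits[0].start, hits[0].end, hits[0].length) == (1, 140, 140)

    def test_two_forward_sites_match_enumeration(self):
        # brute-force oracle over all exact site pairs (max_mismatch=0)
        mid1, mid2 = _random_seq(80, 3), _random_seq(40, 4)
        tpl = F + mid1 + F + mid2 + revcomp(R)
        f_sites = [m.start() for m in re.finditer(f"(?={F})", tpl)]
        r_sites = [m.start() for m in re.finditer(f"(?={revcomp(R)})", tpl)]
        expected = sorted(
            r + len(R) - f
            for f in f_sites
            for r in r_sites
            if r >= f and r + len(R) - f <= 5000
        )
        hits = insilico_pcr(tpl, PrimerPair("P", F, R), max_mismatch=0)
        assert sorted(h.length for h in hits) == expected
        assert len(hits) == 2

    def test_template_revcomp_invariance(self):
        mid = _random_seq(100, 5)
        tpl = F + mid + revcomp(R)
        fwd_hits = insilico_pcr(tpl, PrimerPair("P", F, R))
        rc_hits = insilico_pcr(revcomp(tpl), PrimerPair("P", F, R))
        assert sorted(h.length for h in fwd_hits) == sorted(h.length for h in rc_hits)

    def test_circular_origin_spanning_product(self):
        mid = _random_seq(100, 6)
        linearised = mid[50:] + revcomp(R) + _random_seq(200, 7) + F + mid[:50]
        assert insilico_pcr(linearised, PrimerPair("P", F, R), topology="linear") == []
        hits = insilico_pcr(linearised, PrimerPair("P", F, R), topology="circular")
        assert len(hits) == 1
        assert hits[0].length == len(F) + 100 + len(R)

    def test_three_prime_mismatch_blocks_annealing(self):
        mid = _random_seq(100, 8)
        broken_f = F[:-1] + ("A" if F[-1] != "A" else "C")
        tpl = broken_f + mid + revcomp(R)
        assert insilico_pcr(tpl, PrimerPair("P", F, R), max_mismatch=2) == []

    def test_internal_mismatches_tolerated(self):
        mid = _random_seq(100, 9)
        f_mut = F[:5] + ("A" if F[5] != "A" else "C") + F[6:]
        tpl = f_mut + mid + revcomp(R)
        assert len(insilico_pcr(tpl, PrimerPair("P", F, R), max_mismatch=2)) == 1

    def test_empty_template_rejected(self):
        with pytest.raises(ValueError):
            insilico_pcr("", PrimerPair("P", F, R))


class TestPresenceMatrix:
    def test_vector_panel_discriminates(self):
        vector = make_vector(2000, 3000, seed=2)
        host = make_host_genome(5000, 0.5, seed=3)
        pair = PrimerPair(
            "PCR1",
            vector.sequence[100:120],
            revcomp(vector.sequence[480:500]),
        )
        control = PrimerPair(
            "PCR0", host.sequence[0:20], revcomp(host.sequence[380:400])
        )
        m = presence_matrix(
            {"vector": (vector.sequence, "circular"), "host": host.sequence},
            [control, pair],
        )
        assert m.loc["PCR1", "vector"] == (400,)
        assert m.loc["PCR1", "host"] == ()
        assert m.loc["PCR0", "host"] == (400,)

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError):
            presence_matrix({"a": "ACGT" * 100}, [])


class TestDigestAndProbe:
    def test_manual_partition(self):
        # cuts after positions 20 and 60 on a 100 bp template -> 20/40/40
        seq = list(_random_seq(100, 10))
        seq[19:25] = "GGATCC"
        seq[59:65] = "GGATCC"
        seq = "".join(seq)
        vec = VectorMap("A" * 600, "linear", [Feature("probe", 100, 200)])
        pred = digest_and_probe(seq, "linear", ["BamHI"], vec, TruthRecord())
        assert pred.fragment_sizes_all == [20, 40, 40]
        assert pred.fragments_hit_by_probe == []

    @pytest.mark.parametrize("topology", ["linear", "circular"])
    def test_fragment_sizes_sum_to_genome_length(self, topology):
        seq = _random_seq(20_000, 11)
        vec = make_vector(2000, 3000, seed=2)
        pred = digest_and_probe(seq, topology, ["BamHI", "HindIII"], vec, TruthRecord())
        assert sum(pred.fragment_sizes_all) == len(seq)

    def test_integrated_probe_fragment_sizes(self):
        # independent oracle: regex cut sites -> partition -> probe overlap
        from vectorfree.simulate import HostGenome

        vector = make_vector(2000, 3000, seed=2)
        host_seq = list(_random_seq(10_000, 12))
        motif, off = ENZYMES["BamHI"]
        host_seq[3993:3999] = motif
        host_seq[6999:7005] = motif
        host = HostGenome("".join(host_seq), name="host")
        genome, truth = integrate(host, vector, (1, 2000), 5000)
        pred = digest_and_probe(genome.sequence, "linear", ["BamHI"], vector, truth)
        probe = vector.feature("probe")
        ps, pe = 5000 + probe.start, 5000 + probe.end
        cuts = sorted(
            m.start() + off for m in re.finditer(f"(?={motif})", genome.sequence)
        )
        bounds = [0] + cuts + [len(genome.sequence)]
        expected = [
            b - a
            for a, b in zip(bounds, bounds[1:])
            if min(b, pe) - max(a + 1, ps) + 1 >= 50
        ]
        assert expected  # the constructed sites flank the probe copy
        assert pred.fragments_hit_by_probe == expected

    def test_non_integrated_genome_has_no_probe_hit(self):
        vector = make_vector(2000, 3000, seed=2)
        pred = digest_and_probe(
            _random_seq(10_000, 13), "linear", ["BamHI", "HindIII"], vector, TruthRecord()
        )
        assert pred.fragments_hit_by_probe == []

    def test_probe_sequence_absence_detected(self):
        vector = make_vector(2000, 3000, seed=2)
        truth = TruthRecord(integrated=True, vector_interval=(1, 2000), host_locus=5000)
        with pytest.raises(ValueError):
            digest_and_probe(_random_seq(10_000, 14), "linear", ["BamHI"], vector, truth)


REF = _random_seq(300, 20)
TARGET = (141, 160)


class TestClassifyAlleles:
    def test_reference_is_intact_for_any_interval(self):
        for interval in [(1, 300), (141, 160), (299, 300)]:
            (call,) = classify_alleles([REF], REF, interval)
            assert call.intact and call.frame == "intact" and call.net_indel == 0

    def test_in_frame_deletion(self):
        clone = REF[:150] + REF[156:]
        (call,) = classify_alleles([clone], REF, TARGET)
        assert call.net_indel == -6
        assert call.frame == "in_frame"
        assert not call.intact
        assert any(kind == "deletion" and ln == 6 for _, ln, kind in call.indel_events)

    def test_one_bp_insertion_frameshift(self):
        clone = REF[:150] + "A" + REF[150:]
        (call,) = classify_alleles([clone], REF, TARGET)
        assert call.net_indel == 1
        assert call.frame == "frameshift"
        assert not call.intact

    def test_substitution_in_target_breaks_intact_not_frame(self):
        base = "A" if REF[149] != "A" else "C"
        clone = REF[:149] + base + REF[150:]
        (call,) = classify_alleles([clone], REF, TARGET)
        assert call.net_indel == 0
        assert call.frame == "intact"
        assert not call.intact

    def test_event_outside_target_keeps_intact_flag(self):
        clone = REF[:20] + REF[26:]  # 6 bp deletion far upstream of the target
        (call,) = classify_alleles([clone], REF, TARGET)
        assert call.intact
        assert call.frame == "in_frame"

    def test_unalignable_clone_excluded_with_warning(self):
        junk = _random_seq(300, 21)
        with pytest.warns(UserWarning):
            calls = classify_alleles({"ok": REF, "junk": junk}, REF, TARGET)
        assert [c.clone_id for c in calls] == ["ok"]


class TestLineStatus:
    def test_status_rules(self):
        intact, = classify_alleles([REF], REF, TARGET)
        mutated, = classify_alleles([REF[:150] + REF[156:]], REF, TARGET)
        assert line_status([mutated, mutated]).status == "complete_disruptant"
        assert line_status([intact, mutated]).status == "partial"
        assert line_status([intact]).status == "unedited"

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            line_status([])


class TestOfftargetCheck:
    def test_identical_clones_all_intact(self):
        homolog = _random_seq(250, 22)
        calls = offtarget_check([homolog, homolog], homolog)
        assert all(c.intact for c in calls)

    def test_three_bp_deletion_reported(self):
        homolog = _random_seq(250, 23)
        clone = homolog[:100] + homolog[103:]
        (call,) = offtarget_check([clone], homolog)
        assert not call.intact
        assert call.frame == "in_frame"


class TestEditingEfficiency:
    @pytest.mark.parametrize(
        "candidates,regenerated,expected",
        [(5, 195, 2.6), (2, 224, 0.9), (1, 95, 1.1), (1, 98, 1.0), (0, 100, 0.0)],
    )
    def test_reported_rows(self, candidates, regenerated, expected):
        assert editing_efficiency(candidates, regenerated) == expected

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            editing_efficiency(1, 0)
        with pytest.raises(ValueError):
            editing_efficiency(5, 4)


def test_primer_panel_roundtrip(tmp_path):
    panel = [PrimerPair("PCR0", F, R), PrimerPair("PCR1", R, F)]
    write_primer_panel(tmp_path / "panel.tsv", panel)
    back = read_primer_panel(tmp_path / "panel.tsv")
    assert [(p.set_id, p.forward, p.reverse) for p in back] == [
        ("PCR0", F, R),
        ("PCR1", R, F),
    ]
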