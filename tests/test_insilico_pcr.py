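import numpy as np
import pytest

from plastomics.assays import (
    DEFAULT_ASSAYS,
    INV24_ASSAY,
    INV36_ASSAY,
    PrimerPair,
)
from plastomics.errors import ValidationError
from plastomics.insilico_pcr import (
    PcrParams,
    find_primer_sites,
    genera_without_any_inversion,
    predict_amplicons,
    run_panel_screen,
    screen_inversion,
)
from plastomics.io import PlastomeRecord
from plastomics.seqs import revcomp
from plastomics.synth import (
    DEFAULT_PANEL,
    INV24,
    apply_inversion,
    build_panel,
)

BASES = np.array(list("ACGT"))


def _rand_seq(rng, n):
    return "".join(BASES[rng.integers(0, 4, n)])


class TestFindPrimerSites:
    def test_planted_exact_site(self):
        rng = np.random.default_rng(21)
        primer = "CGTTCCCAATGTGCCTAT"
        seq = _rand_seq(rng, 2000)
        seq = seq[:700] + primer + seq[700 + len(primer):]
        sites = find_primer_sites(seq, primer)
        exact = [s for s in sites if s.mismatches == 0]
        assert len(exact) == 1
        assert exact[0].position == 700 and exact[0].strand == 1

    def test_origin_spanning_site_found_once(self):
        rng = np.random.default_rng(22)
        primer = "ACGGATTACCAGGTTACCAT"
        seq = _rand_seq(rng, 1000)
        # place so 12 bases hang over the origin
        seq = primer[12:] + seq[8:-12] + primer[:12]
        sites = [
            s for s in find_primer_sites(seq, primer) if s.mismatches == 0
        ]
        assert len(sites) == 1
        assert sites[0].position == len(seq) - 12

    def test_brute_force_oracle(self):
        def brute(seq, primer, max_mm, three_exact):
            n, L = len(seq), len(primer)
            ext = seq + seq[: L - 1]
            hits = []
            for strand, laid in ((1, primer), (-1, revcomp(primer))):
                for pos in range(n):
                    window = ext[pos : pos + L]
                    mm = sum(a != b for a, b in zip(window, laid))
                    if mm > max_mm:
                        continue
                    tail = (
                        window[-three_exact:] == laid[-three_exact:]
                        if strand == 1
                        else window[:three_exact] == laid[:three_exact]
                    )
                    if tail:
                        hits.append((pos, strand, mm))
            return sorted(hits)

        rng = np.random.default_rng(23)
        seq = _rand_seq(rng, 6000)
        for t in range(200):
            primer = _rand_seq(rng, 20)
            if t % 4 == 0:  # plant a mutated copy so hits actually occur
                copy = list(primer)
                copy[int(rng.integers(0, 17))] = str(
                    rng.choice(list("ACGT"))
                )
                pos = int(rng.integers(0, len(seq) - 20))
                seq = seq[:pos] + "".join(copy) + seq[pos + 20:]
            got = sorted(
                (s.position, s.strand, s.mismatches)
                for s in find_primer_sites(seq, primer, 2, 3)
            )
            assert got == brute(seq, primer, 2, 3)


class TestPredictAmplicons:
    def _record_with_sites(self, fwd, rev, gap, rng):
        """fwd site, then `gap` random bases, then the rev site (on minus)."""
        left = _rand_seq(rng, 400)
        mid = _rand_seq(rng, gap)
        right = _rand_seq(rng, 400)
        seq = left + fwd + mid + revcomp(rev) + right
        return seq

    def test_convergent_product_length(self):
        rng = np.random.default_rng(24)
        pair = PrimerPair("t", "CGTTCCCAATGTGCCTATAC", "TGGTAGAGCAGAGGACTGAC")
        seq = self._record_with_sites(pair.forward, pair.reverse, 760, rng)
        amps = predict_amplicons(seq, pair, PcrParams(max_amplicon=3000))
        assert len(amps) == 1
        assert amps[0].length == 20 + 760 + 20  # inclusive of both primers

    def test_divergent_sites_long_arc_only(self):
        rng = np.random.default_rng(25)
        pair = PrimerPair("t", "CGTTCCCAATGTGCCTATAC", "TGGTAGAGCAGAGGACTGAC")
        # back-to-back: reverse site first (minus), forward after it
        left = _rand_seq(rng, 200)
        seq = (
            left + revcomp(pair.reverse) + _rand_seq(rng, 50)
            + pair.forward + _rand_seq(rng, 400)
        )
        short = predict_amplicons(seq, pair, PcrParams(max_amplicon=500))
        assert short == []
        long_arc = predict_amplicons(
            seq, pair, PcrParams(max_amplicon=len(seq))
        )
        assert len(long_arc) == 1
        assert long_arc[0].length == len(seq) - 50

    def test_maackia_like_vs_pairs(self, mini_inverted):
        genome = mini_inverted["50+36+24"].sequence
        presence = predict_amplicons(
            genome, INV24_ASSAY.presence_pair, PcrParams()
        )
        absence = predict_amplicons(
            genome, INV24_ASSAY.absence_pair, PcrParams()
        )
        assert len(presence) >= 1
        assert absence == []


class TestScreen:
    def test_present_absent_ambiguous(self, mini_inverted):
        maackia = mini_inverted["50+36+24"]
        lupinus = mini_inverted["50+36"]
        assert screen_inversion(maackia, INV24_ASSAY).call == "PRESENT"
        assert screen_inversion(lupinus, INV24_ASSAY).call == "ABSENT"
        assert screen_inversion(maackia, INV36_ASSAY).call == "PRESENT"
        assert screen_inversion(lupinus, INV36_ASSAY).call == "PRESENT"
        ancestral = mini_inverted["ancestral"]
        assert screen_inversion(ancestral, INV36_ASSAY).call == "ABSENT"
        # all sites removed -> AMBIGUOUS
        rng = np.random.default_rng(26)
        blank = PlastomeRecord("blank", _rand_seq(rng, 4000), True, [])
        assert screen_inversion(blank, INV24_ASSAY).call == "AMBIGUOUS"

    def test_inversion_toggles_both_pairs(self, mini_inverted):
        # reversing the segment abolishes the absence product and creates
        # the presence product, for the 24-kb assay
        before = mini_inverted["50+36"]
        after, _ = apply_inversion(before, INV24)
        b = screen_inversion(before, INV24_ASSAY)
        a = screen_inversion(after, INV24_ASSAY)
        assert b.call == "ABSENT" and a.call == "PRESENT"
        assert b.absence_lengths and not b.presence_lengths
        assert a.presence_lengths and not a.absence_lengths

    def test_rotation_invariance_of_calls(self, mini_inverted):
        rec = mini_inverted["50+36+24"]
        seq = rec.sequence
        for shift in (911, 7000):
            rot = PlastomeRecord(
                rec.id, seq[shift:] + seq[:shift], True, []
            )
            for assay in DEFAULT_ASSAYS:
                assert (
                    screen_inversion(rot, assay).call
                    == screen_inversion(rec, assay).call
                )

    def test_panel_screen_matches_published_pattern(self):
        panel = build_panel(DEFAULT_PANEL, seed=31, profile="mini")
        tribes = {t.taxon: t.tribe for t in DEFAULT_PANEL.taxa}
        result = run_panel_screen(panel, DEFAULT_ASSAYS, tribes=tribes)
        expected = {
            t.taxon: {
                "INV36": "PRESENT" if t.inv36 else "ABSENT",
                "INV24": "PRESENT" if t.inv24 else "ABSENT",
            }
            for t in DEFAULT_PANEL.taxa
        }
        for taxon, row in result.calls.iterrows():
            assert row.to_dict() == expected[taxon], taxon
        assert len(result.genus_tally["INV24"]) == 8
        assert len(result.tribe_tally["INV36"]) == 5
        assert genera_without_any_inversion(result) == [
            "Camoensia", "Cladrastis", "Styphnolobium"
        ]

    def test_empty_assay_list(self, mini_record):
        result = run_panel_screen([("x", mini_record)], ())
        assert result.calls.empty

    def test_primer_validation(self):
        with pytest.raises(ValidationError):
            PrimerPair("short", "ACGTACG", "ACGTACGTACGTACGTA")
        with pytest.raises(ValidationError):
            PrimerPair("bad", "ACGTACGTACGTACGRR", "ACGTACGTACGTACGTA")
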