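import numpy as np
import pytest

from plastomics.errors import (
    AnchorResolutionError,
    ConfigError,
    LookupError_,
    SizingError,
    ValidationError,
)
from plastomics.gene_status import extract_locus
from plastomics.seqs import revcomp
from plastomics.synth import (
    DEFAULT_PANEL,
    FULL_REGIONS,
    INV24,
    INV36,
    INV50,
    MINI_REGIONS,
    MutationSpec,
    RegionLengths,
    apply_inversion,
    build_panel,
    default_gene_catalog,
    generate_plastome,
    mutate_gene,
    panel_from_rows,
)


class TestCatalog:
    def test_at_least_71_cds(self, full_catalog):
        assert full_catalog.cds_count() >= 71

    def test_rps16_structure(self, full_catalog):
        g = full_catalog.get("rps16")
        assert g.exon_lengths is not None and len(g.exon_lengths) == 2
        assert g.intron_length > 0

    def test_anchor_genes_in_lsc(self, full_catalog):
        for name in ("accD", "trnK-UUU", "trnC-GCA", "trnF-GAA",
                     "trnS-GGA", "trnS-GCU", "ndhJ", "rps16"):
            assert full_catalog.get(name).region == "LSC"

    def test_ir_genes_mirrored_in_record(self, mini_record):
        ir_names = [
            g.name for g in default_gene_catalog("mini").in_region("IR")
        ]
        for name in ir_names:
            feats = mini_record.features_named(name)
            assert len(feats) == 2, name
            assert {f.strand for f in feats} == {1, -1}, name
            # the two copies carry identical coding-strand sequence
            s0, s1 = (mini_record.feature_sequence(f) for f in feats)
            assert s0 == s1

    def test_unknown_profile(self):
        with pytest.raises(ConfigError):
            default_gene_catalog("huge")


class TestGenerate:
    def test_full_total_length(self, full_record):
        assert len(full_record) == 154_541
        assert FULL_REGIONS.total == 154_541

    def test_ir_is_exact_reverse_complement(self, full_record):
        L, S, I = FULL_REGIONS.lsc, FULL_REGIONS.ssc, FULL_REGIONS.ir
        ira = full_record.sequence[L:L + I]
        irb = full_record.sequence[L + I + S:]
        assert irb == revcomp(ira)

    def test_determinism_and_seed_sensitivity(self, mini_catalog):
        a = generate_plastome(mini_catalog, MINI_REGIONS, seed=5)
        b = generate_plastome(mini_catalog, MINI_REGIONS, seed=5)
        c = generate_plastome(mini_catalog, MINI_REGIONS, seed=6)
        assert a.sequence == b.sequence and a.features == b.features
        assert c.sequence != a.sequence
        assert [f.gene for f in c.gene_features()] == [
            f.gene for f in a.gene_features()
        ]

    def test_region_too_small(self, mini_catalog):
        with pytest.raises(SizingError):
            generate_plastome(
                mini_catalog, RegionLengths(lsc=3000, ssc=2600, ir=2200),
                seed=0,
            )

    def test_length_equals_requested_regions(self, mini_record):
        assert len(mini_record) == MINI_REGIONS.total


class TestInversions:
    def test_involution_restores_gene_order(self, mini_record):
        for spec in (INV50, INV36, INV24):
            once, _ = apply_inversion(mini_record, spec)
            twice, _ = apply_inversion(once, spec)
            assert [
                (f.gene, f.strand) for f in twice.gene_features()
            ] == [(f.gene, f.strand) for f in mini_record.gene_features()]
            assert twice.sequence == mini_record.sequence

    def test_full_scale_sizes_within_10pct(self, full_record):
        r50, e50 = apply_inversion(full_record, INV50)
        r36, e36 = apply_inversion(r50, INV36)
        _, e24 = apply_inversion(r36, INV24)
        assert abs(e50.size - 50_000) <= 5_000
        assert abs(e36.size - 36_000) <= 3_600
        assert abs(e24.size - 24_000) <= 2_400

    def test_strands_flip_inside_segment_only(self, mini_record):
        out, ev = apply_inversion(mini_record, INV24)
        singles = {
            f.gene
            for f in mini_record.gene_features()
            if len(mini_record.features_named(f.gene)) == 1
        }
        before = {
            f.gene: f
            for f in mini_record.gene_features()
            if f.gene in singles
        }
        checked_inside = 0
        for f in out.gene_features():
            if f.gene not in singles:
                continue  # IR-duplicated genes pair ambiguously by name
            b = before[f.gene]
            inside = ev.left_bp <= f.start and f.end <= ev.right_bp
            if inside:
                assert f.strand == -b.strand, f.gene
                checked_inside += 1
            else:
                assert f.strand == b.strand, f.gene
                assert f.parts == b.parts, f.gene
        assert checked_inside > 5

    def test_gene_content_invariant(self, mini_record):
        out, _ = apply_inversion(mini_record, INV36)
        assert sorted(f.gene for f in out.gene_features()) == sorted(
            f.gene for f in mini_record.gene_features()
        )

    def test_inv36_mediated_by_29bp_repeat(self, mini_record):
        _, ev = apply_inversion(mini_record, INV36)
        assert ev.mediating_repeat == ("repeat29", 29)

    def test_absent_anchor_raises(self, mini_record):
        spec = INV24.__class__(
            "bad", ("igs", "nosuchgene", "right"), ("igs", "petN", "left")
        )
        with pytest.raises(AnchorResolutionError):
            apply_inversion(mini_record, spec)


class TestMutations:
    def test_aaac_duplication_lands_in_exon2(self, mini_record):
        spec = MutationSpec("FRAMESHIFT_INSERTION", motif="AAAC", exon=2)
        out = mutate_gene(mini_record, "rps16", spec, seed=1)
        locus = extract_locus(out, "rps16")
        assert "AAACAAAC" in locus.exons[1]
        # annotation retained
        assert out.features_named("rps16")

    def test_whole_gene_deletion_absent(self, mini_record):
        out = mutate_gene(
            mini_record, "rps16", MutationSpec("WHOLE_GENE_DELETION")
        )
        assert extract_locus(out, "rps16") is None
        assert len(out) < len(mini_record)

    def test_intron_deletion_leaves_exons(self, mini_record):
        before = extract_locus(mini_record, "rps16")
        out = mutate_gene(
            mini_record, "rps16", MutationSpec("INTRON_DELETION", span=100)
        )
        after = extract_locus(out, "rps16")
        assert after.exons == before.exons
        assert len(after.introns[0]) == len(before.introns[0]) - 100

    def test_frameshift_payload_validation(self):
        with pytest.raises(ValidationError):
            MutationSpec("FRAMESHIFT_INSERTION", motif="AAACCC")
        with pytest.raises(ValidationError):
            MutationSpec("FRAMESHIFT_DELETION", span=3)

    def test_unknown_gene(self, mini_record):
        with pytest.raises(LookupError_):
            mutate_gene(
                mini_record, "nope", MutationSpec("START_CODON_MUTATION")
            )


class TestPanel:
    def test_default_panel_16_records(self):
        panel = build_panel(DEFAULT_PANEL, seed=1, profile="mini")
        assert len(panel) == 16

    def test_maackia_row_has_both_inversions(self):
        panel = dict(build_panel(DEFAULT_PANEL, seed=1, profile="mini"))
        maackia = panel["Maackia fauriei"]
        cladrastis = panel["Cladrastis wilsonii"]
        maackia_order = [(f.gene, f.strand) for f in maackia.gene_features()]
        clad_order = [(f.gene, f.strand) for f in cladrastis.gene_features()]
        assert maackia_order != clad_order

    def test_all_absent_panel_shares_gene_order(self):
        rows = [
            {"taxon": f"t{k}", "INV36": "-", "INV24": "-", "INV50": False}
            for k in range(4)
        ]
        panel = build_panel(panel_from_rows(rows), seed=2, profile="mini")
        orders = {
            tuple((f.gene, f.strand) for f in rec.gene_features())
            for _, rec in panel
        }
        assert len(orders) == 1

    def test_bad_state_symbol(self):
        with pytest.raises(ConfigError):
            panel_from_rows([{"taxon": "x", "INV36": "yes"}])

    def test_duplicate_taxa_rejected(self):
        with pytest.raises(ConfigError):
            panel_from_rows(
                [{"taxon": "x", "INV36": "+"}, {"taxon": "x", "INV36": "-"}]
            )
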