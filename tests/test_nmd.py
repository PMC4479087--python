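"""NMD feature extraction, the three-rule classifier and gene aggregation."""

import numpy as np
import pytest

from nmdscope.nmd import (
    RULE_DOWNSTREAM_JUNCTION,
    RULE_LONG_UTR3,
    RULE_UTR3_INTRON,
    ConfigurationError,
    NMDFeatureSet,
    classify_nmd,
    classify_transcript,
    extract_nmd_features,
    gene_level_nmd,
    stop_codon_spliced_offset,
)

from conftest import build_tx, oracle_nmd_features, oracle_prone, random_transcript


class TestFeatureExtraction:
    def test_single_exon_utr3_measured_from_stop(self):
        # spliced length 500, stop codon's 3'-most base at offset 399
        t = build_tx([500], cds=(100, 400))
        f = extract_nmd_features(t)
        assert f.evaluable
        assert f.utr3_length == 100
        assert f.utr3_intron_count == 0
        assert f.max_junction_distance is None

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_junction_30nt_past_stop(self, strand):
        # stop at offset 399; first exon runs 30 nt past it, then a junction
        t = build_tx([430, 200], cds=(100, 400), strand=strand)
        f = extract_nmd_features(t)
        assert f.max_junction_distance == 30
        assert f.utr3_intron_count == 0  # upstream exon still carries CDS
        assert f.utr3_length == 230

    def test_noncoding_transcript_not_evaluable(self):
        t = build_tx([300, 300], biotype="lincRNA")
        f = extract_nmd_features(t)
        assert not f.evaluable
        assert (f.utr3_length, f.utr3_intron_count, f.max_junction_distance) == (0, 0, None)

    def test_intron_between_pure_utr_exons_counted(self):
        # stop exon ends at the stop; two further UTR exons -> one 3'UTR intron
        # at distance 40, none of the junctions beyond 50 nt
        t = build_tx([400, 40, 300], cds=(100, 400))
        f = extract_nmd_features(t)
        assert f.utr3_intron_count == 1
        assert f.max_junction_distance == 40

    def test_junction_at_stop_boundary_not_downstream(self):
        # exon ends exactly at the stop codon's last base: distance 0 junction
        # is neither a 3'UTR intron nor a downstream junction
        t = build_tx([400, 300], cds=(100, 400))
        f = extract_nmd_features(t)
        assert f.utr3_intron_count == 0
        assert f.max_junction_distance is None

    def test_explicit_stop_codon_features_take_precedence(self):
        with_stop = build_tx([500], cds=(100, 397), stop_codon=(397, 400))
        inferred = build_tx([500], cds=(100, 400))
        assert extract_nmd_features(with_stop) == extract_nmd_features(inferred)

    def test_stop_codon_split_across_junction(self):
        # stop codon spans the exon boundary at offset 399/400
        t = build_tx([401, 300], cds=(100, 399), stop_codon=(399, 402))
        f = extract_nmd_features(t)
        assert f.utr3_length == 701 - 402
        assert stop_codon_spliced_offset(t) == 401

    def test_cds_excluding_stop_dialect(self):
        # Ensembl-style: CDS ends 3 bases before the true stop
        excl = build_tx([500], cds=(100, 397))
        f = extract_nmd_features(excl, cds_includes_stop=False)
        assert f.utr3_length == 100  # stop inferred at offset 399


class TestClassifier:
    def _features(self, utr3=0, introns=0, dist=None):
        return NMDFeatureSet("T", True, utr3, introns, dist)

    def test_long_utr3_threshold_is_inclusive(self):
        assert classify_nmd(self._features(utr3=1250)).triggered_rules == {RULE_LONG_UTR3}
        assert not classify_nmd(self._features(utr3=1249)).prone

    def test_junction_threshold_is_strict(self):
        assert not classify_nmd(self._features(utr3=60, dist=50)).prone
        call = classify_nmd(self._features(utr3=60, dist=51))
        assert call.triggered_rules == {RULE_DOWNSTREAM_JUNCTION}

    def test_any_utr3_intron_triggers(self):
        call = classify_nmd(self._features(utr3=60, introns=1, dist=40))
        assert call.triggered_rules == {RULE_UTR3_INTRON}

    def test_no_features_not_prone(self):
        call = classify_nmd(self._features())
        assert not call.prone and call.triggered_rules == frozenset()

    def test_prone_iff_rules_nonempty(self):
        for f in (
            self._features(),
            self._features(utr3=2000),
            self._features(introns=2, dist=10, utr3=100),
            NMDFeatureSet("T", False),
        ):
            call = classify_nmd(f)
            assert call.prone == bool(call.triggered_rules)

    def test_non_evaluable_never_prone(self):
        call = classify_nmd(NMDFeatureSet("T", False))
        assert not call.prone and not call.triggered_rules

    @pytest.mark.parametrize("kwargs", [{"utr3_min_bp": 0}, {"junction_min_nt": -1}])
    def test_nonpositive_thresholds_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            classify_nmd(self._features(), **kwargs)


class TestThresholdSharpness:
    @pytest.mark.parametrize(
        "utr3,expected", [(1249, False), (1250, True), (1251, True)]
    )
    def test_utr3_boundary(self, utr3, expected):
        t = build_tx([400 + utr3], cds=(100, 400))
        _, call = classify_transcript(t)
        assert call.prone is expected
        if expected:
            assert call.triggered_rules == {RULE_LONG_UTR3}

    @pytest.mark.parametrize(
        "dist,expected", [(49, False), (50, False), (51, True)]
    )
    def test_junction_distance_boundary(self, dist, expected):
        # stop-containing exon extends `dist` bases past the stop; the
        # 3'UTR stays short so only the junction rule can fire
        t = build_tx([400 + dist, 200], cds=(100, 400))
        f, call = classify_transcript(t)
        assert f.max_junction_distance == dist
        assert call.prone is expected
        if expected:
            assert call.triggered_rules == {RULE_DOWNSTREAM_JUNCTION}


class TestOracleEquivalence:
    def test_classifier_matches_brute_force_on_random_transcripts(self):
        """100% agreement with the per-spliced-base oracle on 250 random
        transcripts, under both stop-codon dialects."""
        rng = np.random.default_rng(777)
        for i in range(250):
            coding = i % 5 != 0
            dialect = (i % 2) == 0
            t = random_transcript(rng, coding=coding)
            f, call = classify_transcript(t, cds_includes_stop=dialect)
            o = oracle_nmd_features(t, cds_includes_stop=dialect)
            assert f.evaluable == o["evaluable"]
            if f.evaluable:
                assert f.utr3_length == o["utr3"]
                assert f.utr3_intron_count == o["n_utr3_introns"]
                assert f.max_junction_distance == o["max_dist"]
            assert call.prone == oracle_prone(t, cds_includes_stop=dialect)


class TestMonotonicity:
    def test_extending_last_exon_never_decreases_utr3(self, rng):
        for _ in range(30):
            t = random_transcript(rng)
            if not t.cds:
                continue
            base = extract_nmd_features(t).utr3_length
            exon_lens = [e.end - e.start for e in t.exons_in_transcript_order()]
            exon_lens[-1] += 200
            cds_offsets = [
                t.spliced_offset(p) for iv in t.cds for p in (iv.start, iv.end - 1)
            ]
            grown = build_tx(
                exon_lens,
                cds=(min(cds_offsets), max(cds_offsets) + 1),
                strand=t.strand,
            )
            assert extract_nmd_features(grown).utr3_length == base + 200

    def test_adding_utr3_intron_never_unproned(self):
        # a prone-by-intron transcript stays prone when another pure-UTR
        # exon split is introduced
        t = build_tx([400, 40, 300], cds=(100, 400))
        assert classify_transcript(t)[1].prone
        t2 = build_tx([400, 40, 100, 200], cds=(100, 400))
        assert classify_transcript(t2)[1].prone


class TestGeneAggregation:
    def _call(self, tid, prone):
        return classify_nmd(
            NMDFeatureSet(tid, True, utr3_length=2000 if prone else 10)
        )

    def test_any_transcript_or_semantics(self):
        calls = [self._call("t1", True), self._call("t2", False)]
        genes = gene_level_nmd(calls, {"t1": "g", "t2": "g"})
        assert genes["g"].prone and genes["g"].n_prone == 1 and genes["g"].n_transcripts == 2

    def test_all_policy_requires_every_transcript(self):
        calls = [self._call("t1", True), self._call("t2", False)]
        genes = gene_level_nmd(calls, {"t1": "g", "t2": "g"}, policy="all")
        assert not genes["g"].prone

    def test_gene_of_only_non_evaluable_transcripts_not_prone(self):
        calls = [classify_nmd(NMDFeatureSet("t1", False))]
        genes = gene_level_nmd(calls, {"t1": "g"})
        assert not genes["g"].prone

    def test_missing_mapping_raises(self):
        with pytest.raises(ConfigurationError, match="no gene mapping"):
            gene_level_nmd([self._call("t1", True)], {})

    def test_unknown_policy_rejected(self):
        with pytest.raises(ConfigurationError):
            gene_level_nmd([], {}, policy="principal")

    def test_planted_genes_recovered(self):
        from nmdscope.annotation import parse_gtf
        from nmdscope.simulate import generate_annotation

        gtf, truth = generate_annotation(
            n_genes=10, transcripts_per_gene=2, prone_fraction=0.4, seed=4
        )
        models = parse_gtf(gtf)
        calls = [classify_transcript(t)[1] for t in models]
        genes = gene_level_nmd(calls, {t.transcript_id: t.gene_id for t in models})
        assert {g: v.prone for g, v in genes.items()} == truth.gene_prone
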