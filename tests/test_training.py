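"""Annotation labelling, supervised estimation, and model assembly."""

import numpy as np
import pytest

from epigene.binarize import ClassMatrix
from epigene.grid import BinGrid
from epigene.io import Transcript
from epigene.topology import BODY_ROLES, build_topology
from epigene.training import (
    TrainingError,
    assemble_model,
    component_coverage,
    estimate_tu_emissions,
    estimate_tu_transitions,
    filter_polII_transcripts,
    label_annotation_bins,
    train_model,
)

GRID = BinGrid([("chr1", 20_000)], bin_width=200)


def _labels(*transcripts):
    return label_annotation_bins(list(transcripts), GRID)


class TestTopology:
    def test_seventeen_states(self):
        topo = build_topology()
        assert topo.k == 17
        roles = [m.role for m in topo.states]
        assert roles.count("background") == 3
        assert roles.count("TSS") == roles.count("TTS") == 1
        for r in BODY_ROLES:
            assert roles.count(r) == 2  # one per strand

    def test_no_forward_reverse_body_edges(self):
        topo = build_topology()
        fwd = [i for i, m in enumerate(topo.states) if m.strand == "+"]
        rev = [i for i, m in enumerate(topo.states) if m.strand == "-"]
        assert not topo.allowed[np.ix_(fwd, rev)].any()
        assert not topo.allowed[np.ix_(rev, fwd)].any()

    def test_background_connects_only_via_tss_tts(self):
        topo = build_topology()
        bg = [i for i, m in enumerate(topo.states) if m.role == "background"]
        boundary = [topo.index["TSS"], topo.index["TTS"]]
        body = [i for i in range(topo.k) if i not in bg and i not in boundary]
        assert not topo.allowed[np.ix_(bg, body)].any()
        assert not topo.allowed[np.ix_(body, bg)].any()

    def test_edges_touching_tss_tts_are_free(self):
        topo = build_topology()
        for b in (topo.index["TSS"], topo.index["TTS"]):
            assert topo.free_transition[b, topo.allowed[b]].all()
            assert topo.free_transition[topo.allowed[:, b], b].all()

    def test_supervised_edges_are_body_internal(self):
        topo = build_topology()
        for i, j in zip(*np.where(topo.supervised)):
            assert topo.states[i].role in BODY_ROLES
            assert topo.states[j].role in BODY_ROLES
            assert topo.states[i].strand == topo.states[j].strand


class TestLabelAnnotationBins:
    def test_forward_single_exon_layout(self):
        """[100, 1100) on a 200-bp grid spans bins 0–5: TSS at bin 0, TTS at
        the bin containing bp 1099 (bin 5), exon1 between."""
        t = Transcript("t", "chr1", 100, 1100, "+", [(100, 1100)])
        (lab,) = _labels(t)
        assert lab.bins.tolist() == [0, 1, 2, 3, 4, 5]
        assert lab.roles == ["TSS", "exon1", "exon1", "exon1", "exon1", "TTS"]

    def test_reverse_strand_tss_is_rightmost(self):
        t = Transcript("t", "chr1", 100, 1100, "-", [(100, 1100)])
        (lab,) = _labels(t)
        assert lab.roles[0] == "TTS" and lab.roles[-1] == "TSS"
        bins, roles = lab.oriented()
        assert roles[0] == "TSS" and bins[0] == 5

    def test_two_exon_transcript_has_no_internal_states(self):
        t = Transcript("t", "chr1", 0, 1800, "+", [(0, 600), (1200, 1800)])
        (lab,) = _labels(t)
        assert lab.roles == [
            "TSS", "exon1", "exon1", "intron1", "intron1", "intron1",
            "exonL", "exonL", "TTS",
        ]

    def test_reverse_two_exon_roles_in_transcript_orientation(self):
        t = Transcript("t", "chr1", 0, 1800, "-", [(0, 600), (1200, 1800)])
        (lab,) = _labels(t)
        _, roles = lab.oriented()
        assert roles[0] == "TSS" and roles[-1] == "TTS"
        assert roles[1] == "exon1" and roles[-2] == "exonL"

    def test_short_transcript_skipped_with_warning(self):
        t = Transcript("tiny", "chr1", 0, 400, "+", [(0, 400)])
        with pytest.warns(UserWarning, match="skipped"):
            labs = _labels(t)
        assert labs == []

    def test_majority_overlap_assigns_bin_role(self):
        # bin 3 = [600, 800): 150 bp exon1 vs 50 bp intron1 -> exon1
        t = Transcript("t", "chr1", 0, 2000, "+", [(0, 750), (1350, 2000)])
        (lab,) = _labels(t)
        assert lab.roles[3] == "exon1"
        assert lab.roles[4] == "intron1"

    def test_coverage_sums_to_transcript_length(self):
        t = Transcript("t", "chr1", 100, 1900, "+", [(100, 700), (1300, 1900)])
        cov = component_coverage([t], GRID)
        assert cov["bp"].sum() == len(t.as_interval())


class TestEstimateTuTransitions:
    def test_counting_oracle_three_bin_exon1(self):
        """exon1 occupies 3 bins before intron1: P(exon1→exon1) = 2/3 and
        P(exon1→intron1) = 1/3 by direct pair counting."""
        t = Transcript("t", "chr1", 0, 2000, "+", [(0, 800), (1400, 2000)])
        probs = estimate_tu_transitions(_labels(t))
        assert probs[("exon1+", "exon1+")] == pytest.approx(2 / 3)
        assert probs[("exon1+", "intron1+")] == pytest.approx(1 / 3)

    def test_single_exon_transcripts_have_no_intron_transition(self):
        t = Transcript("t", "chr1", 0, 1200, "+", [(0, 1200)])
        with pytest.warns(UserWarning, match="never observed"):
            probs = estimate_tu_transitions(_labels(t))
        assert ("exon1+", "intron1+") not in probs
        assert probs[("exon1+", "exon1+")] + probs[("exon1+", "TTS")] == pytest.approx(1.0)

    def test_reverse_entries_are_strand_mirrored_counts(self):
        """Forward sequence TSS,e1,e1,i1,eL,TTS reversed gives the reverse
        chain TTS→exonL→intron1→exon1→exon1→TSS with hand-computable rows."""
        t = Transcript("t", "chr1", 0, 1200, "+", [(0, 600), (800, 1200)])
        (lab,) = _labels(t)
        assert lab.roles == ["TSS", "exon1", "exon1", "intron1", "exonL", "TTS"]
        with pytest.warns(UserWarning):
            probs = estimate_tu_transitions(_labels(t))
        assert probs[("TTS", "exonL-")] == 1.0
        assert probs[("exonL-", "intron1-")] == 1.0
        assert probs[("intron1-", "exon1-")] == 1.0
        assert probs[("exon1-", "exon1-")] == pytest.approx(0.5)
        assert probs[("exon1-", "TSS")] == pytest.approx(0.5)

    def test_no_supervised_mass_on_forbidden_edges(self):
        """Random annotations with sub-bin components yield off-grammar
        label adjacencies; those are dropped, so every supervised entry lies
        inside the allowed edge set."""
        topo = build_topology()
        rng = np.random.default_rng(5)
        transcripts = []
        pos = 0
        for i in range(12):
            n_ex = int(rng.integers(1, 5))
            exons, p = [], pos
            for e in range(n_ex):
                ex_len = int(rng.integers(1, 4)) * 200
                exons.append((p, p + ex_len))
                p += ex_len + (int(rng.integers(1, 4)) * 200 if e < n_ex - 1 else 0)
            strand = "+" if rng.random() < 0.5 else "-"
            transcripts.append(Transcript(f"t{i}", "chr1", pos, exons[-1][1], strand, exons))
            pos = exons[-1][1] + 400
        grid = BinGrid([("chr1", pos + 400)], 200)
        labels = label_annotation_bins(transcripts, grid)
        probs = estimate_tu_transitions(labels, topo)  # raises on violation
        for (src, dst), v in probs.items():
            assert topo.allowed[topo.index[src], topo.index[dst]]
            assert 0 <= v <= 1


class TestFilterPolII:
    def _labels_at(self, starts):
        ts = [
            Transcript(f"t{i}", "chr1", s, s + 1200, "+", [(s, s + 1200)])
            for i, s in enumerate(starts)
        ]
        return _labels(*ts)

    def test_separable_features_keep_high_cluster(self):
        labels = self._labels_at([0, 2000, 4000, 6000, 8000])
        polii = np.zeros(GRID.n_bins)
        for lab in labels[:3]:  # enriched at TSS/TTS of first three
            polii[[lab.bins[0], lab.bins[-1]]] = 1
        kept, mask = filter_polII_transcripts(labels, polii)
        assert mask.tolist() == [True, True, True, False, False]
        assert [l.transcript_id for l in kept] == ["t0", "t1", "t2"]

    def test_degenerate_identical_features_retain_all(self):
        labels = self._labels_at([0, 2000])
        polii = np.ones(GRID.n_bins)
        with pytest.warns(UserWarning, match="identical"):
            kept, mask = filter_polII_transcripts(labels, polii)
        assert mask.all()

    def test_two_antibody_separable(self):
        labels = self._labels_at([0, 2000])
        ab1 = np.zeros(GRID.n_bins)
        ab2 = np.zeros(GRID.n_bins)
        ab1[[labels[0].bins[0], labels[0].bins[-1]]] = 1
        ab2[[labels[0].bins[0], labels[0].bins[-1]]] = 1
        kept, mask = filter_polII_transcripts(labels, {"ab1": ab1, "ab2": ab2})
        assert mask.tolist() == [True, False]

    def test_requires_two_transcripts_and_one_vector(self):
        labels = self._labels_at([0])
        with pytest.raises(TrainingError):
            filter_polII_transcripts(labels, np.zeros(GRID.n_bins))
        with pytest.raises(TrainingError):
            filter_polII_transcripts(self._labels_at([0, 2000]), {})


class TestEstimateTuEmissions:
    def test_counting_rule(self):
        t = Transcript("t", "chr1", 0, 1200, "+", [(0, 1200)])
        labels = _labels(t)
        # exon1 bins are 1..4; give mark 0 the pattern (1,1,0,1) there
        values = np.zeros((GRID.n_bins, 2), dtype=np.uint8)
        values[[1, 2, 4], 0] = 1
        cm = ClassMatrix(GRID, ["m1", "m2"], values)
        with pytest.warns(UserWarning, match="fallback"):
            emis = estimate_tu_emissions(labels, cm)
        assert emis["exon1"][0] == pytest.approx(0.75)
        assert emis["exon1"][1] == pytest.approx(1e-6)  # all-zero, clipped
        assert np.allclose(emis["exonI"], 0.5)  # unobserved role fallback

    def test_all_ones_clipped_below_one(self):
        t = Transcript("t", "chr1", 0, 1200, "+", [(0, 1200)])
        values = np.ones((GRID.n_bins, 1), dtype=np.uint8)
        cm = ClassMatrix(GRID, ["m"], values)
        with pytest.warns(UserWarning):
            emis = estimate_tu_emissions(_labels(t), cm)
        assert emis["exon1"][0] == pytest.approx(1 - 1e-6)

    def test_empty_filtered_set_rejected(self):
        cm = ClassMatrix(GRID, ["m"], np.zeros((GRID.n_bins, 1), dtype=np.uint8))
        with pytest.raises(TrainingError):
            estimate_tu_emissions([], cm)


class TestAssembleAndTrain:
    def _small_training_setup(self, seed=0):
        from epigene.pipeline import binarize_dataset
        from epigene.simulate import SimulationConfig, simulate_dataset

        config = SimulationConfig(
            seed=seed, contig_sizes={"chrT": 400_000}, n_tus=10, mean_gap_bins=40.0
        )
        ds = simulate_dataset(config)
        cm, polii = binarize_dataset(ds)
        return ds, cm, polii

    def test_assembled_model_invariants(self):
        ds, cm, polii = self._small_training_setup()
        from epigene.training import (
            estimate_tu_emissions,
            estimate_tu_transitions,
            filter_polII_transcripts,
            label_annotation_bins,
        )

        topo = build_topology()
        labels = label_annotation_bins(ds.transcripts, ds.grid)
        trans = estimate_tu_transitions(labels, topo)
        filtered, _ = filter_polII_transcripts(labels, polii)
        emis = estimate_tu_emissions(filtered, cm)
        params = assemble_model(topo, trans, emis, cm)
        assert params.k == 17
        np.testing.assert_allclose(params.transition.sum(axis=1), 1.0, atol=1e-9)
        assert (params.transition[params.structural_zero] == 0).all()
        assert params.initial.sum() == pytest.approx(1.0)

    def test_clamped_rows_identical_after_training(self):
        ds, cm, polii = self._small_training_setup(seed=1)
        model, info = train_model(
            ds.transcripts, cm, polii, grid=ds.grid, max_iter=15, tol=0.0
        )
        topo = build_topology()
        labels = label_annotation_bins(ds.transcripts, ds.grid)
        trans = estimate_tu_transitions(labels, topo)
        filtered, _ = filter_polII_transcripts(labels, polii)
        emis = estimate_tu_emissions(filtered, cm)
        pre = assemble_model(topo, trans, emis, cm)
        clamped_t = ~model.free_transition
        np.testing.assert_array_equal(
            model.transition[clamped_t], pre.transition[clamped_t]
        )
        clamped_e = ~model.free_emission
        np.testing.assert_array_equal(model.emission[clamped_e], pre.emission[clamped_e])
        assert (np.diff(info["loglik_trace"]) >= -1e-8).all()

    def test_mark_order_mismatch_rejected(self):
        ds, cm, polii = self._small_training_setup(seed=2)
        model, _ = train_model(ds.transcripts, cm, polii, grid=ds.grid, max_iter=2)
        from epigene.calling import decode_genome
        from epigene.hmm import HMMError

        shuffled = ClassMatrix(cm.grid, list(reversed(cm.marks)), cm.values[:, ::-1])
        with pytest.raises(HMMError, match="mark order"):
            decode_genome(model, shuffled)
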