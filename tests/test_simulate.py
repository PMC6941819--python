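import numpy as np
import pysam
import pytest

from endofilter.evidence import collect_evidence, positional_bias, soft_clip_ratio
from endofilter.io import ReadAlignment, fetch_reads_at, fetch_reference_window
from endofilter.palindrome import scp_length, scp_spectrum
from endofilter.simulate import (
    SimulationConfig,
    default_signature_matrix,
    simulate_cohort,
    simulate_reference,
    simulate_spectra,
)

SMALL = dict(ref_len=60_000, n_palindromes=40, n_samples=2, n_artifact=15, n_genuine=8, depth=40)


def read_tuples(bam_path):
    with pysam.AlignmentFile(str(bam_path), "rb") as bam:
        return [
            (r.query_name, r.reference_start, r.cigarstring, r.query_sequence)
            for r in bam.fetch(until_eof=True)
        ]


class TestReference:
    def test_registry_entries_verify_as_palindromes(self, small_cohort):
        for row in small_cohort.registry.itertuples():
            w = fetch_reference_window(
                small_cohort.fasta, small_cohort.config.chrom, row.center0 + 1, 20
            )
            assert scp_length(w).arm_len >= row.arm

    def test_fixed_seed_reproduces_fasta_bytes(self, tmp_path):
        cfg = SimulationConfig(seed=3, **SMALL)
        f1, _ = simulate_reference(cfg, tmp_path / "a")
        f2, _ = simulate_reference(cfg, tmp_path / "b")
        assert f1.read_bytes() == f2.read_bytes()

    def test_no_palindromes_gives_flat_scp_spectrum(self, tmp_path):
        cfg = SimulationConfig(seed=5, ref_len=60_000, n_palindromes=0, n_artifact=0,
                               n_genuine=30, n_samples=1, depth=10)
        cohort = simulate_cohort(cfg, tmp_path)
        spec = scp_spectrum(cohort.call_tables[0], cohort.fasta)
        assert spec.get(0, 0) / sum(spec.values()) > 0.8

    def test_too_many_palindromes_rejected(self, tmp_path):
        cfg = SimulationConfig(seed=1, ref_len=3_000, n_palindromes=300, n_artifact=10)
        with pytest.raises(ValueError):
            simulate_reference(cfg, tmp_path)


class TestReads:
    def test_fixed_seed_reproduces_bam(self, tmp_path):
        cfg = SimulationConfig(seed=9, **SMALL)
        c1 = simulate_cohort(cfg, tmp_path / "a")
        c2 = simulate_cohort(cfg, tmp_path / "b")
        assert read_tuples(c1.bam_paths[0]) == read_tuples(c2.bam_paths[0])
        assert c1.truth.equals(c2.truth)

    def test_emitted_reads_satisfy_alignment_invariants(self, small_cohort):
        tuples = read_tuples(small_cohort.bam_paths[0])[:200]
        with pysam.AlignmentFile(str(small_cohort.bam_paths[0]), "rb") as bam:
            for rec in list(bam.fetch(until_eof=True))[:200]:
                ReadAlignment.from_pysam(rec)  # constructor validates

    def test_artifact_offsets_fold_into_edge_window(self, small_cohort):
        cfg = small_cohort.config
        truth = small_cohort.truth
        artifacts = truth[(truth.label == "artifact") & (truth.sample_id == "S1")].head(5)
        lo, hi = cfg.artifact_edge_window
        for t in artifacts.itertuples():
            calls = [c for c in small_cohort.call_tables[0] if c.pos == t.pos]
            reads = fetch_reads_at(small_cohort.bam_paths[0], t.chrom, t.pos)
            ev = collect_evidence(reads, calls[0])
            folded = [min(o, L - 1 - o) for o, L in zip(ev.alt_offsets, ev.alt_read_lens)]
            assert all(lo <= d <= hi for d in folded)
            assert positional_bias(ev).ks_p < 0.05

    def test_artifact_softclip_ratio_matches_binomial(self, small_cohort):
        truth = small_cohort.truth
        artifacts = truth[(truth.label == "artifact") & (truth.sample_id == "S1")]
        p = small_cohort.config.artifact_softclip_prob
        clipped = total = 0
        for t in artifacts.itertuples():
            calls = [c for c in small_cohort.call_tables[0] if c.pos == t.pos]
            reads = fetch_reads_at(small_cohort.bam_paths[0], t.chrom, t.pos)
            ev = collect_evidence(reads, calls[0])
            clipped += ev.n_alt_softclipped
            total += ev.n_alt
        se = np.sqrt(p * (1 - p) / total)
        assert abs(clipped / total - p) < 4 * se

    def test_truth_labels_cover_all_calls(self, small_cohort):
        n_calls = sum(len(t) for t in small_cohort.call_tables)
        assert len(small_cohort.truth) == n_calls
        assert set(small_cohort.truth.label) <= {"artifact", "genuine"}

    def test_artifact_sites_recur_across_samples(self, small_cohort):
        truth = small_cohort.truth
        art = truth[truth.label == "artifact"]
        per_site = art.groupby("pos").sample_id.nunique()
        assert (per_site >= 2).mean() > 0.5  # most artifact sites shared
        gen = truth[truth.label == "genuine"]
        assert (gen.groupby("pos").sample_id.nunique() == 1).all()

    def test_zero_depth_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(depth=0)


class TestSpectra:
    matrix = default_signature_matrix()

    def test_counts_sum_to_n(self):
        counts = simulate_spectra(self.matrix, [1.0, 0.0, 0.0], 500, 1)
        assert counts.sum() == 500

    def test_pure_signature_proportional_to_profile(self):
        counts = simulate_spectra(self.matrix, [1.0, 0.0, 0.0], 50_000, 2)
        f = counts / counts.sum()
        assert np.abs(f - self.matrix.profiles[:, 0]).max() < 0.01

    def test_off_simplex_weights_rejected(self):
        with pytest.raises(ValueError):
            simulate_spectra(self.matrix, [0.5, 0.2, 0.2], 100, 3)
        with pytest.raises(ValueError):
            simulate_spectra(self.matrix, [-0.1, 0.6, 0.5], 100, 3)
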