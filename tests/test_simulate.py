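"""Synthetic read generator: determinism, reference structure, and
Monte-Carlo recovery of the configured error model."""

import numpy as np
import pytest

from amperr.io import write_fastq
from amperr.model import ReferenceAmplicon, TruthSet
from amperr.quality import scan_homopolymers
from amperr.simulate import (
    AmpliconSpec,
    SimulationConfig,
    SimulatedReferences,
    apply_miscalibration,
    generate_references,
    simulate_run,
    simulate_study,
)
from _oracles import per_base_run_lengths


def _cfg(**kw):
    base = dict(n_runs=1, reads_per_amplicon=50, seed=123)
    base.update(kw)
    return SimulationConfig(**base)


class TestGenerateReferences:
    def test_amplicon_count_matches_spec(self):
        cfg = _cfg(amplicon_specs=(AmpliconSpec("A", 120), AmpliconSpec("B", 140)))
        refs = generate_references(cfg)
        assert len(refs.amplicons) == 2

    def test_zero_weight_forbids_long_runs(self):
        cfg = _cfg(amplicon_specs=(AmpliconSpec("A", 300, (20, 20), 0.0),))
        refs = generate_references(cfg)
        assert per_base_run_lengths(refs.amplicons[0].exon_sequence).max() <= 3

    def test_positive_weight_guarantees_a_long_run(self):
        cfg = _cfg(amplicon_specs=(AmpliconSpec("A", 80, (20, 20), 0.5),))
        refs = generate_references(cfg)
        assert per_base_run_lengths(refs.amplicons[0].exon_sequence).max() >= 4

    def test_same_seed_reproduces_sequences(self):
        cfg = _cfg()
        a = generate_references(cfg)
        b = generate_references(cfg)
        assert [x.sequence for x in a.amplicons] == [x.sequence for x in b.amplicons]
        assert a.alleles == b.alleles

    def test_alleles_differ_only_at_expected_variant_positions(self):
        refs = generate_references(_cfg(true_variant_count=3))
        for amp in refs.amplicons:
            ref, allele = amp.sequence, refs.alleles[amp.amplicon_id]
            diffs = [i for i, (x, y) in enumerate(zip(ref, allele)) if x != y]
            expected = sorted(
                pos for a, pos, kind, alt in refs.truth_set.expected if a == amp.amplicon_id
            )
            assert diffs == expected

    def test_pseudogene_differs_at_enough_positions(self):
        refs = generate_references(_cfg(pseudogene_fraction=0.25, n_pseudogene_diffs=4))
        assert refs.pseudogenes, "designated locus must get a pseudogene"
        for amp_id, pg in refs.pseudogenes.items():
            ref = next(a.sequence for a in refs.amplicons if a.amplicon_id == amp_id)
            assert sum(x != y for x, y in zip(ref, pg)) >= 3

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            generate_references(_cfg(amplicon_specs=(AmpliconSpec("A", 10),)))
        with pytest.raises(ValueError):
            generate_references(
                _cfg(amplicon_specs=(AmpliconSpec("A", 120, (20, 20), -1.0),))
            )


class TestSimulateRunBasics:
    def test_zero_rates_give_error_free_truth(self):
        cfg = _cfg(substitution_rate=0.0, indel_base_rate=0.0)
        refs = generate_references(cfg)
        reads, records = simulate_run(refs, cfg, 0)
        assert all(not r.events for r in records)

    def test_read_count_is_exact(self):
        cfg = _cfg(reads_per_amplicon=17)
        refs = generate_references(cfg)
        reads, _ = simulate_run(refs, cfg, 0)
        assert len(reads) == 17 * len(cfg.amplicon_specs)

    def test_fixed_seed_reproduces_fastq_byte_identically(self, tmp_path):
        cfg = _cfg(reads_per_amplicon=20)
        paths = []
        for tag in ("a", "b"):
            refs = generate_references(cfg)
            reads, _ = simulate_run(refs, cfg, 0)
            p = tmp_path / f"{tag}.fastq"
            write_fastq(reads, str(p))
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_base_conservation(self):
        cfg = _cfg(reads_per_amplicon=30)
        study = simulate_study(cfg)
        for run_id, reads in study.reads_by_run.items():
            assert sum(len(r.sequence) for r in reads) == sum(
                len(r.quals) for r in reads
            )

    def test_events_lie_within_amplicon_and_list_empty_iff_error_free(self):
        cfg = _cfg(reads_per_amplicon=200, seed=5)
        study = simulate_study(cfg)
        amp_len = {a.amplicon_id: len(a.sequence) for a in study.references.amplicons}
        sources = {}
        refs = study.references
        for rec, read in zip(study.all_truth, study.all_reads):
            for ev in rec.events:
                assert 0 <= ev.ref_pos < amp_len[rec.amplicon_id]
            src = (
                refs.pseudogenes[rec.amplicon_id]
                if rec.source == "pseudogene"
                else refs.alleles[rec.amplicon_id]
            )
            from amperr.model import revcomp

            expected = src if rec.strand == "+" else revcomp(src)
            assert (read.sequence == expected) == (len(rec.events) == 0)

    def test_pseudogene_fraction_respected(self):
        cfg = _cfg(reads_per_amplicon=2000, pseudogene_fraction=0.25, seed=2)
        refs = generate_references(cfg)
        _, records = simulate_run(refs, cfg, 0)
        pg_amp = next(iter(refs.pseudogenes))
        recs = [r for r in records if r.amplicon_id == pg_amp]
        frac = sum(r.source == "pseudogene" for r in recs) / len(recs)
        sd = np.sqrt(0.25 * 0.75 / len(recs))
        assert abs(frac - 0.25) < 3 * sd
        other = [r for r in records if r.amplicon_id != pg_amp]
        assert all(r.source == "allele" for r in other)

    def test_zero_pseudogene_fraction_means_no_pseudogene_reads(self):
        cfg = _cfg(pseudogene_fraction=0.0)
        refs = generate_references(cfg)
        assert not refs.pseudogenes
        _, records = simulate_run(refs, cfg, 0)
        assert all(r.source == "allele" for r in records)


def _flat_quality_cfg(**kw):
    """Config with a flat positional profile (no modulation) for clean
    Monte-Carlo rate checks."""
    base = dict(
        n_runs=1,
        reads_per_amplicon=100,
        true_variant_count=0,
        pseudogene_fraction=0.0,
        quality_profile=(30.0, 30.0, 10_000.0, 30.0),
        error_site_q_penalty=0,
        miscalibration={"kind": "identity"},
        seed=99,
    )
    base.update(kw)
    return SimulationConfig(**base)


def _manual_refs(exon: str, cfg: SimulationConfig) -> SimulatedReferences:
    """References with a hand-written exon (no flanks beyond primers)."""
    pf = "ACGTACGTACGTACGTACGT"
    pr = "TGCATGCATGCATGCATGCA"
    from amperr.model import revcomp

    seq = pf + exon + revcomp(pr)
    amp = ReferenceAmplicon("amp", "L", seq, (len(pf), len(pf) + len(exon)), pf, pr)
    return SimulatedReferences(
        amplicons=[amp],
        alleles={"amp": seq},
        pseudogenes={},
        truth_set=TruthSet(amplicons={"amp"}),
        diff_positions={"amp": []},
    )


class TestErrorModelMonteCarlo:
    def test_homopolymer_indel_rate_scales_with_run_length(self):
        # isolated 4-mers: per-base indel probability 0.001 * 2^3 = 0.008
        exon = ("AAAA" + "GACTGTCAGTCG") * 16  # 16 isolated A(4) runs, 256 bp
        cfg = _flat_quality_cfg(
            substitution_rate=0.0,
            indel_base_rate=0.001,
            indel_length_slope=2.0,
            reads_per_amplicon=1800,
        )
        refs = _manual_refs(exon, cfg)
        _, records = simulate_run(refs, cfg, 0)
        a_starts = {
            r.start
            for r in scan_homopolymers(refs.amplicons[0].sequence)
            if r.length == 4 and r.base == "A"
        }
        indel_bases = sum(
            ev.length
            for rec in records
            for ev in rec.events
            if ev.kind in ("ins", "del") and ev.ref_pos in a_starts
        )
        traversals = len(records) * len(a_starts) * 4  # >= 10^5 homopolymer bases
        assert traversals >= 100_000
        p = 0.008
        sd = np.sqrt(p * (1 - p) / traversals)
        assert abs(indel_bases / traversals - p) < 3 * sd

    def test_substitution_rate_recovered_over_a_million_bases(self):
        cfg = _flat_quality_cfg(
            substitution_rate=0.002,
            indel_base_rate=0.0,
            reads_per_amplicon=1200,
        )
        refs = generate_references(cfg)
        _, records = simulate_run(refs, cfg, 0)
        insert_bases = sum(
            len(a.sequence) - len(a.primer_fwd) - len(a.primer_rev)
            for a in refs.amplicons
        ) * cfg.reads_per_amplicon
        assert insert_bases >= 1_000_000
        sub_bases = sum(
            ev.length for rec in records for ev in rec.events if ev.kind == "sub"
        )
        p = cfg.substitution_rate
        sd = np.sqrt(p * (1 - p) / insert_bases)
        assert abs(sub_bases / insert_bases - p) < 3 * sd


class TestQualityModel:
    def test_error_sites_show_quality_valley(self):
        cfg = _flat_quality_cfg(
            substitution_rate=0.005, indel_base_rate=0.0, error_site_q_penalty=5,
            reads_per_amplicon=200,
        )
        refs = generate_references(cfg)
        reads, records = simulate_run(refs, cfg, 0)
        by_id = {r.read_id: r for r in reads}
        qs = [
            int(by_id[rec.read_id].quals[ev.read_pos - 1])
            for rec in records
            for ev in rec.events
            if ev.kind == "sub"
        ]
        assert qs, "expected some substitution errors"
        # flat profile at Q30 (p=0.002 -> true Q ~27) minus 5 at error sites
        baseline = int(np.rint(by_id[records[0].read_id].quals.max()))
        assert max(qs) <= baseline - 5

    def test_miscalibration_mappings(self):
        q = np.array([10.0, 29.0, 30.0, 31.0, 38.0])
        np.testing.assert_allclose(apply_miscalibration(q, {"kind": "identity"}), q)
        np.testing.assert_allclose(
            apply_miscalibration(q, {"kind": "offset", "delta": 3}), q + 3
        )
        gs = apply_miscalibration(
            q, {"kind": "gs_junior", "threshold": 30, "above": 3, "below": -2}
        )
        np.testing.assert_allclose(gs, [8.0, 27.0, 30.0, 34.0, 41.0])

    def test_reported_quality_clamped_to_0_40(self):
        cfg = _cfg(reads_per_amplicon=30)
        refs = generate_references(cfg)
        reads, _ = simulate_run(refs, cfg, 0)
        for r in reads:
            assert r.quals.min() >= 0 and r.quals.max() <= 40

    def test_unknown_miscalibration_rejected(self):
        with pytest.raises(ValueError):
            apply_miscalibration(np.array([30.0]), {"kind": "bogus"})


class TestConfigRoundTrip:
    def test_json_round_trip(self):
        cfg = SimulationConfig(seed=42)
        again = SimulationConfig.from_json(cfg.to_json())
        assert again == cfg

    def test_validation_errors(self):
        with pytest.raises(ValueError):
            SimulationConfig(substitution_rate=1.5).validate()
        with pytest.raises(ValueError):
            SimulationConfig(pseudogene_fraction=1.0).validate()
        with pytest.raises(ValueError):
            SimulationConfig(amplicon_specs=()).validate()
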