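"""Mutation placement round trips and experiment simulation."""

import numpy as np
import pytest

from sigdissect.channels import DBS78, ID83, SBS96
from sigdissect.classify import classify_record, merge_adjacent
from sigdissect.compare import cosine_similarity
from sigdissect.reference import ReferenceGenome, generate_reference
from sigdissect.simulate import (
    GroupSpec,
    MutationPlacer,
    SimulationConfig,
    TreatmentSpec,
    UnsatisfiableChannelError,
    demo_signatures,
    place_mutation,
    simulate_experiment,
    study_design,
)


@pytest.fixture()
def placer(rng):
    genome = generate_reference(100_000, 1, 0.41, seed=5)
    return MutationPlacer(genome, rng)


class TestPlacementRoundTrip:
    def test_sbs_direct_example(self, rng):
        genome = ReferenceGenome({"c": "GG" + "ACA" + "GG"})
        rec = place_mutation(genome, "A[C>A]A", SBS96, rng)
        assert classify_record(rec, genome).channel == "A[C>A]A"

    def test_all_sbs_channels(self, placer):
        for channel in SBS96.channels:
            rec = placer.place_sbs(channel, "c1")
            assert classify_record(rec, placer.genome).channel == channel

    def test_all_dbs_channels(self, placer):
        for channel in DBS78.channels:
            r1, r2 = placer.place_dbs(channel, "c1")
            (doublet,), _, _ = merge_adjacent([r1, r2])
            assert classify_record(doublet, placer.genome).channel == channel

    def test_all_id_channels(self, placer):
        for channel in ID83.channels:
            rec = placer.place_id(channel, "c1")
            assert classify_record(rec, placer.genome).channel == channel

    def test_deep_homopolymer_deletion(self, rng):
        genome = generate_reference(100_000, 1, 0.41, seed=8)
        rec = place_mutation(genome, "1:Del:T:5", ID83, rng)
        assert classify_record(rec, genome).channel == "1:Del:T:5"

    def test_unsatisfiable_on_degenerate_genome(self, rng):
        genome = ReferenceGenome({"c": "G" * 500})
        with pytest.raises(UnsatisfiableChannelError):
            place_mutation(genome, "A[C>A]A", SBS96, rng)

    def test_unknown_channel_rejected(self, rng):
        genome = generate_reference(1000, 1, 0.5, seed=1)
        with pytest.raises(KeyError):
            place_mutation(genome, "X[C>A]A", SBS96, rng)

    def test_no_collisions_within_clone(self, placer):
        positions = set()
        for channel in SBS96.channels * 3:
            rec = placer.place_sbs(channel, "c1")
            key = (rec.contig, rec.pos)
            assert key not in positions
            positions.add(key)


def tiny_config(**overrides):
    base = dict(
        groups=[
            GroupSpec("g1", [
                TreatmentSpec("drugA", sbs_burden=150, sbs_mixture={"mnng_like": 1.0}),
            ]),
        ],
        genome_length=200_000,
        n_contigs=1,
        clones_per_condition=3,
        background_sbs_burden=40,
        background_id_burden=5,
        n_parental_variants=5,
        seed=9,
    )
    base.update(overrides)
    return SimulationConfig(**base)


class TestSimulateExperiment:
    def test_degenerate_all_zero_burdens(self, tmp_path):
        cfg = tiny_config(
            groups=[GroupSpec("g1", [TreatmentSpec("inert")])],
            background_sbs_burden=0, background_id_burden=0,
        )
        _, vcfs, _, parental_vcf, truth = simulate_experiment(cfg, tmp_path)
        from sigdissect.variants import read_vcf

        parental = read_vcf(parental_vcf, "p")
        assert len(parental) == 5
        for clone, path in vcfs.items():
            recs = read_vcf(path, clone)
            assert sorted(r.key for r in recs) == sorted(r.key for r in parental)

    def test_single_channel_signature_round_trip(self, tmp_path):
        # all compound mutations must classify to the one channel of their
        # generating signature
        cfg = tiny_config()
        fasta, vcfs, _, _, truth = simulate_experiment(cfg, tmp_path)
        from sigdissect.reference import read_fasta
        from sigdissect.variants import read_vcf

        genome = read_fasta(fasta)
        mix = truth.signature("SBS96", "drugA")
        support = {SBS96.channels[i] for i in np.flatnonzero(mix)}
        clone = next(c for c in vcfs if "drugA" in c)
        src = truth.sources[clone]
        for rec in read_vcf(vcfs[clone], clone):
            if src[rec.key] == "compound":
                assert classify_record(rec, genome).channel in support

    def test_poisson_band_and_determinism(self, tmp_path):
        cfg = tiny_config(seed=31)
        _, _, _, _, truth_a = simulate_experiment(cfg, tmp_path / "a")
        _, _, _, _, truth_b = simulate_experiment(cfg, tmp_path / "b")
        # identical seed => byte-identical outputs
        for name in ("reference.fa", "manifest.tsv", "g1_drugA_c1.vcf"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()
        # realized counts within 4 SD of the Poisson mean
        drug = truth_a.clone_table.query("treatment == 'drugA'")
        for n in drug["compound_sbs"]:
            assert abs(n - 150) <= 4 * np.sqrt(150)
        for n in truth_a.clone_table["background_sbs"]:
            assert abs(n - 40) <= 4 * np.sqrt(40)

    def test_truth_labels_partition_records(self, tmp_path):
        cfg = tiny_config()
        _, vcfs, _, _, truth = simulate_experiment(cfg, tmp_path)
        from sigdissect.variants import read_vcf

        for clone, path in vcfs.items():
            recs = read_vcf(path, clone)
            labels = [truth.sources[clone][r.key] for r in recs]
            assert set(labels) <= {"parental", "background", "compound"}
            assert len(recs) == len(truth.sources[clone])

    def test_config_yaml_round_trip(self, tmp_path):
        cfg = study_design(genome_length=10_000)
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        back = SimulationConfig.from_yaml(path)
        assert back == cfg


class TestDemoSignatures:
    @pytest.mark.parametrize("kind,n", [("SBS96", 96), ("DBS78", 78), ("ID83", 83)])
    def test_valid_catalogs(self, kind, n):
        cat = demo_signatures(kind)
        assert cat.vectors.shape[0] == n
        assert np.allclose(cat.vectors.sum(axis=0), 1.0)

    def test_compound_profiles_are_distinct(self):
        cat = demo_signatures("SBS96")
        names = ["bap_like", "norharmane_like", "mnng_like", "nnk_acetate_like"]
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                sim = cosine_similarity(cat.vector(a), cat.vector(b))
                assert sim < 0.99
        # the two bulky-adduct profiles are similar by design, the others not
        assert cosine_similarity(cat.vector("bap_like"), cat.vector("norharmane_like")) > 0.8
        assert cosine_similarity(cat.vector("bap_like"), cat.vector("mnng_like")) < 0.5
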