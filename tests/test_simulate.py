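"""Ground-truth generator: pool structure, reference fractions, read synthesis."""

import gzip
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from coimeta.align import pairwise_identity
from coimeta.primers import DEFAULT_PRIMERS
from coimeta.reference import write_reference_fasta
from coimeta.simulate import (CommunityDesign, Effect, SiteSpec,
                              build_species_pool, generate_checklist,
                              generate_reference_db, null_design,
                              read_checklist, simulate_community_matrix,
                              synthesize_reads, write_checklist)


class TestSpeciesPool:
    def test_names_unique_and_barcodes_carry_both_amplicons(self, small_pool):
        names = [s.species_name for s in small_pool]
        assert len(set(names)) == len(names)
        for s in small_pool:
            assert 600 <= len(s.barcode_seq) <= 700
            assert len(s.insert("COI1")) == 313
            assert len(s.insert("COI2")) == 325

    def test_amplicons_are_primer_flanked(self, small_pool, primers):
        from coimeta.primers import mismatch_count, primer_bits, read_bits, \
            seq_to_bytes
        for s in small_pool[:4]:
            for mid, pdef in primers.items():
                amp = s.amplicon(mid)
                lf, lr = len(pdef.forward_seq), len(pdef.reverse_seq)
                fb = read_bits(seq_to_bytes(amp[:lf]))
                rb = read_bits(seq_to_bytes(amp[-lr:]))
                assert mismatch_count(primer_bits(pdef.forward_seq), fb) == 0
                assert mismatch_count(primer_bits(pdef.reverse_rc), rb) == 0

    def test_within_genus_identity_in_profiling_band(self, small_pool):
        by_genus = {}
        for s in small_pool:
            by_genus.setdefault(s.genus, []).append(s)
        for genus, members in by_genus.items():
            if genus == "Terragenus":
                continue
            for i, a in enumerate(members):
                for b in members[i + 1:]:
                    if b.sister_of == a.species_name:
                        continue
                    for mid in ("COI1", "COI2"):
                        ident = pairwise_identity(a.insert(mid), b.insert(mid))
                        assert 0.79 <= ident < 0.91

    def test_cross_genus_identity_below_threshold(self, small_pool):
        genera = {}
        for s in small_pool:
            genera.setdefault(s.genus, s)
        reps = list(genera.values())
        for i, a in enumerate(reps):
            for b in reps[i + 1:]:
                assert pairwise_identity(a.insert("COI1"), b.insert("COI1")) < 0.90

    def test_sister_pair_near_but_below_identity_one(self, small_pool):
        sisters = [s for s in small_pool if s.sister_of]
        assert len(sisters) == 1
        s = sisters[0]
        partner = next(p for p in small_pool if p.species_name == s.sister_of)
        ident = pairwise_identity(s.insert("COI1"), partner.insert("COI1"))
        assert 0.97 <= ident < 1.0

    def test_terrestrial_never_on_aquatic_checklists(self, small_pool):
        for s in small_pool:
            if s.habitat_class == "terrestrial":
                assert not s.on_native_checklist
                assert not s.on_invader_checklist

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError, match="no species"):
            build_species_pool(n_species=0)


class TestReferenceDb:
    def test_native_and_invader_fractions_track_requested_fraction(self):
        # survey-scale pool: 897 native + 130 potential invaders
        pool = build_species_pool(
            n_species=1027, genus_size=6, n_invaders=130, n_terrestrial=2,
            n_freshwater=10, n_brackish=10, enforce_identity_band=False,
            seed=3,
        )
        # make the native/invader split exact: invaders were drawn from
        # marine species only, everything else is native
        n_native = sum(s.on_native_checklist for s in pool)
        n_invader = sum(s.on_invader_checklist for s in pool)
        assert n_invader == 130
        records, pool = generate_reference_db(pool, 0.46, seed=5)
        named = [r for r in records if r.species_name]
        assert len(named) == round(0.46 * len(pool))
        by_name = {r.species_name for r in named}
        native_cov = sum(
            s.species_name in by_name for s in pool if s.on_native_checklist
        ) / n_native
        assert native_cov == pytest.approx(0.46, abs=0.01)

    def test_saturation_and_curation_fodder(self, small_pool):
        records, pool = generate_reference_db(small_pool, 1.0, seed=1)
        named = [r for r in records if r.species_name]
        assert len(named) == len(pool)
        assert any(r.species_name is None for r in records)
        assert any(r.habitat == "terrestrial" for r in named)

    def test_reference_fasta_deterministic(self, small_pool, tmp_path):
        paths = []
        for run in range(2):
            pool = build_species_pool(n_species=12, genus_size=4, seed=7)
            records, _ = generate_reference_db(pool, 0.5, seed=9)
            p = tmp_path / f"ref{run}.fasta"
            write_reference_fasta(records, p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_invalid_inputs(self, small_pool):
        with pytest.raises(ValueError, match="no species"):
            generate_reference_db([], 0.5)
        with pytest.raises(ValueError):
            generate_reference_db(small_pool, 1.5)


class TestChecklists:
    def test_roundtrip_and_sizes(self, small_pool, tmp_path):
        inv = generate_checklist(small_pool, "invader")
        assert len(inv) == sum(s.on_invader_checklist for s in small_pool)
        p = tmp_path / "inv.tsv"
        write_checklist(inv, p)
        back = read_checklist(p)
        assert set(back["species"]) == set(inv["species"])

    def test_empty_flag_set_gives_header_only(self, small_pool, tmp_path):
        pool = build_species_pool(n_species=6, genus_size=3, n_invaders=0, seed=2)
        inv = generate_checklist(pool, "invader")
        assert inv.empty and list(inv.columns) == ["species", "phylum", "list_kind"]

    def test_unknown_kind(self, small_pool):
        with pytest.raises(ValueError):
            generate_checklist(small_pool, "watchlist")


class TestCommunitySimulation:
    def test_counts_sum_to_reads_per_sample(self, small_pool):
        design = null_design(n_samples=4, reads_per_sample=500, seed=1)
        truth = simulate_community_matrix(design, small_pool)
        real = truth.counts[~truth.metadata["is_control"]]
        assert (real.sum(axis=1) == 500).all()

    def test_zero_reads_gives_zero_rows(self, small_pool):
        design = null_design(n_samples=3, reads_per_sample=0, seed=1)
        truth = simulate_community_matrix(design, small_pool)
        assert truth.counts.to_numpy().sum() == 0

    def test_planted_multiplier_raises_expected_share(self, small_pool):
        # empirical mean share over 200 draws vs the analytic 3x boost
        marine = sorted(s.species_name for s in small_pool
                        if s.habitat_class == "marine")
        boosted = tuple(marine[:3])
        ratios = []
        for i in range(200):
            sites = [SiteSpec("W", "water_column", depths=("surface",)),
                     SiteSpec("T", "tide_pool")]
            d = CommunityDesign(
                sites=sites, reads_per_sample=4000, error_rate=0.0,
                sample_sigma=0.0, n_controls=0, seed=i,
                effects=[Effect("habitat", "tide_pool", boosted, 3.0)],
            )
            t = simulate_community_matrix(d, small_pool)
            w = t.counts.loc["W-surface-summer", list(boosted)].sum()
            tp = t.counts.loc["T-NA-summer", list(boosted)].sum()
            other_w = t.counts.loc["W-surface-summer"].sum() - w
            other_tp = t.counts.loc["T-NA-summer"].sum() - tp
            ratios.append((tp / other_tp) / (w / other_w))
        assert np.mean(ratios) == pytest.approx(3.0, rel=0.1)

    def test_freshwater_species_only_in_river_influenced_surface(self, small_pool):
        fresh = [s.species_name for s in small_pool
                 if s.habitat_class == "freshwater"]
        sites = [SiteSpec("R", "water_column", river_influence=True),
                 SiteSpec("M", "water_column", river_influence=False),
                 SiteSpec("T", "tide_pool")]
        d = CommunityDesign(sites=sites, reads_per_sample=20_000,
                            sample_sigma=0.0, n_controls=0, seed=3)
        t = simulate_community_matrix(d, small_pool)
        f = t.counts[fresh]
        surface_river = t.metadata.eval(
            "depth == 'surface' and river_influence and ~is_control")
        assert (f[~surface_river.to_numpy()].to_numpy() == 0).all()
        assert f[surface_river.to_numpy()].to_numpy().sum() > 0

    def test_design_validation(self):
        with pytest.raises(ValueError):
            CommunityDesign(sites=[SiteSpec("A", "water_column")], error_rate=0.5)
        with pytest.raises(ValueError):
            Effect("habitat", "tide_pool", ("x",), 0.0)


class TestReadSynthesis:
    def test_zero_error_reads_match_template_and_conservation(self, small_pool):
        d = null_design(n_samples=2, reads_per_sample=200, seed=4)
        truth = simulate_community_matrix(d, small_pool)
        sim = synthesize_reads(truth, small_pool, seed=5, error_rate=0.0)
        by_name = {s.species_name: s for s in small_pool}
        pr = sim.truth.per_read
        # per-read truth sums match per-sample truth counts
        agg = pr.groupby(["sample", "species"]).size()
        for (sid, sp), n in agg.items():
            assert sim.truth.counts.loc[sid, sp] == n
        for sid, sr in sim.samples.items():
            sub = pr[pr["sample"] == sid].reset_index(drop=True)
            for i in range(min(5, sr.n_reads)):
                amp = by_name[sub.loc[i, "species"]].amplicon(sub.loc[i, "marker"])
                assert sr.fwd_seq[i].tobytes().decode() == amp[:250]

    def test_substitution_rate_matches_binomial_mean(self, small_pool):
        d = null_design(n_samples=2, reads_per_sample=6000, seed=6)
        d.error_rate = 0.005
        truth = simulate_community_matrix(d, small_pool)
        sim = synthesize_reads(truth, small_pool, seed=7)
        pr = sim.truth.per_read
        # per-amplicon mean scaled to the 313 nt insert
        amp_len = {m: len(small_pool[0].amplicon(m)) for m in ("COI1", "COI2")}
        per_insert = [
            n_err * 313 / amp_len[m]
            for m, n_err in zip(pr["marker"], pr["n_errors"])
        ]
        assert len(per_insert) >= 10_000
        assert np.mean(per_insert) == pytest.approx(313 * 0.005, rel=0.05)

    def test_negative_controls_nearly_empty(self, small_pool):
        sites = [SiteSpec("A", "water_column", depths=("surface",))]
        d = CommunityDesign(sites=sites, reads_per_sample=100, n_controls=3,
                            control_max_stray=5, seed=8)
        truth = simulate_community_matrix(d, small_pool)
        sim = synthesize_reads(truth, small_pool, seed=9)
        for cid in truth.metadata.index[truth.metadata["is_control"]]:
            assert sim.samples[cid].n_reads <= 5
            # strays are reflected in the completed truth counts
            assert sim.truth.counts.loc[cid].sum() == sim.samples[cid].n_reads

    def test_read_len_overlap_validation(self, small_pool):
        d = null_design(n_samples=2, reads_per_sample=10, seed=1)
        truth = simulate_community_matrix(d, small_pool)
        with pytest.raises(ValueError, match="overlap"):
            synthesize_reads(truth, small_pool, read_len=190)
        with pytest.raises(ValueError, match="exceeds"):
            synthesize_reads(truth, small_pool, read_len=400)

    def test_fastq_output_deterministic_and_parseable(self, small_pool, tmp_path):
        hashes = []
        for run in range(2):
            d = null_design(n_samples=2, reads_per_sample=50, seed=11)
            truth = simulate_community_matrix(d, small_pool)
            sim = synthesize_reads(truth, small_pool, seed=12)
            out = tmp_path / f"run{run}"
            paths = sim.write_fastq(out)
            blob = b"".join(
                Path(p).read_bytes() for pair in paths.values() for p in pair
            )
            hashes.append(blob)
        assert hashes[0] == hashes[1]
        # spot-parse one file
        some = next(iter(tmp_path.glob("run0/*_R1.fastq.gz")))
        with gzip.open(some, "rt") as fh:
            lines = fh.read().splitlines()
        assert lines[0].startswith("@") and set(lines[1]) <= set("ACGT")
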