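import numpy as np
import pytest
from scipy import stats

from exapt.errors import ConfigurationError
from exapt.intervals import GenomeInterval, nearest_distance
from exapt.simulate import (
    SimulationConfig,
    default_consensus,
    derive_peaks,
    mutate_each,
    mutate_sequences,
    place_insertions,
    simulate_dataset,
    simulate_genome,
    simulate_lineage_split,
    write_dataset,
)


def small_config(**overrides):
    defaults = dict(
        chrom_lengths=(300_000, 300_000),
        n_tss=120,
        n_ancestral_sites=40,
        n_te_copies=300,
        other_families=(("B4A", 100),),
        seed=7,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


class TestConfigValidation:
    def test_probabilities_bounded(self):
        with pytest.raises(ConfigurationError):
            small_config(mu=1.5)
        with pytest.raises(ConfigurationError):
            small_config(proximity_bias=-0.1)

    def test_kappa_at_least_one(self):
        with pytest.raises(ConfigurationError):
            small_config(kappa=0.5)

    def test_no_tss_with_copies_is_error(self):
        with pytest.raises(ConfigurationError):
            simulate_genome(small_config(n_tss=0))

    def test_infeasible_packing_is_error(self):
        with pytest.raises(ConfigurationError):
            simulate_genome(small_config(chrom_lengths=(10_000,), n_te_copies=100))


class TestSimulateGenome:
    def test_deterministic_for_seed(self):
        g1, t1, a1 = simulate_genome(small_config())
        g2, t2, a2 = simulate_genome(small_config())
        assert g1 == g2 and t1 == t2 and a1 == a2

    def test_base_composition_uniform(self):
        cfg = small_config(chrom_lengths=(1_000_000,), n_tss=50, n_ancestral_sites=10,
                           n_te_copies=10, other_families=())
        genome, _, _ = simulate_genome(cfg)
        seq = genome["chr1"]
        n = len(seq)
        se = np.sqrt(n * 0.25 * 0.75)
        for base in "ACGT":
            assert abs(seq.count(base) - n * 0.25) < 3 * se

    def test_ancestral_sites_disjoint_and_fixed_width(self):
        _, _, sites = simulate_genome(small_config())
        w = small_config().ancestral_site_width
        by_chrom = {}
        for s in sites:
            assert s.length == w
            by_chrom.setdefault(s.chrom, []).append(s)
        for chrom_sites in by_chrom.values():
            chrom_sites.sort(key=lambda s: s.start)
            for a, b in zip(chrom_sites, chrom_sites[1:]):
                assert a.end <= b.start

    def test_every_chromosome_gets_a_tss(self):
        _, tss, _ = simulate_genome(small_config(n_tss=2))
        assert {t.chrom for t in tss} == {"chr1", "chr2"}


class TestMutationEngine:
    def test_zero_rate_is_identity(self, rng):
        copies, records = mutate_sequences("ACGTACGT" * 10, 20, 0.0, 10.0, rng)
        assert all(c == "ACGTACGT" * 10 for c in copies)
        assert all(r == [] for r in records)

    def test_ebox_maturation_rate_first_order(self):
        # P(E-Box 2 matured) ~ kappa * mu for small mu
        rng = np.random.default_rng(5)
        model = default_consensus()
        mu, kappa = 1e-3, 5.0
        copies, _ = mutate_sequences(model.sequence, 10_000, mu, kappa, rng)
        matured = sum(c[123:129] == "CACGTG" for c in copies)
        p_hat = matured / 10_000
        se = np.sqrt(kappa * mu * (1 - kappa * mu) / 10_000)
        assert abs(p_hat - kappa * mu) < 3 * se

    def test_unit_kappa_equalizes_cpg_and_noncpg_rates(self):
        rng = np.random.default_rng(9)
        consensus = default_consensus().sequence
        copies, _ = mutate_sequences(consensus, 3000, 0.05, 1.0, rng)
        arr = np.frombuffer(consensus.encode(), dtype=np.uint8)
        cpg = np.zeros(len(consensus), dtype=bool)
        cpg[:-1] |= (arr[:-1] == ord("C")) & (arr[1:] == ord("G"))
        cpg[1:] |= (arr[1:] == ord("G")) & (arr[:-1] == ord("C"))
        diff = np.stack(
            [np.frombuffer(c.encode(), dtype=np.uint8) != arr for c in copies]
        )
        cpg_rate = diff[:, cpg].mean()
        rest_rate = diff[:, ~cpg].mean()
        n_cpg = diff[:, cpg].size
        se = np.sqrt(0.05 * 0.95 * (1 / n_cpg + 1 / diff[:, ~cpg].size))
        assert abs(cpg_rate - rest_rate) < 3 * se

    def test_deamination_channel_targets(self):
        rng = np.random.default_rng(11)
        copies, records = mutate_sequences("TTCGTT", 2000, 0.02, 10.0, rng)
        for rec in records:
            for pos, src, dst in rec:
                if pos == 2:
                    assert (src, dst) == ("C", "T")
                if pos == 3:
                    assert (src, dst) == ("G", "A")

    def test_batched_mutation_matches_sources(self):
        rng = np.random.default_rng(3)
        sources = ["ACGTACGTAC", "TTTTCGTTTT", "GGGGGGGGGG"]
        out = mutate_each(sources, 0.0, 10.0, rng)
        assert out == sources


class TestPlacement:
    def _setup(self, **overrides):
        cfg = small_config(**overrides)
        _, _, sites = simulate_genome(cfg)
        return cfg, sites

    def test_full_bias_respects_window(self):
        cfg, sites = self._setup(proximity_bias=1.0, proximity_window=10_000)
        rng = np.random.default_rng(cfg.seed)
        annots, proximal = place_insertions(
            [147] * 200, [cfg.family_name] * 200, cfg, sites, rng
        )
        assert proximal.all()
        dists = [
            d for _, _, d in nearest_distance([a.interval for a in annots], sites)
        ]
        assert max(dists) <= 10_000

    def test_no_overlap_with_ancestral_sites(self):
        cfg, sites = self._setup(proximity_bias=1.0)
        rng = np.random.default_rng(0)
        annots, _ = place_insertions([147] * 300, [cfg.family_name] * 300, cfg, sites, rng)
        for a in annots:
            for s in sites:
                assert a.interval.overlap_bp(s) == 0

    def test_zero_bias_matches_uniform_null(self):
        cfg, sites = self._setup(proximity_bias=0.0)
        rng = np.random.default_rng(1)
        annots, proximal = place_insertions(
            [147] * 500, [cfg.family_name] * 500, cfg, sites, rng
        )
        assert not proximal.any()
        placed = [d for _, _, d in nearest_distance([a.interval for a in annots], sites)]
        # oracle: uniform random points on the same genome, same avoidance rule
        uniform_points = []
        lengths = dict(zip(["chr1", "chr2"], cfg.chrom_lengths))
        while len(uniform_points) < 2000:
            chrom = "chr1" if rng.random() < 0.5 else "chr2"
            s = int(rng.integers(0, lengths[chrom] - 147))
            cand = GenomeInterval(chrom, s, s + 147)
            if all(cand.overlap_bp(site) == 0 for site in sites):
                uniform_points.append(cand)
        null = [d for _, _, d in nearest_distance(uniform_points, sites)]
        assert stats.ks_2samp(placed, null).pvalue > 0.001

    def test_control_family_placed_uniformly_despite_bias(self):
        cfg, sites = self._setup(proximity_bias=1.0)
        rng = np.random.default_rng(2)
        annots, proximal = place_insertions(
            [147] * 100, ["B4A"] * 100, cfg, sites, rng
        )
        assert not proximal.any()


class TestDerivePeaks:
    def _dataset_pieces(self, **overrides):
        cfg = small_config(**overrides)
        rng = np.random.default_rng(cfg.seed)
        _, _, sites = simulate_genome(cfg, rng)
        copies, _ = mutate_sequences(
            cfg.consensus_model.sequence, cfg.n_te_copies, cfg.mu, cfg.kappa, rng
        )
        annots, proximal = place_insertions(
            [len(c) for c in copies], [cfg.family_name] * len(copies), cfg, sites, rng
        )
        seqs = {a.interval.name: c for a, c in zip(annots, copies)}
        return cfg, sites, annots, seqs, proximal, rng

    def test_no_binding_leaves_only_ancestral_peaks(self):
        cfg, sites, annots, seqs, proximal, rng = self._dataset_pieces(
            binding_base_prob=0.0, maturation_coupling=0.0, binding_noise=0.0
        )
        peaks, truth = derive_peaks(annots, seqs, proximal, cfg, sites, rng)
        assert len(peaks) == len(sites)
        assert not truth.table["bound"].any()

    def test_deterministic_limit_binds_every_matured_copy(self):
        cfg, sites, annots, seqs, proximal, rng = self._dataset_pieces(
            binding_base_prob=1.0, maturation_coupling=0.0
        )
        peaks, truth = derive_peaks(annots, seqs, proximal, cfg, sites, rng)
        t = truth.table
        assert (t.loc[t.matured_pair, "bound"]).all()
        assert not (t.loc[~t.matured_pair, "bound"]).any()

    def test_truth_covers_every_copy_once(self):
        cfg, sites, annots, seqs, proximal, rng = self._dataset_pieces()
        _, truth = derive_peaks(annots, seqs, proximal, cfg, sites, rng)
        assert len(truth.table) == len(annots)
        assert truth.table.index.is_unique
        assert truth.table[["proximal", "matured_pair", "bound"]].notna().all().all()


class TestLineageSplit:
    def test_zero_rate_descendants_identical(self):
        cfg = small_config()
        seqs = {"a": "ACGTACGTAC", "b": "TTTTCGTTTT"}
        split = simulate_lineage_split(
            seqs, cfg, np.random.default_rng(0), mu_mouse=0.0, mu_rat=0.0,
            loss_fraction=0.0,
        )
        assert split.mouse == seqs and split.rat == seqs
        assert split.ortholog_map == {"a": "a", "b": "b"}

    def test_loss_fraction_controls_ortholog_rate(self):
        cfg = small_config()
        seqs = {f"c{i}": "ACGT" * 25 for i in range(4000)}
        split = simulate_lineage_split(
            seqs, cfg, np.random.default_rng(1), loss_fraction=0.4
        )
        frac = len(split.ortholog_map) / 4000
        se = np.sqrt(0.4 * 0.6 / 4000)
        assert abs(frac - 0.6) < 3 * se

    def test_post_split_maturation_independent(self):
        cfg = small_config(mu=0.0)  # unmatured shared ancestors
        model = default_consensus()
        seqs = {f"c{i}": model.sequence for i in range(10_000)}
        split = simulate_lineage_split(
            seqs, cfg, np.random.default_rng(2), mu_mouse=0.02, mu_rat=0.02,
            loss_fraction=0.0,
        )
        m = np.array([split.mouse[c][123:129] == "CACGTG" for c in sorted(seqs)])
        r = np.array([split.rat[c][123:129] == "CACGTG" for c in sorted(seqs)])
        p_both = (m & r).mean()
        expected = m.mean() * r.mean()
        se = np.sqrt(expected * (1 - expected) / 10_000)
        assert abs(p_both - expected) < 3 * se + 1e-6


class TestFullDataset:
    def test_byte_identical_outputs_for_seed(self, tmp_path):
        cfg = small_config(n_te_copies=100, other_families=(("B4A", 40),))
        d1 = write_dataset(simulate_dataset(cfg), tmp_path / "a")
        d2 = write_dataset(simulate_dataset(cfg), tmp_path / "b")
        assert d1 == d2

    def test_cross_references_consistent(self):
        cfg = small_config(n_te_copies=150, other_families=())
        ds = simulate_dataset(cfg)
        t = ds.truth.table
        assert set(t.index) == set(ds.copy_sequences)
        # embedded genome sequence equals the copy sequence at its coordinates
        for cid, row in t.head(20).iterrows():
            emb = ds.genome[row.chrom][row.start: row.end]
            seq = ds.copy_sequences[cid]
            if row.strand == "-":
                from exapt.motifs import reverse_complement

                seq = reverse_complement(seq)
            assert emb == seq

    def test_bound_implies_matured_pair_without_noise(self):
        ds = simulate_dataset(small_config(binding_noise=0.0))
        t = ds.truth.table
        assert (t.loc[t.bound, "matured_pair"]).all()
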