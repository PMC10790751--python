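"""Fragment-ANI estimator: identity cases, oracle agreement, gene sharing."""

import numpy as np
import pytest

from anigap._seq import decode
from anigap import ani
from anigap.simulate import Gene, GenomeRecord, SimConfig, simulate_species
from anigap.simulate import _mutate  # noqa: PLC2701 - oracle needs the event model


def _record(genome_id, seq):
    return GenomeRecord(genome_id, {f"{genome_id}_c1": seq}, [], {})


@pytest.fixture(scope="module")
def random_genome():
    rng = np.random.default_rng(17)
    return rng.integers(0, 4, size=30_000, dtype=np.uint8)


class TestComputeAni:
    def test_self_comparison_is_identity(self, random_genome):
        g = _record("self", decode(random_genome))
        pair = ani.compute_ani(g, g)
        assert pair.ani == 100.0
        assert pair.shared_fraction == 1.0
        assert pair.n_fragments == 10

    def test_thirty_substitutions_in_one_fragment(self, random_genome):
        # all 30 mismatches inside fragment 3 of 10: identities 9x100 + 1x99
        mutated = random_genome.copy()
        pos = 3 * 3000 + np.arange(30) * 90 + 11
        mutated[pos] = (mutated[pos] + 1) % 4
        pair = ani.compute_ani(
            _record("q", decode(random_genome)), _record("r", decode(mutated)),
            keep_fragments=True,
        )
        idents = sorted(round(f.identity, 6) for f in pair.fragments)
        assert idents == [99.0] + [100.0] * 9
        assert pair.ani == pytest.approx(99.9)
        assert pair.shared_fraction == 1.0

    def test_matches_hamming_oracle_on_indel_free_pairs(self):
        # planted divergences 0.1%..4%: fragment ANI within 0.05 points of
        # the exact Hamming identity on the ancestral coordinate frame
        rng = np.random.default_rng(23)
        root = rng.integers(0, 4, size=100_000, dtype=np.uint8)
        for div in (0.001, 0.005, 0.02, 0.04):
            other = _mutate(root, int(div * root.size * 4 / 3), rng)
            exact = 100.0 * np.mean(root == other)
            pair = ani.compute_ani(_record("a", decode(root)), _record("b", decode(other)))
            assert pair.ani == pytest.approx(exact, abs=0.05)
            assert pair.shared_fraction == 1.0

    def test_added_divergence_decreases_ani(self):
        # mean ANI strictly decreases with planted divergence (20 seeds)
        divs = (0.002, 0.01, 0.03)
        means = []
        for div in divs:
            vals = []
            for seed in range(20):
                rng = np.random.default_rng(1000 + seed)
                root = rng.integers(0, 4, size=30_000, dtype=np.uint8)
                other = _mutate(root, int(div * root.size), rng)
                vals.append(
                    ani.compute_ani(_record("a", decode(root)), _record("b", decode(other))).ani
                )
            means.append(np.mean(vals))
        assert means[0] > means[1] > means[2]

    def test_short_genome_has_no_fragments(self):
        g = _record("tiny", "ACGT" * 100)
        with pytest.raises(ValueError, match="no fragments"):
            ani.compute_ani(g, g)

    def test_unrelated_genomes_have_undefined_ani(self):
        rng = np.random.default_rng(5)
        a = _record("a", decode(rng.integers(0, 4, 9000, dtype=np.uint8)))
        b = _record("b", decode(rng.integers(0, 4, 9000, dtype=np.uint8)))
        pair = ani.compute_ani(a, b)
        assert pair.ani is None
        assert pair.n_bidirectional == 0

    def test_fragments_never_span_contigs(self, random_genome):
        seq = decode(random_genome)
        split = GenomeRecord("s", {"c1": seq[:7500], "c2": seq[7500:]}, [], {})
        pair = ani.compute_ani(split, _record("r", seq), keep_fragments=True)
        # 7500 -> 2 complete fragments, 22500 -> 7: terminal remainders dropped
        assert pair.n_fragments == 9
        assert pair.ani == pytest.approx(100.0)


class TestPairTable:
    def test_one_row_per_unordered_pair(self, small_pairs, small_species):
        genomes, _ = small_species
        n = len(genomes)
        assert len(small_pairs) == n * (n - 1) // 2

    def test_longer_genome_is_reference(self, small_pairs, small_species):
        genomes, _ = small_species
        length = {g.genome_id: g.length for g in genomes}
        for p in small_pairs:
            lq, lr = length[p.query_id], length[p.ref_id]
            assert lr > lq or (lr == lq and p.ref_id < p.query_id)

    def test_equal_length_tie_broken_lexicographically(self, random_genome):
        seq = decode(random_genome)
        pairs = ani.pair_table([_record("b", seq), _record("a", seq)])
        assert pairs[0].ref_id == "a" and pairs[0].query_id == "b"

    def test_duplicate_ids_rejected(self, random_genome):
        seq = decode(random_genome)
        with pytest.raises(ValueError, match="duplicate"):
            ani.pair_table([_record("a", seq), _record("a", seq)])

    def test_direction_symmetry_on_indel_free_pairs(self):
        rng = np.random.default_rng(3)
        root = rng.integers(0, 4, size=60_000, dtype=np.uint8)
        other = _mutate(root, 600, rng)
        a, b = _record("a", decode(root)), _record("b", decode(other))
        fwd = ani.compute_ani(a, b).ani
        rev = ani.compute_ani(b, a).ani
        assert abs(fwd - rev) < 0.05


class TestSharedGeneFraction:
    def test_identical_genomes_share_everything(self, small_species):
        genomes, _ = small_species
        g = genomes[0]
        share = ani.shared_gene_fraction(g, g)
        assert share.shared_gene_fraction == 1.0
        assert not share.nonshared_a and not share.nonshared_b

    def test_deletion_formula(self):
        # 100 genes vs 95 after deleting 5: 95 orthologs / 97.5 mean genes
        rng = np.random.default_rng(11)
        seqs = [decode(rng.integers(0, 4, 300, dtype=np.uint8)) for _ in range(100)]
        spacer = "A" * 50

        def build(gid, keep):
            parts, genes, pos = [], [], 0
            for i in keep:
                parts.append(spacer)
                pos += len(spacer)
                genes.append(Gene(f"g{i:03d}", f"{gid}_c1", pos, pos + 300, "+",
                                  "annotated", False))
                parts.append(seqs[i])
                pos += 300
            return GenomeRecord(gid, {f"{gid}_c1": "".join(parts)}, genes, {})

        a = build("a", range(100))
        b = build("b", range(95))
        share = ani.shared_gene_fraction(a, b)
        assert share.shared_gene_fraction == pytest.approx(95 / 97.5)
        assert len(share.nonshared_a) == 5 and not share.nonshared_b

    def test_agrees_with_truth_presence_matrix(self, small_species):
        genomes, truth = small_species
        a, b = genomes[0], genomes[1]  # same genomovar: gene sequences nearly identical
        share = ani.shared_gene_fraction(a, b)
        pres = truth.presence
        both = int((pres.loc[a.genome_id] & pres.loc[b.genome_id]).sum())
        mean_genes = (int(pres.loc[a.genome_id].sum()) + int(pres.loc[b.genome_id].sum())) / 2
        assert share.shared_gene_fraction == pytest.approx(both / mean_genes)

    def test_zero_gene_genome_rejected(self, random_genome):
        g = _record("nogenes", decode(random_genome))
        with pytest.raises(ValueError):
            ani.shared_gene_fraction(g, g)


def test_read_identity_resolution():
    # one mismatch: 1% on a 100 bp read, 0.4% on a 250 bp read
    assert ani.single_mismatch_identity_drop(100) == pytest.approx(1.0)
    assert ani.single_mismatch_identity_drop(250) == pytest.approx(0.4)
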