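"""Feature assignment, UMI collapse and matrix assembly."""

import itertools
import random

import numpy as np
import pytest

from spatialcite import (
    PixelAddress,
    TranscriptomeIndex,
    assign_transcript_toy,
    build_matrix,
    collapse_umis,
    hamming,
    match_adt_tag,
)
from spatialcite.demux import demux_library
from spatialcite.fixtures import random_panel, random_transcriptome
from spatialcite.quantify import _directional_count, assign_features


@pytest.fixture(scope="module")
def small_panel():
    return random_panel(10, seed=5, n_isotype=1)


class TestMatchADTTag:
    def test_exact_tag_assigns(self, small_panel):
        e = small_panel.entries[0]
        payload = e.tag_seq + "A" * 20
        assert match_adt_tag(payload, small_panel, 1, (0, 15)) == e.antibody_id

    def test_one_substitution_corrects_via_brute_force_nearest(self, small_panel):
        e = small_panel.entries[3]
        mutated = "T" + e.tag_seq[1:] if e.tag_seq[0] != "T" else "A" + e.tag_seq[1:]
        # verify by brute force that the mutated tag is uniquely nearest
        dists = sorted(hamming(mutated, x.tag_seq) for x in small_panel)
        assert dists[0] == 1 and dists[1] > 1
        assert match_adt_tag(mutated + "AAAA", small_panel, 1, (0, 15)) == e.antibody_id

    def test_equidistant_tag_is_no_match(self):
        from spatialcite.panel import ADTPanel, ADTPanelEntry

        panel = ADTPanel(
            [
                ADTPanelEntry("ab1", "AAAAAAAAAAAAAAA"),
                ADTPanelEntry("ab2", "AAAAAAAAAAAAAAT"),
            ]
        )
        query = "AAAAAAAAAAAAAAC"  # distance 1 from both
        assert all(hamming(query, e.tag_seq) == 1 for e in panel)
        assert match_adt_tag(query, panel, 1, (0, 15)) is None

    def test_matcher_table_agrees_with_scan_on_random_tags(self, small_panel):
        rng = np.random.default_rng(8)
        bases = np.array(list("ACGT"))
        matcher = small_panel.build_matcher(1)
        for _ in range(2000):
            tag = "".join(rng.choice(bases, size=15))
            hit = matcher.get(tag)
            via_table = hit[0] if hit else None
            assert via_table == match_adt_tag(tag, small_panel, 1, (0, 15))


class TestToyTranscriptAssigner:
    TX = random_transcriptome([f"g{i}" for i in range(8)], seed=2, length=200)

    def test_substring_assigns_its_gene(self):
        index = TranscriptomeIndex(self.TX, k=31)
        for gene, seq in self.TX.items():
            assert assign_transcript_toy(seq[50:140], index) == gene

    def test_sequence_shared_by_two_genes_is_ambiguous(self):
        shared = "ACGT" * 20
        seqs = {"gA": shared + "AAAAA" * 8, "gB": shared + "CCCCC" * 8}
        index = TranscriptomeIndex(seqs, k=31)
        assert index.assign(shared) is None

    def test_random_sequence_is_no_match(self):
        """A random 90-mer should hit no 31-mer of an unrelated toy
        transcriptome (expected spurious hit rate ~ n_kmers/4^31)."""
        index = TranscriptomeIndex(self.TX, k=31)
        rng = random.Random(4)
        for _ in range(50):
            q = "".join(rng.choice("ACGT") for _ in range(90))
            assert index.assign(q) is None

    def test_payload_shorter_than_k_is_no_match(self):
        index = TranscriptomeIndex(self.TX, k=31)
        assert index.assign("ACGTACGT") is None


class TestCollapseUMIs:
    P = PixelAddress(1, 1)
    Q = PixelAddress(2, 1)

    def test_triplicate_reads_count_once(self):
        recs = [(self.P, "f", "AAAA")] * 3
        assert collapse_umis(recs) == {(self.P, "f"): 1}

    def test_directional_merges_likely_pcr_error_exact_does_not(self):
        recs = [(self.P, "f", "AAAA")] * 10 + [(self.P, "f", "AAAT")]
        assert collapse_umis(recs, mode="exact") == {(self.P, "f"): 2}
        # directional rule: 10 >= 2*1-1 and Hamming(AAAA,AAAT)=1 -> one network
        assert collapse_umis(recs, mode="directional1mm") == {(self.P, "f"): 1}

    def test_directional_keeps_balanced_pair_separate(self):
        # 5 vs 5: 5 < 2*5-1, no directed edge either way
        recs = [(self.P, "f", "AAAA")] * 5 + [(self.P, "f", "AAAT")] * 5
        assert collapse_umis(recs, mode="directional1mm") == {(self.P, "f"): 2}

    def test_same_umi_different_pixels_counts_in_each(self):
        recs = [(self.P, "f", "AAAA"), (self.Q, "f", "AAAA")]
        assert collapse_umis(recs) == {(self.P, "f"): 1, (self.Q, "f"): 1}

    def test_exact_mode_equals_brute_force_on_random_records(self):
        rng = random.Random(12)
        pixels = [PixelAddress(r, c) for r in range(1, 4) for c in range(1, 4)]
        recs = [
            (
                rng.choice(pixels),
                rng.choice("fgh"),
                "".join(rng.choice("ACGT") for _ in range(4)),
            )
            for _ in range(10_000)
        ]
        expected: dict = {}
        for p, f, u in set(recs):  # brute force: distinct triples
            expected[(p, f)] = expected.get((p, f), 0) + 1
        assert collapse_umis(recs, mode="exact") == expected

    def test_directional_count_matches_exhaustive_oracle_on_small_sets(self):
        """Exhaustively check the directional network count against an
        independent oracle that enumerates reachability over all
        orderings of every small UMI multiset."""

        def oracle(counts: dict[str, int]) -> int:
            nodes = sorted(counts, key=lambda u: (-counts[u], u))
            edges = {
                (u, v)
                for u, v in itertools.permutations(nodes, 2)
                if hamming(u, v) == 1 and counts[u] >= 2 * counts[v] - 1
            }
            seen: set = set()
            roots = 0
            for n in nodes:
                if n in seen:
                    continue
                roots += 1
                frontier = [n]
                seen.add(n)
                while frontier:
                    u = frontier.pop()
                    for v in nodes:
                        if v not in seen and (u, v) in edges:
                            seen.add(v)
                            frontier.append(v)
            return roots

        rng = random.Random(3)
        for _ in range(300):
            umis = {
                "".join(rng.choice("AC") for _ in range(3)): rng.randint(1, 12)
                for _ in range(rng.randint(1, 6))
            }
            assert _directional_count(umis) == oracle(umis)


class TestBuildMatrix:
    def test_protein_matrix_retains_zero_rows(self, small_panel):
        counts = {(PixelAddress(1, 1), small_panel.antibody_ids[0]): 2}
        m = build_matrix(counts, "protein", small_panel, (10, 10))
        assert m.features == small_panel.antibody_ids  # all 10 rows kept
        assert m.shape == (10, 1)

    def test_empty_counts_gives_full_panel_by_zero_pixels(self, small_panel):
        m = build_matrix({}, "protein", small_panel, (10, 10))
        assert m.shape == (len(small_panel), 0)

    def test_rna_matrix_drops_unobserved_genes(self):
        counts = {(PixelAddress(1, 1), "g1"): 3}
        m = build_matrix(counts, "RNA", ["g0", "g1", "g2"], (5, 5))
        assert m.features == ["g1"]
        full = build_matrix(
            counts, "RNA", ["g0", "g1", "g2"], (5, 5), drop_unobserved_genes=False
        )
        assert full.features == ["g0", "g1", "g2"]

    def test_pixel_label_convention(self):
        assert PixelAddress(3, 41).label == "3x41"

    def test_out_of_grid_pixel_rejected(self, small_panel):
        from spatialcite.errors import DataError

        counts = {(PixelAddress(7, 1), small_panel.antibody_ids[0]): 1}
        with pytest.raises(DataError, match="outside"):
            build_matrix(counts, "protein", small_panel, (5, 5))

    def test_permutation_invariance(self, small_panel):
        rng = random.Random(9)
        recs = [
            (
                PixelAddress(rng.randint(1, 3), rng.randint(1, 3)),
                rng.choice(small_panel.antibody_ids),
                "".join(rng.choice("ACGT") for _ in range(6)),
            )
            for _ in range(500)
        ]
        m1 = build_matrix(collapse_umis(recs), "protein", small_panel, (3, 3))
        shuffled = recs[:]
        rng.shuffle(shuffled)
        m2 = build_matrix(collapse_umis(shuffled), "protein", small_panel, (3, 3))
        assert m1 == m2


class TestRecovery:
    @pytest.mark.parametrize("mu", [0.5, 5.0, 50.0])
    def test_error_free_counts_equal_distinct_umi_truth(
        self, tmp_path, whitelists, layout, mu
    ):
        """Across low/medium/high expression, quantified counts equal the
        simulator's distinct-UMI truth exactly in error-free runs."""
        from spatialcite.simulate import Domain, ErrorModel, TissueModel, simulate_run

        panel = random_panel(6, seed=1, n_isotype=0)
        tx = random_transcriptome(["gx", "gy"], seed=6, length=250)
        grid = (4, 4)
        model = TissueModel(
            grid=grid,
            domains=[
                Domain(
                    "all",
                    np.ones(grid, dtype=bool),
                    {"gx": mu, "gy": mu / 5},
                    {panel.antibody_ids[0]: mu, panel.antibody_ids[1]: mu / 5},
                )
            ],
        )
        sim = simulate_run(
            model, panel, tx, whitelists, layout, ErrorModel(0.0, 1.0, seed=33),
            tmp_path / f"mu{mu}",
        )
        index = TranscriptomeIndex(tx)
        for modality, pair, kwargs in (
            ("RNA", (sim.rna_r1, sim.rna_r2), {"transcriptome": index}),
            ("protein", (sim.adt_r1, sim.adt_r2), {"panel": panel}),
        ):
            records, _ = demux_library(
                (str(pair[0]), str(pair[1])), layout, *whitelists, modality=modality
            )
            counts = collapse_umis(assign_features(records, modality, **kwargs))
            features = panel if modality == "protein" else index.genes
            got = build_matrix(
                counts, modality, features, (50, 50), drop_unobserved_genes=False
            )
            truth = sim.truth.distinct_umi_matrix(modality)
            if sim.truth.total_molecules(modality):
                assert got == truth

    def test_noisy_recovery_correlation_at_least_099(
        self, tmp_path, tissue, panel, fixture_set, whitelists, layout
    ):
        """At substitution rate 0.005, per-(pixel,feature) quantified counts
        correlate with distinct-UMI truth at Pearson r >= 0.99."""
        from spatialcite.simulate import ErrorModel, simulate_run

        sim = simulate_run(
            tissue, panel, fixture_set.transcriptome, whitelists, layout,
            ErrorModel(substitution_rate=0.005, pcr_duplication=1.0, seed=303),
            tmp_path / "sub005",
        )
        truth = sim.truth.distinct_umi_matrix("protein")
        records, _ = demux_library(
            (str(sim.adt_r1), str(sim.adt_r2)), layout, *whitelists,
            modality="protein",
        )
        counts = collapse_umis(assign_features(records, "protein", panel=panel))
        got = build_matrix(counts, "protein", panel, (50, 50))
        t = truth.to_frame()
        g = got.to_frame().reindex(index=t.index, columns=t.columns, fill_value=0)
        r = np.corrcoef(t.to_numpy().ravel(), g.to_numpy().ravel())[0, 1]
        assert r >= 0.99
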