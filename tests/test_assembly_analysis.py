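"""Assembly-frame analysis: sheets, orientations, composition, beta content."""

import numpy as np
import pytest

from coapep.assembly_analysis import (AnalysisParams, AssemblyFrame,
                                      ChainRecord, beta_content,
                                      classify_pair_orientation,
                                      composition_ratio, neighbor_statistics,
                                      partition_sheets, strand_vector)
from coapep.errors import AnalysisError
from coapep.fixtures import DESIGN_PAIRS, make_fixture
from coapep.scaffold_model import ScaffoldGeometry, build_scaffold


def scaffold_frame(scaffold, species=None, coords=None) -> AssemblyFrame:
    coords = scaffold.ca_coords if coords is None else coords
    chains = []
    for k, slot in enumerate(scaffold.slots):
        sp = slot.species if species is None else species[k]
        chains.append(ChainRecord(chain_id=str(k), species=sp,
                                  coords=coords[k]))
    return AssemblyFrame(chains=chains)


@pytest.fixture
def ideal_frame(scaffold):
    return scaffold_frame(scaffold)


class TestStrandVector:
    def test_collinear_points_give_axis(self):
        coords = np.column_stack([np.arange(8) * 3.5, np.zeros(8), np.zeros(8)])
        assert np.allclose(strand_vector(ChainRecord("a", "A", coords)),
                           [1, 0, 0])

    def test_reversed_chain_negates_vector(self, ideal_frame):
        chain = ideal_frame.chains[0]
        v = strand_vector(chain)
        reversed_chain = ChainRecord("r", "A", chain.coords[::-1])
        assert np.allclose(strand_vector(reversed_chain), -v)

    def test_unit_norm(self, ideal_frame):
        for chain in ideal_frame.chains:
            assert np.linalg.norm(strand_vector(chain)) == pytest.approx(
                1.0, abs=1e-9)

    def test_degenerate_chain_rejected(self):
        coords = np.ones((5, 3))
        with pytest.raises(AnalysisError):
            strand_vector(ChainRecord("d", "A", coords))


class TestOrientationClassifier:
    def test_identity_parallel_and_mirror_antiparallel(self):
        v = np.array([0.6, 0.8, 0.0])
        assert classify_pair_orientation(v, v) == "parallel"
        assert classify_pair_orientation(v, -v) == "antiparallel"

    def test_orthogonal_vectors_unclassified(self):
        assert classify_pair_orientation(np.array([1.0, 0, 0]),
                                         np.array([0, 1.0, 0])) == "unclassified"


class TestPartition:
    def test_ideal_scaffold_two_sheets_of_six(self, ideal_frame):
        partition = partition_sheets(ideal_frame)
        assert [len(s) for s in partition] == [6, 6]
        assert partition[0] == list(range(6))

    def test_distant_chains_are_singletons(self, scaffold):
        coords = scaffold.ca_coords + \
            np.arange(scaffold.n_slots)[:, None, None] * 200.0
        frame = scaffold_frame(scaffold, coords=coords)
        assert all(len(s) == 1 for s in partition_sheets(frame))

    def test_partition_robust_to_coordinate_noise(self, scaffold):
        rng = np.random.default_rng(0)
        noisy = scaffold.ca_coords + rng.normal(0, 0.3,
                                                scaffold.ca_coords.shape)
        clean = partition_sheets(scaffold_frame(scaffold))
        jittered = partition_sheets(scaffold_frame(scaffold, coords=noisy))
        assert jittered == clean


class TestNeighborStatistics:
    def test_ideal_lattice_statistics_exact(self, ideal_frame):
        stats = neighbor_statistics(ideal_frame)
        assert stats.fraction_within_nearest("AB", "antiparallel") == 1.0
        assert stats.fraction_within_next("AA", "parallel") \
            + stats.fraction_within_next("BB", "parallel") == 1.0
        assert stats.fraction_cross("parallel") == 1.0
        assert stats.total_pairs() == sum(stats.within_nearest.values()) \
            + sum(stats.within_next_nearest.values()) \
            + sum(stats.cross_nearest.values())

    def test_single_sheet_has_no_cross_counts(self):
        scaffold = build_scaffold(ScaffoldGeometry(n_sheets=1))
        stats = neighbor_statistics(scaffold_frame(scaffold))
        assert sum(stats.cross_nearest.values()) == 0

    def test_invariant_under_rigid_motion(self, scaffold, ideal_frame):
        from scipy.spatial.transform import Rotation

        rot = Rotation.from_euler("zyx", [33, 71, -12], degrees=True)
        moved = scaffold_frame(
            scaffold, coords=rot.apply(
                scaffold.ca_coords.reshape(-1, 3)).reshape(
                    scaffold.ca_coords.shape) + np.array([5.0, -3.0, 9.0]))
        assert neighbor_statistics(moved).within_nearest == \
            neighbor_statistics(ideal_frame).within_nearest

    def test_shuffled_labels_match_hypergeometric_expectation(self, scaffold):
        # relabeling 6A+6B at random makes an adjacent pair mixed with
        # probability 2*(6/12)*(6/11) = 6/11
        rng = np.random.default_rng(21)
        labels = ["A"] * 6 + ["B"] * 6
        fractions = []
        for _ in range(200):
            rng.shuffle(labels)
            frame = scaffold_frame(scaffold, species=list(labels))
            stats = neighbor_statistics(frame)
            mixed = stats.within_nearest[("AB", "antiparallel")]
            fractions.append(mixed / sum(stats.within_nearest.values()))
        fractions = np.array(fractions)
        sem = fractions.std(ddof=1) / np.sqrt(len(fractions))
        assert abs(fractions.mean() - 6 / 11) < 3 * sem


class TestCompositionRatio:
    def test_ideal_fixture_ratio_unity(self, ideal_frame):
        assert composition_ratio(ideal_frame) == pytest.approx(1.0)

    def test_constructed_excess_of_a(self, scaffold):
        species = ["A"] * 9 + ["B"] * 3
        frame = scaffold_frame(scaffold, species=species)
        assert composition_ratio(frame) == pytest.approx(3.0)

    def test_invariant_under_chain_reordering(self, scaffold, ideal_frame):
        rng = np.random.default_rng(3)
        order = rng.permutation(scaffold.n_slots)
        shuffled = AssemblyFrame(
            chains=[ideal_frame.chains[i] for i in order])
        assert composition_ratio(shuffled) == composition_ratio(ideal_frame)

    def test_no_aggregated_b_reported_as_undefined(self, scaffold):
        frame = scaffold_frame(scaffold, species=["A"] * scaffold.n_slots)
        assert composition_ratio(frame) is None


class TestBetaContent:
    def test_ideal_scaffold_full_content(self, ideal_frame):
        series = beta_content(ideal_frame)
        assert series.fractions[0] == 1.0

    def test_dispersed_frame_zero_content(self, scaffold):
        coords = scaffold.ca_coords + \
            np.arange(scaffold.n_slots)[:, None, None] * 300.0
        series = beta_content(scaffold_frame(scaffold, coords=coords))
        assert series.fractions[0] == 0.0

    def test_half_dispersed_half_content(self, tmp_path):
        from coapep.assembly_analysis import read_frames

        fx = make_fixture("mixed_dispersed", tmp_path)
        frame = read_frames(fx["pdb"])[0]
        series = beta_content(frame)
        assert series.fractions[0] == pytest.approx(fx["truth"]["beta_content"])


class TestFixtureRoundTrip:
    def test_noisy_fibril_statistics_survive_noise(self, tmp_path):
        from coapep.assembly_analysis import read_frames

        fx = make_fixture("noisy_fibril", tmp_path, rng_seed=5,
                          params={"sigma": 0.3})
        frame = read_frames(fx["pdb"])[0]
        partition = partition_sheets(frame)
        assert [len(s) for s in partition] == [6, 6]
        stats = neighbor_statistics(frame, partition)
        assert stats.fraction_within_nearest("AB", "antiparallel") == 1.0
        assert stats.fraction_cross("parallel") == 1.0
        assert composition_ratio(frame) == pytest.approx(1.0)
        assert beta_content(frame).fractions[0] == 1.0
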