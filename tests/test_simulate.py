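"""Tests of the synthetic pan-genome and curve-data generators."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from panforge.partition import partition
from panforge.simulate import (
    ProteinFamilySpec,
    SyntheticPanGenomeSpec,
    generate_curve_data,
    generate_presence_absence,
    generate_protein_families,
    write_genome_fastas,
)


class TestPresenceAbsenceGeneration:
    def test_core_only_matrix_is_all_true(self):
        spec = SyntheticPanGenomeSpec(n_genomes=3, core_size=10)
        matrix, truth = generate_presence_absence(spec)
        assert matrix.data.shape == (10, 3)
        assert matrix.data.to_numpy().all()
        assert (truth == "core").all() and len(truth) == 10

    def test_same_seed_gives_byte_identical_matrices(self, tmp_path):
        spec = SyntheticPanGenomeSpec(
            n_genomes=6, core_size=30, accessory=((2, 10), (4, 5)),
            unique_rate=3.0, seed=42,
        )
        m1, t1 = generate_presence_absence(spec)
        m2, t2 = generate_presence_absence(spec)
        assert m1 == m2
        assert t1.equals(t2)
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        m1.to_tsv(p1)
        m2.to_tsv(p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_accessory_families_have_drawn_frequency(self):
        spec = SyntheticPanGenomeSpec(
            n_genomes=8, core_size=0, accessory=((3, 25), (6, 15)), seed=7
        )
        matrix, truth = generate_presence_absence(spec)
        counts = matrix.presence_counts()
        assert sorted(counts) == [3] * 25 + [6] * 15
        assert (truth == "accessory").all()

    def test_singleton_count_matches_poisson_expectation(self):
        # mean over replicates of total singletons ~ Poisson(n_genomes * lam)
        lam, n_genomes, reps = 5.0, 10, 600
        totals = []
        for seed in range(reps):
            spec = SyntheticPanGenomeSpec(
                n_genomes=n_genomes, core_size=1, unique_rate=lam, seed=seed
            )
            _, truth = generate_presence_absence(spec)
            totals.append(int((truth == "unique").sum()))
        expected = n_genomes * lam
        se = np.sqrt(expected / reps)
        assert abs(np.mean(totals) - expected) < 3 * se

    def test_expected_pan_size_matches_monte_carlo_mean(self):
        spec_kwargs = dict(
            n_genomes=5, core_size=20, accessory=((2, 5), (3, 4)), unique_rate=2.0
        )
        expected = SyntheticPanGenomeSpec(seed=0, **spec_kwargs).expected_pan_size
        assert expected == 20 + 9 + 10
        sizes = [
            generate_presence_absence(
                SyntheticPanGenomeSpec(seed=s, **spec_kwargs)
            )[0].n_families
            for s in range(500)
        ]
        se = np.sqrt(10 / 500)  # only the Poisson part varies
        assert abs(np.mean(sizes) - expected) < 3 * se

    def test_truth_labels_agree_with_partition_module(self):
        for seed in range(5):
            spec = SyntheticPanGenomeSpec(
                n_genomes=7, core_size=15, accessory=((2, 8), (5, 6)),
                unique_rate=4.0, seed=seed,
            )
            matrix, truth = generate_presence_absence(spec)
            part = partition(matrix)
            assert part.labels().sort_index().equals(truth.sort_index())

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_genomes=0, core_size=1),
            dict(n_genomes=3, core_size=-1),
            dict(n_genomes=3, core_size=1, unique_rate=-0.5),
            dict(n_genomes=3, core_size=1, accessory=((3, 2),)),  # freq == n
            dict(n_genomes=3, core_size=1, accessory=((1, 2),)),  # freq < 2
            dict(n_genomes=3, core_size=1, accessory=((4, 2),)),  # freq > n
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SyntheticPanGenomeSpec(seed=0, **kwargs)

    @given(
        n_genomes=st.integers(2, 8),
        core_size=st.integers(0, 30),
        seed=st.integers(0, 2**31 - 1),
    )
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_realized_core_count_equals_spec(self, n_genomes, core_size, seed):
        spec = SyntheticPanGenomeSpec(
            n_genomes=n_genomes, core_size=core_size, unique_rate=1.0, seed=seed
        )
        matrix, truth = generate_presence_absence(spec)
        assert int((matrix.presence_counts() == n_genomes).sum()) == core_size
        assert int((truth == "core").sum()) == core_size


class TestCurveData:
    def test_noise_free_heap_values_are_exact(self):
        df = generate_curve_data(
            "heap", {"k": 1848.134, "gamma": 0.156}, range(1, 10)
        )
        assert df["n"].iloc[0] == pytest.approx(1848.134, abs=1e-12)
        np.testing.assert_allclose(
            df["n"], 1848.134 * df["N"].to_numpy(float) ** 0.156
        )

    def test_degenerate_expdecay_is_constant(self):
        df = generate_curve_data(
            "expdecay", {"k": 0.0, "t": 1.0, "tg_theta": 7.0}, [1, 2, 3, 4]
        )
        assert (df["n"] == 7.0).all()

    def test_residual_sd_matches_requested_noise(self):
        k, gamma, sd = 1000.0, 0.3, 2.0
        df = generate_curve_data(
            "heap", {"k": k, "gamma": gamma}, range(1, 10001), noise_sd=sd, seed=11
        )
        resid = df["n"] - k * df["N"].to_numpy(float) ** gamma
        assert np.std(resid) == pytest.approx(sd, rel=0.05)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            generate_curve_data("heap", {"k": 1, "gamma": 0}, [1, 2], noise_sd=-1)
        with pytest.raises(ValueError):
            generate_curve_data("heap", {"k": 1, "gamma": 0}, [])
        with pytest.raises(ValueError):
            generate_curve_data("heap", {"k": 1, "gamma": 0}, [2, 1])
        with pytest.raises(ValueError):
            generate_curve_data("nope", {}, [1, 2])


class TestProteinFamilies:
    def test_zero_rate_gives_identical_family_members(self):
        spec = ProteinFamilySpec(family_sizes=(4,), substitution_rate=0.0, seed=3)
        records, truth = generate_protein_families(spec)
        seqs = {str(r.seq) for r in records}
        assert len(seqs) == 1

    def test_record_and_family_bookkeeping(self):
        spec = ProteinFamilySpec(family_sizes=(3, 2), seed=1)
        records, truth = generate_protein_families(spec)
        assert len(records) == 5
        assert truth["family_id"].nunique() == 2
        assert truth["protein_id"].is_unique
        # member j of each family sits in genome j
        assert truth["genome_id"].nunique() == 3

    def test_same_seed_reproduces_sequences(self):
        spec = ProteinFamilySpec(family_sizes=(3, 3), seed=9)
        r1, _ = generate_protein_families(spec)
        r2, _ = generate_protein_families(spec)
        assert [str(a.seq) for a in r1] == [str(b.seq) for b in r2]

    def test_substitution_rate_reflected_in_divergence(self):
        rate = 0.1
        spec = ProteinFamilySpec(
            family_sizes=(200,), seed_length=300, substitution_rate=rate, seed=5
        )
        records, _ = generate_protein_families(spec)
        # all members derive from one seed; average per-site difference from
        # the consensus is close to rate * 19/20 (a substitution can pick any
        # non-identical residue, so observed != seed at rate exactly)
        seqs = np.array([list(str(r.seq)) for r in records])
        consensus = pd.DataFrame(seqs).mode().iloc[0].to_numpy()
        diff = (seqs != consensus).mean()
        assert diff == pytest.approx(rate, rel=0.15)

    def test_empty_family_sizes_rejected(self):
        with pytest.raises(ValueError):
            ProteinFamilySpec(family_sizes=())

    def test_fasta_written_one_file_per_genome(self, tmp_path):
        spec = ProteinFamilySpec(family_sizes=(3, 2), seed=1)
        records, truth = generate_protein_families(spec)
        paths = write_genome_fastas(records, tmp_path)
        assert sorted(p.stem for p in paths) == sorted(truth["genome_id"].unique())
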